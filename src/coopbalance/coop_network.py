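"""Sparse genus co-abundance network and cooperatives (coops).

The network is inferred by Meinshausen-Buhlmann neighborhood selection on
clr abundances: each genus is lasso-regressed on all others along a
geometric lambda path (10 values down to 0.2 * lambda_max), edges combined
with the OR rule. The penalty is chosen by StARS-style stability over
random 80% subsamples, and only edges reproduced in >= 80% of subsamples
are kept (edge weight = selection frequency). Cooperatives are Louvain
communities of the resulting stability-weighted graph.
"""

from __future__ import annotations

import zlib

import networkx as nx
import numpy as np
from sklearn.linear_model import lasso_path

from .datatypes import (
    AnalysisConfig,
    Balance,
    ClrMatrix,
    CoopPartition,
    CountTable,
)


def filter_genera(
    t: CountTable, min_reads: int = 20, min_samples: int = 10
) -> CountTable:
    """Keep genera with count > min_reads in > min_samples samples (strict)."""
    n_over = (t.counts > min_reads).sum(axis=0)
    keep = [tax for tax, k in zip(t.taxon_ids, n_over) if k > min_samples]
    if not keep:
        raise ValueError("no genera survive the abundance filter")
    return t.select_taxa(keep)


def _lambda_path(X: np.ndarray, n_lambda: int, lambda_min: float) -> np.ndarray:
    """Geometric path from lambda_max (empty model) to lambda_min*lambda_max.

    lambda_max is the smallest penalty at which every neighborhood is empty:
    the largest absolute pairwise correlation (columns are standardized and
    the lasso objective is 1/(2n)||y - Xw||^2 + lambda ||w||_1).
    """
    n = X.shape[0]
    corr = np.abs(X.T @ X / n)
    np.fill_diagonal(corr, 0.0)
    lam_max = float(corr.max())
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lambda_min * lam_max, n_lambda)


def _neighborhood_adjacency(X: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """OR-rule adjacency per lambda from per-node lasso paths.

    Returns a boolean array (n_lambda, d, d), symmetric with zero diagonal.
    """
    n, d = X.shape
    adj = np.zeros((lambdas.size, d, d), dtype=bool)
    others = np.arange(d)
    for j in range(d):
        mask = others != j
        _, coefs, _ = lasso_path(X[:, mask], X[:, j], alphas=lambdas)
        nz = coefs != 0  # (d-1, n_lambda)
        adj[:, j, mask] |= nz.T
    adj |= adj.transpose(0, 2, 1)  # OR rule
    return adj


def infer_network(c: ClrMatrix, config: AnalysisConfig | None = None) -> nx.Graph:
    """Stability-selected co-abundance graph on clr columns.

    Subsamples are drawn deterministically from ``config.seed`` after
    sorting samples by id, so the graph is invariant to input sample order.
    """
    config = config or AnalysisConfig()
    n = len(c.sample_ids)
    if n < 30:
        raise ValueError(f"network inference needs >= 30 samples, got {n}")
    order = np.argsort(np.array(c.sample_ids))
    X = c.values[order]
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    d = X.shape[1]
    lambdas = _lambda_path(X, config.n_lambda, config.lambda_min)

    rng = np.random.default_rng([config.seed, zlib.crc32(b"network")])
    n_sub = max(2, int(round(config.subsample_fraction * n)))
    freq = np.zeros((config.n_lambda, d, d))
    for _ in range(config.n_subsamples):
        take = rng.choice(n, size=n_sub, replace=False)
        Xs = X[take]
        Xs = (Xs - Xs.mean(axis=0)) / Xs.std(axis=0, ddof=0)
        freq += _neighborhood_adjacency(Xs, lambdas)
    freq /= config.n_subsamples

    # StARS: edge-wise instability 2*theta*(1-theta) averaged over all pairs,
    # monotonized along decreasing lambda; smallest lambda still stable wins.
    iu = np.triu_indices(d, k=1)
    instability = (2 * freq * (1 - freq))[:, iu[0], iu[1]].mean(axis=1)
    monotone = np.maximum.accumulate(instability)  # lambdas descend along axis 0
    stable = np.flatnonzero(monotone <= config.stars_beta)
    lam_idx = int(stable[-1]) if stable.size else 0

    g = nx.Graph()
    g.add_nodes_from(c.taxon_ids)
    sel = freq[lam_idx]
    for a, b in zip(*np.nonzero(np.triu(sel >= config.stability_threshold, k=1))):
        g.add_edge(c.taxon_ids[a], c.taxon_ids[b], stability=float(sel[a, b]))
    g.graph["lambda"] = float(lambdas[lam_idx])
    g.graph["lambda_index"] = lam_idx
    g.graph["instability"] = float(instability[lam_idx])
    return g


def louvain_coops(
    g: nx.Graph,
    mean_abundance: dict[str, float] | None = None,
    config: AnalysisConfig | None = None,
) -> CoopPartition:
    """Louvain communities of the stability-weighted graph.

    Louvain is restarted ``louvain_restarts`` times with derived seeds and
    the best-modularity partition kept. Single-node communities are
    reported as singletons, not coops. Coops are named after their most
    abundant member genus ("<Genus>-coop"), falling back to the
    alphabetically first member when no abundances are given.
    """
    config = config or AnalysisConfig()
    universe = sorted(g.nodes)
    if g.number_of_edges() == 0:
        return CoopPartition({}, set(universe), universe, graph=g)
    best_mod, best_parts = -np.inf, None
    for r in range(config.louvain_restarts):
        parts = nx.community.louvain_communities(
            g, weight="stability", seed=config.seed * 1000 + r
        )
        mod = nx.community.modularity(g, parts, weight="stability")
        if mod > best_mod:
            best_mod, best_parts = mod, parts
    communities: dict[str, set[str]] = {}
    singletons: set[str] = set()
    named = []
    for part in best_parts:
        if len(part) < 2:
            singletons.update(part)
            continue
        if mean_abundance:
            head = max(sorted(part), key=lambda t: mean_abundance.get(t, 0.0))
        else:
            head = min(part)
        named.append((head, part))
    seen: dict[str, int] = {}
    for head, part in sorted(named, key=lambda x: (x[0], sorted(x[1]))):
        k = seen.get(head, 0)
        seen[head] = k + 1
        name = f"{head}-coop" if k == 0 else f"{head}-coop{k + 1}"
        communities[name] = set(part)
    return CoopPartition(
        communities,
        singletons,
        universe,
        graph=g,
        params={
            "n_subsamples": config.n_subsamples,
            "n_lambda": config.n_lambda,
            "lambda_min": config.lambda_min,
            "stability_threshold": config.stability_threshold,
            "modularity": float(best_mod),
        },
    )


def coop_balance(part: CoopPartition, coop_id: str) -> Balance:
    """Balance with the coop's genera over all other filtered genera."""
    if coop_id not in part.communities:
        raise KeyError(f"unknown coop {coop_id!r}")
    members = part.communities[coop_id]
    rest = [t for t in part.universe if t not in members]
    if not rest:
        raise ValueError("coop covers the whole genus universe (empty denominator)")
    return Balance(tuple(sorted(members)), tuple(rest))
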