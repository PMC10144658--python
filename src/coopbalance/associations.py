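"""Statistical screens: parameter de-duplication, alpha/beta diversity
tests, coop-balance and per-taxon clr linear models, and BH-FDR control.

One permutation engine serves both PERMANOVA (categorical factors) and
distance-based redundancy analysis (continuous factors): the factor is
coded into a model matrix, the Gower-centred distance matrix is projected
through its hat matrix, and the pseudo-F statistic is compared with its
permutation distribution.
"""

from __future__ import annotations

import logging
import zlib
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .composition import balance_values
from .coop_network import coop_balance
from .datatypes import (
    AssociationResult,
    ClrMatrix,
    CoopPartition,
    DiversityTable,
    ParameterScreen,
    SampleMetadata,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# parameter de-duplication


def dedup_parameters(
    m: SampleMetadata, group: str, rho: float = 0.8
) -> ParameterScreen:
    """Collapse clusters of highly correlated parameters to one representative.

    Parameters within the group are linked when |Spearman rho| > ``rho``
    over pairwise-complete observations; connected components form
    clusters; the representative is the member with fewest missing values
    (ties broken lexicographically).
    """
    params = m.parameters_in_group(group)
    if not params:
        raise ValueError(f"no parameters in group {group!r}")
    X = m.parameters[params]
    k = len(params)
    adj = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            pair = X.iloc[:, [i, j]].dropna()
            if len(pair) < 3:
                continue
            r = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1]).statistic
            if np.isfinite(r) and abs(r) > rho:
                adj[i, j] = adj[j, i] = True
    # connected components by union-find
    parent = list(range(k))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(k):
        for j in range(i + 1, k):
            if adj[i, j]:
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(k):
        clusters.setdefault(find(i), []).append(i)
    missing = X.isna().sum()
    retained, dropped = [], {}
    for members in clusters.values():
        names = sorted(params[i] for i in members)
        rep = min(names, key=lambda p: (missing[p], p))
        retained.append(rep)
        for p in names:
            if p != rep:
                dropped[p] = rep
    return ParameterScreen(group, sorted(retained), dropped)


# ---------------------------------------------------------------------------
# alpha diversity


def alpha_assoc(
    div: DiversityTable,
    factor: pd.Series,
    metric: str = "shannon",
    factor_name: str | None = None,
    parameter_group: str = "",
) -> AssociationResult:
    """Univariate linear model of an alpha-diversity metric on a factor.

    Continuous factors give an OLS slope and t-test p; categorical factors
    give a one-way ANOVA F and p.
    """
    y = div.series(metric).loc[div.sample_ids]
    factor = factor.loc[div.sample_ids]
    factor_name = factor_name or str(factor.name or "factor")
    if pd.api.types.is_numeric_dtype(factor):
        pair = pd.DataFrame({"y": y, "x": factor.astype(float)}).dropna()
        n = len(pair)
        if n < 10:
            raise ValueError(f"need >= 10 complete cases, got {n}")
        if pair["x"].nunique() == 1:
            raise ValueError("constant factor")
        fit = stats.linregress(pair["x"], pair["y"])
        return AssociationResult(
            metric, "alpha", factor_name, parameter_group,
            float(fit.slope), float(fit.rvalue**2), float(fit.pvalue), None, n,
        )
    pair = pd.DataFrame({"y": y, "g": factor}).dropna()
    n = len(pair)
    groups = [v["y"].to_numpy() for _, v in pair.groupby("g", observed=True)]
    if len(groups) < 2:
        raise ValueError("constant factor")
    f, p = stats.f_oneway(*groups)
    ss_between = sum(len(g) * (g.mean() - pair["y"].mean()) ** 2 for g in groups)
    ss_total = ((pair["y"] - pair["y"].mean()) ** 2).sum()
    r2 = float(ss_between / ss_total) if ss_total > 0 else 0.0
    return AssociationResult(
        metric, "alpha", factor_name, parameter_group, float(f), r2, float(p), None, n
    )


# ---------------------------------------------------------------------------
# beta diversity: PERMANOVA / dbRDA engine


def _model_matrix(factor: np.ndarray) -> np.ndarray:
    """Dummy-code a categorical factor or center a continuous one (no intercept
    column: the Gower-centred matrix already absorbs it)."""
    if np.issubdtype(np.asarray(factor).dtype, np.number):
        x = np.asarray(factor, dtype=float)
        return (x - x.mean())[:, None]
    levels = sorted(set(factor))
    if len(levels) < 2:
        raise ValueError("constant factor")
    X = np.column_stack([(factor == lev).astype(float) for lev in levels[1:]])
    return X - X.mean(axis=0, keepdims=True)


def permutation_beta_test(
    d: pd.DataFrame,
    factor: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
    factor_name: str | None = None,
    parameter_group: str = "",
) -> AssociationResult:
    """Pseudo-F permutation test of a factor against a distance matrix.

    PERMANOVA for categorical factors and dbRDA for continuous ones share
    this engine: with G the Gower-centred -D^2/2 matrix and H the hat
    matrix of the factor's model matrix, SS_model = tr(HGH),
    R^2 = SS_model / tr(G), and F = (SS_model/df_m) / (SS_res/df_r). The
    p-value uses the (1 + #{F_perm >= F}) / (1 + n_perm) estimator over
    random relabelings.
    """
    factor = factor.loc[d.index]
    factor_name = factor_name or str(factor.name or "factor")
    mask = factor.notna().to_numpy()
    ids = [s for s, ok in zip(d.index, mask) if ok]
    n = len(ids)
    if n < 10:
        raise ValueError(f"need >= 10 complete cases, got {n}")
    D = d.loc[ids, ids].to_numpy()
    vals = factor.loc[ids].to_numpy()
    X = _model_matrix(vals)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular model matrix")
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    ss_total = float(np.trace(G))
    df_m = X.shape[1]
    df_r = n - df_m - 1
    Q, _ = np.linalg.qr(X)

    rng = np.random.default_rng([seed, zlib.crc32(factor_name.encode())])
    perms = np.vstack(
        [np.arange(n)] + [rng.permutation(n) for _ in range(n_perm)]
    )
    # tr(H G H) = sum_k q_k' G q_k, with rows of Q permuted per relabeling
    Qp = Q[perms, :]                          # (n_perm+1, n, df_m)
    GQ = np.einsum("ij,pjk->pik", G, Qp)
    ss_model = np.einsum("pik,pik->p", Qp, GQ)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stats = (ss_model / df_m) / ((ss_total - ss_model) / df_r)
    f_stats = np.nan_to_num(f_stats, nan=np.inf, posinf=np.inf)
    f_obs = f_stats[0]
    p = float((f_stats >= f_obs - 1e-12).sum() / (1 + n_perm))
    return AssociationResult(
        "aitchison", "beta", factor_name, parameter_group,
        float(f_obs), float(ss_model[0] / ss_total), p, None, n,
    )


# ---------------------------------------------------------------------------
# coop balances and per-taxon clr screens


def coop_balance_assoc(
    c: ClrMatrix,
    part: CoopPartition,
    factor: pd.Series,
    factor_name: str | None = None,
    parameter_group: str = "",
) -> list[AssociationResult]:
    """Standardized linear model of each coop balance against a factor.

    Both the balance values and the factor are standardized, so the slope
    is the Pearson correlation — a unitless coefficient comparable across
    factors and coops.
    """
    factor = factor.loc[c.sample_ids]
    factor_name = factor_name or str(factor.name or "factor")
    numeric = pd.api.types.is_numeric_dtype(factor)
    out = []
    for coop in part.coop_names:
        bal = coop_balance(part, coop)
        y = balance_values(c, bal)
        pair = pd.DataFrame({"b": y, "x": factor.to_numpy()}).dropna()
        n = len(pair)
        if n < 3 or pair["b"].std() == 0:
            logger.warning("coop %s skipped (zero-variance balance or n<3)", coop)
            continue
        if numeric:
            x = pair["x"].astype(float)
            if x.std() == 0:
                raise ValueError("constant factor")
            zb = (pair["b"] - pair["b"].mean()) / pair["b"].std(ddof=1)
            zx = (x - x.mean()) / x.std(ddof=1)
            fit = stats.linregress(zb, zx)
            stat, r2, p = float(fit.slope), float(fit.rvalue**2), float(fit.pvalue)
        else:
            stat, r2, p = _anova(pair["b"], pair["x"])
        out.append(
            AssociationResult(coop, "coop", factor_name, parameter_group,
                              stat, r2, p, None, n)
        )
    return out


def _anova(y: pd.Series, g: pd.Series) -> tuple[float, float, float]:
    """One-way ANOVA: F, eta-squared, p."""
    groups = [v.to_numpy() for _, v in y.groupby(g, observed=True)]
    if len(groups) < 2:
        raise ValueError("constant factor")
    f, p = stats.f_oneway(*groups)
    ss_b = sum(len(v) * (v.mean() - y.mean()) ** 2 for v in groups)
    ss_t = ((y - y.mean()) ** 2).sum()
    return float(f), float(ss_b / ss_t) if ss_t > 0 else 0.0, float(p)


def taxon_clr_assoc(
    c: ClrMatrix,
    factor: pd.Series,
    factor_name: str | None = None,
    parameter_group: str = "",
    rank: str = "",
) -> list[AssociationResult]:
    """Per-taxon univariate linear model of clr abundance on a factor,
    BH-corrected within the screen. Categorical factors use one-way ANOVA."""
    factor = factor.loc[c.sample_ids]
    factor_name = factor_name or str(factor.name or "factor")
    feature_prefix = f"{rank}:" if rank else ""
    if not pd.api.types.is_numeric_dtype(factor):
        mask = factor.notna().to_numpy()
        g = factor[mask]
        n = int(mask.sum())
        results = []
        for j, tax in enumerate(c.taxon_ids):
            f, r2, p = _anova(pd.Series(c.values[mask, j], index=g.index), g)
            results.append(
                AssociationResult(
                    f"{feature_prefix}{tax}", "taxon_clr", factor_name,
                    parameter_group, f, r2, p, None, n,
                )
            )
        qs = bh_fdr([r.p for r in results])
        for r_, q_ in zip(results, qs):
            r_.q = float(q_)
        return results
    x = factor.astype(float).to_numpy()
    mask = np.isfinite(x)
    n = int(mask.sum())
    if n < 10:
        raise ValueError(f"need >= 10 complete cases, got {n}")
    X = c.values[mask]
    xz = x[mask]
    if xz.std() == 0:
        raise ValueError("constant factor")
    xc = xz - xz.mean()
    Yc = X - X.mean(axis=0, keepdims=True)
    sxx = float(xc @ xc)
    slopes = Yc.T @ xc / sxx
    resid = Yc - np.outer(xc, slopes)
    dof = n - 2
    se = np.sqrt((resid**2).sum(axis=0) / dof / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, slopes / se, 0.0)
    pvals = 2 * stats.t.sf(np.abs(tstat), dof)
    sy = Yc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sy > 0, (slopes * xz.std(ddof=1) / sy) ** 2, 0.0)
    qvals = bh_fdr(pvals)
    return [
        AssociationResult(
            f"{feature_prefix}{tax}", "taxon_clr", factor_name, parameter_group,
            float(slopes[j]), float(r2[j]), float(pvals[j]), float(qvals[j]), n,
        )
        for j, tax in enumerate(c.taxon_ids)
    ]


# ---------------------------------------------------------------------------
# multiple testing


def bh_fdr(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, clipped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_fdr(results: list[AssociationResult]) -> list[AssociationResult]:
    """BH within each parameter-group x feature-family cell (in place)."""
    cells: dict[tuple[str, str], list[AssociationResult]] = {}
    for r in results:
        cells.setdefault((r.parameter_group, r.feature_type), []).append(r)
    for rs in cells.values():
        qs = bh_fdr([r.p for r in rs])
        for r, q in zip(rs, qs):
            r.q = float(q)
    return results
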