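"""Compositional transforms, diversity, rarefaction and ordination.

All statistics downstream operate in Aitchison geometry: counts are
pseudocounted (zeros -> 0.5 by default), closed to proportions and
centred-log-ratio (clr) transformed, after which Euclidean machinery is
valid. Beta diversity is the Aitchison distance (Euclidean on clr rows).
"""

from __future__ import annotations

import logging
import zlib

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity import alpha as skbio_alpha
from skbio.stats.ordination import pcoa as skbio_pcoa

from .datatypes import Balance, ClrMatrix, CountTable, DiversityTable, OrdinationResult

logger = logging.getLogger(__name__)


def _sample_rng(seed: int, sample_id: str, stage: str) -> np.random.Generator:
    """Generator keyed to (seed, stage, sample id): stable under reordering."""
    return np.random.default_rng(
        [seed, zlib.crc32(stage.encode()), zlib.crc32(sample_id.encode())]
    )


def rarefy(t: CountTable, depth: int | str, seed: int = 0) -> CountTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    ``depth="min"`` resolves to the smallest per-sample total. Uses the
    multivariate hypergeometric draw, keyed per sample id so the result does
    not depend on sample order.
    """
    sums = t.sample_sums()
    if depth == "min":
        depth = int(sums.min())
    depth = int(depth)
    short = [s for s, tot in zip(t.sample_ids, sums) if tot < depth]
    if short:
        raise ValueError(
            f"rarefaction depth {depth} exceeds totals of samples: {short}"
        )
    out = np.empty_like(t.counts)
    for i, sid in enumerate(t.sample_ids):
        row = t.counts[i]
        if row.sum() == depth:
            out[i] = row
        else:
            rng = _sample_rng(seed, sid, "rarefy")
            out[i] = rng.multivariate_hypergeometric(row, depth, method="marginals")
    rarefied = CountTable(list(t.sample_ids), list(t.taxon_ids), out, t.lineages)
    return rarefied


def clr_transform(t: CountTable, pseudocount: float = 0.5) -> ClrMatrix:
    """Centred log-ratio transform with zero replacement.

    Zero counts are replaced by ``pseudocount`` *before* closure, rows are
    closed to proportions, logged, and the row log geometric mean is
    subtracted, giving sum-zero rows.
    """
    if not pseudocount > 0:
        raise ValueError("pseudocount must be positive")
    x = t.counts.astype(float)
    if (x.sum(axis=1) == 0).any():
        bad = [s for s, tot in zip(t.sample_ids, x.sum(axis=1)) if tot == 0]
        raise ValueError(f"all-zero samples cannot be clr-transformed: {bad}")
    x[x == 0] = pseudocount
    props = x / x.sum(axis=1, keepdims=True)
    logp = np.log(props)
    clr = logp - logp.mean(axis=1, keepdims=True)
    return ClrMatrix(list(t.sample_ids), list(t.taxon_ids), clr)


def clr_from_proportions(props: np.ndarray) -> np.ndarray:
    """clr of strictly positive composition rows (no pseudocounting)."""
    logp = np.log(np.asarray(props, dtype=float))
    return logp - logp.mean(axis=-1, keepdims=True)


def aitchison_distance(c: ClrMatrix) -> pd.DataFrame:
    """Pairwise Euclidean distance between clr rows (the Aitchison metric)."""
    d = squareform(pdist(c.values, metric="euclidean"))
    return pd.DataFrame(d, index=c.sample_ids, columns=c.sample_ids)


def pcoa_biplot(
    d: pd.DataFrame, c: ClrMatrix, n_axes: int = 2
) -> OrdinationResult:
    """Classical metric scaling of a distance matrix with clr biplot arrows.

    Arrows are the covariances of each clr taxon with each retained axis;
    taxa rank by summed squared covariance (arrow length ~ variance the
    taxon explains in the retained plane).
    """
    if list(d.index) != c.sample_ids:
        raise ValueError("distance matrix and clr matrix sample order differ")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = skbio_pcoa(DistanceMatrix(d.to_numpy(), ids=list(d.index)))
    eigvals = res.eigvals.to_numpy()
    pos = eigvals[eigvals > 0]
    neg = eigvals[eigvals < 0]
    if neg.size and pos.size and (-neg.min()) > pos[:n_axes].min():
        raise ValueError(
            "negative eigenvalues exceed retained positive ones; "
            "distance matrix is not Euclidean-embeddable"
        )
    coords = res.samples.to_numpy()[:, :n_axes]
    # deterministic sign convention: largest-|coordinate| sample positive
    for k in range(coords.shape[1]):
        j = int(np.argmax(np.abs(coords[:, k])))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    total = np.clip(eigvals, 0, None).sum()
    proportion = np.clip(eigvals[:n_axes], 0, None) / total if total > 0 else np.zeros(n_axes)
    n = len(c.sample_ids)
    clr_centered = c.values - c.values.mean(axis=0, keepdims=True)
    scores_centered = coords - coords.mean(axis=0, keepdims=True)
    arrows = clr_centered.T @ scores_centered / (n - 1)
    return OrdinationResult(
        sample_ids=list(c.sample_ids),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=proportion,
        taxon_ids=list(c.taxon_ids),
        arrows=arrows,
    )


def shannon(t: CountTable, base: float = 2, rarefaction_depth: int | None = None) -> DiversityTable:
    """Per-sample Shannon index (default base 2, i.e. bits)."""
    _warn_if_unrarefied(t)
    vals = np.array(
        [skbio_alpha.shannon(row, base=base) for row in t.counts], dtype=float
    )
    return DiversityTable(
        list(t.sample_ids),
        pd.DataFrame({"shannon": vals}, index=t.sample_ids),
        rarefaction_depth,
    )


def chao1(t: CountTable, rarefaction_depth: int | None = None) -> DiversityTable:
    """Per-sample bias-corrected Chao1 richness: S_obs + F1(F1-1)/(2(F2+1))."""
    _warn_if_unrarefied(t)
    vals = np.array(
        [skbio_alpha.chao1(row, bias_corrected=True) for row in t.counts], dtype=float
    )
    return DiversityTable(
        list(t.sample_ids),
        pd.DataFrame({"chao1": vals}, index=t.sample_ids),
        rarefaction_depth,
    )


def _warn_if_unrarefied(t: CountTable) -> None:
    sums = t.sample_sums()
    if sums.size and sums.min() != sums.max():
        logger.warning(
            "alpha diversity on an unrarefied table (depths %d..%d); "
            "rarefy first for comparability", sums.min(), sums.max()
        )


def balance_values(c: ClrMatrix, bal: Balance, method: str = "dot") -> np.ndarray:
    """Per-sample balance value.

    ``method="dot"`` computes b . clr_row with the normalized coefficient
    vector; ``method="meanlog"`` computes sqrt(pq/(p+q)) * (mean clr over
    the numerator - mean clr over the denominator). The two agree to 1e-9.
    """
    if method == "dot":
        b = bal.coefficients(c.taxon_ids)
        return c.values @ b
    if method == "meanlog":
        idx = {t: j for j, t in enumerate(c.taxon_ids)}
        p_idx = [idx[t] for t in bal.numerator]
        q_idx = [idx[t] for t in bal.denominator]
        p, q = bal.p, bal.q
        scale = np.sqrt(p * q / (p + q))
        return scale * (
            c.values[:, p_idx].mean(axis=1) - c.values[:, q_idx].mean(axis=1)
        )
    raise ValueError(f"unknown method {method!r}")
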