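"""Nearest-balance selection and its cross-validated reproducible form.

Given a factor, its association with the microbiome is summarized as a
per-taxon direction vector in clr space (clr-factor covariances, or the
group mean difference for a two-level factor). The *nearest balance* is the
balance whose coefficient vector has maximal cosine similarity with that
direction. Reproducibility is assessed by re-identifying the balance on
100 random half-samples and keeping taxa assigned to one side in more than
90 of the iterations.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import AnalysisConfig, Balance, ClrMatrix, ReproducibleBalance


@dataclass
class AssociationDirection:
    """Per-taxon association vector in clr space (sum-zero)."""

    taxon_ids: list[str]
    v: np.ndarray
    factor: str
    n: int

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if abs(self.v.sum()) > 1e-9 * max(1.0, np.abs(self.v).max()):
            raise ValueError("association direction must sum to zero")


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("constant factor has no association direction")
    return (x - x.mean()) / sd


def association_direction(
    c: ClrMatrix, factor: pd.Series | np.ndarray, name: str = "factor"
) -> AssociationDirection:
    """clr-factor covariance vector (complete cases only).

    For a numeric factor, v_j = cov(clr_j, standardized factor). For a
    two-level categorical factor, v is the difference of group mean clr
    vectors (second level minus first, levels sorted). Either choice only
    matters up to scale: the nearest-balance search is scale-invariant.
    """
    if isinstance(factor, pd.Series):
        factor = factor.loc[c.sample_ids]
    values = np.asarray(factor)
    numeric = np.issubdtype(values.dtype, np.number)
    if numeric:
        mask = np.isfinite(values.astype(float))
    else:
        mask = np.array([v is not None and v == v for v in values])
    X = c.values[mask]
    f = values[mask]
    n = int(mask.sum())
    if n < 10:
        raise ValueError(f"need >= 10 complete cases, got {n}")
    if numeric:
        z = _standardize(f.astype(float))
        Xc = X - X.mean(axis=0, keepdims=True)
        v = Xc.T @ z / (n - 1)
    else:
        levels = sorted(set(f))
        if len(levels) != 2:
            raise ValueError(
                f"categorical factor must have exactly 2 levels, got {levels}"
            )
        v = X[f == levels[1]].mean(axis=0) - X[f == levels[0]].mean(axis=0)
    return AssociationDirection(list(c.taxon_ids), v, name, n)


# ---------------------------------------------------------------------------
# nearest-balance search


def _sorted_order(direction: AssociationDirection) -> np.ndarray:
    """Indices sorting v descending, ties by taxon id (lexicographic)."""
    ids = np.array(direction.taxon_ids)
    return np.lexsort((ids, -direction.v))


def nearest_balance(direction: AssociationDirection) -> Balance:
    """Balance maximizing cosine similarity with the direction vector.

    Components are sorted descending; for every (p, q) the numerator is the
    top-p set and the denominator the bottom-q set. This restriction is
    exact: balance coefficients are constant within each side, so for fixed
    side sizes the cosine is maximized by the extreme components.
    """
    v = direction.v
    n = v.size
    if n < 2 or np.ptp(v) == 0:
        raise ValueError("direction must have >= 2 distinct components")
    order = _sorted_order(direction)
    vs = v[order]
    csum = np.concatenate([[0.0], np.cumsum(vs)])
    total = csum[-1]
    norm_v = float(np.linalg.norm(v))
    best = (-np.inf, None)
    for p in range(1, n):
        s_p = csum[p]
        for q in range(1, n - p + 1):
            s_q = total - csum[n - q]
            dot = (
                np.sqrt(q / (p * (p + q))) * s_p
                - np.sqrt(p / (q * (p + q))) * s_q
            )
            if dot > best[0]:
                best = (dot, (p, q))
    p, q = best[1]
    ids = np.array(direction.taxon_ids)
    return Balance(tuple(ids[order[:p]]), tuple(ids[order[n - q:]]))


def balance_cosine(direction: AssociationDirection, bal: Balance) -> float:
    b = bal.coefficients(direction.taxon_ids)
    return float(b @ direction.v / np.linalg.norm(direction.v))


def brute_force_nearest_balance(direction: AssociationDirection) -> Balance:
    """Exhaustive oracle over all 3^n assignments to {num, den, out}.

    Only feasible for n <= 12. Among equal-cosine optima, the assignment
    with smallest (p, q) over the descending-sorted components is kept —
    the same preference order as the fast search.
    """
    v = direction.v
    n = v.size
    if n > 12:
        raise ValueError("brute force limited to n <= 12 taxa")
    order = _sorted_order(direction)
    vs = v[order]
    norm_v = np.linalg.norm(v)
    # all assignments as base-3 digits: 0 = out, 1 = numerator, 2 = denominator
    codes = np.arange(3 ** n)
    digits = (codes[:, None] // 3 ** np.arange(n)[None, :]) % 3
    in_num = digits == 1
    in_den = digits == 2
    p = in_num.sum(axis=1)
    q = in_den.sum(axis=1)
    valid = (p >= 1) & (q >= 1)
    s_p = in_num @ vs
    s_q = in_den @ vs
    with np.errstate(divide="ignore", invalid="ignore"):
        dot = np.where(
            valid,
            np.sqrt(q / (p * (p + q))) * s_p - np.sqrt(p / (q * (p + q))) * s_q,
            -np.inf,
        )
    best = dot.max()
    cand = np.flatnonzero(dot >= best - 1e-12 * max(1.0, abs(best)))
    # tie-break: smallest (p, q), then lexicographically earliest membership
    key = sorted(
        cand,
        key=lambda i: (
            p[i], q[i],
            tuple((~in_num[i]).astype(int)), tuple((~in_den[i]).astype(int)),
        ),
    )
    i = key[0]
    ids = np.array(direction.taxon_ids)[order]
    return Balance(tuple(ids[in_num[i]]), tuple(ids[in_den[i]]))


# ---------------------------------------------------------------------------
# cross-validated reproducible balance


def _nominal_significance(X: np.ndarray, f: np.ndarray, alpha: float) -> np.ndarray:
    """Per-taxon two-sided p < alpha for the clr-factor correlation."""
    from scipy import stats

    n = len(f)
    z = _standardize(f.astype(float))
    Xc = X - X.mean(axis=0, keepdims=True)
    sx = X.std(axis=0, ddof=1)
    cov = Xc.T @ z / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(sx > 0, cov / sx, 0.0)
    df = n - 2
    t = r * np.sqrt(df / np.clip(1 - r**2, 1e-12, None))
    p = 2 * stats.t.sf(np.abs(t), df)
    return p < alpha


def cross_validated_balance(
    c: ClrMatrix,
    factor: pd.Series | np.ndarray,
    config: AnalysisConfig | None = None,
    name: str = "factor",
) -> ReproducibleBalance:
    """Half-sample cross-validation of the nearest balance.

    ``cv_iterations`` random half-subsamples (floor(n/2), without
    replacement) each yield a nearest balance; taxa assigned to the same
    side in more than ``cv_threshold`` iterations form the final balance.
    Returns an empty (flagged) result when no taxon is reproducible.

    A balance member is tallied only when its own clr-factor association
    is nominally significant in that iteration (two-sided p <
    ``cv_member_alpha``). Because half-subsamples overlap, the extreme
    components of the *full-sample* noise direction would otherwise stay
    on one side in nearly every iteration, and a null factor would still
    yield a non-empty "reproducible" balance; gating membership on
    per-iteration evidence makes reproducibility an actual filter while
    leaving genuinely associated taxa (whose per-iteration tests pass
    almost surely) untouched.
    """
    config = config or AnalysisConfig()
    if isinstance(factor, pd.Series):
        factor = factor.loc[c.sample_ids]
    values = np.asarray(factor, dtype=float)
    mask = np.isfinite(values)
    ids = [s for s, m in zip(c.sample_ids, mask) if m]
    sub = c.select_samples(ids)
    f = values[mask]
    n = len(ids)
    if n < 20:
        raise ValueError(f"cross-validation needs >= 20 complete cases, got {n}")
    rng = np.random.default_rng(
        [config.seed, zlib.crc32(b"cv_balance"), zlib.crc32(name.encode())]
    )
    half = n // 2
    num_counts = np.zeros(len(c.taxon_ids), dtype=int)
    den_counts = np.zeros(len(c.taxon_ids), dtype=int)
    col = {t: j for j, t in enumerate(c.taxon_ids)}
    for _ in range(config.cv_iterations):
        take = rng.choice(n, size=half, replace=False)
        sub_c = ClrMatrix(
            [ids[i] for i in take], list(c.taxon_ids), sub.values[take]
        )
        try:
            direction = association_direction(sub_c, f[take], name)
            bal = nearest_balance(direction)
        except ValueError:
            continue
        sig = _nominal_significance(sub_c.values, f[take], config.cv_member_alpha)
        for t in bal.numerator:
            if sig[col[t]]:
                num_counts[col[t]] += 1
        for t in bal.denominator:
            if sig[col[t]]:
                den_counts[col[t]] += 1
    full_direction = association_direction(sub, f, name)
    coeffs = pd.Series(full_direction.v, index=c.taxon_ids)
    num_final = [t for t in c.taxon_ids if num_counts[col[t]] > config.cv_threshold]
    den_final = [t for t in c.taxon_ids if den_counts[col[t]] > config.cv_threshold]
    balance = (
        Balance(tuple(num_final), tuple(den_final))
        if num_final and den_final
        else None
    )
    return ReproducibleBalance(
        factor=name,
        taxon_ids=list(c.taxon_ids),
        numerator_counts=num_counts,
        denominator_counts=den_counts,
        cv_iterations=config.cv_iterations,
        balance=balance,
        coefficients=coeffs,
        n=n,
    )
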