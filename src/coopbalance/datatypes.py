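"""Core data structures for compositional microbiome association analysis.

The analysis lives in Aitchison geometry: raw counts (`CountTable`) are
pseudocounted and centred-log-ratio transformed (`ClrMatrix`), and effects
are expressed as balances — normalized log-contrasts between two disjoint
taxon sets (`Balance`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Taxonomic ranks from coarsest to finest, as used in lineage maps.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


class ValidationError(ValueError):
    """Raised when a table or parameter violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dupes = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValidationError(f"duplicate {what} identifiers: {dupes}")


@dataclass
class CountTable:
    """Integer sample x taxon count matrix with per-taxon lineages.

    Parameters
    ----------
    sample_ids, taxon_ids
        Unique identifiers for rows and columns of ``counts``.
    counts
        Non-negative integer matrix of shape ``(n_samples, n_taxa)``.
    lineages
        Per-taxon mapping ``rank -> clade name`` (possibly partial; missing
        lower ranks mean the taxon is unclassified there).
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray
    lineages: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.taxon_ids, "taxon")
        c = np.asarray(self.counts)
        if c.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError(
                f"counts shape {c.shape} does not match "
                f"({len(self.sample_ids)}, {len(self.taxon_ids)})"
            )
        if not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)):
                raise ValidationError("counts must be integers")
            c = np.round(c).astype(np.int64)
        if (c < 0).any():
            raise ValidationError("counts must be non-negative")
        self.counts = c.astype(np.int64)
        # every taxon gets a lineage entry, possibly empty (fully unclassified)
        self.lineages = {t: dict(self.lineages.get(t, {})) for t in self.taxon_ids}

    # -- convenience -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(
            list(sample_ids), list(self.taxon_ids), self.counts[idx, :], self.lineages
        )

    def select_taxa(self, taxon_ids: Sequence[str]) -> "CountTable":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return CountTable(
            list(self.sample_ids),
            list(taxon_ids),
            self.counts[:, idx],
            {t: self.lineages[t] for t in taxon_ids},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.taxon_ids == other.taxon_ids
            and np.array_equal(self.counts, other.counts)
            and self.lineages == other.lineages
        )


@dataclass
class SampleMetadata:
    """Per-sample group label plus named continuous clinical parameters.

    ``parameters`` is a float DataFrame indexed by sample id; missing values
    are NaN. Each parameter belongs to exactly one parameter group (immune,
    cardiovascular, ...); parameters without a mapping fall in "ungrouped".
    """

    sample_ids: list[str]
    group_label: pd.Series
    parameters: pd.DataFrame
    parameter_groups: dict[str, str] = field(default_factory=dict)
    reference_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        self.group_label = pd.Series(self.group_label, index=self.sample_ids)
        self.parameters = self.parameters.astype(float).loc[self.sample_ids]
        for p in self.parameters.columns:
            self.parameter_groups.setdefault(p, "ungrouped")

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.parameter_groups.values()))

    def parameters_in_group(self, group: str) -> list[str]:
        return sorted(
            p for p, g in self.parameter_groups.items()
            if g == group and p in self.parameters.columns
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        ids = [str(s) for s in sample_ids]
        return SampleMetadata(
            ids,
            self.group_label.loc[ids],
            self.parameters.loc[ids],
            dict(self.parameter_groups),
            dict(self.reference_ranges),
        )


@dataclass
class AnalysisConfig:
    """Tunable knobs of the pipeline with study defaults.

    Defaults mirror the analysis protocol: pseudocount 0.5 before clr,
    rarefaction to the minimum sample depth, 100 half-sample iterations with
    a >90 reproducibility cut for the nearest balance, genus filter
    (>20 reads in >10 samples), 10 subsamples x 10 lambdas (min 0.2) for
    the co-abundance network, parameter de-duplication at |Spearman| > 0.8,
    999 permutations and BH-FDR at 0.05.
    """

    pseudocount: float = 0.5
    rarefaction_depth: int | str = "min"
    cv_iterations: int = 100
    cv_threshold: int = 90
    cv_member_alpha: float = 0.05
    dedup_rho: float = 0.8
    n_subsamples: int = 10
    n_lambda: int = 10
    lambda_min: float = 0.2
    subsample_fraction: float = 0.8
    stability_threshold: float = 0.8
    stars_beta: float = 0.01
    min_reads: int = 20
    min_samples: int = 10
    n_permutations: int = 999
    fdr_alpha: float = 0.05
    louvain_restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pseudocount", "cv_iterations", "cv_threshold", "dedup_rho",
            "n_subsamples", "n_lambda", "lambda_min", "min_reads",
            "min_samples", "n_permutations", "fdr_alpha",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if self.cv_threshold > self.cv_iterations:
            raise ValidationError("cv_threshold must not exceed cv_iterations")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class ClrMatrix:
    """Centred log-ratio transformed abundance matrix (rows sum to zero)."""

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError("clr values shape mismatch")
        if v.size and np.abs(v.sum(axis=1)).max() > 1e-9:
            raise ValidationError("clr rows must sum to zero")
        self.values = v

    def column(self, taxon_id: str) -> np.ndarray:
        return self.values[:, self.taxon_ids.index(taxon_id)]

    def select_samples(self, sample_ids: Sequence[str]) -> "ClrMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ClrMatrix(list(sample_ids), list(self.taxon_ids), self.values[idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)


@dataclass(frozen=True)
class Balance:
    """Normalized log-contrast between numerator set P and denominator set Q.

    The coefficient vector carries +sqrt(q/(p(p+q))) on P and
    -sqrt(p/(q(p+q))) on Q (p = |P|, q = |Q|), so it is unit-norm and
    sum-zero; the per-sample balance value is its dot product with the clr
    row, equivalently sqrt(pq/(p+q)) times the difference of mean logs.
    """

    numerator: tuple[str, ...]
    denominator: tuple[str, ...]

    def __post_init__(self) -> None:
        num = tuple(sorted(set(self.numerator)))
        den = tuple(sorted(set(self.denominator)))
        object.__setattr__(self, "numerator", num)
        object.__setattr__(self, "denominator", den)
        if not num or not den:
            raise ValidationError("balance needs non-empty numerator and denominator")
        if set(num) & set(den):
            raise ValidationError("numerator and denominator overlap")

    @property
    def p(self) -> int:
        return len(self.numerator)

    @property
    def q(self) -> int:
        return len(self.denominator)

    def coefficients(self, taxon_ids: Sequence[str]) -> np.ndarray:
        """Coefficient vector over ``taxon_ids`` (zero off the balance)."""
        missing = (set(self.numerator) | set(self.denominator)) - set(taxon_ids)
        if missing:
            raise ValidationError(f"balance taxa absent from table: {sorted(missing)}")
        p, q = self.p, self.q
        b = np.zeros(len(taxon_ids))
        pos = np.sqrt(q / (p * (p + q)))
        neg = -np.sqrt(p / (q * (p + q)))
        index = {t: j for j, t in enumerate(taxon_ids)}
        for t in self.numerator:
            b[index[t]] = pos
        for t in self.denominator:
            b[index[t]] = neg
        return b

    def flip(self) -> "Balance":
        return Balance(self.denominator, self.numerator)


@dataclass
class OrdinationResult:
    """Principal-coordinates embedding with taxon biplot arrows."""

    sample_ids: list[str]
    coordinates: np.ndarray           # (n_samples, n_axes)
    eigenvalues: np.ndarray           # all eigenvalues, non-increasing
    proportion_explained: np.ndarray  # per retained axis
    taxon_ids: list[str]
    arrows: np.ndarray                # (n_taxa, n_axes) covariance loadings

    def top_taxa(self, n: int = 10) -> list[str]:
        score = (self.arrows ** 2).sum(axis=1)
        order = np.argsort(-score, kind="stable")
        return [self.taxon_ids[j] for j in order[:n]]


@dataclass
class DiversityTable:
    """Per-sample alpha-diversity metrics computed at a fixed read depth."""

    sample_ids: list[str]
    metrics: pd.DataFrame
    rarefaction_depth: int | None = None

    def series(self, metric: str) -> pd.Series:
        return self.metrics[metric]


@dataclass
class AssociationResult:
    """One factor x microbiome-feature test with FDR annotation."""

    feature: str
    feature_type: str          # alpha | beta | coop | taxon_clr | nearest_balance
    factor: str
    parameter_group: str
    statistic: float           # linear coefficient or pseudo-F
    r2: float | None
    p: float
    q: float | None            # BH-adjusted, filled per screen
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValidationError(f"p-value {self.p} outside [0, 1]")


@dataclass
class CoopPartition:
    """Genus cooperatives: Louvain communities of the co-abundance graph."""

    communities: dict[str, set[str]]   # coop name -> genus set
    singletons: set[str]
    universe: list[str]                # all filtered genera (balance denominator pool)
    graph: object = None               # networkx graph with stability weights
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        members = [g for c in self.communities.values() for g in c]
        if len(members) != len(set(members)):
            raise ValidationError("coops must be disjoint")
        for name, c in self.communities.items():
            if len(c) < 2:
                raise ValidationError(f"coop {name} has fewer than 2 genera")

    @property
    def coop_names(self) -> list[str]:
        return sorted(self.communities)


@dataclass
class ReproducibleBalance:
    """Cross-validated nearest balance with per-taxon reproducibility tallies."""

    factor: str
    taxon_ids: list[str]
    numerator_counts: np.ndarray   # times assigned to numerator, out of cv_iterations
    denominator_counts: np.ndarray
    cv_iterations: int
    balance: Balance | None        # None when no taxon passes the threshold
    coefficients: pd.Series        # full-data association coefficients for display
    n: int

    @property
    def is_empty(self) -> bool:
        return self.balance is None

    def membership_table(self) -> pd.DataFrame:
        """Long table of final-balance members: side, reproducibility, coefficient."""
        rows = []
        if self.balance is not None:
            for side, taxa, counts in (
                ("numerator", self.balance.numerator, self.numerator_counts),
                ("denominator", self.balance.denominator, self.denominator_counts),
            ):
                for t in taxa:
                    j = self.taxon_ids.index(t)
                    rows.append(
                        {
                            "taxon": t,
                            "side": side,
                            "reproducibility": counts[j] / self.cv_iterations,
                            "coefficient": self.coefficients[t],
                        }
                    )
        return pd.DataFrame(rows, columns=["taxon", "side", "reproducibility", "coefficient"])


@dataclass
class ParameterScreen:
    """De-duplication outcome for one parameter group."""

    group: str
    retained: list[str]
    dropped: dict[str, str]    # dropped parameter -> retained representative

    def __post_init__(self) -> None:
        overlap = set(self.retained) & set(self.dropped)
        if overlap:
            raise ValidationError(f"parameters both retained and dropped: {sorted(overlap)}")
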