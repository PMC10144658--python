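"""Synthetic genus-level cohorts with planted, exportable ground truth.

The generator emulates a three-group stool-microbiome cohort (48/46/86
samples) of ~120 genera: latent log-abundances are multivariate normal
with block correlation inside planted "cooperative" genus blocks, factor
effects are added in clr space along a planted balance's coefficient
vector (beta per SD of the factor), and reads are drawn multinomially at a
per-sample depth uniform in [10459, 40000]. Clinical parameters come in
groups containing clusters of highly inter-correlated variables
(Spearman > 0.8) plus pure-noise parameters.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import Balance, CountTable, SampleMetadata


@dataclass
class PlantedEffect:
    """A factor acting on a balance: beta clr-units per SD of the factor."""

    factor: str
    numerator: tuple[int, ...]   # genus indices
    denominator: tuple[int, ...]
    beta: float

    def __post_init__(self) -> None:
        if set(self.numerator) & set(self.denominator):
            raise ValueError("planted numerator/denominator overlap")


@dataclass
class ParameterGroupSpec:
    """Cluster sizes (each cluster shares one latent variable) and noise count."""

    cluster_sizes: tuple[int, ...] = ()
    n_null: int = 0
    planted_factors: tuple[str, ...] = ()


def default_parameter_spec() -> dict[str, ParameterGroupSpec]:
    """Four parameter groups mirroring a deep-phenotyping panel:
    immune (18), cardiovascular (21), endothelial (5), metabolites (21)."""
    return {
        "immune": ParameterGroupSpec((3,), 14, ("lymphocytes_pct",)),
        "cardiovascular": ParameterGroupSpec((3, 2), 16),
        "endothelial": ParameterGroupSpec((2,), 3),
        "metabolites": ParameterGroupSpec((), 21),
    }


def default_coop_blocks(n_genera: int = 120) -> list[tuple[int, ...]]:
    """Four disjoint blocks of 5-15 genera at the head of the index range."""
    sizes = (10, 8, 12, 6)
    blocks, start = [], 0
    for s in sizes:
        blocks.append(tuple(range(start, start + s)))
        start += s
    if start > n_genera:
        raise ValueError("coop blocks exceed genus count")
    return blocks


@dataclass
class SyntheticScenario:
    """Full description of one simulated cohort."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"A": 48, "N": 46, "S": 86}
    )
    n_genera: int = 120
    depth_range: tuple[int, int] = (10459, 40000)
    coop_blocks: list[tuple[int, ...]] = field(default_factory=default_coop_blocks)
    rho_block: float = 0.7
    planted_effects: list[PlantedEffect] = field(
        default_factory=lambda: [
            PlantedEffect(
                "lymphocytes_pct",
                numerator=tuple(range(40, 47)),
                denominator=tuple(range(50, 57)),
                beta=2.0,
            )
        ]
    )
    parameter_spec: dict[str, ParameterGroupSpec] = field(
        default_factory=default_parameter_spec
    )
    latent_sigma: float = 1.0
    mu_sigma: float = 2.0
    core_mu_mean: float = 1.5
    core_mu_sd: float = 0.75
    cluster_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        flat = [g for b in self.coop_blocks for g in b]
        if len(flat) != len(set(flat)):
            raise ValueError("coop blocks must be disjoint")
        for eff in self.planted_effects:
            for g in (*eff.numerator, *eff.denominator):
                if not 0 <= g < self.n_genera:
                    raise ValueError(f"effect genus index {g} out of range")
        if any(v < 2 for v in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 2")

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())

    @classmethod
    def null(cls, seed: int = 0, **kwargs) -> "SyntheticScenario":
        """Scenario with no planted factor effects (factors still generated)."""
        s = cls(seed=seed, **kwargs)
        s.planted_effects = [
            PlantedEffect(e.factor, e.numerator, e.denominator, 0.0)
            for e in s.planted_effects
        ]
        return s


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    coop_partition: list[set[str]]
    balances: dict[str, Balance]          # factor -> planted balance (genus ids)
    betas: dict[str, float]
    factor_values: dict[str, np.ndarray]  # standardized factor per sample
    null_factors: list[str]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "coop_partition": [sorted(c) for c in self.coop_partition],
            "balances": {
                f: {"numerator": list(b.numerator), "denominator": list(b.denominator)}
                for f, b in self.balances.items()
            },
            "betas": self.betas,
            "null_factors": self.null_factors,
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def _genus_ids(n: int) -> list[str]:
    return [f"Genus{j:03d}" for j in range(n)]


def _lineages(n: int) -> dict[str, dict[str, str]]:
    ids = _genus_ids(n)
    out = {}
    for j, g in enumerate(ids):
        out[g] = {
            "kingdom": "Bacteria",
            "phylum": f"Phylum{j % 5:02d}",
            "class": f"Class{j % 10:02d}",
            "order": f"Order{j % 20:02d}",
            "family": f"Family{j % 40:02d}",
            "genus": g,
        }
    return out


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(stage.encode())])


def simulate_counts(s: SyntheticScenario) -> tuple[CountTable, GroundTruth]:
    """Draw genus counts and return them with the planted ground truth.

    Latent log-abundance z ~ MVN(mu, Sigma) with Sigma block-structured per
    ``coop_blocks``; each planted effect adds beta * factor * b (b = the
    balance's unit coefficient vector) to z, a pure clr-space shift since
    b sums to zero; counts ~ Multinomial(depth, softmax(z)).
    """
    n, d = s.n_samples, s.n_genera
    ids = _genus_ids(d)
    rng = _rng(s.seed, "counts")

    # baseline log-abundances: one dominant genus, long tail; genera carrying
    # planted structure sit in the abundant "core" so they are observable
    mu = rng.normal(0.0, s.mu_sigma, size=d)
    structural = sorted(
        {g for b in s.coop_blocks for g in b}
        | {g for e in s.planted_effects for g in (*e.numerator, *e.denominator)}
    )
    if structural:
        mu[structural] = _rng(s.seed, "core_mu").normal(
            s.core_mu_mean, s.core_mu_sd, size=len(structural)
        )

    cov = np.eye(d)
    for block in s.coop_blocks:
        for a in block:
            for b in block:
                if a != b:
                    cov[a, b] = s.rho_block
    cov *= s.latent_sigma**2
    chol = np.linalg.cholesky(cov)
    z = mu[None, :] + rng.standard_normal((n, d)) @ chol.T

    factor_values: dict[str, np.ndarray] = {}
    balances: dict[str, Balance] = {}
    betas: dict[str, float] = {}
    for eff in s.planted_effects:
        f = _rng(s.seed, f"factor:{eff.factor}").standard_normal(n)
        f = (f - f.mean()) / f.std(ddof=0)
        bal = Balance(
            tuple(ids[g] for g in eff.numerator),
            tuple(ids[g] for g in eff.denominator),
        )
        b = bal.coefficients(ids)
        z += eff.beta * np.outer(f, b)
        factor_values[eff.factor] = f
        balances[eff.factor] = bal
        betas[eff.factor] = eff.beta

    props = np.exp(z - z.max(axis=1, keepdims=True))
    props /= props.sum(axis=1, keepdims=True)
    depths = rng.integers(s.depth_range[0], s.depth_range[1] + 1, size=n)
    counts = np.vstack(
        [rng.multinomial(depths[i], props[i]) for i in range(n)]
    )
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    table = CountTable(sample_ids, ids, counts, _lineages(d))
    truth = GroundTruth(
        coop_partition=[{ids[g] for g in block} for block in s.coop_blocks],
        balances=balances,
        betas=betas,
        factor_values=factor_values,
        null_factors=[],
    )
    return table, truth


def simulate_metadata(s: SyntheticScenario, truth: GroundTruth) -> SampleMetadata:
    """Clinical parameters: planted factors as generated, correlated
    clusters (monotone transforms of one latent + small noise), and
    independent standard-normal null parameters; group labels per
    ``group_sizes``."""
    n = s.n_samples
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    labels = [g for g, k in s.group_sizes.items() for _ in range(k)]
    columns: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    null_factors: list[str] = []
    transforms = (
        lambda u: u,
        np.exp,
        lambda u: u**3,
        lambda u: u + 0.1 * u**2,
    )
    for gname in sorted(s.parameter_spec):
        spec = s.parameter_spec[gname]
        for f in spec.planted_factors:
            if f not in truth.factor_values:
                raise ValueError(f"planted factor {f!r} missing from ground truth")
            columns[f] = truth.factor_values[f]
            groups[f] = gname
        rng = _rng(s.seed, f"params:{gname}")
        for ci, size in enumerate(spec.cluster_sizes):
            u = rng.standard_normal(n)
            for k in range(size):
                name = f"{gname}_cluster{ci + 1}_{k + 1}"
                noisy = u + s.cluster_noise_sd * rng.standard_normal(n)
                columns[name] = transforms[k % len(transforms)](noisy)
                groups[name] = gname
        for k in range(spec.n_null):
            name = f"{gname}_null{k + 1}"
            columns[name] = rng.standard_normal(n)
            groups[name] = gname
            null_factors.append(name)
    truth.null_factors = null_factors
    params = pd.DataFrame(columns, index=sample_ids)
    return SampleMetadata(
        sample_ids, pd.Series(labels, index=sample_ids), params, groups
    )


def simulate_cohort(
    s: SyntheticScenario,
) -> tuple[CountTable, SampleMetadata, GroundTruth]:
    """Counts + metadata + ground truth in one call."""
    table, truth = simulate_counts(s)
    meta = simulate_metadata(s, truth)
    return table, meta, truth
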