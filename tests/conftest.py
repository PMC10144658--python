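import numpy as np
import pandas as pd
import pytest

import coopbalance as cb


@pytest.fixture
def tiny_counts() -> cb.CountTable:
    """3 samples x 4 taxa with two genera sharing a family."""
    counts = np.array(
        [
            [10, 5, 3, 2],
            [0, 8, 6, 1],
            [4, 4, 4, 4],
        ]
    )
    lineages = {
        "gA": {"kingdom": "Bacteria", "family": "F1", "genus": "gA"},
        "gB": {"kingdom": "Bacteria", "family": "F1", "genus": "gB"},
        "gC": {"kingdom": "Bacteria", "family": "F2", "genus": "gC"},
        "gD": {"kingdom": "Bacteria"},
    }
    return cb.CountTable(["s1", "s2", "s3"], ["gA", "gB", "gC", "gD"], counts, lineages)


@pytest.fixture(scope="session")
def planted_cohort():
    """Default planted scenario (seed 1): cohort + derived tables."""
    scenario = cb.SyntheticScenario(seed=1)
    table, meta, truth = cb.simulate_cohort(scenario)
    rarefied = cb.rarefy(table, "min", seed=1)
    filtered = cb.filter_genera(rarefied)
    clr = cb.clr_transform(filtered)
    return {
        "scenario": scenario,
        "table": table,
        "meta": meta,
        "truth": truth,
        "rarefied": rarefied,
        "filtered": filtered,
        "clr": clr,
        "config": cb.AnalysisConfig(seed=1),
    }


@pytest.fixture(scope="session")
def null_cohort():
    """Null scenario (all planted betas zero), seed 11."""
    scenario = cb.SyntheticScenario.null(seed=11)
    table, meta, truth = cb.simulate_cohort(scenario)
    rarefied = cb.rarefy(table, "min", seed=11)
    filtered = cb.filter_genera(rarefied)
    clr = cb.clr_transform(filtered)
    return {
        "scenario": scenario,
        "table": table,
        "meta": meta,
        "truth": truth,
        "rarefied": rarefied,
        "filtered": filtered,
        "clr": clr,
        "config": cb.AnalysisConfig(seed=11),
    }


def random_clr_matrix(rng: np.random.Generator, n: int, d: int) -> cb.ClrMatrix:
    """Helper: clr matrix of random positive compositions."""
    from coopbalance.composition import clr_from_proportions

    x = rng.dirichlet(np.ones(d), size=n)
    return cb.ClrMatrix(
        [f"s{i}" for i in range(n)],
        [f"t{j}" for j in range(d)],
        clr_from_proportions(x),
    )
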