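import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import coopbalance as cb
from coopbalance.associations import attach_fdr, bh_fdr, permutation_beta_test
from coopbalance.composition import clr_from_proportions
from coopbalance.datatypes import CoopPartition

from conftest import random_clr_matrix


class TestDedupParameters:
    def _meta(self, frame, group="g"):
        ids = [f"s{i}" for i in range(len(frame))]
        frame.index = ids
        return cb.SampleMetadata(
            ids, pd.Series(["A"] * len(ids), index=ids), frame,
            {c: group for c in frame.columns},
        )

    def test_duplicate_parameter_collapsed(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        m = self._meta(pd.DataFrame({"a": x, "b": x}))
        screen = cb.dedup_parameters(m, "g")
        assert screen.retained == ["a"]
        assert screen.dropped == {"b": "a"}

    def test_transitive_chain_single_cluster(self):
        # a-b and b-c highly correlated, a-c weaker: one connected component
        rng = np.random.default_rng(1)
        n = 300
        b = rng.standard_normal(n)
        a = b + 0.25 * rng.standard_normal(n)
        c = b + 0.25 * rng.standard_normal(n)
        m = self._meta(pd.DataFrame({"a": a, "b": b, "c": c}))
        rho_ab = stats.spearmanr(a, b).statistic
        rho_ac = stats.spearmanr(a, c).statistic
        assert rho_ab > 0.8 and rho_ac < rho_ab  # fixture sanity
        screen = cb.dedup_parameters(m, "g")
        assert len(screen.retained) == 1
        assert len(screen.dropped) == 2

    def test_independent_parameters_all_retained(self):
        rng = np.random.default_rng(2)
        m = self._meta(pd.DataFrame(rng.standard_normal((60, 4)), columns=list("abcd")))
        screen = cb.dedup_parameters(m, "g")
        assert screen.retained == ["a", "b", "c", "d"]

    def test_representative_has_fewest_missing(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(50)
        a = x.copy()
        a[:5] = np.nan
        m = self._meta(pd.DataFrame({"a": a, "b": x}))
        screen = cb.dedup_parameters(m, "g")
        assert screen.retained == ["b"]


class TestBhFdr:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestAlphaAssoc:
    def _div(self, values):
        ids = [f"s{i}" for i in range(len(values))]
        return cb.DiversityTable(
            ids, pd.DataFrame({"shannon": values}, index=ids)
        )

    def test_identity_factor_perfect_fit(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(30)
        div = self._div(y)
        res = cb.alpha_assoc(div, pd.Series(y, index=div.sample_ids))
        assert res.statistic == pytest.approx(1.0)
        assert res.p < 1e-20

    def test_categorical_equal_group_means_f_near_zero(self):
        y = np.tile([1.0, 2.0, 3.0], 4)  # identical triplets per group
        div = self._div(y)
        g = pd.Series(
            ["A"] * 3 + ["B"] * 3 + ["C"] * 3 + ["D"] * 3, index=div.sample_ids
        )
        res = cb.alpha_assoc(div, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_null_factor_p_uniform(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(100)
        div = self._div(y)
        ps = [
            cb.alpha_assoc(
                div, pd.Series(rng.standard_normal(100), index=div.sample_ids)
            ).p
            for _ in range(200)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_factor_rejected(self):
        div = self._div(np.arange(12.0))
        with pytest.raises(ValueError):
            cb.alpha_assoc(div, pd.Series(np.ones(12), index=div.sample_ids))


class TestPermutationBetaTest:
    def test_categorical_equals_binary_continuous(self):
        # same engine: 2-level factor == its 0/1 coding, F and p identical
        rng = np.random.default_rng(0)
        c = random_clr_matrix(rng, 40, 10)
        d = cb.aitchison_distance(c)
        labels = pd.Series(
            np.array(["A"] * 20 + ["B"] * 20, dtype=object), index=d.index, name="f"
        )
        codes = pd.Series(
            np.r_[np.zeros(20), np.ones(20)], index=d.index, name="f"
        )
        r_cat = permutation_beta_test(d, labels, n_perm=99, seed=5)
        r_num = permutation_beta_test(d, codes, n_perm=99, seed=5)
        assert r_cat.statistic == pytest.approx(r_num.statistic)
        assert r_cat.p == r_num.p
        assert r_cat.r2 == pytest.approx(r_num.r2)

    def test_matches_skbio_permanova_statistic(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova

        rng = np.random.default_rng(1)
        c = random_clr_matrix(rng, 30, 8)
        d = cb.aitchison_distance(c)
        labels = np.array(["A"] * 10 + ["B"] * 10 + ["C"] * 10, dtype=object)
        ours = permutation_beta_test(
            d, pd.Series(labels, index=d.index, name="g"), n_perm=99, seed=0
        )
        theirs = permanova(
            DistanceMatrix(d.to_numpy(), ids=list(d.index)), labels, permutations=99
        )
        assert ours.statistic == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_matches_vegan_adonis2(self, tmp_path):
        # independent oracle: R vegan's adonis2 on the same distances/factor
        rng = np.random.default_rng(2)
        c = random_clr_matrix(rng, 24, 6)
        d = cb.aitchison_distance(c)
        x = pd.Series(rng.standard_normal(24), index=d.index, name="x")
        ours = permutation_beta_test(d, x, n_perm=99, seed=0)
        d.to_csv(tmp_path / "d.tsv", sep="\t")
        x.to_frame().to_csv(tmp_path / "x.tsv", sep="\t")
        script = textwrap.dedent(
            """
            suppressMessages(library(vegan))
            D <- as.dist(as.matrix(read.table("d.tsv", sep="\\t", header=TRUE, row.names=1)))
            x <- read.table("x.tsv", sep="\\t", header=TRUE, row.names=1)$x
            fit <- adonis2(D ~ x, permutations=99)
            cat(fit$F[1], fit$R2[1], sep="\\n")
            """
        )
        (tmp_path / "check.R").write_text(script)
        out = subprocess.run(
            ["Rscript", "check.R"], cwd=tmp_path, capture_output=True, text=True
        )
        assert out.returncode == 0, out.stderr
        f_r, r2_r = map(float, out.stdout.split())
        assert ours.statistic == pytest.approx(f_r, rel=1e-6)
        assert ours.r2 == pytest.approx(r2_r, rel=1e-6)

    def test_strong_group_shift_minimal_p(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((40, 8))
        z[20:, 0] += 4.0  # large clr mean shift for one taxon
        props = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        c = cb.ClrMatrix(
            [f"s{i}" for i in range(40)],
            [f"t{j}" for j in range(8)],
            clr_from_proportions(props),
        )
        d = cb.aitchison_distance(c)
        labels = pd.Series(
            np.array(["A"] * 20 + ["B"] * 20, dtype=object), index=d.index, name="g"
        )
        res = permutation_beta_test(d, labels, n_perm=999, seed=0)
        assert res.p == pytest.approx(1 / 1000)

    def test_saturated_grouping_r2_one(self):
        rng = np.random.default_rng(4)
        c = random_clr_matrix(rng, 12, 6)
        d = cb.aitchison_distance(c)
        g = pd.Series(
            np.array([f"g{i}" for i in range(12)], dtype=object),
            index=d.index, name="g",
        )
        res = permutation_beta_test(d, g, n_perm=9, seed=0)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)

    def test_null_factor_p_uniform(self):
        rng = np.random.default_rng(5)
        c = random_clr_matrix(rng, 50, 10)
        d = cb.aitchison_distance(c)
        ps = [
            permutation_beta_test(
                d,
                pd.Series(rng.standard_normal(50), index=d.index, name="x"),
                n_perm=199,
                seed=s,
            ).p
            for s in range(200)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestCoopBalanceAssoc:
    def _setup(self, rng, n=180, d=12):
        c = random_clr_matrix(rng, n, d)
        universe = list(c.taxon_ids)
        part = CoopPartition(
            {"c-coop": set(universe[:4])}, set(universe[4:]), universe
        )
        return c, part

    def test_constructed_slope_recovered(self):
        # factor = 0.8 * standardized balance + noise -> slope ~ 0.8
        slopes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            c, part = self._setup(rng)
            bal = cb.coop_balance(part, "c-coop")
            v = cb.balance_values(c, bal)
            z = (v - v.mean()) / v.std(ddof=1)
            f = 0.8 * z + np.sqrt(1 - 0.64) * rng.standard_normal(len(z))
            res = cb.coop_balance_assoc(
                c, part, pd.Series(f, index=c.sample_ids, name="f")
            )[0]
            slopes.append(res.statistic)
        assert abs(np.mean(slopes) - 0.8) < 0.1

    def test_sign_flip_negates_coefficient(self):
        rng = np.random.default_rng(0)
        c, part = self._setup(rng)
        f = pd.Series(rng.standard_normal(180), index=c.sample_ids, name="f")
        a = cb.coop_balance_assoc(c, part, f)[0]
        b = cb.coop_balance_assoc(c, part, -f)[0]
        assert a.statistic == pytest.approx(-b.statistic)

    def test_null_slope_small(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(100 + seed)
            c, part = self._setup(rng)
            f = pd.Series(rng.standard_normal(180), index=c.sample_ids, name="f")
            res = cb.coop_balance_assoc(c, part, f)[0]
            hits += abs(res.statistic) < 0.25
        assert hits >= 38  # >= 95% of seeds


class TestTaxonClrAssoc:
    def test_planted_taxon_has_smallest_p(self):
        rng = np.random.default_rng(0)
        n, d = 120, 10
        z = rng.standard_normal((n, d))
        f = rng.standard_normal(n)
        z[:, 4] += 1.0 * f
        props = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        c = cb.ClrMatrix(
            [f"s{i}" for i in range(n)], [f"t{j}" for j in range(d)],
            clr_from_proportions(props),
        )
        res = cb.taxon_clr_assoc(c, pd.Series(f, index=c.sample_ids, name="f"))
        best = min(res, key=lambda r: r.p)
        assert best.feature == "t4"

    def test_result_count_matches_taxa(self):
        rng = np.random.default_rng(1)
        c = random_clr_matrix(rng, 50, 7)
        res = cb.taxon_clr_assoc(
            c, pd.Series(rng.standard_normal(50), index=c.sample_ids, name="f")
        )
        assert len(res) == 7
        assert all(r.q is not None and r.q >= r.p - 1e-12 for r in res)

    def test_null_factor_min_q_rarely_significant(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            c = random_clr_matrix(rng, 100, 15)
            res = cb.taxon_clr_assoc(
                c, pd.Series(rng.standard_normal(100), index=c.sample_ids, name="f")
            )
            hits += min(r.q for r in res) > 0.05
        assert hits >= 0.9 * n_seeds - 1


class TestAttachFdr:
    def test_fdr_within_group_by_family(self):
        mk = lambda ft, g, p: cb.AssociationResult(
            "x", ft, "f", g, 0.0, None, p, None, 10
        )
        rs = [
            mk("coop", "immune", 0.01),
            mk("coop", "immune", 0.02),
            mk("coop", "cardio", 0.5),
            mk("alpha", "immune", 0.04),
        ]
        attach_fdr(rs)
        # immune coop family corrected together (m=2)
        assert rs[0].q == pytest.approx(0.02)
        assert rs[2].q == pytest.approx(0.5)   # alone in its cell
        assert rs[3].q == pytest.approx(0.04)  # alpha family separate
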