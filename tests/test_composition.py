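import numpy as np
import pytest

import coopbalance as cb
from coopbalance.composition import clr_from_proportions

from conftest import random_clr_matrix


def _table(counts, sample_ids=None, taxon_ids=None):
    counts = np.atleast_2d(np.asarray(counts))
    n, d = counts.shape
    return cb.CountTable(
        sample_ids or [f"s{i}" for i in range(n)],
        taxon_ids or [f"t{j}" for j in range(d)],
        counts,
        {},
    )


class TestClr:
    def test_uniform_composition_maps_to_zero(self):
        c = cb.clr_transform(_table([[5, 5, 5, 5]]))
        np.testing.assert_allclose(c.values, 0.0, atol=1e-12)

    def test_zero_replacement_hand_value(self):
        # counts (1, 0), pseudocount 0.5 -> parts (1, 0.5) -> clr (ln2/2, -ln2/2)
        c = cb.clr_transform(_table([[1, 0]]), pseudocount=0.5)
        np.testing.assert_allclose(
            c.values[0], [np.log(2) / 2, -np.log(2) / 2], atol=1e-12
        )

    def test_scale_invariance(self):
        a = cb.clr_transform(_table([[3, 7, 11]]))
        b = cb.clr_transform(_table([[30, 70, 110]]))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        c = cb.clr_transform(_table(rng.integers(0, 100, size=(5, 8))))
        np.testing.assert_allclose(c.values.sum(axis=1), 0.0, atol=1e-9)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            cb.clr_transform(_table([[0, 0, 0]]))

    def test_nonpositive_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            cb.clr_transform(_table([[1, 2]]), pseudocount=0)


class TestAitchisonDistance:
    def test_identical_samples_distance_zero(self):
        c = cb.clr_transform(_table([[1, 2, 3], [1, 2, 3]]))
        d = cb.aitchison_distance(c)
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_two_part_closed_form(self):
        # d((1/2,1/2), (0.8,0.2)) = sqrt(2)*ln2
        c = cb.ClrMatrix(
            ["x", "y"], ["t1", "t2"],
            clr_from_proportions(np.array([[0.5, 0.5], [0.8, 0.2]])),
        )
        d = cb.aitchison_distance(c)
        assert d.iloc[0, 1] == pytest.approx(np.sqrt(2) * np.log(2), rel=1e-12)

    def test_perturbation_invariance(self):
        # d(x (+) z, y (+) z) == d(x, y) for random compositions
        rng = np.random.default_rng(5)
        for _ in range(25):
            d = rng.integers(3, 10)
            x, y, z = rng.dirichlet(np.ones(d), size=3)
            xz = x * z / (x * z).sum()
            yz = y * z / (y * z).sum()
            ids = [f"t{j}" for j in range(d)]
            d1 = cb.aitchison_distance(
                cb.ClrMatrix(["a", "b"], ids, clr_from_proportions(np.array([x, y])))
            ).iloc[0, 1]
            d2 = cb.aitchison_distance(
                cb.ClrMatrix(["a", "b"], ids, clr_from_proportions(np.array([xz, yz])))
            ).iloc[0, 1]
            assert d1 == pytest.approx(d2, rel=1e-9)


class TestRarefy:
    def test_sample_at_exact_depth_unchanged(self):
        t = _table([[3, 4, 3], [10, 10, 10]])
        r = cb.rarefy(t, 10, seed=0)
        np.testing.assert_array_equal(r.counts[0], [3, 4, 3])

    def test_all_sums_equal_depth(self, planted_cohort):
        r = planted_cohort["rarefied"]
        sums = r.sample_sums()
        assert (sums == sums[0]).all()

    def test_depth_exceeding_total_lists_offenders(self):
        t = _table([[5, 5], [50, 50]], sample_ids=["low", "high"])
        with pytest.raises(ValueError, match="low"):
            cb.rarefy(t, 20, seed=0)

    def test_hypergeometric_expectation(self):
        # taxon at proportion 0.3 of 1000 reads, depth 100:
        # mean count over seeds ~ 30 within 3 SE of hypergeometric
        t = _table([[300, 700]])
        draws = np.array(
            [cb.rarefy(t, 100, seed=s).counts[0, 0] for s in range(200)]
        )
        # hypergeometric variance: n*K/N*(N-K)/N*(N-n)/(N-1)
        var = 100 * 0.3 * 0.7 * (1000 - 100) / (1000 - 1)
        se = np.sqrt(var / 200)
        assert abs(draws.mean() - 30.0) < 3 * se

    def test_deterministic_and_order_stable(self):
        t = _table([[40, 60], [70, 30]], sample_ids=["a", "b"])
        r1 = cb.rarefy(t, 50, seed=3)
        t_rev = t.select_samples(["b", "a"])
        r2 = cb.rarefy(t_rev, 50, seed=3)
        np.testing.assert_array_equal(
            r1.counts[0], r2.counts[1]
        )


class TestDiversity:
    def test_shannon_equal_abundances(self):
        div = cb.shannon(_table([[5] * 8]))
        assert div.series("shannon").iloc[0] == pytest.approx(3.0)

    def test_shannon_single_taxon_zero(self):
        div = cb.shannon(_table([[9, 0, 0]]))
        assert div.series("shannon").iloc[0] == pytest.approx(0.0)

    def test_shannon_change_of_base(self):
        t = _table([[3, 5, 9]])
        b2 = cb.shannon(t, base=2).series("shannon").iloc[0]
        be = cb.shannon(t, base=np.e).series("shannon").iloc[0]
        assert be == pytest.approx(b2 * np.log(2))

    def test_chao1_hand_value(self):
        # S_obs=10, F1=2, F2=1 -> 10 + 2*1/(2*2) = 10.5
        counts = [1, 1, 2] + [5] * 7
        div = cb.chao1(_table([counts]))
        assert div.series("chao1").iloc[0] == pytest.approx(10.5)

    def test_chao1_no_singletons_is_observed_richness(self):
        div = cb.chao1(_table([[4, 5, 6]]))
        assert div.series("chao1").iloc[0] == pytest.approx(3.0)

    def test_chao1_at_least_observed(self, planted_cohort):
        div = cb.chao1(planted_cohort["rarefied"])
        s_obs = (planted_cohort["rarefied"].counts > 0).sum(axis=1)
        assert (div.series("chao1").to_numpy() >= s_obs - 1e-9).all()


class TestBalanceValues:
    def test_equal_abundance_parts_give_zero(self):
        c = cb.clr_transform(_table([[7, 7, 3]]))
        bal = cb.Balance(("t0",), ("t1",))
        assert cb.balance_values(c, bal)[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_part_closed_form(self):
        # (0.8, 0.2): sqrt(1/2) * (ln 0.8 - ln 0.2) = ln4 / sqrt2
        c = cb.ClrMatrix(
            ["s"], ["t0", "t1"], clr_from_proportions(np.array([[0.8, 0.2]]))
        )
        bal = cb.Balance(("t0",), ("t1",))
        assert cb.balance_values(c, bal)[0] == pytest.approx(
            np.log(4) / np.sqrt(2), rel=1e-12
        )

    def test_dot_and_meanlog_paths_agree(self):
        rng = np.random.default_rng(2)
        c = random_clr_matrix(rng, 30, 12)
        bal = cb.Balance(("t0", "t3", "t5"), ("t1", "t7", "t8", "t11"))
        np.testing.assert_allclose(
            cb.balance_values(c, bal, method="dot"),
            cb.balance_values(c, bal, method="meanlog"),
            atol=1e-9,
        )

    def test_invariant_to_sample_scaling(self):
        a = cb.clr_transform(_table([[10, 20, 30, 40]]))
        b = cb.clr_transform(_table([[100, 200, 300, 400]]))
        bal = cb.Balance(("t0", "t2"), ("t3",))
        assert cb.balance_values(a, bal)[0] == pytest.approx(
            cb.balance_values(b, bal)[0]
        )


class TestPcoaBiplot:
    def test_eigenvalues_nonnegative_for_aitchison(self, planted_cohort):
        clr = planted_cohort["clr"]
        d = cb.aitchison_distance(clr)
        ord_ = cb.pcoa_biplot(d, clr)
        assert ord_.eigenvalues.min() >= -1e-6 * ord_.eigenvalues.max()
        assert ord_.proportion_explained.sum() <= 1.0 + 1e-9

    def test_exact_embedding_when_rank_two(self):
        # 3 samples in a 3-taxon system: clr rank <= 2, distances exact
        rng = np.random.default_rng(4)
        c = random_clr_matrix(rng, 3, 3)
        d = cb.aitchison_distance(c)
        ord_ = cb.pcoa_biplot(d, c, n_axes=2)
        from scipy.spatial.distance import pdist, squareform

        d2 = squareform(pdist(ord_.coordinates))
        np.testing.assert_allclose(d2, d.to_numpy(), atol=1e-8)

    def test_matches_clr_pca_scores(self, planted_cohort):
        # PCoA on Aitchison == PCA of clr up to sign
        clr = planted_cohort["clr"]
        d = cb.aitchison_distance(clr)
        ord_ = cb.pcoa_biplot(d, clr, n_axes=2)
        X = clr.values - clr.values.mean(axis=0)
        # PCA via SVD
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        scores = X @ vt[:2].T
        for k in range(2):
            r = np.corrcoef(scores[:, k], ord_.coordinates[:, k])[0, 1]
            assert abs(r) > 1 - 1e-6

    def test_top_taxa_ranked_by_arrow_length(self, planted_cohort):
        clr = planted_cohort["clr"]
        d = cb.aitchison_distance(clr)
        ord_ = cb.pcoa_biplot(d, clr)
        lengths = (ord_.arrows**2).sum(axis=1)
        top = ord_.top_taxa(5)
        assert lengths[clr.taxon_ids.index(top[0])] == pytest.approx(lengths.max())
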