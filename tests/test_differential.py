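"""NB exact test calibration, BH-FDR, filtering and expression flags."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from osteotag import differential as diff


def bh_oracle(p):
    """Definitional BH: p_(i) * n / i with running minimum from the top."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestDispersion:
    def test_poisson_counts_give_near_zero(self, rng):
        counts = rng.poisson(100.0, size=(2000, 8))
        groups = np.array(["a"] * 4 + ["b"] * 4)
        est = diff.estimate_common_dispersion(counts, np.ones(8), groups)
        assert abs(est.phi) < 0.02

    def test_recovers_planted_dispersion(self, rng):
        lam = 100.0 * rng.gamma(1 / 0.2, 0.2, size=(2000, 8))
        counts = rng.poisson(lam)
        groups = np.array(["a"] * 4 + ["b"] * 4)
        est = diff.estimate_common_dispersion(counts, np.ones(8), groups)
        assert 0.1 <= est.phi <= 0.3

    def test_constant_replicates_give_zero(self):
        counts = np.tile([[50], [80]], (1, 6))
        groups = np.array(["a"] * 3 + ["b"] * 3)
        assert diff.estimate_common_dispersion(counts, np.ones(6), groups).phi == 0.0

    def test_mean_filter_failure_raises(self):
        counts = np.ones((5, 4))
        with pytest.raises(ValueError, match="mean-count"):
            diff.estimate_common_dispersion(
                counts, np.ones(4), np.array(["a", "a", "b", "b"])
            )


class TestExactTest:
    def test_balanced_equal_sums_give_p_one(self):
        p = diff.nb_exact_test([10, 10], [10, 10], [1, 1], [1, 1], phi=0.1)
        assert p == pytest.approx(1.0)

    def test_phi_zero_equals_conditional_binomial(self, rng):
        for _ in range(30):
            ya = int(rng.integers(0, 60))
            yb = int(rng.integers(0, 60))
            n_a, n_b = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            p = diff.nb_exact_test(
                [ya] + [0] * (n_a - 1), [yb] + [0] * (n_b - 1),
                np.ones(n_a), np.ones(n_b), phi=0.0,
            )
            total = ya + yb
            pmf = stats.binom.pmf(np.arange(total + 1), total, n_a / (n_a + n_b))
            want = pmf[pmf <= pmf[ya] * (1 + 1e-9)].sum() if total else 1.0
            assert p == pytest.approx(min(1.0, want), rel=1e-9)

    def test_label_swap_symmetry(self, rng):
        for _ in range(20):
            a = rng.poisson(50, 3)
            b = rng.poisson(80, 3)
            p1 = diff.nb_exact_test(a, b, np.ones(3), np.ones(3), 0.1)
            p2 = diff.nb_exact_test(b, a, np.ones(3), np.ones(3), 0.1)
            assert p1 == pytest.approx(p2, rel=1e-9)

    def test_uniform_library_rescaling_invariance(self, rng):
        a, b = rng.poisson(40, 4), rng.poisson(70, 4)
        libs_a, libs_b = rng.uniform(0.5, 2.0, 4), rng.uniform(0.5, 2.0, 4)
        p1 = diff.nb_exact_test(a, b, libs_a, libs_b, 0.1)
        p2 = diff.nb_exact_test(a, b, 7.3 * libs_a, 7.3 * libs_b, 0.1)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_type_one_error_calibrated(self, rng):
        # 2000-feature null at phi=0.1, 4 vs 4
        rej = 0
        n = 2000
        for _ in range(n):
            lam = 100.0 * rng.gamma(10.0, 0.1, 8)
            y = rng.poisson(lam)
            p = diff.nb_exact_test(y[:4], y[4:], np.ones(4), np.ones(4), 0.1)
            rej += p < 0.05
        assert 0.03 <= rej / n <= 0.07

    def test_power_increases_with_effect_size(self, rng):
        def power(logfc):
            hits = 0
            for _ in range(150):
                a = rng.poisson(100.0 * rng.gamma(10, 0.1, 4))
                b = rng.poisson(100.0 * 2.0 ** logfc * rng.gamma(10, 0.1, 4))
                hits += diff.nb_exact_test(a, b, np.ones(4), np.ones(4), 0.1) < 0.05
            return hits / 150

        powers = [power(x) for x in (0.25, 0.75, 1.5)]
        assert powers[0] <= powers[1] <= powers[2]
        assert powers[2] > 0.9

    def test_enumeration_bound_raises_and_approximation_works(self):
        big = [2_000_000], [2_100_000]
        with pytest.raises(ValueError, match="approximate"):
            diff.nb_exact_test(big[0], big[1], [1], [1], 0.1, max_enumeration=10**6)
        p = diff.nb_exact_test(big[0], big[1], [1], [1], 0.1,
                               max_enumeration=10**6, approximate=True)
        assert 0 <= p <= 1


class TestBH:
    def test_printed_examples(self):
        assert diff.bh_fdr(np.array([0.03]))[0] == pytest.approx(0.03)
        assert diff.bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_definitional_oracle(self, rng):
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 200)))
            assert diff.bh_fdr(p) == pytest.approx(bh_oracle(p), rel=1e-12)

    def test_monotone_and_never_below_p(self, rng):
        p = rng.uniform(size=100)
        q = diff.bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q >= p - 1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            diff.bh_fdr(np.array([0.5, 1.2]))


class TestIndependentFilter:
    def test_high_count_features_choose_threshold_zero(self, rng):
        means = rng.uniform(100, 200, 50)
        pvals = rng.uniform(size=50)
        t, fdr, _ = diff.independent_filter(means, pvals, [0, 10, 50])
        assert t == 0.0

    def test_filtering_pure_null_low_counts_gains_rejections(self, rng):
        # low-count features are pure null; high-count carry strong signal
        means = np.concatenate([np.full(300, 2.0), np.full(100, 50.0)])
        pvals = np.concatenate([rng.uniform(size=300), rng.uniform(0, 1e-4, 100)])
        t, fdr, nrej = diff.independent_filter(means, pvals, [0, 10])
        _, _, nrej0 = diff.independent_filter(means, pvals, [0])
        assert nrej >= nrej0
        assert np.isnan(fdr[:300]).all() or t == 0.0

    def test_deterministic(self, rng):
        means = rng.uniform(0, 100, 80)
        pvals = rng.uniform(size=80)
        out1 = diff.independent_filter(means, pvals, [0, 5, 20])
        out2 = diff.independent_filter(means, pvals, [0, 5, 20])
        assert out1[0] == out2[0] and np.array_equal(out1[1], out2[1], equal_nan=True)


def fake_de(genes, logfc, fdr):
    return pd.DataFrame(
        {"logFC": logfc, "fdr": fdr, "pvalue": fdr, "mean_a": 1.0, "mean_b": 1.0},
        index=pd.Index(genes, name="feature"),
    )


class TestExpressionFlags:
    def test_down_in_one_knockout_only_is_not_down_in_both(self):
        genes = ["g1", "g2"]
        de1 = fake_de(genes, [-2.0, -2.0], [0.001, 0.001])
        de2 = fake_de(genes, [-2.0, 0.1], [0.001, 0.9])
        flags = diff.classify_expression_changes(
            de1, de2, pd.Series([5.0, 5.0], index=genes))
        assert flags.loc["g1", "down_in_both"]
        assert not flags.loc["g2", "down_in_both"]

    def test_low_wt_rpkm_excluded_regardless_of_fdr(self):
        genes = ["g1"]
        de = fake_de(genes, [-3.0], [1e-9])
        flags = diff.classify_expression_changes(
            de, de, pd.Series([0.5], index=genes))
        assert not flags.loc["g1", "expressed"]
        assert not flags.loc["g1", "down_in_both"]

    def test_mismatched_universe_raises(self):
        de1 = fake_de(["g1"], [0.0], [1.0])
        de2 = fake_de(["g2"], [0.0], [1.0])
        with pytest.raises(ValueError, match="universe"):
            diff.classify_expression_changes(de1, de2, pd.Series([1.0], index=["g1"]))

    def test_planted_down_in_both_recovery(self, rng):
        # 100 well-expressed genes, 40 planted at logFC -1.5 in both
        # knockouts; n=4, phi=0.1 (the biological CV dominates at these
        # counts, so power reflects the dispersion, not shot noise)
        n_genes, n_down = 100, 40
        mu = np.exp(rng.normal(np.log(300), 0.5, n_genes)).clip(50)
        down = np.zeros(n_genes, bool)
        down[:n_down] = True

        def draw(fold):
            lam = mu[:, None] * fold[:, None] * rng.gamma(10, 0.1, (n_genes, 4))
            return rng.poisson(lam)

        wt = draw(np.ones(n_genes))
        fold = np.where(down, 2.0 ** -1.5, 1.0)
        ko1, ko2 = draw(fold), draw(fold)
        counts = np.hstack([wt, ko1, ko2])
        groups = ["wt"] * 4 + ["ko1"] * 4 + ["ko2"] * 4
        libs = diff.expression_lib_sizes(counts, groups)
        ids = [f"g{i}" for i in range(n_genes)]
        g = np.array(groups)
        de1 = diff.exact_test_table(counts, ids, g == "wt", g == "ko1", libs)
        de2 = diff.exact_test_table(counts, ids, g == "wt", g == "ko2", libs)
        flags = diff.classify_expression_changes(
            de1, de2, pd.Series(10.0, index=ids))
        recovered = flags["down_in_both"].to_numpy()[:n_down].mean()
        assert recovered >= 0.95
        false_rate = flags["down_in_both"].to_numpy()[n_down:].mean()
        assert false_rate <= 0.02


class TestLibSizes:
    def test_median_of_ratios_tracks_depth(self, rng):
        mu = np.exp(rng.normal(5, 1, 300))
        depth = np.array([1.0, 2.0, 0.5, 1.5])
        counts = rng.poisson(mu[:, None] * depth[None, :])
        libs = diff.median_of_ratios_lib_sizes(counts)
        ratios = libs / libs[0]
        assert ratios == pytest.approx(depth / depth[0], rel=0.05)

    def test_expression_lib_sizes_resist_composition_shift(self, rng):
        # one third of features shifted down 3x in group b: totals are
        # confounded, the trimmed ratio estimator is not
        mu = np.exp(rng.normal(5, 0.5, 300))
        fold = np.ones(300)
        fold[:100] = 1 / 3
        a = rng.poisson(mu[:, None] * np.ones(4)[None, :] * rng.gamma(10, .1, (300, 4)))
        b = rng.poisson((mu * fold)[:, None] * rng.gamma(10, .1, (300, 4)))
        counts = np.hstack([a, b])
        groups = ["a"] * 4 + ["b"] * 4
        libs = diff.expression_lib_sizes(counts, groups)
        bias = np.log2(libs[4:].mean() / libs[:4].mean())
        assert abs(bias) < 0.1
        naive_bias = np.log2(counts[:, 4:].sum() / counts[:, :4].sum())
        assert abs(naive_bias) > 0.3
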