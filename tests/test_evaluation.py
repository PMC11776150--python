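import itertools

import numpy as np
import pytest
from scipy import stats

from scale_leveler import (
    SpikeDesign,
    SyntheticConfig,
    ccdf_curve,
    ccdf_ensemble,
    correlation_difference_distribution,
    correlation_distribution,
    detection_rate_by_expression,
    empirical_roc,
    generate_synthetic_dataset,
    multigene_roc,
    multigene_sum_distribution,
    roc_ensemble,
    single_patient_t,
    two_population_t,
)
from scale_leveler.pipeline import spiking_runners

from conftest import make_log_matrix


class TestTwoPopulationT:
    def test_matches_textbook_formula_on_toy_vectors(self):
        m = make_log_matrix(np.array([[1.0, 2, 3, 4, 5, 6]]))
        tv = two_population_t(m, [0, 1, 2], [3, 4, 5])
        # pooled variance 1, t = 3 / sqrt(2/3)
        assert tv.t[0] == pytest.approx(3 / np.sqrt(2 / 3), abs=1e-10)
        assert tv.dof == 4
        ref = stats.ttest_ind(m.values[0, 3:], m.values[0, :3],
                              equal_var=True)
        assert tv.t[0] == pytest.approx(ref.statistic, abs=1e-10)

    def test_identical_groups_give_zero(self):
        vals = np.column_stack([np.arange(5.0) + 1] * 4)
        vals += np.random.default_rng(0).normal(0, 1e-6, vals.shape)
        m = make_log_matrix(vals)
        m2 = make_log_matrix(np.column_stack([vals[:, :2], vals[:, :2]]))
        tv = two_population_t(m2, [0, 1], [2, 3])
        np.testing.assert_allclose(tv.t, 0, atol=1e-8)

    def test_swapping_groups_negates_t(self, small_log_matrix):
        a, b = [0, 1, 2], [3, 4, 5]
        t1 = two_population_t(small_log_matrix, a, b).t
        t2 = two_population_t(small_log_matrix, b, a).t
        np.testing.assert_allclose(t1, -t2, atol=1e-12)

    def test_zero_pooled_variance_names_gene(self):
        m = make_log_matrix(np.full((2, 6), 3.0))
        with pytest.raises(ValueError, match="g00000"):
            two_population_t(m, [0, 1, 2], [3, 4, 5])

    def test_overlapping_groups_rejected(self, small_log_matrix):
        with pytest.raises(ValueError, match="disjoint"):
            two_population_t(small_log_matrix, [0, 1], [1, 2])


class TestSinglePatientT:
    def test_patient_at_reference_mean_scores_zero(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(5, 1, (10, 8))
        vals = np.column_stack([ref, ref.mean(axis=1)])
        m = make_log_matrix(vals)
        z = single_patient_t(m, 8, list(range(8)))
        np.testing.assert_allclose(z, 0, atol=1e-12)

    def test_two_sigma_patient_with_large_reference(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(5, 1, (5, 2000))
        mu = ref.mean(axis=1)
        sd = ref.std(axis=1, ddof=1)
        vals = np.column_stack([ref, mu + 2 * sd])
        z = single_patient_t(make_log_matrix(vals), 2000, list(range(2000)))
        np.testing.assert_allclose(z, 2.0, atol=0.01)

    def test_consistent_with_singleton_two_population_t(self,
                                                        small_log_matrix):
        ref = list(range(1, small_log_matrix.n_samples))
        z = single_patient_t(small_log_matrix, 0, ref)
        tv = two_population_t(small_log_matrix, ref, [0])
        np.testing.assert_allclose(z, tv.t, atol=1e-10)

    def test_patient_inside_reference_rejected(self, small_log_matrix):
        with pytest.raises(ValueError):
            single_patient_t(small_log_matrix, 0, [0, 1, 2])


class TestCcdf:
    def test_fraction_exceeding_grid_points(self):
        t = np.array([1.0, 2.0, 3.0])
        assert ccdf_curve(t, np.array([1.5]))[0] == pytest.approx(2 / 3)
        assert ccdf_curve(t, np.array([0.0]))[0] == 1.0
        assert ccdf_curve(t, np.array([5.0]))[0] == 0.0

    def test_matches_gaussian_tail_for_normal_statistics(self):
        rng = np.random.default_rng(3)
        N = 100_000
        z = rng.standard_normal(N)
        grid = np.array([-1.0, 0.0, 1.0, 2.0])
        curve = ccdf_curve(z, grid)
        expect = stats.norm.sf(grid)
        tol = 3 * np.sqrt(expect * (1 - expect) / N)
        assert np.all(np.abs(curve - expect) <= tol)

    def test_ensemble_curves_monotone_bounded_and_bracketed(self):
        grid = np.linspace(-3, 3, 25)

        def runner(rng):
            return rng.standard_normal(500)

        ens = ccdf_ensemble(runner, grid, R=50, seed=5)
        assert np.all(np.diff(ens.mean_curve) <= 1e-12)
        assert np.all((ens.per_draw >= 0) & (ens.per_draw <= 1))
        assert np.all(ens.band_lo <= ens.mean_curve + 1e-12)
        assert np.all(ens.mean_curve <= ens.band_hi + 1e-12)


class TestEmpiricalRoc:
    def test_hand_enumerated_six_gene_roc(self):
        pos = [3.0, 1.0, 0.5]
        neg = [2.0, 0.8, 0.2]
        grid = np.array([0.0, 1 / 3, 2 / 3, 1.0])
        np.testing.assert_allclose(empirical_roc(pos, neg, grid),
                                   [1 / 3, 2 / 3, 1.0, 1.0], atol=1e-12)

    def test_perfect_separation(self):
        tpr = empirical_roc([5.0, 6.0], [1.0, 2.0],
                            np.array([0.0, 0.01, 0.5, 1.0]))
        np.testing.assert_allclose(tpr, [1, 1, 1, 1])

    def test_tied_scores_average_over_block(self):
        # one positive and one negative tied at the top: diagonal segment
        tpr = empirical_roc([2.0], [2.0], np.array([0.0, 0.5, 1.0]))
        np.testing.assert_allclose(tpr, [0.0, 0.5, 1.0])

    def test_null_spike_gives_diagonal_mean_roc(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(3, 12, (2000, 1)) + rng.normal(0, 0.5, (2000, 60))
        m = make_log_matrix(vals)
        spiked_runner, null_runner = spiking_runners(m, 10, 0.0)
        grid = np.linspace(0, 1, 101)
        ens = roc_ensemble(spiked_runner, null_runner, grid, R=50, seed=7)
        assert np.abs(ens.mean_curve - grid).max() < 0.05
        assert np.all(np.diff(ens.mean_curve) >= -1e-12)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            empirical_roc([], [1.0], np.array([0.5]))


class TestMultigeneConvolution:
    def test_point_mass_is_fixed_point(self):
        d = multigene_sum_distribution(np.zeros(10), k=5, bin_width=0.1)
        assert d.probabilities[np.argmin(np.abs(d.bin_grid))] == 1.0

    def test_two_point_distribution_exact(self):
        d = multigene_sum_distribution(np.array([0.0, 1.0]), k=2,
                                       bin_width=1.0)
        np.testing.assert_allclose(d.bin_grid, [0, 1, 2])
        np.testing.assert_allclose(d.probabilities, [0.25, 0.5, 0.25])

    def test_k1_equals_binned_input_and_moments_scale(self):
        rng = np.random.default_rng(8)
        t = rng.normal(0, 1, 400)
        bw = 0.01
        d1 = multigene_sum_distribution(t, k=1, bin_width=bw)
        binned = np.rint(t / bw) * bw
        assert (d1.probabilities * d1.bin_grid).sum() == pytest.approx(
            binned.mean(), abs=1e-9)
        for k in (2, 4):
            dk = multigene_sum_distribution(t, k=k, bin_width=bw)
            mean_k = (dk.probabilities * dk.bin_grid).sum()
            var_k = (dk.probabilities * dk.bin_grid ** 2).sum() - mean_k ** 2
            assert mean_k == pytest.approx(k * binned.mean(), abs=bw * k)
            assert var_k == pytest.approx(k * binned.var(), rel=0.01)

    def test_k3_matches_brute_force_enumeration(self):
        vals = np.array([-2.0, -1.0, 0.0, 1.0, 3.0])
        bw = 1.0
        d = multigene_sum_distribution(vals, k=3, bin_width=bw)
        sums = {}
        for combo in itertools.product(vals, repeat=3):
            s = round(sum(combo))
            sums[s] = sums.get(s, 0) + 1 / 125
        for g, p in zip(d.bin_grid, d.probabilities):
            assert p == pytest.approx(sums.get(round(g), 0.0), abs=1e-12)

    def test_zero_k_rejected(self):
        with pytest.raises(ValueError):
            multigene_sum_distribution(np.zeros(3), k=0)


class TestMultigeneRoc:
    def test_identical_distributions_give_diagonal(self):
        rng = np.random.default_rng(9)
        t = rng.normal(0, 1, 1000)
        d = multigene_sum_distribution(t, k=2, bin_width=0.05)
        grid = np.linspace(0, 1, 51)
        tpr = multigene_roc(d, d, grid)
        assert np.abs(tpr - grid).max() < 0.03

    def test_disjoint_support_gives_step_curve(self):
        null = multigene_sum_distribution(np.array([0.0, 1.0]), k=1,
                                          bin_width=1.0)
        spiked = multigene_sum_distribution(np.array([10.0, 11.0]), k=1,
                                            bin_width=1.0)
        tpr = multigene_roc(spiked, null, np.array([0.001, 0.5, 1.0]))
        np.testing.assert_allclose(tpr, 1.0)

    def test_matches_threshold_enumeration_oracle(self):
        null_vals = np.array([0.0, 1.0, 2.0, 2.0])
        spk_vals = np.array([1.0, 2.0, 3.0, 3.0])
        null = multigene_sum_distribution(null_vals, k=1, bin_width=1.0)
        spk = multigene_sum_distribution(spk_vals, k=1, bin_width=1.0)
        thresholds = [3.0, 2.0, 1.0, 0.0, -1.0]
        pts = [((null_vals > thr).mean(), (spk_vals > thr).mean())
               for thr in thresholds] + [(0.0, 0.0), (1.0, 1.0)]
        for f in [0.0, 0.25, 0.5, 0.6, 0.75, 0.9, 1.0]:
            # best achievable TPR among thresholds with FPR <= f
            t_expect = max(t for fp, t in pts if fp <= f + 1e-12)
            got = multigene_roc(spk, null, np.array([f]))[0]
            assert got == pytest.approx(t_expect, abs=1e-12)

    def test_mismatched_bin_width_rejected(self):
        a = multigene_sum_distribution(np.array([0.0, 1.0]), 1, 1.0)
        b = multigene_sum_distribution(np.array([0.0, 1.0]), 1, 0.5)
        with pytest.raises(ValueError):
            multigene_roc(a, b, np.array([0.5]))


class TestDetectionRateByExpression:
    def test_degenerate_thresholds(self):
        rng = np.random.default_rng(10)
        vals = rng.uniform(3, 12, (400, 1)) + rng.normal(0, 0.5, (400, 30))
        m = make_log_matrix(vals)
        design = SpikeDesign(list(range(5)), list(range(400)), 0.0)
        _, zero = detection_rate_by_expression(m, design, np.inf, block=100,
                                               R=5, seed=0)
        np.testing.assert_allclose(zero, 0.0)
        design_hi = SpikeDesign(list(range(5)), list(range(400)), 3100.0)
        _, one = detection_rate_by_expression(m, design_hi, 0.0, block=100,
                                              R=5, seed=0)
        assert one.min() > 0.9

    def test_low_expression_genes_harder_to_detect(self):
        # mean-linked sd (noisier at low expression) must depress the
        # detection rate of low-expressed genes
        cfg = SyntheticConfig(n_genes=2000, n_samples=60, distortion=None,
                              noise_sd=0.0, gene_sd=(1.0, 0.25), seed=11)
        truth, _, _ = generate_synthetic_dataset(cfg)
        design = SpikeDesign(list(range(15)), list(range(2000)), 40.0)
        grid, rates = detection_rate_by_expression(truth, design, 3.0,
                                                  block=500, R=30, seed=12)
        assert np.all(np.diff(rates) >= -0.02)
        assert rates[-1] > rates[0]


class TestCorrelationDistributions:
    def test_monotone_pair_has_rho_one(self):
        g1 = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        m = make_log_matrix(np.vstack([g1, np.exp(g1)]))
        d = correlation_distribution(m)
        assert d.correlations[0] == pytest.approx(1.0)

    def test_scrambled_null_sd(self):
        rng = np.random.default_rng(13)
        M = 40
        vals = rng.normal(5, 1, (300, M))
        d = correlation_distribution(make_log_matrix(vals), n_pairs=4000,
                                     seed=14)
        assert d.mean == pytest.approx(0.0, abs=0.02)
        assert d.sd == pytest.approx(1 / np.sqrt(M - 1), rel=0.1)

    def test_tied_ranks_match_hand_computation(self):
        m = make_log_matrix(np.array([[1.0, 1.0, 2.0], [1.0, 2.0, 3.0]]))
        d = correlation_distribution(m)
        # ranks with ties averaged: [1.5, 1.5, 3] vs [1, 2, 3]
        expected = stats.spearmanr([1, 1, 2], [1, 2, 3]).statistic
        assert d.correlations[0] == pytest.approx(expected, abs=1e-12)

    def test_constant_gene_pairs_skipped_and_counted(self):
        m = make_log_matrix(np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]))
        d = correlation_distribution(m)
        assert d.n_skipped == 1 and d.correlations.size == 0

    def test_identical_matrices_give_zero_differences(self, small_log_matrix):
        pairs = np.array([[0, 1], [2, 3], [4, 5]])
        d = correlation_difference_distribution(small_log_matrix,
                                                small_log_matrix, pairs)
        np.testing.assert_allclose(d.correlations, 0, atol=1e-12)

    def test_per_sample_transform_broadens_differences(self):
        rng = np.random.default_rng(15)
        vals = rng.uniform(3, 12, (100, 1)) + rng.normal(0, 0.5, (100, 30))
        mA = make_log_matrix(vals)
        # per-sample monotone warp across genes perturbs per-gene ranks
        warped = vals + 0.05 * (vals - 7.0) ** 2
        warped += rng.normal(0, 0.3, warped.shape)
        mB = make_log_matrix(warped)
        pairs = np.array([[i, j] for i in range(20) for j in range(i + 1, 20)])
        d = correlation_difference_distribution(mA, mB, pairs)
        assert d.correlations.std() > 0.02

    def test_mean_range_filter_matches_brute_force(self):
        rng = np.random.default_rng(16)
        vals = rng.uniform(3, 6, (30, 1)) + rng.normal(0, 0.2, (30, 10))
        m = make_log_matrix(vals)
        pairs = np.array([[i, j] for i in range(30) for j in range(i + 1, 30)])
        means = vals.mean(axis=1)
        lo, hi = 4.0, 5.0
        expected = [(i, j) for i, j in pairs
                    if lo <= means[i] <= hi and lo <= means[j] <= hi]
        d = correlation_difference_distribution(m, m, pairs,
                                                mean_range=(lo, hi))
        assert d.correlations.size == len(expected)

    def test_mismatched_gene_sets_rejected(self, small_log_matrix):
        other = make_log_matrix(small_log_matrix.values,
                                gene_ids=[f"x{i}" for i in range(50)])
        with pytest.raises(ValueError):
            correlation_difference_distribution(small_log_matrix, other,
                                                np.array([[0, 1]]))
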