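import math

import numpy as np
import pytest
import scipy.stats as sps

from cnvcohort import consensus as cns
from cnvcohort import qc, stats
from cnvcohort.synthetic import SimConfig, simulate_cohort


class TestChi2CountTest:
    def test_zero_when_all_counts_equal_mean(self):
        r = stats.chi2_count_test([5, 5, 5])
        assert r.statistic == 0.0 and r.p_value == 1.0 and r.df == 2

    def test_hand_arithmetic_with_given_expectation(self):
        r = stats.chi2_count_test([8, 12], expected=10)
        assert r.statistic == pytest.approx(0.8)
        assert r.df == 1
        assert r.p_value == pytest.approx(sps.chi2.sf(0.8, 1))

    def test_permutation_invariant(self):
        a = stats.chi2_count_test([3, 9, 4, 8])
        b = stats.chi2_count_test([8, 4, 9, 3])
        assert a.statistic == pytest.approx(b.statistic)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            stats.chi2_count_test([5])
        with pytest.raises(ValueError):
            stats.chi2_count_test([0, 0, 0])


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        r = stats.kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluation_tie_free(self):
        # groups ([1,2],[3,4]): ranks 1..4, R1=3, R2=7
        # H = 12/(4*5) * (9/2 + 49/2) - 3*5 = 2.4
        r = stats.kruskal_wallis([[1, 2], [3, 4]])
        assert r.statistic == pytest.approx(2.4)
        assert r.df == 1

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            groups = [rng.normal(size=int(rng.integers(3, 40))) for _ in range(int(rng.integers(2, 6)))]
            mine = stats.kruskal_wallis(groups)
            ref = sps.kruskal(*groups)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-8)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-8)

    def test_tie_correction_matches_reference_on_tied_counts(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            groups = [rng.integers(0, 4, size=12).astype(float) for _ in range(3)]
            if np.unique(np.concatenate(groups)).size == 1:
                continue
            mine = stats.kruskal_wallis(groups, tie_correction=True)
            ref = sps.kruskal(*groups)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-8)

    def test_uncorrected_variant_available(self):
        groups = [[1, 1, 2], [2, 3, 3]]
        assert (
            stats.kruskal_wallis(groups, tie_correction=False).statistic
            <= stats.kruskal_wallis(groups, tie_correction=True).statistic
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        groups = [rng.lognormal(size=10) for _ in range(3)]
        a = stats.kruskal_wallis(groups)
        b = stats.kruskal_wallis([np.log(g) for g in groups])
        assert a.statistic == pytest.approx(b.statistic)


class TestShapiroWilk:
    def test_w_bounded_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for n in (3, 5, 12, 100, 500):
            r = stats.shapiro_wilk(rng.lognormal(size=n))
            assert 0.0 < r.statistic <= 1.0

    def test_constant_sample_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            stats.shapiro_wilk([4.0] * 10)

    def test_sample_size_limits(self):
        with pytest.raises(ValueError):
            stats.shapiro_wilk([1.0, 2.0])

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(4)
        for n in (3, 4, 6, 11, 12, 30, 200, 1500):
            x = rng.normal(size=n)
            mine = stats.shapiro_wilk(x)
            ref = sps.shapiro(x)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-6)
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-4)

    def test_rejects_heavy_tailed_lengths(self):
        rng = np.random.default_rng(5)
        rejections = sum(
            stats.shapiro_wilk(rng.lognormal(mean=8, sigma=1.2, size=100)).p_value < 0.05
            for _ in range(200)
        )
        assert rejections / 200 > 0.9


class TestMultipropTest:
    def test_zero_statistic_when_proportions_equal(self):
        r = stats.multiprop_test([0.01, 0.01, 0.01], 1e6)
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_hand_evaluation_two_individuals(self):
        p, d = [0.01, 0.02], 1e6
        pbar = 0.015
        expected = (
            d * ((0.01 - pbar) ** 2 + (0.02 - pbar) ** 2)
            / (0.01 * 0.99 + 0.02 * 0.98)
            * 2
        )
        r = stats.multiprop_test(p, d)
        assert r.statistic == pytest.approx(expected)
        assert r.p_value == pytest.approx(sps.chi2.sf(expected, 1))

    def test_statistic_linear_in_genome_length(self):
        p = [0.01, 0.03, 0.02]
        assert stats.multiprop_test(p, 2e6).statistic == pytest.approx(
            2 * stats.multiprop_test(p, 1e6).statistic
        )

    def test_boundary_proportions_rejected(self):
        with pytest.raises(ValueError):
            stats.multiprop_test([0.0, 0.5], 1e6)
        with pytest.raises(ValueError):
            stats.multiprop_test([0.5], 1e6)


class TestBonferroni:
    def test_scaling_capping_and_order(self):
        assert stats.bonferroni([0.01], 5) == [0.05]
        assert stats.bonferroni([0.5], 5) == [1.0]
        adjusted = stats.bonferroni([0.04, 0.001, 0.2], 3)
        assert adjusted == pytest.approx([0.12, 0.003, 0.6])
        assert all(a >= p for a, p in zip(adjusted, [0.04, 0.001, 0.2]))


def _suite_for(seed, **overrides):
    params = dict(
        breeds={"A": 5, "B": 5, "C": 5, "D": 5},
        n_low_coverage=0,
        n_shared_global=2,
        n_shared_per_breed=2,
        n_private_per_sample=6,
        fp_rate_rd=0.5,
    )
    params.update(overrides)
    cfg = SimConfig(seed=seed, **params)
    sim = simulate_cohort(cfg)
    kept, _ = qc.filter_samples(sim.manifest, cfg.build)
    csets = [
        cns.build_consensus(
            cns.filter_by_length(sim.rd_calls[s.sample_id]),
            cns.filter_by_length(sim.sr_calls[s.sample_id]),
        )
        for s in kept
    ]
    return stats.run_variation_suite(csets, sim.manifest, cfg.build, seed=seed)


class TestVariationSuite:
    def test_deterministic_rerun(self):
        a = _suite_for(13)
        b = _suite_for(13)
        assert a.equals(b)

    def test_report_covers_both_types_and_all_tests(self):
        report = _suite_for(17)
        assert set(report["cnv_type"]) == {"DUP", "DEL"}
        assert {"chi2_count", "kruskal_wallis", "shapiro_wilk", "multiprop"} <= set(report["test"])
        assert report["p_value"].between(0, 1).all()
        adj = report["p_adjusted"].dropna()
        assert (adj >= report.loc[adj.index, "p_value"] - 1e-12).all()

    def test_interbreed_count_test_calibrated_under_null(self):
        # identical per-breed count distributions (no breed-private pools):
        # the between-breed rank test should stay non-significant at 5% in
        # >= 90% of replicates
        nonsig = 0
        n_rep = 100
        for rep in range(n_rep):
            report = _suite_for(1000 + rep, n_shared_per_breed=0, n_private_per_sample=8)
            rows = report[(report["scope"] == "between_breeds")]
            nonsig += int((rows["p_value"] > 0.05).all())
        assert nonsig / n_rep >= 0.9

    def test_interbreed_count_test_detects_shifted_breed(self):
        # one breed's private-call budget shifted far above the others
        detected = 0
        for rep in range(20):
            cfg = SimConfig(
                seed=5000 + rep,
                breeds={"A": 5, "B": 5, "C": 5, "D": 5},
                n_low_coverage=0,
                n_shared_global=0,
                n_shared_per_breed=0,
                n_private_per_sample=6,
                fp_rate_rd=0.0,
            )
            sim = simulate_cohort(cfg)
            kept, _ = qc.filter_samples(sim.manifest, cfg.build)
            csets = []
            for s in kept:
                rd = sim.rd_calls[s.sample_id]
                if s.breed == "A":  # drop most of breed A's calls: strong shift
                    rd = rd[:2]
                csets.append(cns.build_consensus(cns.filter_by_length(rd), sim.sr_calls[s.sample_id]))
            report = stats.run_variation_suite(csets, sim.manifest, cfg.build, validated_only=False)
            rows = report[report["scope"] == "between_breeds"]
            detected += int((rows["p_value"] < 0.05).any())
        assert detected / 20 >= 0.9
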