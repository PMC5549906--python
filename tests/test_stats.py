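"""Statistical protocol: summaries, rank tests, letters, report building."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps

from wafernoise import (
    AcquisitionCondition,
    EmptyInputError,
    InsufficientReplicatesError,
    ParameterError,
    PipelineConfig,
    UndefinedStatisticError,
    WaferScanConfig,
    build_report,
    group_summary,
    kruskal_wallis,
    mann_whitney,
    percent_change,
    significance_letters,
    simulate_protocol,
)


class TestGroupSummary:
    def test_hand_computed_example(self):
        s = group_summary([1, 2, 3, 4, 5])
        assert s.mean == pytest.approx(3.0)
        assert s.sd == pytest.approx(math.sqrt(2.5))  # n-1 denominator
        assert s.cv == pytest.approx(100 * math.sqrt(2.5) / 3)
        assert s.iqr == pytest.approx(2.0)  # linear-interpolated Q3 - Q1
        # CI half-width: t(0.975, 4) * sd / sqrt(5)
        assert s.ci_half == pytest.approx(
            sps.t.ppf(0.975, 4) * math.sqrt(2.5) / math.sqrt(5)
        )

    def test_constant_replicates_have_zero_spread(self):
        s = group_summary([5, 5, 5, 5])
        assert (s.sd, s.iqr, s.cv, s.ci_half) == (0.0, 0.0, 0.0, 0.0)

    def test_sd_cv_consistency(self, rng):
        values = rng.gamma(5.0, 2.0, size=10)
        s = group_summary(values)
        assert s.sd == pytest.approx(s.cv * s.mean / 100, rel=1e-12)

    def test_normal_ci_is_narrower_than_t(self, rng):
        values = rng.gamma(5.0, 2.0, size=8)
        t_ci = group_summary(values, ci_method="t").ci_half
        z_ci = group_summary(values, ci_method="normal").ci_half
        assert z_ci < t_ci

    def test_single_replicate(self):
        with pytest.raises(InsufficientReplicatesError):
            group_summary([4.2])
        s = group_summary([4.2], strict=False)
        assert s.mean == 4.2 and math.isnan(s.sd)

    def test_empty_and_negative_inputs(self):
        with pytest.raises(EmptyInputError):
            group_summary([])
        with pytest.raises(ParameterError):
            group_summary([1.0, -0.5])


class TestKruskalWallis:
    def test_interleaved_groups_not_significant(self):
        res = kruskal_wallis([[1, 3, 5], [2, 4, 6]])
        assert res.pvalue > 0.05

    def test_all_identical_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            kruskal_wallis([[2, 2, 2], [2, 2, 2]])

    def test_empty_group_rejected(self):
        with pytest.raises(EmptyInputError):
            kruskal_wallis([[1, 2], []])
        with pytest.raises(ParameterError):
            kruskal_wallis([[1, 2, 3]])

    def test_two_group_kw_matches_mann_whitney_normal_theory(self, rng):
        # without ties and without continuity correction, chi2(H, 1) and
        # the two-sided normal Mann-Whitney p are the same test
        for _ in range(20):
            n1, n2 = rng.integers(5, 12, size=2)
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            a, b = pooled[:n1], pooled[n1:]
            p_kw = kruskal_wallis([a, b]).pvalue
            p_mw = mann_whitney(a, b, mode="approx", continuity=False).pvalue
            assert abs(p_kw - p_mw) < 0.02


class TestMannWhitney:
    def test_identical_samples_full_overlap(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)  # n1*n2/2
        assert res.pvalue == pytest.approx(1.0)

    def test_exact_two_vs_two(self):
        res = mann_whitney([1, 2], [3, 4], mode="exact")
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1 / 3)  # 2 of C(4,2)=6 splits

    def test_exact_matches_independent_enumeration(self, rng):
        # oracle: direct pair-count permutation over all splits
        def oracle(a, b):
            pooled = np.concatenate([a, b])
            n1 = len(a)

            def u_of(idx):
                ia = set(idx)
                xa = pooled[list(idx)]
                xb = pooled[[i for i in range(len(pooled)) if i not in ia]]
                gt = sum(1 for x in xa for y in xb if x > y)
                eq = sum(1 for x in xa for y in xb if x == y)
                return gt + 0.5 * eq

            obs = u_of(range(n1))
            mid = n1 * (len(pooled) - n1) / 2
            splits = list(itertools.combinations(range(len(pooled)), n1))
            hits = sum(1 for s in splits
                       if abs(u_of(s) - mid) >= abs(obs - mid) - 1e-12)
            return obs, hits / len(splits)

        for n1 in range(1, 5):
            for n2 in range(1, 5):
                a = rng.integers(0, 5, size=n1).astype(float)  # ties likely
                b = rng.integers(0, 5, size=n2).astype(float)
                res = mann_whitney(a, b, mode="exact")
                u_exp, p_exp = oracle(a, b)
                assert res.statistic == pytest.approx(u_exp)
                assert res.pvalue == pytest.approx(p_exp)

    def test_exact_refused_when_too_many_arrangements(self):
        a, b = np.arange(10.0), np.arange(10.0) + 5
        with pytest.raises(ParameterError):
            mann_whitney(a, b, mode="exact")
        # auto falls back to the normal approximation
        assert mann_whitney(a, b).mode == "approx"

    def test_empty_sample_rejected(self):
        with pytest.raises(EmptyInputError):
            mann_whitney([], [1, 2])


class TestSignificanceLetters:
    def test_separated_conditions_list_each_other(self, rng):
        near_one = 1 + 0.05 * rng.standard_normal(10)
        near_ten = 10 + 0.05 * rng.standard_normal(10)
        out = significance_letters({"0": near_one, "30.1": near_ten})
        assert out == {"0": {"b"}, "30.1": {"a"}}

    def test_identical_distributions_give_empty_sets(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0]
        out = significance_letters({"0": values, "30.1": values[::-1],
                                    "45.1": values})
        assert all(s == set() for s in out.values())

    def test_single_condition_empty_mapping(self):
        assert significance_letters({"0": [1, 2, 3]}) == {}

    def test_letter_sets_are_symmetric(self, rng):
        groups = {
            lab: rng.gamma(3, 2, size=8)
            for lab in ("0", "30.1", "30.2", "45.1", "45.2")
        }
        groups["45.2"] = groups["45.2"] + 50  # force one clear separation
        out = significance_letters(groups)
        letters = dict(zip(("0", "30.1", "30.2", "45.1", "45.2"), "abcde"))
        for la in out:
            for lb in out:
                if la != lb:
                    assert (letters[lb] in out[la]) == (letters[la] in out[lb])

    def test_holm_correction_is_more_conservative(self, rng):
        groups = {lab: rng.standard_normal(8) + shift
                  for lab, shift in [("0", 0.0), ("30.1", 0.8), ("30.2", 1.6),
                                     ("45.1", 2.4), ("45.2", 3.2)]}
        raw = significance_letters(groups, holm=False)
        adj = significance_letters(groups, holm=True)
        assert sum(len(s) for s in adj.values()) <= sum(len(s) for s in raw.values())

    def test_condition_objects_accepted(self):
        a = AcquisitionCondition(0)
        b = AcquisitionCondition(30, 1)
        out = significance_letters({a: [1, 1, 1, 2], b: [1, 2, 1, 1]})
        assert set(out) == {"0", "30.1"}


class TestPercentChange:
    def test_signed_changes(self):
        assert percent_change(7.54, 10.68) == pytest.approx(41.6, abs=0.05)
        assert percent_change(10.68, 5.29) == pytest.approx(-50.5, abs=0.05)
        assert percent_change(3.3, 3.3) == 0.0

    def test_nonpositive_reference_rejected(self):
        for ref in (0.0, -1.0):
            with pytest.raises(ParameterError):
                percent_change(ref, 5.0)


class TestAcquisitionCondition:
    def test_labels(self):
        assert AcquisitionCondition(0).label == "0"
        assert AcquisitionCondition(30, 2).label == "30.2"

    def test_direction_rules(self):
        with pytest.raises(ParameterError):
            AcquisitionCondition(0, 1)
        with pytest.raises(ParameterError):
            AcquisitionCondition(45)


@pytest.fixture(scope="module")
def homogeneous_report():
    base = WaferScanConfig(resolution=41, sigma_um=8.0, edge_multiplier=1.0,
                           outlier_rate=0.0)
    scans = simulate_protocol(base, replicates=4, seed=11)
    cfg = PipelineConfig(kernel_radius_mm=1000.0)
    return build_report({"sim": scans}, cfg), cfg


class TestBuildReport:
    def test_table_shape_and_columns(self, homogeneous_report):
        report, _ = homogeneous_report
        frame = report.to_frame()
        assert len(frame) == 5 * 2  # conditions x regions
        assert set(frame["region"]) == {"whole", "central"}
        for col in ("mean_rq_um", "sd_um", "iqr_um", "cv_pct", "ci_half_um"):
            assert col in frame.columns

    def test_homogeneous_noise_recovers_sigma(self, homogeneous_report):
        report, _ = homogeneous_report
        frame = report.to_frame()
        assert np.allclose(frame["mean_rq_um"], 8.0, rtol=0.03)

    def test_determinism(self, homogeneous_report):
        report, cfg = homogeneous_report
        base = WaferScanConfig(resolution=41, sigma_um=8.0, edge_multiplier=1.0,
                               outlier_rate=0.0)
        again = build_report({"sim": simulate_protocol(base, replicates=4,
                                                       seed=11)}, cfg)
        np.testing.assert_array_equal(
            report.to_frame()["mean_rq_um"].to_numpy(),
            again.to_frame()["mean_rq_um"].to_numpy(),
        )

    def test_json_serialization_covers_all_tests(self, homogeneous_report):
        report, _ = homogeneous_report
        blob = report.to_json_dict()
        assert len(blob["table"]) == 10
        assert len(blob["whole_vs_central"]) == 5
        assert len(blob["pairwise"]) == 2 * math.comb(5, 2)
        assert blob["parameters"]["kernel_radius_mm"] == 1000.0
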