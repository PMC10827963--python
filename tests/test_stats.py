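"""Descriptive measures, contrast decisions and Bayes factors."""

import math

import numpy as np
import pingouin as pg
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu, rankdata

from dualrec.stats import (
    contrast_decision,
    corrected_acceptance_rate,
    evidence_label,
    jzs_ttest_bf,
    rank_bf,
    run_bf_tests,
)


class TestCar:
    def test_examples(self):
        assert corrected_acceptance_rate(0.8, 0.25) == pytest.approx(0.55)
        assert corrected_acceptance_rate(0.4, 0.4) == 0.0

    def test_rejects_non_rates(self):
        with pytest.raises(ValueError):
            corrected_acceptance_rate(1.2, 0.1)


class TestContrastDecision:
    def test_zero_draws_not_substantial(self):
        res = contrast_decision(np.zeros(1000))
        assert res.mean_diff == 0.0
        assert not res.substantial

    def test_normal_draws_quantile_oracle(self):
        rng = np.random.default_rng(12)
        draws = rng.normal(0.24, 0.09, 10_000)
        res = contrast_decision(draws)
        assert res.substantial
        assert res.bci_95[0] == pytest.approx(0.064, abs=0.01)
        assert res.bci_95[1] == pytest.approx(0.416, abs=0.01)
        # the interval is exactly the central 95% of the supplied draws
        assert res.bci_95 == pytest.approx(tuple(np.percentile(draws, [2.5, 97.5])))

    def test_null_coverage(self):
        hits = 0
        for seed in range(40):
            draws = np.random.default_rng(seed).normal(0.0, 1.0, 4000)
            hits += not contrast_decision(draws).substantial
        assert hits >= 36  # ~95% of null intervals cover zero

    def test_few_draws_warns(self):
        res = contrast_decision(np.random.default_rng(0).normal(size=100))
        assert res.warnings


class TestEvidenceLabels:
    @pytest.mark.parametrize(
        "bf, label",
        [
            (0.078, "strong H0"),     # strong evidence for the null
            (3.112, "moderate H1"),   # moderate evidence for the alternative
            (11.263, "strong H1"),    # strong evidence for the alternative
            (0.207, "moderate H0"),
            (1.096, "weak H1"),
            (0.556, "weak H0"),
        ],
    )
    def test_reported_pairings(self, bf, label):
        assert evidence_label(bf) == label

    def test_rejects_non_positive(self):
        for bad in (0.0, -2.0, float("nan")):
            with pytest.raises(ValueError):
                evidence_label(bad)

    @given(st.floats(min_value=1e-6, max_value=1e6), st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_total_monotone_partition(self, a, b):
        order = ["strong H0", "moderate H0", "weak H0", "weak H1", "moderate H1", "strong H1"]
        la, lb = evidence_label(a), evidence_label(b)
        if a <= b:
            assert order.index(la) <= order.index(lb)


class TestJzsBayesFactor:
    def test_null_t_favours_null(self):
        x = np.array([1.0, -1.0, 0.5, -0.5, 2.0, -2.0])
        res = jzs_ttest_bf(x)
        assert res.statistic == pytest.approx(0.0)
        assert res.bf < 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_prior_splitting_identity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.2, 1.0, 25)
        two = jzs_ttest_bf(x).bf
        plus = jzs_ttest_bf(x, direction="greater").bf
        minus = jzs_ttest_bf(x, direction="less").bf
        assert (plus + minus) / 2 == pytest.approx(two, abs=1e-6)

    @pytest.mark.parametrize("n", [10, 30, 77])
    def test_against_independent_implementation(self, n):
        rng = np.random.default_rng(n)
        x = rng.normal(0.3, 1.0, n)
        res = jzs_ttest_bf(x)
        reference = float(pg.bayesfactor_ttest(res.statistic, n, paired=True, r=1 / math.sqrt(2)))
        assert res.bf == pytest.approx(reference, rel=1e-6)

    def test_two_sample_matches_reference(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0.6, 1, 20), rng.normal(0.0, 1, 25)
        res = jzs_ttest_bf(a, b)
        reference = float(pg.bayesfactor_ttest(res.statistic, 20, 25, paired=False, r=1 / math.sqrt(2)))
        assert res.bf == pytest.approx(reference, rel=1e-6)

    def test_monotone_in_t(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0.0, 1.0, 30)
        base -= base.mean()
        bfs = [jzs_ttest_bf(base + shift).bf for shift in (0.1, 0.3, 0.6, 1.0)]
        assert all(b1 < b2 for b1, b2 in zip(bfs, bfs[1:]))

    def test_reciprocity(self):
        res = jzs_ttest_bf(np.random.default_rng(4).normal(0.5, 1, 15))
        assert res.bf01 == pytest.approx(1.0 / res.bf)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            jzs_ttest_bf(np.ones(10))


class TestRankBayesFactor:
    def test_large_shift_gives_strong_evidence(self):
        x = np.random.default_rng(0).normal(3.0, 1.0, 30)
        res = rank_bf(x, direction="greater", seed=1)
        assert res.bf > 10
        assert res.evidence == "strong H1"

    def test_signed_rank_statistic_convention(self):
        d = np.array([1.2, -0.4, 0.8, 2.0, -1.5, 0.0, 0.3])
        res = rank_bf(d, seed=0, n_samples=200, n_burn=50)
        nz = d[d != 0]
        expected_w = rankdata(np.abs(nz))[nz > 0].sum()
        assert res.statistic == expected_w

    def test_rank_sum_statistic_is_mann_whitney(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(1, 1, 12), rng.normal(0, 1, 15)
        res = rank_bf(a, b, seed=0, n_samples=200, n_burn=50)
        assert res.statistic == mannwhitneyu(a, b).statistic

    def test_null_calibration(self):
        bfs = [
            rank_bf(np.random.default_rng(500 + i).normal(0, 1, 30), seed=i,
                    n_samples=800, n_burn=200).bf
            for i in range(40)
        ]
        assert float(np.median(bfs)) < 1.0

    def test_concordance_with_t_test(self):
        agree = 0
        for i in range(40):
            x = np.random.default_rng(900 + i).normal(0.8, 1.0, 25)
            bt = jzs_ttest_bf(x).bf
            br = rank_bf(x, seed=i, n_samples=800, n_burn=200).bf
            agree += (bt > 1) == (br > 1)
        assert agree >= 36  # >= 90% directional agreement at a 0.8 SD effect

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            rank_bf(np.zeros(10), seed=0)

    def test_paired_equals_difference_form(self):
        rng = np.random.default_rng(5)
        a = rng.normal(1.0, 1.0, 20)
        b = rng.normal(0.0, 1.0, 20)
        r1 = rank_bf(a, b, paired=True, seed=7)
        r2 = rank_bf(a - b, seed=7)
        assert r1.bf == pytest.approx(r2.bf)


def test_batch_runner_over_estimates_table():
    import pandas as pd

    rng = np.random.default_rng(10)
    frame = pd.DataFrame(
        {
            "participant": [f"p{i}" for i in range(30)],
            "est_RC_frequent": rng.normal(0.45, 0.15, 30).clip(0, 1),
            "est_RC_infrequent": rng.normal(0.20, 0.15, 30).clip(0, 1),
        }
    )
    tests = [
        {"name": "rc-effect", "parameter_a": "RC_frequent", "parameter_b": "RC_infrequent",
         "test": "rank", "paired": True, "direction": "greater", "seed": 1},
        {"name": "rc-t", "parameter_a": "RC_frequent", "parameter_b": "RC_infrequent",
         "test": "t", "paired": True, "direction": "greater"},
    ]
    report = run_bf_tests(frame, tests)
    assert list(report["name"]) == ["rc-effect", "rc-t"]
    assert (report["bf"] > 1).all()
    assert set(report.columns) >= {"bf", "statistic", "evidence", "direction"}
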