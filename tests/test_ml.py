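"""Maximum-likelihood fitting: self-consistency, closed forms, calibration."""

import numpy as np
import pandas as pd
import pytest

from dualrec.design import build_design, probe_cell_totals
from dualrec.ml import fit_dataset, fit_ml, goodness_of_fit
from dualrec.model import ACCEPT, REJECT, Branch, MptModel, build_dual_recollection_model
from dualrec.simulate import make_experiment_dataset


def expected_frequency_counts(design, model, theta, scale=1000):
    """Exact expected frequencies under theta (no sampling noise)."""
    totals = probe_cell_totals(design)
    lookup = {(r.probe, r.item_class): r.n_total for r in totals.itertuples()}
    vec = np.array([theta[p] for p in model.parameter_names])
    p = model.p_yes(vec)
    rows = []
    for i, (probe, item_class) in enumerate(model.categories):
        n = lookup[(probe, item_class)] * scale
        rows.append({"probe": probe, "item_class": item_class, "n_yes": n * p[i], "n_total": n})
    return pd.DataFrame(rows)


THETA_STAR = {
    "RC_frequent": 0.35, "RT_frequent": 0.45, "b_Cf": 0.16,
    "RC_infrequent": 0.28, "RT_infrequent": 0.41, "b_Ci": 0.12,
    "F_frequent": 0.15, "b_either": 0.10, "F_infrequent": 0.22,
}


class TestSelfConsistency:
    def test_recovers_generating_theta_from_expected_frequencies(self, exp3_high, exp3_model):
        counts = expected_frequency_counts(exp3_high, exp3_model, THETA_STAR)
        fit = fit_ml(counts, exp3_model, seed=1)
        assert fit.converged
        for p in exp3_model.parameter_names:
            assert fit.estimates[p] == pytest.approx(THETA_STAR[p], abs=1e-4)
        assert fit.g2 < 1e-6

    def test_likelihood_at_estimates_dominates_truth(self, exp3_high, exp3_model):
        from dualrec.ml import _binomial_loglik, _counts_arrays

        counts = expected_frequency_counts(exp3_high, exp3_model, THETA_STAR)
        fit = fit_ml(counts, exp3_model, seed=2)
        y, n = _counts_arrays(counts, exp3_model)
        ll_true = _binomial_loglik(
            exp3_model.p_yes(np.array([THETA_STAR[p] for p in exp3_model.parameter_names])), y, n
        )
        assert fit.log_likelihood >= ll_true - 1e-9

    def test_branch_order_invariance(self, exp3_high, exp3_model):
        counts = expected_frequency_counts(exp3_high, exp3_model, THETA_STAR, scale=10)
        permuted = MptModel({key: tuple(reversed(br)) for key, br in exp3_model.trees.items()})
        f1 = fit_ml(counts, exp3_model, seed=3)
        f2 = fit_ml(counts, permuted, seed=3)
        for p in exp3_model.parameter_names:
            assert f1.estimates[p] == pytest.approx(f2.estimates[p], abs=1e-6)


class TestClosedForms:
    def test_distractor_only_model_is_observed_rate(self):
        trees = {
            (q, "distractor"): (Branch(((f"b_{q}", True),), ACCEPT), Branch(((f"b_{q}", False),), REJECT))
            for q in ("q1", "q2", "q3")
        }
        model = MptModel(trees)
        counts = pd.DataFrame(
            {
                "probe": ["q1", "q2", "q3"],
                "item_class": ["distractor"] * 3,
                "n_yes": [3, 10, 7],
                "n_total": [10, 40, 28],
            }
        )
        fit = fit_ml(counts, model, n_starts=4, seed=0)
        assert fit.estimates["b_q1"] == pytest.approx(0.3, abs=1e-6)
        assert fit.estimates["b_q2"] == pytest.approx(0.25, abs=1e-6)
        assert fit.estimates["b_q3"] == pytest.approx(0.25, abs=1e-6)
        assert fit.g2 == pytest.approx(0.0, abs=1e-9)

    def test_empty_cell_rejected_with_tree_name(self, exp3_high, exp3_model):
        counts = expected_frequency_counts(exp3_high, exp3_model, THETA_STAR, scale=1)
        counts = counts[~((counts.probe == "Ci?") & (counts.item_class == "frequent"))]
        with pytest.raises(ValueError, match=r"Ci\?"):
            fit_ml(counts, exp3_model, seed=0)


class TestRecovery:
    def test_large_sample_recovery_bias_small(self, exp3_high, exp3_model):
        """Monte-Carlo recovery: ~1e4 trials per cell, many replicates."""
        rng = np.random.default_rng(77)
        theta_vec = np.array([THETA_STAR[p] for p in exp3_model.parameter_names])
        p = exp3_model.p_yes(theta_vec)
        n = np.full(len(exp3_model.categories), 10_000)
        errs = []
        for _ in range(50):
            y = rng.binomial(n, p)
            counts = pd.DataFrame(
                {
                    "probe": [c[0] for c in exp3_model.categories],
                    "item_class": [c[1] for c in exp3_model.categories],
                    "n_yes": y,
                    "n_total": n,
                }
            )
            fit = fit_ml(counts, exp3_model, n_starts=4, seed=int(rng.integers(2**31)), compute_se=False)
            errs.append(
                np.mean([abs(fit.estimates[p_] - THETA_STAR[p_]) for p_ in exp3_model.parameter_names])
            )
        assert float(np.mean(errs)) < 0.02

    def test_recovery_bias_shrinks_with_cell_size(self, exp3_high, exp3_model):
        rng = np.random.default_rng(5)
        theta_vec = np.array([THETA_STAR[p] for p in exp3_model.parameter_names])
        p = exp3_model.p_yes(theta_vec)
        maes = []
        for scale in (1, 10, 100):
            base = np.array(
                [probe_cell_totals(exp3_high).set_index(["probe", "item_class"]).loc[c, "n_total"]
                 for c in exp3_model.categories]
            )
            n = base * scale
            errs = []
            for _ in range(12):
                y = rng.binomial(n, p)
                counts = pd.DataFrame(
                    {
                        "probe": [c[0] for c in exp3_model.categories],
                        "item_class": [c[1] for c in exp3_model.categories],
                        "n_yes": y,
                        "n_total": n,
                    }
                )
                fit = fit_ml(counts, exp3_model, n_starts=3, seed=int(rng.integers(2**31)),
                             compute_se=False)
                errs.append(np.mean([abs(fit.estimates[q] - THETA_STAR[q])
                                     for q in exp3_model.parameter_names]))
            maes.append(float(np.mean(errs)))
        assert maes[2] < maes[1] < maes[0]


class TestGoodnessOfFit:
    def test_saturated_model_fits_perfectly(self):
        # one free probability per category: G2 = 0 with df = 0
        rng = np.random.default_rng(1)
        trees = {
            (f"q{i}?", "a"): (Branch(((f"p{i}", True),), ACCEPT), Branch(((f"p{i}", False),), REJECT))
            for i in range(5)
        }
        model = MptModel(trees)
        n = np.full(5, 200)
        counts = pd.DataFrame(
            {
                "probe": [c[0] for c in model.categories],
                "item_class": [c[1] for c in model.categories],
                "n_yes": rng.binomial(n, 0.3),
                "n_total": n,
            }
        )
        fit = fit_ml(counts, model, seed=4)
        g2, df, p = goodness_of_fit(fit, counts)
        assert df == 0
        assert p is None
        assert g2 == pytest.approx(0.0, abs=1e-6)

    def test_df_zero_reports_undefined_p(self, exp3_high, exp3_model):
        # the exp3 layout has as many parameters as categories: df = 0
        rng = np.random.default_rng(1)
        totals = probe_cell_totals(exp3_high)
        counts = pd.DataFrame(
            {
                "probe": totals.probe,
                "item_class": totals.item_class,
                "n_total": totals.n_total * 10,
                "n_yes": rng.binomial(totals.n_total * 10, 0.3),
            }
        )
        fit = fit_ml(counts, exp3_model, seed=4)
        assert fit.df == 0
        assert fit.p_value is None

    def test_g2_calibrated_against_chi_square(self):
        """Under the model, G2 follows chi-square(df); check the mean."""
        design = build_design("exp2-font-neutral")
        model = build_dual_recollection_model(design)  # 8 params, 9 categories: df = 1
        rng = np.random.default_rng(31)
        theta = {p: 0.4 if not p.startswith("b_") else 0.15 for p in model.parameter_names}
        vec = np.array([theta[p] for p in model.parameter_names])
        p = model.p_yes(vec)
        totals = probe_cell_totals(design)
        base = np.array(
            [totals.set_index(["probe", "item_class"]).loc[c, "n_total"] for c in model.categories]
        )
        n = base * 30
        g2s = []
        for _ in range(250):
            y = rng.binomial(n, p)
            counts = pd.DataFrame(
                {
                    "probe": [c[0] for c in model.categories],
                    "item_class": [c[1] for c in model.categories],
                    "n_yes": y,
                    "n_total": n,
                }
            )
            fit = fit_ml(counts, model, n_starts=3, seed=int(rng.integers(2**31)), compute_se=False)
            g2s.append(fit.g2)
        assert fit.df == 1
        assert abs(float(np.mean(g2s)) - 1.0) < 0.1  # E[chi-square(1)] = 1


def test_fit_dataset_emits_batch_table(exp3_model):
    ds = make_experiment_dataset("exp3-high", seed=9, n_participants=4)
    table = fit_dataset(ds, exp3_model, n_starts=4, seed=0)
    assert len(table) == 4
    assert {f"est_{p}" for p in exp3_model.parameter_names} <= set(table.columns)
    assert {f"se_{p}" for p in exp3_model.parameter_names} <= set(table.columns)
    assert table["converged"].all()
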