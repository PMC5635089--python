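"""Mixed models, likelihood-ratio tests, ROC, ICC and nonparametrics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from aaquant.stats import (
    ModelSpec, SpecificationError, auc_mann_whitney, compute_icc,
    fit_lmm, group_tests, icc_band, linear_regression, lrt_select,
    mann_whitney, roc_threshold, wilcoxon_signed_rank,
)


def simulate_lmm(n_subjects=20, n_branches=60, beta=0.15, subj_sd=0.05,
                 resid_sd=0.10, seed=0, lobes=False):
    """Response = 1.0 + beta*CF + subject intercept + noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        status = "CF" if s < n_subjects // 2 else "control"
        b0 = rng.normal(0, subj_sd)
        for k in range(n_branches):
            rows.append({
                "subject_id": f"S{s}",
                "disease_status": status,
                "volume_state": "inspiration" if k % 2 else "expiration",
                "lobe": ["RUL", "RLL", "LUL", "LLL"][(k // 2) % 4],
                "AoutA": 1.0 + beta * (status == "CF") + b0
                + rng.normal(0, resid_sd),
            })
    return pd.DataFrame(rows)


def trapezoid_auc_oracle(values, labels):
    """Independent oracle: trapezoidal area under the empirical ROC curve."""
    from sklearn.metrics import roc_curve
    fpr, tpr, _ = roc_curve(labels, values)
    return float(np.trapezoid(tpr, fpr))


class TestLMM:
    def test_zero_noise_recovers_exactly(self):
        df = simulate_lmm(n_subjects=8, n_branches=20, beta=0.2,
                          subj_sd=0.0, resid_sd=0.0)
        fit = fit_lmm(df, ModelSpec("AoutA", fixed=("disease_status",),
                                    lobe_col=None))
        term = [t for t in fit.params.index if "disease_status" in t][0]
        est = -fit.params[term] if "control" in term else fit.params[term]
        assert est == pytest.approx(0.2, abs=1e-6)
        assert fit.var_subject < 1e-6 and fit.var_residual < 1e-6
        assert fit.singular

    def test_recovers_disease_effect(self):
        df = simulate_lmm(seed=3)
        fit = fit_lmm(df, ModelSpec("AoutA", lobe_col=None))
        term = [t for t in fit.params.index if "disease_status" in t][0]
        est = -fit.params[term] if "control" in term else fit.params[term]
        assert est == pytest.approx(0.15, abs=0.05)
        assert fit.var_subject == pytest.approx(0.05 ** 2, abs=0.004)
        assert fit.var_residual == pytest.approx(0.10 ** 2, rel=0.15)

    def test_balanced_design_matches_ols_oracle(self):
        df = simulate_lmm(n_subjects=10, n_branches=12, subj_sd=0.0, seed=5)
        fit = fit_lmm(df, ModelSpec("AoutA", lobe_col=None))
        import statsmodels.formula.api as smf
        ols = smf.ols("AoutA ~ disease_status + volume_state", df).fit()
        np.testing.assert_allclose(fit.params.to_numpy(),
                                   ols.params.to_numpy(), atol=1e-4)

    def test_rank_deficient_design_rejected(self):
        df = simulate_lmm(n_subjects=6, n_branches=10)
        df["dup"] = df["disease_status"]
        with pytest.raises(SpecificationError, match="rank-deficient"):
            fit_lmm(df, ModelSpec("AoutA", fixed=("disease_status", "dup"),
                                  lobe_col=None))

    def test_missing_columns_rejected(self):
        with pytest.raises(SpecificationError, match="missing"):
            fit_lmm(pd.DataFrame({"AoutA": [1.0, 2.0]}), ModelSpec("AoutA"))

    def test_lobe_variance_component_recovered(self):
        rng = np.random.default_rng(7)
        df = simulate_lmm(n_subjects=12, n_branches=40, subj_sd=0.05, seed=7)
        lobe_shift = {"RUL": 0.15, "RLL": -0.15, "LUL": 0.1, "LLL": -0.1}
        df["AoutA"] += df["lobe"].map(lobe_shift) * (1 + 0 * rng.random(len(df)))
        fit = fit_lmm(df, ModelSpec("AoutA"))
        assert fit.var_lobe > 0.008  # true lobe variance ~0.016


class TestLRT:
    def test_identical_models_statistic_zero(self):
        df = simulate_lmm(n_subjects=8, n_branches=10)
        spec = ModelSpec("AoutA", lobe_col=None)
        full = fit_lmm(df, spec, reml=False)
        stat, dof, p = lrt_select(full, full)
        assert stat == 0.0 and dof == 0 and p == 1.0

    def test_reml_fits_rejected(self):
        df = simulate_lmm(n_subjects=8, n_branches=10)
        full = fit_lmm(df, ModelSpec("AoutA", lobe_col=None))
        with pytest.raises(SpecificationError, match="ML"):
            lrt_select(full, full)

    def test_non_nested_rejected(self):
        df = simulate_lmm(n_subjects=8, n_branches=10)
        a = fit_lmm(df, ModelSpec("AoutA", fixed=("disease_status",),
                                  lobe_col=None), reml=False)
        b = fit_lmm(df, ModelSpec("AoutA", fixed=("volume_state",),
                                  lobe_col=None), reml=False)
        with pytest.raises(SpecificationError, match="nested"):
            lrt_select(a, b)

    def test_true_effect_detected(self):
        df = simulate_lmm(seed=11)
        full = fit_lmm(df, ModelSpec("AoutA", lobe_col=None), reml=False)
        reduced = fit_lmm(df, ModelSpec("AoutA", fixed=("volume_state",),
                                        lobe_col=None), reml=False)
        stat, dof, p = lrt_select(full, reduced)
        assert dof == 1 and p < 0.001


class TestROC:
    def test_rank_auc_equals_trapezoid_oracle_exhaustively(self):
        """All 2^n - 2 two-class labelings of a fixed value set, with ties."""
        rng = np.random.default_rng(0)
        values = np.round(rng.normal(size=7), 1)  # rounding forces ties
        for labels in itertools.product([0, 1], repeat=7):
            labels = np.array(labels, dtype=bool)
            if labels.all() or not labels.any():
                continue
            assert auc_mann_whitney(values, labels) == pytest.approx(
                trapezoid_auc_oracle(values, labels), abs=1e-12)

    def test_perfect_separation(self):
        res = roc_threshold([1, 2, 3, 10, 11, 12],
                            [False, False, False, True, True, True], n_boot=50)
        assert res.auc == 1.0
        assert 3 < res.threshold < 10
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(SpecificationError):
            roc_threshold([1.0, 2.0], [True, True])

    def test_youden_tie_breaks_toward_higher_threshold(self):
        # thresholds 1.5 and 2.5 give identical Youden; pick 2.5
        res = roc_threshold([1, 2, 3, 4], [False, False, True, True], n_boot=0)
        assert res.threshold == pytest.approx(2.5)

    def test_ci_contains_auc(self):
        rng = np.random.default_rng(1)
        vals = np.r_[rng.normal(0, 1, 50), rng.normal(1, 1, 50)]
        labs = np.r_[np.zeros(50, bool), np.ones(50, bool)]
        subj = np.repeat(np.arange(20), 5)
        res = roc_threshold(vals, labs, subjects=subj, n_boot=200,
                            rng=np.random.default_rng(2))
        assert res.auc_ci[0] <= res.auc <= res.auc_ci[1]

    def test_bootstrap_deterministic_given_seed(self):
        rng_vals = np.random.default_rng(3)
        vals = np.r_[rng_vals.normal(0, 1, 40), rng_vals.normal(1, 1, 40)]
        labs = np.r_[np.zeros(40, bool), np.ones(40, bool)]
        a = roc_threshold(vals, labs, n_boot=100, rng=np.random.default_rng(9))
        b = roc_threshold(vals, labs, n_boot=100, rng=np.random.default_rng(9))
        assert a.auc_ci == b.auc_ci


class TestICC:
    def icc_data(self, n_targets=60, between=1.0, within=1.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for t in range(n_targets):
            mu = rng.normal(0, between)
            for r in range(2):
                rows.append({"branch_id": f"t{t}",
                             "value": mu + rng.normal(0, within)})
        return pd.DataFrame(rows)

    def test_equal_variances_give_half(self):
        res = compute_icc(self.icc_data(n_targets=200, seed=4))
        assert res.icc == pytest.approx(0.5, abs=0.1)
        assert res.band in ("moderate", "good")

    def test_perfect_agreement(self):
        df = self.icc_data(within=0.0)
        res = compute_icc(df)
        assert res.icc == 1.0
        assert res.band == "very good"

    def test_no_replication_rejected(self):
        df = pd.DataFrame({"branch_id": ["a", "b"], "value": [1.0, 2.0]})
        with pytest.raises(SpecificationError, match="replication"):
            compute_icc(df)

    def test_hierarchical_nesting_counts_all_strata(self):
        rng = np.random.default_rng(8)
        rows = []
        for s in range(12):
            subj_mu = rng.normal(0, 1.0)
            for g in range(3):
                gen_mu = subj_mu + rng.normal(0, 0.5)
                for b in range(4):
                    mu = gen_mu + rng.normal(0, 0.5)
                    for _ in range(2):
                        rows.append({"subject_id": f"S{s}", "generation": g,
                                     "branch_id": f"S{s}g{g}b{b}",
                                     "value": mu + rng.normal(0, 0.7)})
        df = pd.DataFrame(rows)
        res = compute_icc(df, subject_col="subject_id",
                          generation_col="generation")
        # truth: between = 1 + .25 + .25 = 1.5, within = .49 -> ICC ~ 0.75
        assert res.icc == pytest.approx(0.75, abs=0.12)
        assert set(res.var_components) == {"subject", "generation", "branch",
                                           "residual"}

    @pytest.mark.parametrize("icc,band", [
        (0.2, "below-moderate"), (0.45, "moderate"), (0.7, "good"),
        (0.8, "very good"), (0.95, "very good"),
    ])
    def test_bands(self, icc, band):
        assert icc_band(icc) == band


class TestGroupTests:
    def test_identical_pairs_p_one(self):
        res = wilcoxon_signed_rank([3, 4, 5], [3, 4, 5])
        assert res["p"] == 1.0

    def test_pairing_mismatch_rejected(self):
        with pytest.raises(SpecificationError):
            wilcoxon_signed_rank([1, 2, 3], [1, 2])

    def test_mann_whitney_type_i_error_calibrated(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_sims = 400
        for _ in range(n_sims):
            x, y = rng.normal(size=(2, 30))
            if mann_whitney(x, y)["p"] <= 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_sims <= 0.10

    def test_regression_null_p_uniform(self):
        rng = np.random.default_rng(1)
        pvals = [linear_regression(rng.normal(size=25),
                                   rng.normal(size=25))["p"]
                 for _ in range(200)]
        # uniformity of null p-values (Kolmogorov-Smirnov)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01
        frac = np.mean(np.asarray(pvals) <= 0.05)
        assert 0.01 <= frac <= 0.11

    def test_battery_on_count_table(self):
        rows = []
        rng = np.random.default_rng(2)
        for s in range(8):
            status = "CF" if s < 4 else "control"
            base = 120 if status == "CF" else 80
            for state, frac in (("inspiration", 1.0), ("expiration", 0.5)):
                rows.append({"subject_id": f"S{s}", "disease_status": status,
                             "volume_state": state,
                             "n_ok": int(base * frac + rng.integers(0, 10)),
                             "age_years": 8 + s, "height_cm": 120 + 4 * s})
        res = group_tests(pd.DataFrame(rows))
        assert res["wilcoxon_insp_vs_exp_CF"]["p"] < 0.15
        assert "mannwhitney_cf_vs_control_inspiration" in res
        assert "regression_count_vs_height" in res

    def test_battery_missing_state_rejected(self):
        df = pd.DataFrame([{"subject_id": "a", "disease_status": "CF",
                            "volume_state": "inspiration", "n_ok": 5}])
        with pytest.raises(SpecificationError):
            group_tests(df)
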