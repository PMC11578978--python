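"""The logistic scorer, stepwise fitting, ROC/Youden and metrics."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sst
from scipy.special import expit

from adhdm import (adhdm_score, classification_metrics,
                   derive_confusion_from_rates, fit_stepwise_logit,
                   moderator_glm, prepare_design, published_model,
                   roc_and_youden, stress_reactivity)
from adhdm.model import SeparationError
from adhdm.simulate import simulate_labelled_cohort


def baseline_features(model, z=0.0):
    """Feature values whose standardized predictors all equal ``z``."""
    s = model.standardization
    return {
        "RMSSD": np.exp(s["log_RMSSD"][0] + z * s["log_RMSSD"][1]),
        "RR": s["RR"][0] + z * s["RR"][1],
        "stdTonic": np.exp(s["log_stdTonic"][0] + z * s["log_stdTonic"][1]),
        "mPhasic": np.exp(s["log_mPhasic"][0] + z * s["log_mPhasic"][1]),
    }


class TestScorer:
    def test_female_age9_at_zero_predictors(self, model):
        """Linear predictor collapses to intercept + age term: -0.4436."""
        p = adhdm_score(baseline_features(model), "female", 9, model)
        assert p == pytest.approx(expit(4.6315 - 0.5639 * 9), abs=1e-6)
        assert p == pytest.approx(0.391, abs=0.001)

    def test_male_age9_adds_gender_coefficient(self, model):
        p = adhdm_score(baseline_features(model), "male", 9, model)
        assert p == pytest.approx(expit(4.6315 - 0.5639 * 9 + 0.4627),
                                  abs=1e-6)
        assert p == pytest.approx(0.505, abs=0.001)

    def test_monotone_in_tonic_variability(self, model):
        """stdTonic has a positive coefficient, so the score increases."""
        scores = []
        for z in (-1.0, 0.0, 1.0, 2.0):
            fv = baseline_features(model)
            s = model.standardization["log_stdTonic"]
            fv["stdTonic"] = np.exp(s[0] + z * s[1])
            scores.append(adhdm_score(fv, "female", 9, model))
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_nonpositive_log_input_missing(self, model):
        fv = baseline_features(model)
        fv["mPhasic"] = 0.0
        with pytest.warns(UserWarning, match="non-positive"):
            assert np.isnan(adhdm_score(fv, "female", 9, model))


class TestStepwise:
    def test_noise_covariate_removed(self, model):
        removed = 0
        n_rep = 20
        for seed in range(n_rep):
            c = simulate_labelled_cohort(200, model, seed=seed)
            rng = np.random.default_rng(seed + 5000)
            c["noise"] = rng.normal(size=len(c))
            design = prepare_design(c, ["RMSSD", "RR", "stdTonic",
                                        "mPhasic", "noise"])
            y = (c.group == "ADHD").astype(float).to_numpy()
            fit = fit_stepwise_logit(
                design, y, ["log_RMSSD", "RR", "log_stdTonic",
                            "log_mPhasic", "noise"])
            if "noise" not in fit.retained:
                removed += 1
        assert removed >= int(0.8 * n_rep)

    def test_true_predictors_retained_in_majority(self, model):
        hits = 0
        n_rep = 20
        truth = {"log_RMSSD", "RR", "log_stdTonic", "log_mPhasic"}
        for seed in range(n_rep):
            c = simulate_labelled_cohort(200, model, seed=seed + 300)
            design = prepare_design(c, ["RMSSD", "RR", "stdTonic", "mPhasic"])
            y = (c.group == "ADHD").astype(float).to_numpy()
            fit = fit_stepwise_logit(design, y, sorted(truth))
            if set(fit.retained) == truth:
                hits += 1
        assert hits > n_rep / 2

    def test_perfect_separation_raises(self):
        n = 60
        y = np.repeat([0.0, 1.0], n // 2)
        design = pd.DataFrame({
            "gender_male": np.tile([0.0, 1.0], n // 2),
            "age": np.linspace(7, 12, n),
            "sep": y * 2 - 1,  # perfectly separates
        })
        with pytest.raises(SeparationError):
            fit_stepwise_logit(design, y, ["sep"])


class TestRocYouden:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        labels = np.array([0, 0, 0, 1, 1])
        out = roc_and_youden(scores, labels)
        assert out["AUC"] == 1.0 and out["J"] == 1.0
        assert 0.3 < out["cutoff"] < 0.8

    def test_uninformative_scores(self):
        out = roc_and_youden(np.full(10, 0.5), [0, 1] * 5)
        assert out["AUC"] == 0.5

    def test_cutoff_matches_bruteforce_enumeration(self, rng):
        """Youden cutoff agrees with exhaustive threshold search."""
        for _ in range(100):
            scores = rng.random(20)
            labels = rng.random(20) < 0.5
            if labels.all() or not labels.any():
                continue
            out = roc_and_youden(scores, labels)
            best_j = -np.inf
            for thr in np.unique(np.concatenate([[0.0], scores, [1.0]])):
                pred = scores >= thr
                j = (pred[labels].mean() + (~pred[~labels]).mean() - 1)
                best_j = max(best_j, j)
            assert out["J"] == pytest.approx(best_j, abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.random(50)
        labels = rng.random(50) < 0.4
        a1 = roc_and_youden(scores, labels)["AUC"]
        a2 = roc_and_youden(np.exp(3 * scores), labels)["AUC"]
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_and_youden([0.1, 0.9], [1, 1])


class TestMetrics:
    def test_perfect_agreement(self):
        rep = classification_metrics([1, 0, 1], [1, 0, 1])
        assert rep.sensitivity == rep.specificity == rep.accuracy == 1.0

    def test_published_confusion_metrics(self):
        """TP=42, FP=4, FN=7, TN=23 reproduce the published 85.5 / 91.3 /
        88.4 percent metrics."""
        labels = [1] * 49 + [0] * 27
        preds = [1] * 42 + [0] * 7 + [1] * 4 + [0] * 23
        rep = classification_metrics(labels, preds)
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (42, 4, 7, 23)
        assert round(100 * rep.accuracy, 1) == 85.5
        assert round(100 * rep.precision, 1) == 91.3
        assert round(100 * rep.f1, 1) == 88.4

    def test_metrics_match_direct_formulas(self, rng):
        for _ in range(100):
            labels = rng.random(40) < 0.5
            preds = rng.random(40) < 0.5
            if not labels.any() or labels.all() or not preds.any():
                continue
            rep = classification_metrics(labels, preds)
            tp = np.sum(labels & preds)
            assert rep.accuracy == pytest.approx(
                np.mean(labels == preds), abs=1e-12)
            assert rep.precision == pytest.approx(tp / preds.sum(), abs=1e-12)
            assert rep.f1 == pytest.approx(
                2 * tp / (2 * tp + np.sum(~labels & preds)
                          + np.sum(labels & ~preds)), abs=1e-12)

    def test_derive_confusion_published_rates(self):
        rep = derive_confusion_from_rates(0.857, 0.852, 49, 27)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (42, 7, 23, 4)

    def test_derive_confusion_trivial_cases(self):
        rep = derive_confusion_from_rates(1.0, 1.0, 10, 5)
        assert rep.fn == 0 and rep.fp == 0
        rep = derive_confusion_from_rates(0.5, 1.0, 10, 5)
        assert rep.tp == 5 and rep.fn == 5


@settings(deadline=None, max_examples=50, derandomize=True)
@given(tp=st.integers(0, 50), fp=st.integers(0, 50),
       fn=st.integers(0, 50), tn=st.integers(0, 50))
def test_report_metrics_consistent_with_counts(tp, fp, fn, tn):
    """Stored metrics always recompute exactly from the integer counts."""
    from adhdm.model import ClassificationReport

    if tp + fn == 0 or tn + fp == 0 or tp + fp == 0 or tp == 0:
        return
    rep = ClassificationReport(tp=tp, fp=fp, fn=fn, tn=tn)
    d = rep.as_dict()
    assert d["sensitivity"] == tp / (tp + fn)
    assert d["specificity"] == tn / (tn + fp)
    assert d["accuracy"] == (tp + tn) / (tp + fp + fn + tn)
    assert all(0 <= d[k] <= 1 for k in
               ("sensitivity", "specificity", "accuracy", "precision", "F1"))


class TestReactivity:
    def make_cohort(self, delta_adhd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for group, n in (("TD", 20), ("ADHD", 20)):
            for i in range(n):
                sid = f"{group}{i}"
                base = rng.normal(1.0, 0.1)
                d = rng.normal(0, 0.05) + (delta_adhd if group == "ADHD" else 0)
                rows.append((sid, group, "baseline", base))
                rows.append((sid, group, "stress", base + d))
        return pd.DataFrame(rows, columns=["subject_id", "group", "stage",
                                           "mTonic"])

    def test_duplicated_stage_null_deltas(self):
        c = self.make_cohort()
        c.loc[c.stage == "stress", "mTonic"] = \
            c.loc[c.stage == "baseline", "mTonic"].to_numpy()
        recs = stress_reactivity(c, ["mTonic"])
        assert np.allclose(recs[0].deltas["delta"], 0.0)
        assert recs[0].comparison.p_value > 0.9

    def test_planted_group_delta_detected(self):
        recs = stress_reactivity(self.make_cohort(delta_adhd=0.3), ["mTonic"])
        assert recs[0].comparison.p_value < 0.05

    def test_missing_stage_reduces_n(self):
        c = self.make_cohort()
        c = c[~((c.subject_id == "TD0") & (c.stage == "stress"))]
        recs = stress_reactivity(c, ["mTonic"])
        assert len(recs[0].deltas) == 39


class TestModeratorGLM:
    def test_two_level_equals_t_test(self, rng):
        scores = rng.random(40)
        cov = np.array(["a", "b"] * 20)
        out = moderator_glm(scores, cov)
        t_p = sst.ttest_ind(scores[cov == "a"], scores[cov == "b"]).pvalue
        assert out["p"] == pytest.approx(t_p, rel=1e-9)

    def test_perfect_moderator(self, rng):
        scores = rng.random(40)
        cov = np.where(scores > np.median(scores), "hi", "lo")
        out = moderator_glm(scores, cov)
        assert out["p"] < 1e-3
        assert out["estimates"]["hi"] > out["estimates"]["lo"]

    def test_null_moderator_p_uniform(self, model):
        """Under independence the moderator p-value is uniform."""
        pvals = []
        rng = np.random.default_rng(17)
        for _ in range(200):
            scores = rng.random(60)
            cov = rng.choice(["x", "y", "z"], size=60)
            pvals.append(moderator_glm(scores, cov)["p"])
        ks = sst.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_single_level_errors(self):
        with pytest.raises(ValueError):
            moderator_glm([0.1, 0.2, 0.3], ["a", "a", "a"])
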