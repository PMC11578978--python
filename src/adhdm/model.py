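"""The multiparametric logistic ADHD classifier (ADHDm) and its metrics.

The shipped model combines four baseline autonomic parameters —
log RMSSD (vagal tone), respiratory rate, log tonic-EDA variability and
log mean phasic EDA — adjusted by gender and age, with a fixed published
coefficient vector and a Youden-selected probability cutoff of 0.63.
Physiological predictors are z-scored before the coefficients apply; the
original standardization constants were not published, so the default
constants are reconstructed from the published per-group baseline moments
(pooled across groups) and are labelled as such in the serialized model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy import stats as sst

import statsmodels.api as sm

from .moments import (PUBLISHED_GROUP_SIZES, lognormal_params,
                      published_moments)
from .stats import GroupComparison, compare_groups

#: published coefficient vector of the final model
ADHDM_COEFFICIENTS = {
    "intercept": 4.6315,
    "gender_male": 0.4627,
    "age": -0.5639,
    "log_RMSSD": 0.8023,
    "RR": -0.7679,
    "log_stdTonic": 2.8265,
    "log_mPhasic": -2.2015,
}
ADHDM_CUTOFF = 0.63

#: physiological predictor -> (source feature, log-transformed?)
PREDICTOR_SOURCES = {
    "log_RMSSD": ("RMSSD", True),
    "RR": ("RR", False),
    "log_stdTonic": ("stdTonic", True),
    "log_mPhasic": ("mPhasic", True),
}

#: feature-table columns the model log-transforms before standardizing
LOG_FEATURES = ("RMSSD", "stdTonic", "mPhasic")


class SeparationError(RuntimeError):
    """Raised when a candidate perfectly separates the classes."""


@dataclass
class ADHDmModel:
    """Fixed-coefficient logistic scorer with standardization constants."""

    coefficients: dict[str, float]
    standardization: dict[str, tuple[float, float]]
    cutoff: float = ADHDM_CUTOFF
    provenance: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must lie in (0, 1)")
        for name, (_, sd) in self.standardization.items():
            if sd <= 0:
                raise ValueError(f"standardization SD for {name} must be > 0")

    def linear_predictor(self, features, gender: str, age: float) -> float:
        lp = self.coefficients["intercept"]
        lp += self.coefficients["gender_male"] * (gender == "male")
        lp += self.coefficients["age"] * float(age)
        for pred, (src, use_log) in PREDICTOR_SOURCES.items():
            value = features[src]
            if value is None or not np.isfinite(value):
                return np.nan
            if use_log:
                if value <= 0:
                    warnings.warn(
                        f"non-positive {src} under a log term; score missing",
                        stacklevel=2)
                    return np.nan
                value = np.log(value)
            mean, sd = self.standardization[pred]
            lp += self.coefficients[pred] * (value - mean) / sd
        return float(lp)

    def to_json(self, path) -> None:
        doc = {"coefficients": self.coefficients,
               "standardization": {k: list(v) for k, v
                                   in self.standardization.items()},
               "cutoff": self.cutoff, "provenance": self.provenance}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ADHDmModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(coefficients=doc["coefficients"],
                   standardization={k: tuple(v) for k, v
                                    in doc["standardization"].items()},
                   cutoff=doc["cutoff"], provenance=doc.get("provenance", ""))


def reconstructed_standardization() -> dict[str, tuple[float, float]]:
    """Standardization constants rebuilt from the published baseline
    moments, pooled across groups with the per-parameter available n."""
    moments = published_moments()
    out = {}
    for pred, (src, use_log) in PREDICTOR_SOURCES.items():
        stats = []
        for group, pre in (("TD", "td"), ("ADHD", "adhd")):
            row = moments.table.loc[src]
            n = float(row[f"{pre}_n"])
            mean, sd = float(row[f"{pre}_mean"]), float(row[f"{pre}_sd"])
            if use_log:
                mean, sd = lognormal_params(mean, sd)
            stats.append((n, mean, sd))
        n_tot = sum(s[0] for s in stats)
        mu = sum(s[0] * s[1] for s in stats) / n_tot
        second = sum(s[0] * (s[2] ** 2 + s[1] ** 2) for s in stats) / n_tot
        out[pred] = (mu, float(np.sqrt(second - mu ** 2)))
    return out


def published_model() -> ADHDmModel:
    """The published coefficient vector with reconstructed constants."""
    return ADHDmModel(
        coefficients=dict(ADHDM_COEFFICIENTS),
        standardization=reconstructed_standardization(),
        cutoff=ADHDM_CUTOFF,
        provenance=("coefficients as published; standardization constants "
                    "reconstructed from pooled published baseline moments"))


def adhdm_score(features, gender: str, age: float,
                model: ADHDmModel | None = None) -> float:
    """Probability that the subject belongs to the ADHD class."""
    model = model or published_model()
    lp = model.linear_predictor(features, gender, age)
    return float(expit(lp)) if np.isfinite(lp) else np.nan


def score_cohort(cohort: pd.DataFrame,
                 model: ADHDmModel | None = None) -> pd.Series:
    """Vectorized ADHDm score per cohort row."""
    model = model or published_model()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cohort.apply(
            lambda row: adhdm_score(row, row["gender"], row["age"], model),
            axis=1)


# ---------------------------------------------------------------------------
# design-set fitting


def prepare_design(cohort: pd.DataFrame, candidates: list[str],
                   standardization: dict | None = None) -> pd.DataFrame:
    """Log-transform skewed candidates and z-score all of them.

    Returns a frame with columns ``gender_male``, ``age`` and one z-scored
    column per candidate (named ``log_<name>`` where a log applies).
    Sample moments are used unless explicit constants are given.
    """
    out = pd.DataFrame(index=cohort.index)
    out["gender_male"] = (cohort["gender"] == "male").astype(float)
    out["age"] = cohort["age"].astype(float)
    for name in candidates:
        vals = cohort[name].astype(float)
        col = name
        if name in LOG_FEATURES:
            if (vals <= 0).any():
                raise ValueError(f"non-positive values under log for {name}")
            vals = np.log(vals)
            col = f"log_{name}"
        if standardization and col in standardization:
            mean, sd = standardization[col]
        else:
            mean, sd = float(vals.mean()), float(vals.std(ddof=1))
        if sd == 0:
            raise ValueError(f"zero variance candidate {name}")
        out[col] = (vals - mean) / sd
    return out


@dataclass
class StepwiseFit:
    retained: list[str]
    forced: list[str]
    table: pd.DataFrame     # coef, se, wald_chi2, p per term
    result: object = field(repr=False, default=None)

    @property
    def coefficients(self) -> pd.Series:
        return self.table["coef"]


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, Xc).fit(disp=0, maxiter=500, method="lbfgs")
    if np.abs(res.params).max() > 50 or np.isnan(res.bse).any():
        worst = Xc.columns[int(np.argmax(np.abs(res.params)))]
        raise SeparationError(
            f"quasi-complete separation (term {worst!r})")
    return res


def fit_stepwise_logit(design: pd.DataFrame, y, candidates: list[str],
                       forced: tuple[str, ...] = ("gender_male", "age"),
                       alpha: float = 0.05) -> StepwiseFit:
    """Backward-stepwise logistic fit with forced adjustment terms.

    Starting from forced + candidates, the non-forced term with the
    largest Wald p-value above ``alpha`` is removed and the model refit
    until every non-forced term is significant.  Forced terms are never
    removed.
    """
    y = np.asarray(y, dtype=float)
    terms = list(forced) + [c for c in candidates if c not in forced]
    while True:
        res = _fit_logit(y, design[terms])
        pvals = res.pvalues.drop("const")
        droppable = pvals[[t for t in terms if t not in forced]]
        if droppable.empty or droppable.max() <= alpha:
            break
        terms.remove(droppable.idxmax())
    table = pd.DataFrame({
        "coef": res.params, "se": res.bse,
        "wald_chi2": (res.params / res.bse) ** 2,
        "p": res.pvalues})
    retained = [t for t in terms if t not in forced]
    return StepwiseFit(retained=retained, forced=list(forced),
                       table=table, result=res)


# ---------------------------------------------------------------------------
# ROC, Youden cutoff, confusion metrics


def roc_and_youden(scores, labels) -> dict[str, float]:
    """AUC (rank formulation with tie correction) and Youden cutoff.

    The cutoff is placed at the midpoint between adjacent distinct scores
    maximizing sensitivity + specificity - 1; ties break toward the lower
    threshold.  Predictions use score >= cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos, n_neg = labels.sum(), (~labels).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sst.rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    uniq = np.unique(scores)
    thresholds = np.concatenate([[uniq[0] - 1.0],
                                 (uniq[:-1] + uniq[1:]) / 2,
                                 [uniq[-1] + 1.0]])
    best_j, best_thr = -np.inf, thresholds[0]
    for thr in thresholds:
        pred = scores >= thr
        sens = (pred & labels).sum() / n_pos
        spec = (~pred & ~labels).sum() / n_neg
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_thr = j, thr
    return {"AUC": float(auc), "cutoff": float(best_thr), "J": float(best_j)}


@dataclass
class ClassificationReport:
    tp: int
    fp: int
    fn: int
    tn: int
    cutoff: float | None = None
    auc: float | None = None

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fp + self.fn + self.tn)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp)

    @property
    def f1(self) -> float:
        return 2 * self.tp / (2 * self.tp + self.fp + self.fn)

    def as_dict(self) -> dict:
        d = {"TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn,
             "sensitivity": self.sensitivity, "specificity": self.specificity,
             "accuracy": self.accuracy, "precision": self.precision,
             "F1": self.f1}
        if self.cutoff is not None:
            d["cutoff"] = self.cutoff
        if self.auc is not None:
            d["AUC"] = self.auc
        return d

    def to_text(self) -> str:
        lines = [f"          predicted+  predicted-",
                 f"actual+   TP={self.tp:<8d} FN={self.fn:<8d}",
                 f"actual-   FP={self.fp:<8d} TN={self.tn:<8d}", ""]
        for name in ("sensitivity", "specificity", "accuracy",
                     "precision", "f1"):
            lines.append(f"{name:<12s} {100 * getattr(self, name):.1f}%")
        if self.auc is not None:
            lines.append(f"{'AUC':<12s} {self.auc:.3f}")
        return "\n".join(lines)


def classification_metrics(labels, predictions,
                           cutoff: float | None = None,
                           auc: float | None = None) -> ClassificationReport:
    """Confusion counts and the five standard metrics."""
    labels = np.asarray(labels).astype(bool)
    predictions = np.asarray(predictions).astype(bool)
    if labels.size == 0 or labels.size != predictions.size:
        raise ValueError("labels and predictions must be equal-length, "
                         "non-empty")
    tp = int((labels & predictions).sum())
    fp = int((~labels & predictions).sum())
    fn = int((labels & ~predictions).sum())
    tn = int((~labels & ~predictions).sum())
    return ClassificationReport(tp=tp, fp=fp, fn=fn, tn=tn,
                                cutoff=cutoff, auc=auc)


def derive_confusion_from_rates(sensitivity: float, specificity: float,
                                n_pos: int, n_neg: int) -> ClassificationReport:
    """Integer confusion matrix implied by printed rates and class sizes."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class sizes must be >= 1")
    tp = int(round(sensitivity * n_pos))
    tn = int(round(specificity * n_neg))
    return ClassificationReport(tp=tp, fn=n_pos - tp, tn=tn, fp=n_neg - tn)


# ---------------------------------------------------------------------------
# stress reactivity and moderator analyses


@dataclass
class ReactivityRecord:
    parameter: str
    deltas: pd.DataFrame     # subject_id, group, delta
    comparison: GroupComparison


def stress_reactivity(cohort: pd.DataFrame,
                      parameters: list[str] | None = None,
                      alpha: float = 0.05) -> list[ReactivityRecord]:
    """Stress-minus-baseline deltas per subject and their group comparison.

    Subjects missing either stage for a parameter are excluded from that
    parameter's comparison.
    """
    if parameters is None:
        parameters = [c for c in cohort.columns
                      if pd.api.types.is_float_dtype(cohort[c])]
    base = cohort[cohort["stage"] == "baseline"].set_index("subject_id")
    stress = cohort[cohort["stage"] == "stress"].set_index("subject_id")
    common = base.index.intersection(stress.index)
    records = []
    for name in parameters:
        delta = (stress.loc[common, name].astype(float)
                 - base.loc[common, name].astype(float)).dropna()
        frame = pd.DataFrame({
            "subject_id": delta.index,
            "group": base.loc[delta.index, "group"].to_numpy(),
            "delta": delta.to_numpy()})
        cmp_table = frame.rename(columns={"delta": name})
        comparison = compare_groups(cmp_table, name, alpha=alpha)
        records.append(ReactivityRecord(parameter=name, deltas=frame,
                                        comparison=comparison))
    return records


def moderator_glm(scores, covariate) -> dict:
    """Gaussian GLM of model scores on a categorical moderator.

    Returns the overall F-test p-value and per-level mean estimates.
    """
    scores = pd.Series(np.asarray(scores, dtype=float))
    covariate = pd.Series(np.asarray(covariate, dtype=object),
                          index=scores.index)
    levels = covariate.value_counts()
    if len(levels) < 2 or (levels < 2).any():
        raise ValueError("need >= 2 covariate levels with >= 2 observations")
    dummies = pd.get_dummies(covariate, drop_first=True).astype(float)
    X = sm.add_constant(dummies)
    res = sm.OLS(scores.to_numpy(), X.to_numpy()).fit()
    estimates = {lvl: float(scores[covariate == lvl].mean())
                 for lvl in levels.index}
    return {"p": float(res.f_pvalue), "estimates": estimates}


def confusion_at_cutoff(scores, labels, cutoff: float) -> ClassificationReport:
    """Classify at a fixed probability cutoff and summarize."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    auc = roc_and_youden(scores, labels)["AUC"]
    return classification_metrics(labels, scores >= cutoff,
                                  cutoff=cutoff, auc=auc)
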