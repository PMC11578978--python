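"""Cohort-level statistics: descriptive comparisons, EM imputation,
propensity-score matching, balance checks, and VIF variable reduction.

Test selection mirrors common biostatistical practice: Shapiro-Wilk
normality per group decides between Student's t and Mann-Whitney U, with a
log transformation attempted for skewed strictly-positive variables;
categorical variables use the chi-square test without continuity
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

import statsmodels.api as sm

from .types import GROUPS


@dataclass
class GroupComparison:
    parameter: str
    n_td: int
    n_adhd: int
    mean_td: float
    sd_td: float
    mean_adhd: float
    sd_adhd: float
    test: str              # "t", "mannwhitney" or "chi2"
    transform: str         # "none" or "log"
    p_value: float
    shapiro_p: dict = field(default_factory=dict)


def _group_values(cohort: pd.DataFrame, parameter: str):
    vals = {}
    for g in GROUPS:
        v = cohort.loc[cohort["group"] == g, parameter].dropna()
        if v.empty:
            raise ValueError(
                f"group {g} has no observed values for {parameter!r}")
        vals[g] = v
    return vals["TD"], vals["ADHD"]


def compare_groups(cohort: pd.DataFrame, parameter: str,
                   alpha: float = 0.05) -> GroupComparison:
    """Two-group comparison with normality-driven test selection."""
    col = cohort[parameter]
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        table = pd.crosstab(cohort[parameter], cohort["group"])
        chi2 = sst.chi2_contingency(table.values, correction=False)
        counts = table.sum()
        return GroupComparison(
            parameter=parameter,
            n_td=int(counts.get("TD", 0)), n_adhd=int(counts.get("ADHD", 0)),
            mean_td=np.nan, sd_td=np.nan, mean_adhd=np.nan, sd_adhd=np.nan,
            test="chi2", transform="none", p_value=float(chi2.pvalue))

    td, adhd = _group_values(cohort, parameter)
    if len(td) < 3 or len(adhd) < 3:
        raise ValueError(
            f"need >= 3 observed values per group for {parameter!r}")
    stats = dict(
        parameter=parameter, n_td=len(td), n_adhd=len(adhd),
        mean_td=float(td.mean()), sd_td=float(td.std(ddof=1)),
        mean_adhd=float(adhd.mean()), sd_adhd=float(adhd.std(ddof=1)))

    def shapiro_pair(a, b):
        return float(sst.shapiro(a).pvalue), float(sst.shapiro(b).pvalue)

    if td.nunique() == 1 and adhd.nunique() == 1:
        # degenerate: identical constants within groups
        p = 1.0 if td.iloc[0] == adhd.iloc[0] else 0.0
        return GroupComparison(**stats, test="t", transform="none",
                               p_value=p)

    sw_td, sw_adhd = shapiro_pair(td, adhd)
    shapiro_p = {"TD": sw_td, "ADHD": sw_adhd}
    if sw_td > alpha and sw_adhd > alpha:
        p = sst.ttest_ind(td, adhd).pvalue
        return GroupComparison(**stats, test="t", transform="none",
                               p_value=float(p), shapiro_p=shapiro_p)
    if (td > 0).all() and (adhd > 0).all():
        ltd, ladhd = np.log(td), np.log(adhd)
        sw_ltd, sw_ladhd = shapiro_pair(ltd, ladhd)
        shapiro_p.update({"TD_log": sw_ltd, "ADHD_log": sw_ladhd})
        if sw_ltd > alpha and sw_ladhd > alpha:
            p = sst.ttest_ind(ltd, ladhd).pvalue
            return GroupComparison(**stats, test="t", transform="log",
                                   p_value=float(p), shapiro_p=shapiro_p)
    p = sst.mannwhitneyu(td, adhd, alternative="two-sided").pvalue
    return GroupComparison(**stats, test="mannwhitney", transform="none",
                           p_value=float(p), shapiro_p=shapiro_p)


# ---------------------------------------------------------------------------
# EM-based imputation


def em_mvn(X: np.ndarray, max_iter: int = 200,
           tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """ML mean/covariance of a multivariate normal with missing entries.

    Classic EM: missing coordinates are replaced by their conditional
    expectations and the covariance update includes the conditional
    covariance correction.  On complete data this returns the sample
    moments (ddof=0) after one step.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    miss = np.isnan(X)
    if miss.all(axis=0).any():
        raise ValueError("a column is entirely missing")
    Xf = X.copy()
    col_mean = np.nanmean(X, axis=0)
    for j in range(p):
        Xf[miss[:, j], j] = col_mean[j]
    mu = Xf.mean(axis=0)
    sigma = np.cov(Xf, rowvar=False, ddof=0) + 1e-8 * np.eye(p)

    patterns: dict[bytes, np.ndarray] = {}
    for i in range(n):
        patterns.setdefault(miss[i].tobytes(), []).append(i)
    patterns = {k: np.asarray(v) for k, v in patterns.items()}

    for _ in range(max_iter):
        scatter_corr = np.zeros((p, p))
        for key, rows in patterns.items():
            m = np.frombuffer(key, dtype=bool)
            if not m.any():
                continue
            o = ~m
            Soo = sigma[np.ix_(o, o)]
            Smo = sigma[np.ix_(m, o)]
            W = Smo @ np.linalg.pinv(Soo)
            cond_cov = sigma[np.ix_(m, m)] - W @ Smo.T
            for i in rows:
                Xf[i, m] = mu[m] + W @ (X[i, o] - mu[o])
            scatter_corr[np.ix_(m, m)] += len(rows) * cond_cov
        mu_new = Xf.mean(axis=0)
        diff = Xf - mu_new
        sigma_new = (diff.T @ diff + scatter_corr) / n
        delta = max(np.abs(mu_new - mu).max(),
                    np.abs(sigma_new - sigma).max())
        mu, sigma = mu_new, sigma_new
        if delta < tol:
            break
    return mu, sigma


def impute_missing(cohort: pd.DataFrame,
                   feature_cols: list[str] | None = None,
                   n_draws: int = 0, seed: int = 0) -> pd.DataFrame:
    """Fill missing feature entries by EM conditional expectations.

    Features are z-scored (observed moments) before the EM fit and
    back-transformed after.  With ``n_draws`` > 0, that many draws from
    the conditional normal are averaged instead (a multiple-imputation
    variant pooled by averaging).  Observed cells and metadata are never
    modified.
    """
    if feature_cols is None:
        feature_cols = [c for c in cohort.columns
                        if pd.api.types.is_float_dtype(cohort[c])]
    X = cohort[feature_cols].to_numpy(dtype=float)
    obs_frac = 1.0 - np.isnan(X).mean(axis=0)
    if (obs_frac < 0.5).any():
        bad = [c for c, f in zip(feature_cols, obs_frac) if f < 0.5]
        raise ValueError(f"columns under 50% observed: {bad}")
    center = np.nanmean(X, axis=0)
    scale = np.nanstd(X, axis=0, ddof=1)
    scale[scale == 0] = 1.0
    Z = (X - center) / scale
    if not np.isnan(Z).any():
        return cohort.copy()
    mu, sigma = em_mvn(Z)

    Zf = Z.copy()
    miss = np.isnan(Z)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for i in range(Z.shape[0]):
        m = miss[i]
        if not m.any():
            continue
        o = ~m
        Soo = sigma[np.ix_(o, o)]
        Smo = sigma[np.ix_(m, o)]
        W = Smo @ np.linalg.pinv(Soo)
        cond_mean = mu[m] + W @ (Z[i, o] - mu[o])
        if n_draws > 0:
            cond_cov = sigma[np.ix_(m, m)] - W @ Smo.T
            draws = rng.multivariate_normal(
                cond_mean, cond_cov, size=n_draws, method="svd")
            Zf[i, m] = draws.mean(axis=0)
        else:
            Zf[i, m] = cond_mean
    out = cohort.copy()
    filled = Zf * scale + center
    filled[~miss] = X[~miss]  # observed cells bitwise untouched
    out[feature_cols] = filled
    return out


# ---------------------------------------------------------------------------
# propensity-score matching


@dataclass
class MatchResult:
    propensity_coef: pd.Series
    log_propensity: pd.Series          # indexed by subject_id
    pairs: dict                        # td_id -> [adhd_id, ...]
    matched_ids: list
    balance: dict                      # {"pre": {...}, "post": {...}}
    caliper: float


def _design(cohort: pd.DataFrame, covariates) -> pd.DataFrame:
    d = pd.DataFrame(index=cohort.index)
    for c in covariates:
        if c == "gender":
            d["gender_male"] = (cohort["gender"] == "male").astype(float)
        else:
            d[c] = cohort[c].astype(float)
    return d


def _covariate_balance_p(cohort: pd.DataFrame) -> dict[str, float]:
    out = {}
    table = pd.crosstab(cohort["gender"], cohort["group"])
    if table.shape == (2, 2):
        out["gender"] = float(
            sst.chi2_contingency(table.values, correction=False).pvalue)
    else:
        out["gender"] = np.nan
    td = cohort.loc[cohort["group"] == "TD", "age"].astype(float)
    ad = cohort.loc[cohort["group"] == "ADHD", "age"].astype(float)
    if len(td) > 1 and len(ad) > 1 and (td.std() > 0 or ad.std() > 0):
        out["age"] = float(sst.ttest_ind(td, ad).pvalue)
    else:
        out["age"] = np.nan
    return out


def match_cohort(cohort: pd.DataFrame,
                 covariates: tuple[str, ...] = ("gender", "age"),
                 caliper: float = 0.2, max_ratio: int = 2) -> MatchResult:
    """Greedy nearest-neighbor matching on the log propensity score.

    TD subjects anchor the pairs (processed in descending propensity
    order, hardest to match first); each receives up to ``max_ratio``
    distinct ADHD subjects within the caliper (given in SDs of the log
    propensity; 0 demands exact ties).  ADHD subjects are used without
    replacement.  TD subjects with no admissible match are dropped with a
    warning.
    """
    base = cohort.drop_duplicates("subject_id")
    X = _design(base, covariates)
    y = (base["group"] == "ADHD").astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError("both groups must be present")
    Xc = sm.add_constant(X.to_numpy())
    if np.allclose(X.to_numpy().std(axis=0), 0):
        prop = np.full(len(base), y.mean())
        coef = pd.Series(dtype=float)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        prop = np.clip(fit.predict(Xc), 1e-12, 1 - 1e-12)
        coef = pd.Series(fit.params, index=["const"] + list(X.columns))
    logp = pd.Series(np.log(prop), index=base["subject_id"].to_numpy())

    sd = float(logp.std(ddof=1))
    cal_dist = caliper * sd if sd > 0 else 0.0

    td = base[base["group"] == "TD"].copy()
    adhd = base[base["group"] == "ADHD"].copy()
    td["lp"] = logp[td["subject_id"]].to_numpy()
    adhd["lp"] = logp[adhd["subject_id"]].to_numpy()
    # hardest-to-match anchors first; ties broken by id for determinism
    td = td.sort_values(["lp", "subject_id"], ascending=[False, True])
    available = adhd.sort_values("subject_id").set_index("subject_id")["lp"]

    pairs: dict[str, list[str]] = {sid: [] for sid in td["subject_id"]}
    for _ in range(max_ratio):
        for sid, lp in zip(td["subject_id"], td["lp"]):
            if available.empty:
                break
            dist = (available - lp).abs()
            best = dist.sort_index().idxmin()  # ties -> lowest id
            if dist[best] <= cal_dist + 1e-12:
                pairs[sid].append(best)
                available = available.drop(best)
    dropped = [sid for sid, p in pairs.items() if not p]
    for sid in dropped:
        warnings.warn(f"TD subject {sid} has no match within the caliper",
                      stacklevel=2)
        del pairs[sid]
    matched = sorted(pairs) + sorted(a for p in pairs.values() for a in p)

    pre = _covariate_balance_p(base)
    post = _covariate_balance_p(base[base["subject_id"].isin(matched)])
    return MatchResult(propensity_coef=coef, log_propensity=logp,
                       pairs=pairs, matched_ids=matched,
                       balance={"pre": pre, "post": post}, caliper=caliper)


def check_balance(match: MatchResult, cohort: pd.DataFrame,
                  cluster_by_pair: bool = False) -> dict[str, float]:
    """Post-match covariate influence on the class label.

    Fits a binomial GLM of group on gender and age over the matched set;
    with ``cluster_by_pair`` the covariance is clustered on the matched
    pair (anti-conservative for the small cluster counts typical here, so
    model-based covariance is the default).  Returns per-covariate
    p-values.
    """
    base = cohort.drop_duplicates("subject_id").set_index("subject_id")
    rows, groups = [], []
    for k, (td_id, adhd_ids) in enumerate(sorted(match.pairs.items())):
        for sid in [td_id] + list(adhd_ids):
            rows.append(sid)
            groups.append(k)
    if not rows:
        raise ValueError("matched set is empty")
    sel = base.loc[rows]
    X = sm.add_constant(_design(sel, ("gender", "age")).to_numpy())
    y = (sel["group"] == "ADHD").astype(float).to_numpy()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, X, family=sm.families.Binomial())
            if cluster_by_pair:
                fit = model.fit(cov_type="cluster",
                                cov_kwds={"groups": np.asarray(groups)})
            else:
                fit = model.fit()
        pvals = fit.pvalues
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise ValueError(f"singular balance fit: {exc}") from exc
    if np.isnan(pvals).any():
        raise ValueError("singular balance fit: undefined p-values")
    return {"gender": float(pvals[1]), "age": float(pvals[2])}


# ---------------------------------------------------------------------------
# VIF reduction


def vif_values(cohort: pd.DataFrame, candidates: list[str]) -> pd.Series:
    """VIF_j = 1/(1-R^2_j) of each candidate regressed on the others."""
    X = cohort[list(candidates)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("candidates must be complete (impute first)")
    out = {}
    for j, name in enumerate(candidates):
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(X.shape[0]), others])
        yj = X[:, j]
        coef, _, _, _ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        if ss_tot == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_reduce(cohort: pd.DataFrame, candidates: list[str],
               threshold: float = 5.0) -> list[str]:
    """Iteratively drop the largest-VIF candidate while any exceeds the
    threshold; survivors are returned in input order."""
    if cohort.shape[0] <= len(candidates) + 1:
        raise ValueError("need more rows than candidates for VIF")
    keep = list(candidates)
    while len(keep) > 1:
        vifs = vif_values(cohort, keep)
        worst = vifs.idxmax()
        if vifs[worst] > threshold:
            keep.remove(worst)
        else:
            break
    return keep
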