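"""Group comparisons, EM imputation, matching, balance, and VIF."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from adhdm import (check_balance, compare_groups, impute_missing,
                   match_cohort, published_moments, simulate_feature_cohort,
                   vif_reduce, vif_values)
from adhdm.stats import em_mvn


def two_group_frame(td_vals, adhd_vals, name="x"):
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(len(td_vals) + len(adhd_vals))],
        "group": ["TD"] * len(td_vals) + ["ADHD"] * len(adhd_vals),
        name: np.concatenate([td_vals, adhd_vals]),
    })


class TestCompareGroups:
    def test_identical_groups_null(self, rng):
        vals = rng.normal(size=30)
        c = compare_groups(two_group_frame(vals, vals), "x")
        assert c.p_value > 0.99

    def test_separated_normals_use_t_test(self, rng):
        td = rng.normal(0, 1, 30)
        adhd = rng.normal(2, 1, 30)
        c = compare_groups(two_group_frame(td, adhd), "x")
        assert c.test == "t" and c.transform == "none"
        assert c.p_value < 1e-6
        # against the textbook pooled-variance formula
        assert c.p_value == pytest.approx(
            sst.ttest_ind(td, adhd).pvalue, rel=1e-9)

    def test_published_gender_table_chi2(self):
        """11/18 vs 51/18 male/female split gives p rounding to 0.001."""
        rows = (["male"] * 11 + ["female"] * 18
                + ["male"] * 51 + ["female"] * 18)
        frame = pd.DataFrame({
            "group": ["TD"] * 29 + ["ADHD"] * 69, "gender": rows})
        c = compare_groups(frame, "gender")
        assert c.test == "chi2"
        assert round(c.p_value, 3) == 0.001

    def test_lognormal_data_log_transformed(self, rng):
        td = np.exp(rng.normal(0, 1, 60))
        adhd = np.exp(rng.normal(0.1, 1, 60))
        c = compare_groups(two_group_frame(td, adhd), "x")
        assert c.test in ("t", "mannwhitney")
        if c.test == "t":
            assert c.transform == "log"

    def test_empty_group_errors(self):
        frame = two_group_frame(np.ones(5) * np.nan, np.ones(5))
        with pytest.raises(ValueError, match="x"):
            compare_groups(frame, "x")


class TestImputation:
    def make_mvn(self, n=500, seed=0, frac=0.1):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(5, 5))
        cov = A @ A.T + np.eye(5)
        X = rng.multivariate_normal(np.arange(5.0), cov, size=n)
        mask = rng.random(X.shape) < frac
        Xm = X.copy()
        Xm[mask] = np.nan
        cols = [f"f{i}" for i in range(5)]
        frame = pd.DataFrame(Xm, columns=cols)
        frame.insert(0, "group", ["TD", "ADHD"] * (n // 2))
        frame.insert(0, "subject_id", [f"s{i}" for i in range(n)])
        return frame, X, mask, cols

    def test_complete_table_identity(self):
        frame, X, _, cols = self.make_mvn(frac=0.0)
        out = impute_missing(frame, feature_cols=cols)
        pd.testing.assert_frame_equal(out, frame)

    def test_beats_mean_imputation(self):
        frame, X, mask, cols = self.make_mvn()
        out = impute_missing(frame, feature_cols=cols)
        em_err = (out[cols].to_numpy() - X)[mask]
        col_means = np.nanmean(frame[cols].to_numpy(), axis=0)
        mean_filled = np.where(np.isnan(frame[cols].to_numpy()),
                               col_means, frame[cols].to_numpy())
        mean_err = (mean_filled - X)[mask]
        assert np.sqrt(np.mean(em_err ** 2)) < np.sqrt(np.mean(mean_err ** 2))

    def test_observed_cells_bitwise_identical(self):
        frame, _, mask, cols = self.make_mvn()
        out = impute_missing(frame, feature_cols=cols)
        obs = ~mask
        assert np.array_equal(out[cols].to_numpy()[obs],
                              frame[cols].to_numpy()[obs])

    def test_em_on_complete_data_gives_sample_moments(self, rng):
        X = rng.normal(size=(200, 4))
        mu, sigma = em_mvn(X)
        np.testing.assert_allclose(mu, X.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(
            sigma, np.cov(X, rowvar=False, ddof=0), atol=1e-6)

    def test_fully_missing_column_errors(self):
        frame, _, _, cols = self.make_mvn(n=50)
        frame[cols[0]] = np.nan
        with pytest.raises(ValueError):
            impute_missing(frame, feature_cols=cols)


@pytest.fixture(scope="module")
def confounded_cohort():
    """Cohort mirroring the published gender/age imbalance."""
    return simulate_feature_cohort(29, 69, published_moments(), seed=8)


class TestMatching:
    def test_matching_balances_gender(self, confounded_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mr = match_cohort(confounded_cohort)
        assert mr.balance["pre"]["gender"] < 0.05
        assert mr.balance["post"]["gender"] > 0.05

    def test_no_adhd_subject_matched_twice(self, confounded_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mr = match_cohort(confounded_cohort)
        used = [a for v in mr.pairs.values() for a in v]
        assert len(used) == len(set(used))
        assert set(mr.matched_ids) <= set(confounded_cohort.subject_id)

    def test_degenerate_covariates_deterministic(self):
        c = simulate_feature_cohort(5, 8, seed=1)
        c["gender"] = "male"
        c["age"] = 9
        a = match_cohort(c)
        b = match_cohort(c)
        assert a.pairs == b.pairs
        assert a.log_propensity.nunique() == 1

    def test_zero_caliper_exact_matches_only(self):
        c = simulate_feature_cohort(5, 8, seed=1)
        c["gender"] = "male"
        c["age"] = 9
        mr = match_cohort(c, caliper=0.0)
        # all propensities tie, so exact matches exist for everyone
        assert all(len(v) >= 1 for v in mr.pairs.values())

    def test_matched_count_monotone_in_caliper(self, confounded_cohort):
        sizes = []
        for cal in (0.05, 0.2, 1.0, np.inf):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mr = match_cohort(confounded_cohort, caliper=cal)
            sizes.append(len(mr.matched_ids))
        assert sizes == sorted(sizes)

    def test_check_balance_post_match(self, confounded_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mr = match_cohort(confounded_cohort)
            p = check_balance(mr, confounded_cohort)
        assert p["gender"] > 0.05 and p["age"] > 0.05


class TestVIF:
    def test_orthogonal_columns_kept(self, rng):
        n = 200
        X = rng.normal(size=(n, 3))
        Q, _ = np.linalg.qr(X)
        frame = pd.DataFrame(Q, columns=["a", "b", "c"])
        vifs = vif_values(frame, ["a", "b", "c"])
        assert np.allclose(vifs, 1.0, atol=1e-6)
        assert vif_reduce(frame, ["a", "b", "c"]) == ["a", "b", "c"]

    def test_near_collinear_dropped_first(self, rng):
        x1 = rng.normal(size=300)
        x2 = rng.normal(size=300)
        x3 = x1 + x2 + 1e-6 * rng.normal(size=300)
        frame = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        vifs = vif_values(frame, ["x1", "x2", "x3"])
        assert vifs["x3"] > 1e6
        kept = vif_reduce(frame, ["x1", "x2", "x3"])
        assert "x3" not in kept or vifs.drop("x3").max() > vifs["x3"]
        assert kept == ["x1", "x2"]

    def test_vif_equals_bruteforce(self, rng):
        """Reported VIFs equal 1/(1-R^2) from an independent regression."""
        for _ in range(100):
            n, p = 60, 4
            X = rng.normal(size=(n, p))
            X[:, 0] += 0.5 * X[:, 1]
            frame = pd.DataFrame(X, columns=[f"v{i}" for i in range(p)])
            vifs = vif_values(frame, list(frame.columns))
            j = int(rng.integers(p))
            yj = X[:, j]
            others = np.delete(X, j, axis=1)
            A = np.column_stack([np.ones(n), others])
            beta = np.linalg.lstsq(A, yj, rcond=None)[0]
            r2 = 1 - np.sum((yj - A @ beta) ** 2) / np.sum(
                (yj - yj.mean()) ** 2)
            assert vifs.iloc[j] == pytest.approx(1 / (1 - r2), abs=1e-9)

    def test_perfect_collinearity_infinite_vif(self, rng):
        x1 = rng.normal(size=100)
        frame = pd.DataFrame({"x1": x1, "x2": 2 * x1, "x3": rng.normal(size=100)})
        vifs = vif_values(frame, ["x1", "x2", "x3"])
        assert np.isinf(vifs["x1"]) and np.isinf(vifs["x2"])
        assert vif_reduce(frame, ["x1", "x2", "x3"])[-1] == "x3"
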