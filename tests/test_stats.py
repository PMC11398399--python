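"""Cohort statistics: covariate correction, LOO-LDA, ROC/DeLong, Spearman
maps and Laplace B-spline trajectories."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from histoatlas import phantom, stats
from histoatlas.stats import CohortTable


def cohort_frame(n=40, seed=0, rois=("hip_mm3",)):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "age_years": rng.uniform(30, 90, n),
            "sex": rng.choice(["F", "M"], n),
            "icv_mm3": np.exp(rng.normal(np.log(1.4e6), 0.1, n)),
        }
    )
    for r in rois:
        df[r] = df["icv_mm3"] * rng.uniform(2e-3, 3e-3, n)
    return CohortTable(df)


class TestCorrectVolumes:
    def test_icv_division(self):
        t = cohort_frame()
        out = stats.correct_volumes(t, ())
        doubled = t.df.copy()
        doubled.loc[0, "icv_mm3"] *= 2
        out2 = stats.correct_volumes(CohortTable(doubled), ())
        assert np.isclose(out2.iloc[0, 0], out.iloc[0, 0] / 2)

    def test_sex_regression_equalises_group_means(self):
        t = cohort_frame(n=100, seed=1)
        df = t.df.copy()
        male = (df["sex"] == "M").to_numpy()
        df["hip_mm3"] = df["hip_mm3"] + df["icv_mm3"] * 1e-4 * male
        out = stats.correct_volumes(CohortTable(df), ("sex",))
        m = out.to_numpy()[male, 0].mean()
        f = out.to_numpy()[~male, 0].mean()
        assert abs(m - f) < 1e-10

    def test_empty_covariates_equals_division_only(self):
        t = cohort_frame(seed=2)
        a = stats.correct_volumes(t, ())
        expected = t.df["hip_mm3"] / t.df["icv_mm3"]
        assert np.allclose(a["hip_mm3"], expected)

    def test_missing_covariate_rejected(self):
        t = cohort_frame()
        with pytest.raises(ValueError, match="height"):
            stats.correct_volumes(t, ("height",))

    def test_train_coefficients_apply_to_held_out(self):
        t = cohort_frame(n=50, seed=3)
        corr = stats.VolumeCorrector(("sex", "age")).fit(t)
        held = CohortTable(t.df.iloc[:5].copy())
        out = corr.apply(held)
        assert out.shape == (5, 1)
        assert np.all(np.isfinite(out))


class TestLooLda:
    def test_midpoint_criterion_is_zero(self):
        mu0 = np.array([1.0, -2.0])
        mu1 = np.array([3.0, 4.0])
        sigma = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert stats.lda_criterion(0.5 * (mu0 + mu1), mu0, mu1, sigma) == 0.0

    def test_printed_formula_value(self):
        """Σ = I, μ0 = (0,0), μ1 = (2,0), x = (2,0): L = 2."""
        L = stats.lda_criterion(
            np.array([2.0, 0.0]), np.zeros(2), np.array([2.0, 0.0]), np.eye(2)
        )
        assert np.isclose(L, 2.0)

    def test_label_swap_negates_criteria(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3))
        y = np.array([0] * 15 + [1] * 15)
        X[y == 1] += 1.0
        a = stats.loo_lda(X, y)
        b = stats.loo_lda(X, 1 - y)
        assert np.allclose(a, -b)

    def test_rescaling_feature_invariant(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(24, 4))
        y = np.array([0, 1] * 12)
        X[y == 1, 0] += 2.0
        a = stats.loo_lda(X, y)
        X2 = X.copy()
        X2[:, 0] *= 37.5
        b = stats.loo_lda(X2, y)
        assert np.allclose(a, b, atol=1e-10)

    def test_tiny_training_group_rejected(self):
        X = np.zeros((4, 2))
        y = np.array([0, 0, 1, 1])
        with pytest.raises(ValueError, match=">= 2"):
            stats.loo_lda(X, y)


class TestRoc:
    def test_perfect_separation(self):
        r = stats.roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auroc == 1.0
        assert r.accuracy_at_elbow == 1.0

    def test_random_criteria_near_half(self):
        rng = np.random.default_rng(4)
        c = rng.normal(size=10_000)
        y = np.repeat([0, 1], 5000)
        assert abs(stats.roc(c, y).auroc - 0.5) < 0.02

    def test_matches_exhaustive_pair_oracle_with_ties(self):
        rng = np.random.default_rng(5)
        c = rng.integers(0, 5, 20).astype(float)  # many ties
        y = rng.integers(0, 2, 20)
        if y.sum() in (0, len(y)):
            y[0] = 1 - y[0]
        pos = c[y == 1]
        neg = c[y == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        oracle = wins / (len(pos) * len(neg))
        assert np.isclose(stats.roc(c, y).auroc, oracle)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        c = rng.normal(size=50)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        a = stats.roc(c, y).auroc
        b = stats.roc(np.exp(c) + 5, y).auroc
        assert np.isclose(a, b)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            stats.roc([1, 2, 3], [1, 1, 1])


class TestDelong:
    def test_identical_criteria_give_null(self):
        c = np.array([0.1, 0.7, 0.3, 0.9])
        y = np.array([0, 1, 0, 1])
        z, p = stats.delong_test(c, c, y)
        assert z == 0.0 and p == 1.0

    def test_variance_nonnegative_random(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = 30
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            z, p = stats.delong_test(rng.normal(size=n), rng.normal(size=n), y)
            assert 0.0 <= p <= 1.0

    def test_agrees_with_paired_bootstrap_oracle(self):
        """DeLong p within 0.02 of a 10^4-replicate paired bootstrap."""
        rng = np.random.default_rng(8)
        n = 120
        y = np.repeat([0, 1], n // 2)
        signal = y + rng.normal(0, 1.2, n)
        a = signal + rng.normal(0, 0.4, n)
        b = 0.55 * signal + rng.normal(0, 0.9, n)
        z, p = stats.delong_test(a, b, y)

        reps = 10_000
        diffs = np.empty(reps)
        idx0 = np.where(y == 0)[0]
        idx1 = np.where(y == 1)[0]
        for r in range(reps):
            i0 = rng.choice(idx0, len(idx0))
            i1 = rng.choice(idx1, len(idx1))
            i = np.concatenate([i0, i1])
            diffs[r] = (
                stats.roc(a[i], y[i]).auroc - stats.roc(b[i], y[i]).auroc
            )
        delta = stats.roc(a, y).auroc - stats.roc(b, y).auroc
        boot_p = 2 * min((diffs <= 0).mean(), (diffs >= 0).mean())
        assert abs(p - boot_p) < 0.02 or (p < 0.01 and boot_p < 0.01)
        assert np.sign(z) == np.sign(delta)

    def test_unpaired_inputs_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            stats.delong_test([1, 2], [1, 2, 3], [0, 1, 1])


class TestSpearmanMap:
    def test_strictly_monotone_extremes(self):
        n = 30
        ages = np.linspace(30, 90, n)
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "age_years": ages,
                "sex": ["F"] * n,
                "icv_mm3": np.ones(n),
                "up_mm3": np.exp(ages / 30.0),
                "down_mm3": 1.0 / ages,
            }
        )
        out = stats.spearman_age_map(CohortTable(df), covariates=())
        assert out.loc["up_mm3", "rho"] == 1.0
        assert out.loc["down_mm3", "rho"] == -1.0

    def test_matches_rank_oracle_with_ties(self):
        rng = np.random.default_rng(9)
        n = 60
        ages = rng.integers(30, 90, n).astype(float)
        vols = rng.integers(0, 6, n).astype(float)
        rho_pkg, _ = sps.spearmanr(vols, ages)
        ra = sps.rankdata(vols)
        rb = sps.rankdata(ages)
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert abs(rho_pkg - oracle) < 1e-12

    def test_constant_volume_reported_undefined(self):
        n = 10
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "age_years": np.linspace(30, 90, n),
                "sex": ["F"] * n,
                "icv_mm3": np.ones(n),
                "flat_mm3": np.ones(n),
            }
        )
        out = stats.spearman_age_map(CohortTable(df), covariates=())
        assert np.isnan(out.loc["flat_mm3", "rho"])

    def test_power_on_synthetic_cohort(self):
        """Declining trajectory, n=500: negative rho with p < 0.01."""
        spec = phantom.TrajectorySpec(
            np.array([30.0, 51.6, 73.3, 95.0]),
            {"roi": np.array([3e-3, 2.6e-3, 2.2e-3, 1.8e-3])},
            {"roi": np.full(4, 2e-4)},
            {"roi": 5e-5},
        )
        t = phantom.make_cohort(500, (30, 95), spec, seed=21)
        out = stats.spearman_age_map(t, covariates=("sex",))
        assert out.loc["roi_mm3", "rho"] < 0
        assert out.loc["roi_mm3", "p"] < 0.01


class TestLaplaceTrajectory:
    def test_constant_data_flat_fit(self):
        rng = np.random.default_rng(10)
        ages = rng.uniform(30, 95, 200)
        v = 5.0 + rng.laplace(0, 1e-4, 200)
        fit = stats.fit_laplace_bspline(ages, v)
        grid = np.linspace(30, 95, 50)
        assert np.abs(fit.mu(grid) - 5.0).max() / 5.0 < 0.01
        assert fit.b(grid).max() < 0.01

    def test_parameter_recovery_at_n1000(self):
        """μ(a) recovered with RMSE < 5% of the curve's range."""
        rng = np.random.default_rng(11)
        ages = rng.uniform(30, 95, 1000)
        B = stats.trajectory_basis(ages)
        tmu = np.array([3.0, 2.6, 2.2, 1.5])
        tb = np.array([0.10, 0.15, 0.10, 0.20])
        v = B @ tmu + rng.laplace(0, B @ tb)
        fit = stats.fit_laplace_bspline(ages, v)
        grid = np.linspace(30, 95, 100)
        Bg = stats.trajectory_basis(grid)
        rmse = np.sqrt(np.mean((Bg @ fit.theta_mu - Bg @ tmu) ** 2))
        assert rmse < 0.05 * np.ptp(Bg @ tmu)

    def test_band_coverage_on_fresh_draws(self):
        """μ ± 3b covers 95% ± 1% of fresh Laplace data."""
        rng = np.random.default_rng(12)
        ages = rng.uniform(30, 95, 1000)
        B = stats.trajectory_basis(ages)
        tmu = np.array([3.0, 2.6, 2.2, 1.5])
        tb = np.array([0.10, 0.15, 0.10, 0.20])
        fit = stats.fit_laplace_bspline(ages, B @ tmu + rng.laplace(0, B @ tb))
        ages2 = rng.uniform(30, 95, 10_000)
        B2 = stats.trajectory_basis(ages2)
        fresh = B2 @ tmu + rng.laplace(0, B2 @ tb)
        lo, hi = fit.band(ages2)
        cov = ((fresh >= lo) & (fresh <= hi)).mean()
        assert abs(cov - 0.95) <= 0.01

    def test_log_likelihood_non_decreasing(self):
        rng = np.random.default_rng(13)
        ages = rng.uniform(30, 95, 100)
        v = 2.0 - 0.01 * ages + rng.laplace(0, 0.1, 100)
        fit = stats.fit_laplace_bspline(ages, v)
        assert fit.converged

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="10"):
            stats.fit_laplace_bspline([40.0] * 5, [1.0] * 5)

    def test_interval_convention_rounds_to_three(self):
        hw = stats.laplace_central_interval_halfwidth(0.95)
        assert round(hw) == 3
        assert np.isclose(hw, np.log(20))
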