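"""Downstream volumetric statistics.

Covers the cohort-level analyses run on per-subject ROI volumes:

* covariate correction — ICV by division, then nuisance covariates (sex,
  age) regressed out, with train-fold coefficients applicable to held-out
  subjects;
* regularised leave-one-out LDA with the criterion
  ``L(x̄) = (μ̄₁ − μ̄₀)ᵀ Σ⁻¹ (x̄ − ½(μ̄₁ + μ̄₀))`` and ``Σ = S + λI`` on
  unit-variance features (λ = 1 by default);
* ROC analysis (rank-based AUROC, accuracy at the Youden elbow) and the
  paired DeLong test for comparing two AUROCs;
* per-ROI Spearman correlation of corrected volume with age;
* age-dependent Laplace regression where both the location μ(a) and the
  scale b(a) are cubic B-splines, fitted by gradient ascent on the exact
  log-likelihood.  The central 95% interval of a Laplace distribution is
  μ ± ln(20)·b ≈ μ ± 3b, which is the band the fit reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, optimize, stats as sps

DEFAULT_KNOT_AGES = (30.0, 51.6, 73.3, 95.0)
REQUIRED_COLUMNS = ("subject_id", "age_years", "sex", "icv_mm3")


# ---------------------------------------------------------------------------
# cohort container

@dataclass
class CohortTable:
    """Per-subject ages, sex, intracranial volume and ROI volumes (mm³)."""

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort table missing required columns: {missing}")
        if len(self.df) and not np.all(np.isfinite(self.df["age_years"])):
            raise ValueError("non-finite ages in cohort")
        if len(self.df) and not np.all(self.df["icv_mm3"] > 0):
            raise ValueError("ICV must be positive")

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def roi_columns(self) -> list[str]:
        return [
            c for c in self.df.columns if c.endswith("_mm3") and c != "icv_mm3"
        ]


# ---------------------------------------------------------------------------
# covariate correction

def _design(df: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(df))]
    for cov in covariates:
        if cov == "sex":
            cols.append((df["sex"].astype(str).str.upper() == "M").astype(float))
        elif cov == "age":
            cols.append(df["age_years"].astype(float).to_numpy())
        else:
            if cov not in df.columns:
                raise ValueError(f"missing covariate column: {cov}")
            cols.append(df[cov].astype(float).to_numpy())
    return np.column_stack(cols)


@dataclass
class VolumeCorrector:
    """ICV-division followed by linear regression of nuisance covariates.

    Fitted on a training fold; ``apply`` uses the training coefficients, so
    held-out subjects inside a leave-one-out loop are corrected without
    peeking.
    """

    covariates: tuple
    coef_: dict = field(default_factory=dict)
    mean_: dict = field(default_factory=dict)

    def fit(self, cohort: CohortTable) -> "VolumeCorrector":
        X = _design(cohort.df, self.covariates)
        for roi in cohort.roi_columns:
            y = (cohort.df[roi] / cohort.df["icv_mm3"]).to_numpy(float)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            self.coef_[roi] = beta
            self.mean_[roi] = float(y.mean())
        return self

    def apply(self, cohort: CohortTable) -> pd.DataFrame:
        X = _design(cohort.df, self.covariates)
        out = {}
        for roi in cohort.roi_columns:
            y = (cohort.df[roi] / cohort.df["icv_mm3"]).to_numpy(float)
            out[roi] = y - X @ self.coef_[roi] + self.mean_[roi]
        return pd.DataFrame(out, index=cohort.df.index)


def correct_volumes(
    cohort: CohortTable, covariates: Iterable[str] = ("sex",)
) -> pd.DataFrame:
    """ICV-corrected (division) then covariate-regressed ROI volumes.

    An empty covariate set reduces to ICV division alone.
    """
    covariates = tuple(covariates)
    if not covariates:
        out = {
            roi: (cohort.df[roi] / cohort.df["icv_mm3"]).to_numpy(float)
            for roi in cohort.roi_columns
        }
        return pd.DataFrame(out, index=cohort.df.index)
    return VolumeCorrector(covariates).fit(cohort).apply(cohort)


# ---------------------------------------------------------------------------
# regularised leave-one-out LDA

def lda_criterion(
    x: np.ndarray, mu0: np.ndarray, mu1: np.ndarray, sigma: np.ndarray
) -> float:
    """Linear discriminant log-likelihood-ratio criterion.

    Zero at the midpoint of the class means; positive toward class 1.
    """
    w = np.linalg.solve(sigma, mu1 - mu0)
    return float(w @ (x - 0.5 * (mu0 + mu1)))


def _pooled_cov(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    parts = []
    dof = 0
    for g in (0, 1):
        Xg = X[y == g]
        parts.append((Xg - Xg.mean(axis=0)).T @ (Xg - Xg.mean(axis=0)))
        dof += len(Xg) - 1
    return (parts[0] + parts[1]) / dof


def loo_lda(features, group_labels, lam: float = 1.0) -> np.ndarray:
    """Leave-one-out LDA criterion per subject.

    For each held-out subject the remaining subjects are scaled to unit
    variance, class means and the pooled covariance S are estimated, and the
    criterion is evaluated with Σ = S + λI at the (identically scaled)
    held-out feature vector.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(group_labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("group labels must be 0/1")
    n, p = X.shape
    out = np.empty(n)
    for i in range(n):
        keep = np.ones(n, bool)
        keep[i] = False
        Xt, yt = X[keep], y[keep]
        if min((yt == 0).sum(), (yt == 1).sum()) < 2:
            raise ValueError("each group needs >= 2 training members after LOO")
        loc = Xt.mean(axis=0)
        scale = Xt.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
        Z = (Xt - loc) / scale
        S = _pooled_cov(Z, yt)
        sigma = S + lam * np.eye(p)
        if lam == 0:
            if np.linalg.matrix_rank(sigma) < p:
                raise np.linalg.LinAlgError(
                    "singular pooled covariance; use lambda > 0"
                )
        mu0 = Z[yt == 0].mean(axis=0)
        mu1 = Z[yt == 1].mean(axis=0)
        out[i] = lda_criterion((X[i] - loc) / scale, mu0, mu1, sigma)
    return out


# ---------------------------------------------------------------------------
# ROC / DeLong

@dataclass
class RocResult:
    auroc: float
    accuracy_at_elbow: float
    elbow_threshold: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray


def roc(criteria, group_labels) -> RocResult:
    """Rank-based AUROC (ties count ½) and accuracy at the Youden elbow.

    The elbow is the threshold maximising sensitivity + specificity; ties
    break toward higher sensitivity.
    """
    c = np.asarray(criteria, dtype=float)
    y = np.asarray(group_labels).astype(int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both groups must be non-empty")
    ranks = sps.rankdata(c)
    auroc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    thr = np.concatenate(([np.inf], np.unique(c)[::-1]))
    sens = np.array([(c[y == 1] >= t).mean() for t in thr])
    spec = np.array([(c[y == 0] < t).mean() for t in thr])
    j = sens + spec
    best = int(np.argmax(j + 1e-12 * sens))
    acc = ((c[y == 1] >= thr[best]).sum() + (c[y == 0] < thr[best]).sum()) / len(c)
    return RocResult(float(auroc), float(acc), float(thr[best]), thr, sens, spec)


def _delong_components(c: np.ndarray, y: np.ndarray):
    X = c[y == 1]
    Y = c[y == 0]
    psi = (X[:, None] > Y[None, :]).astype(float) + 0.5 * (
        X[:, None] == Y[None, :]
    )
    return psi.mean(axis=1), psi.mean(axis=0), psi.mean()


def delong_test(criteria_a, criteria_b, group_labels):
    """Paired DeLong test for the difference of two AUROCs.

    Both criterion vectors must score the same subjects in the same order.
    Returns (z, two-sided p).
    """
    a = np.asarray(criteria_a, dtype=float)
    b = np.asarray(criteria_b, dtype=float)
    y = np.asarray(group_labels).astype(int)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("criteria must be paired on identical subjects")
    v10a, v01a, auc_a = _delong_components(a, y)
    v10b, v01b, auc_b = _delong_components(b, y)
    m = len(v10a)
    n = len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0 if diff == 0 else np.sign(diff) * np.inf
    else:
        z = diff / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z)) if np.isfinite(z) else 0.0
    return float(z), float(p)


# ---------------------------------------------------------------------------
# Spearman age maps

def spearman_age_map(
    cohort: CohortTable,
    corrected: pd.DataFrame | None = None,
    covariates: Iterable[str] = ("sex",),
    fdr: bool = True,
) -> pd.DataFrame:
    """Spearman rho (and p) of corrected ROI volume against age, per ROI.

    Rank-based, so monotone nonlinear ageing trajectories are handled.
    Constant volumes yield undefined (NaN) rho rather than 0.
    """
    if cohort.n < 3:
        raise ValueError("need at least 3 subjects")
    if corrected is None:
        corrected = correct_volumes(cohort, covariates)
    ages = cohort.df["age_years"].to_numpy(float)
    rows = []
    for roi in corrected.columns:
        v = corrected[roi].to_numpy(float)
        if np.ptp(v) == 0:
            rows.append((roi, np.nan, np.nan))
            continue
        rho, p = sps.spearmanr(v, ages)
        rows.append((roi, rho, p))
    out = pd.DataFrame(rows, columns=["roi", "rho", "p"]).set_index("roi")
    if fdr:
        mask = out["p"].notna()
        q = np.full(len(out), np.nan)
        if mask.sum():
            pvals = out.loc[mask, "p"].to_numpy()
            order = np.argsort(pvals)
            ranked = pvals[order] * len(pvals) / (np.arange(len(pvals)) + 1)
            ranked = np.minimum.accumulate(ranked[::-1])[::-1]
            qq = np.empty_like(ranked)
            qq[order] = np.clip(ranked, 0, 1)
            q[mask.to_numpy()] = qq
        out["q_fdr"] = q
    return out


# ---------------------------------------------------------------------------
# Laplace-noise B-spline trajectories

def trajectory_knot_vector(knot_ages: Sequence[float]) -> np.ndarray:
    """Clamped cubic knot vector with one coefficient per control age."""
    a = np.asarray(knot_ages, dtype=float)
    if a.ndim != 1 or len(a) < 4 or np.any(np.diff(a) <= 0):
        raise ValueError("knot ages must be >= 4 strictly increasing values")
    interior = np.linspace(a[0], a[-1], len(a) - 2)[1:-1]
    return np.concatenate([[a[0]] * 4, interior, [a[-1]] * 4])


def trajectory_basis(ages, knot_ages=DEFAULT_KNOT_AGES) -> np.ndarray:
    """Design matrix of the clamped cubic B-spline basis at given ages.

    Rows are non-negative and sum to one (partition of unity), so a curve
    with positive control values is positive everywhere.  Ages outside the
    knot range are clamped to the range ends.
    """
    t = trajectory_knot_vector(knot_ages)
    a = np.clip(np.asarray(ages, dtype=float), t[0], t[-1])
    # design_matrix is strict about the right endpoint
    a = np.minimum(a, t[-1] - 1e-9 * max(1.0, abs(t[-1])))
    B = interpolate.BSpline.design_matrix(a, t, 3).toarray()
    return B


def _softplus(x):
    return np.logaddexp(0.0, x)


def _softplus_inv(y):
    return np.log(np.expm1(y))


@dataclass
class TrajectoryFit:
    """Maximum-likelihood Laplace trajectory: location and scale B-splines."""

    theta_mu: np.ndarray
    theta_b: np.ndarray
    knot_ages: np.ndarray
    converged: bool
    log_likelihood: float
    n_iterations: int = 0

    def mu(self, ages) -> np.ndarray:
        return trajectory_basis(ages, self.knot_ages) @ self.theta_mu

    def b(self, ages) -> np.ndarray:
        return trajectory_basis(ages, self.knot_ages) @ self.theta_b

    def band(self, ages):
        """The reported 95% interval μ ± 3b (exact central coverage e⁻³)."""
        m = self.mu(ages)
        s = self.b(ages)
        return m - 3.0 * s, m + 3.0 * s


SCALE_FLOOR = 1e-6


def _lad_spline_init(B: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Least-absolute-deviations fit of the location spline via an LP."""
    n, m = B.shape
    # variables: theta (m, free) then slacks t (n, >=0); minimise sum t
    c = np.concatenate([np.zeros(m), np.ones(n)])
    A = np.block([[B, -np.eye(n)], [-B, -np.eye(n)]])
    ub = np.concatenate([v, -v])
    res = optimize.linprog(
        c,
        A_ub=A,
        b_ub=ub,
        bounds=[(None, None)] * m + [(0, None)] * n,
        method="highs",
    )
    if not res.success:  # pragma: no cover - LAD LP on finite data
        beta, *_ = np.linalg.lstsq(B, v, rcond=None)
        return beta
    return res.x[:m]


def fit_laplace_bspline(
    ages,
    volumes,
    knot_ages=DEFAULT_KNOT_AGES,
    max_iters: int = 2000,
    tol: float = 1e-9,
    step0: float = 0.1,
) -> TrajectoryFit:
    """Fit an age-dependent Laplace model by gradient ascent.

    Maximises ``Σₙ log p(vₙ; μ(aₙ; θμ), b(aₙ; θb))`` where both curves are
    cubic B-splines on the given control ages.  The scale curve is kept
    positive through a softplus reparameterisation with a small floor.
    """
    ages = np.asarray(ages, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if len(ages) < 10:
        raise ValueError("need at least 10 subjects within the knot range")
    B = trajectory_basis(ages, knot_ages)

    theta_mu = _lad_spline_init(B, v)
    resid = v - B @ theta_mu
    b0 = max(float(np.mean(np.abs(resid))), 10 * SCALE_FLOOR)
    eta = np.full(B.shape[1], float(_softplus_inv(np.asarray(b0))))

    def ll_and_grad(tm, et):
        tb = _softplus(et) + SCALE_FLOOR
        mu = B @ tm
        b = B @ tb
        r = v - mu
        ll = float(np.sum(-np.log(2.0 * b) - np.abs(r) / b))
        g_mu = B.T @ (np.sign(r) / b)
        g_b = B.T @ (-1.0 / b + np.abs(r) / b ** 2)
        g_eta = g_b * (1.0 / (1.0 + np.exp(-et)))
        return ll, g_mu, g_eta

    ll, g_mu, g_eta = ll_and_grad(theta_mu, eta)
    history = [ll]
    step = step0
    converged = False
    it = 0
    for it in range(1, max_iters + 1):
        g = np.concatenate([g_mu, g_eta])
        gn = np.linalg.norm(g)
        if gn < 1e-10:
            converged = True
            break
        improved = False
        s = step
        for _ in range(30):
            tm = theta_mu + s * g_mu / gn
            et = eta + s * g_eta / gn
            cand, cgm, cge = ll_and_grad(tm, et)
            if cand > ll:
                rel = (cand - ll) / max(1.0, abs(ll))
                theta_mu, eta, ll, g_mu, g_eta = tm, et, cand, cgm, cge
                step = min(s * 1.3, 10.0)
                improved = True
                if rel < tol:
                    converged = True
                break
            s *= 0.5
        history.append(ll)
        if not improved or converged:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"Laplace B-spline fit did not converge in {max_iters} iterations; "
            f"log-likelihood trace tail: {history[-5:]}"
        )
    return TrajectoryFit(
        theta_mu=theta_mu,
        theta_b=_softplus(eta) + SCALE_FLOOR,
        knot_ages=np.asarray(knot_ages, dtype=float),
        converged=True,
        log_likelihood=ll,
        n_iterations=it,
    )


def laplace_central_interval_halfwidth(coverage: float = 0.95) -> float:
    """Half-width of the central interval of Laplace(0, b), in units of b.

    For 95% coverage this is ln(20) ≈ 2.996, i.e. the familiar μ ± 3b band.
    """
    return float(-np.log(1.0 - coverage))
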