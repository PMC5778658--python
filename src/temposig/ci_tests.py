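"""Conditional independence tests Ind(X; T | Z) for temporal data.

Each study design gets a matching nested-model coefficient test:

* temporal-longitudinal — a Gaussian random-intercept mixed model fitted by
  maximum likelihood; the coefficient of X in the full model is tested with
  an F statistic (:func:`test_glmm`), or a marginal GEE model with a CS or
  AR(1) working correlation and a leave-one-subject-out jackknife Wald test
  (:func:`test_gee`).
* static-longitudinal — a two-stage approach: per-subject least-squares
  intercepts and slopes on time summarise every feature trajectory into a
  K x 2p matrix (:func:`build_gamma`), then nested logistic/multinomial
  models on those columns are compared by a likelihood-ratio test
  (:func:`test_twostage`).
* temporal-distinct / static-distinct — with one measurement per subject
  there is no within-subject correlation and the models reduce to ordinary
  nested linear (partial F) or logistic/multinomial (LRT) regressions
  (:func:`test_distinct`).

All tests share one degeneracy convention: when X adds no new direction to
the column span of the conditioning design, the test returns p = 1 (never
reject) instead of raising.  This keeps a feature-selection search safe on
collinear candidates and is what makes equivalent-signature detection
possible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .dataset import Scenario, TemporalDataset
from .errors import ConfigurationError, DataIntegrityError, InsufficientSampleError

_RANK_TOL = 1e-10  # relative squared-residual threshold for "x in span(design)"


@dataclass
class CITestResult:
    """Outcome of one conditional independence test.

    ``dof`` is a ``(num, den)`` pair for F tests and a single integer for
    chi-square tests.  ``log_p`` is the natural log of the p-value, kept
    separately so that ranking and caching remain stable when p underflows.
    """

    statistic: float
    p_value: float
    dof: tuple
    test_name: str
    log_p: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "dof": self.dof,
            "test_name": self.test_name,
            "log_p": self.log_p,
            "degenerate": self.degenerate,
        }


def _degenerate(name: str) -> CITestResult:
    return CITestResult(0.0, 1.0, (0,), name, 0.0, degenerate=True)


def _adds_rank(base: np.ndarray, x: np.ndarray) -> bool:
    """True when column x is not (numerically) in the span of ``base``."""
    sx = float(x @ x)
    if sx == 0.0:
        return False
    coef, *_ = np.linalg.lstsq(base, x, rcond=None)
    resid = x - base @ coef
    return float(resid @ resid) / sx > _RANK_TOL


def _std(v: np.ndarray) -> np.ndarray:
    """Feature columns are standardised internally before model fitting.

    Coefficient tests are invariant to affine rescaling of the predictors
    in exact arithmetic; standardising makes them invariant in floating
    point too (identically conditioned iteration paths) and keeps designs
    well-conditioned regardless of measurement units."""
    s = v.std()
    if s == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / s


def _fixed_design(ds: TemporalDataset, Z) -> np.ndarray:
    """Conditioning design [1, tau, Z] shared by the temporal-scenario tests."""
    cols = [np.ones(ds.N), ds.time]
    for z in Z:
        cols.append(_std(ds.features[:, z]))
    return np.column_stack(cols)


# ====================================================================== #
# Gaussian random-intercept mixed model (maximum likelihood)
# ====================================================================== #
def _profile_ml_parts(psi: float, XtX, Xty, yty, Xsum, ysum, n_i, N):
    """GLS pieces for V_i = I + psi * J via the Woodbury identity."""
    w = psi / (1.0 + n_i * psi)  # per-subject shrinkage weight
    A = XtX - np.einsum("i,ij,ik->jk", w, Xsum, Xsum)
    c = Xty - (w * ysum) @ Xsum
    beta = np.linalg.solve(A, c)
    rss = yty - 2 * beta @ Xty + beta @ XtX @ beta
    # subtract the shrinkage part of the quadratic form
    proj = ysum - Xsum @ beta
    rss_v = rss - float(w @ proj**2)
    sigma2 = max(rss_v / N, 1e-300)
    logdet = float(np.sum(np.log1p(n_i * psi)))
    ll = -0.5 * (N * np.log(2 * np.pi * sigma2) + logdet + N)
    return ll, beta, sigma2, A


def fit_random_intercept_ml(y: np.ndarray, X: np.ndarray, groups: list[np.ndarray]):
    """ML fit of ``y = X b + 1 b_i + e`` with a per-subject random intercept.

    The likelihood is profiled over the variance ratio psi = sigma_b^2 /
    sigma^2: for fixed psi the model is generalised least squares with
    ``V_i = I + psi J``, inverted in closed form, so the whole fit is a
    bounded one-dimensional optimisation.

    Returns ``(beta, cov_beta, sigma2, sigma_b2, loglik)``; ``cov_beta`` is
    the ML fixed-effect covariance ``sigma2 * (X' V^{-1} X)^{-1}``.
    """
    N = len(y)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    Xsum = np.vstack([X[idx].sum(axis=0) for idx in groups])
    ysum = np.array([y[idx].sum() for idx in groups])
    n_i = np.array([len(idx) for idx in groups], dtype=float)

    def neg_ll(log_psi: float) -> float:
        ll, *_ = _profile_ml_parts(np.exp(log_psi), XtX, Xty, yty, Xsum, ysum, n_i, N)
        return -ll

    def grad(psi: float) -> float:
        # envelope theorem: beta(psi) minimises the GLS quadratic form, so
        # only the explicit psi dependence contributes
        _, beta, sigma2, _ = _profile_ml_parts(psi, XtX, Xty, yty, Xsum, ysum, n_i, N)
        proj = ysum - Xsum @ beta
        drss = -float(np.sum(proj**2 / (1.0 + n_i * psi) ** 2))
        dlogdet = float(np.sum(n_i / (1.0 + n_i * psi)))
        return -0.5 * (N * drss / (sigma2 * N) + dlogdet)

    res = optimize.minimize_scalar(
        neg_ll, bounds=(-12.0, 12.0), method="bounded", options={"xatol": 1e-8}
    )
    ll_opt = -res.fun
    ll0, *_ = _profile_ml_parts(0.0, XtX, Xty, yty, Xsum, ysum, n_i, N)
    psi = float(np.exp(res.x)) if ll_opt > ll0 else 0.0
    if psi > 0.0:
        # a value-only search localises psi to ~sqrt(eps); polish to full
        # precision on the analytic stationarity condition
        lo, hi = psi / 1.5, psi * 1.5
        glo, ghi = grad(lo), grad(hi)
        if glo * ghi < 0:
            psi = float(optimize.brentq(grad, lo, hi, xtol=1e-300, rtol=1e-15))
    ll, beta, sigma2, A = _profile_ml_parts(psi, XtX, Xty, yty, Xsum, ysum, n_i, N)
    cov_beta = sigma2 * np.linalg.inv(A)
    return beta, cov_beta, sigma2, psi * sigma2, ll


def test_glmm(ds: TemporalDataset, x: int, Z=(), *, random_intercept: bool = True) -> CITestResult:
    """F-test of the coefficient of feature ``x`` in the random-intercept model
    ``T = a + b_i + gamma * tau + delta Z + beta x``.

    Only the full (alternative) model is fitted; the statistic is
    ``F = (beta_hat / se)^2`` on (1, N - K - P + 1) degrees of freedom with
    P the number of fixed-effect parameters.  The F calibration controls
    type-I error better than the likelihood-ratio chi-square at the small
    subject counts typical of longitudinal omics studies.

    ``random_intercept=False`` forces ``sigma_b^2 = 0``, collapsing the
    test to the classical ordinary-least-squares partial F on
    (1, N - P) degrees of freedom.
    """
    Z = _clean_z(x, Z, ds.p)
    if ds.scenario is not Scenario.TEMPORAL_LONGITUDINAL:
        raise ConfigurationError("test_glmm requires the temporal_longitudinal scenario")
    base = _fixed_design(ds, Z)
    xcol = _std(ds.features[:, x])
    if not _adds_rank(base, xcol):
        return _degenerate("glmm_F")
    P_fixed = len(Z) + 3
    if not random_intercept:
        df_den = ds.N - P_fixed
        if df_den <= 0:
            raise InsufficientSampleError(f"need N > {P_fixed} measurements")
        design = np.column_stack([base, xcol])
        y = ds.target
        c0, *_ = np.linalg.lstsq(base, y, rcond=None)
        c1, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss0 = float(np.sum((y - base @ c0) ** 2))
        rss1 = float(np.sum((y - design @ c1) ** 2))
        F = (rss0 - rss1) / (rss1 / df_den)
        log_p = float(stats.f.logsf(F, 1, df_den))
        return CITestResult(float(F), float(np.exp(log_p)), (1, df_den), "ols_F", log_p)
    df_den = ds.N - ds.K - P_fixed + 1
    if df_den <= 0:
        raise InsufficientSampleError(
            f"need N > K + P - 1 = {ds.K + P_fixed - 1}, got N = {ds.N}"
        )
    design = np.column_stack([base, xcol])
    groups = ds.subject_row_indices()
    try:
        beta, cov, _, _, _ = fit_random_intercept_ml(ds.target, design, groups)
    except np.linalg.LinAlgError:
        warnings.warn("mixed-model fit failed; falling back to sigma_b^2 = 0")
        coef, *_ = np.linalg.lstsq(design, ds.target, rcond=None)
        r = ds.target - design @ coef
        s2 = float(r @ r) / ds.N
        beta = coef
        cov = s2 * np.linalg.inv(design.T @ design)
    se = float(np.sqrt(cov[-1, -1]))
    F = (beta[-1] / se) ** 2
    log_p = float(stats.f.logsf(F, 1, df_den))
    return CITestResult(float(F), float(np.exp(log_p)), (1, df_den), "glmm_F", log_p)


# ====================================================================== #
# Gaussian GEE with CS / AR(1) working correlation, jackknife variance
# ====================================================================== #
def _working_corr(occ: np.ndarray, alpha: float, corstr: str) -> np.ndarray:
    n = len(occ)
    if corstr == "cs":
        R = np.full((n, n), alpha)
        np.fill_diagonal(R, 1.0)
    else:  # ar1, geometric decay in occasion-rank lag
        lag = np.abs(occ[:, None] - occ[None, :])
        R = alpha ** lag.astype(float)
    return R


def _estimate_alpha(e, groups, occ, corstr, P):
    num = 0.0
    den = 0.0
    for idx in groups:
        ei, oi = e[idx], occ[idx]
        n = len(idx)
        if n < 2:
            continue
        if corstr == "cs":
            num += (ei.sum() ** 2 - ei @ ei) / 2.0
            den += n * (n - 1) / 2.0
        else:
            order = np.argsort(oi)
            es = ei[order]
            num += float(es[:-1] @ es[1:])
            den += n - 1
    den -= P
    if den <= 0:
        return 0.0
    return num / den


def _gee_gaussian(y, X, groups, occ, corstr, maxiter=25, tol=1e-6):
    """Iterated Gaussian GEE solve; returns coefficient, per-subject
    information/score pieces, scale and working-correlation parameter."""
    N, P = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    alpha = 0.0
    max_ni = max(len(idx) for idx in groups)
    for _ in range(maxiter):
        r = y - X @ beta
        phi = float(r @ r) / (N - P)
        e = r / np.sqrt(phi)
        alpha = _estimate_alpha(e, groups, occ, corstr, P)
        lo = -1.0 / (max_ni - 1) + 1e-6 if (corstr == "cs" and max_ni > 1) else -0.99
        if not (lo <= alpha <= 0.99):
            warnings.warn(f"working-correlation estimate {alpha:.3f} clipped to feasible range")
            alpha = float(np.clip(alpha, lo, 0.99))
        A = np.zeros((P, P))
        c = np.zeros(P)
        for idx in groups:
            Rinv = np.linalg.inv(_working_corr(occ[idx], alpha, corstr))
            XtR = X[idx].T @ Rinv
            A += XtR @ X[idx]
            c += XtR @ y[idx]
        beta_new = np.linalg.solve(A, c)
        delta = np.max(np.abs(beta_new - beta)) / max(1.0, np.max(np.abs(beta)))
        beta = beta_new
        if delta < tol:
            break
    r = y - X @ beta
    phi = float(r @ r) / (N - P)
    A_list, s_list = [], []
    for idx in groups:
        Rinv = np.linalg.inv(_working_corr(occ[idx], alpha, corstr))
        XtR = X[idx].T @ Rinv
        A_list.append(XtR @ X[idx])
        s_list.append(XtR @ r[idx])
    return beta, A_list, s_list, phi, alpha


def jackknife_variance(beta, A_list, s_list):
    """Leave-one-subject-out one-step jackknife covariance.

    For each subject the coefficient is updated by one Gauss-Newton step
    from the full-data solution after removing that subject's contribution;
    the variance is ``(K - P)/K * sum_i (b_(-i) - b)(b_(-i) - b)'``.
    """
    K = len(A_list)
    P = len(beta)
    A = np.sum(A_list, axis=0)
    devs = np.zeros((K, P))
    for i in range(K):
        Ai = A - A_list[i]
        devs[i] = np.linalg.solve(Ai, -s_list[i])
    factor = max(K - P, 1) / K
    return factor * devs.T @ devs


def test_gee(
    ds: TemporalDataset,
    x: int,
    Z=(),
    *,
    corstr: str = "cs",
    variance: str = "jackknife",
) -> CITestResult:
    """Wald test of the coefficient of ``x`` in the marginal model
    ``T = a + gamma * tau + delta Z + beta x`` fitted by GEE.

    ``corstr`` selects the working correlation: ``"cs"`` (exchangeable,
    constant within-subject correlation) or ``"ar1"`` (decaying as
    alpha^|j-j'| in the occasion-rank lag).  The default variance is the
    leave-one-subject-out jackknife, preferred when the number of subjects
    is small (K <= 30); ``variance="model"`` uses the model-based
    covariance ``phi * (X'V^{-1}X)^{-1}`` instead.
    """
    Z = _clean_z(x, Z, ds.p)
    if ds.scenario.is_static:
        raise ConfigurationError("test_gee requires a continuous (temporal) target")
    if corstr not in ("cs", "ar1"):
        raise ConfigurationError(f"unknown working correlation {corstr!r}")
    if ds.K < 3:
        raise InsufficientSampleError("GEE test requires at least 3 subjects")
    base = _fixed_design(ds, Z)
    xcol = _std(ds.features[:, x])
    name = f"gee_wald_{corstr}"
    if not _adds_rank(base, xcol):
        return _degenerate(name)
    design = np.column_stack([base, xcol])
    P = design.shape[1]
    if ds.N <= P:
        raise InsufficientSampleError(f"need N > {P} measurements, got {ds.N}")
    groups = ds.subject_row_indices()
    occ = ds.occasion_ranks()
    beta, A_list, s_list, phi, _ = _gee_gaussian(ds.target, design, groups, occ, corstr)
    if variance == "jackknife" and ds.K > P:
        cov = jackknife_variance(beta, A_list, s_list)
    else:
        if variance == "jackknife":
            warnings.warn("too few subjects for the jackknife; using model-based variance")
        cov = phi * np.linalg.inv(np.sum(A_list, axis=0))
    v = float(cov[-1, -1])
    W = beta[-1] ** 2 / v if v > 0 else np.inf
    log_p = float(stats.chi2.logsf(W, 1))
    return CITestResult(float(W), float(np.exp(log_p)), (1,), name, log_p)


# ====================================================================== #
# Static-longitudinal two-stage test
# ====================================================================== #
@dataclass
class GammaMatrix:
    """Per-subject trajectory summaries: a K x 2p matrix of least-squares
    intercepts and slopes on time, feature-major (intercept before slope)."""

    values: np.ndarray
    subjects: np.ndarray
    feature_names: list[str]

    @property
    def K(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1] // 2

    def columns_for(self, feature: int) -> tuple[int, int]:
        """(intercept column, slope column) of a feature."""
        return 2 * feature, 2 * feature + 1


def build_gamma(ds: TemporalDataset) -> GammaMatrix:
    """Fit ``G = gamma_0 + gamma_1 * tau`` per subject and feature.

    Each subject's trajectories are reduced to an intercept and a slope,
    giving a K x 2p matrix on which static-target models operate.  Requires
    at least two distinct time values per subject (the slope is
    unidentifiable otherwise).
    """
    rows = ds.subject_row_indices()
    values = np.empty((ds.K, 2 * ds.p))
    for i, idx in enumerate(rows):
        tau = ds.time[idx]
        if len(np.unique(tau)) < 2:
            raise DataIntegrityError(
                f"subject {ds.subjects[i]!r} has a single distinct time; slope unidentifiable"
            )
        D = np.column_stack([np.ones(len(idx)), tau])
        coef, *_ = np.linalg.lstsq(D, ds.features[idx], rcond=None)  # 2 x p
        values[i, 0::2] = coef[0]
        values[i, 1::2] = coef[1]
    return GammaMatrix(values, ds.subjects.copy(), list(ds.feature_names))


def _fit_categorical_ll(y: np.ndarray, design: np.ndarray) -> float:
    """Maximised log-likelihood of a logistic (2 classes) or multinomial
    (C > 2) model; falls back to BFGS with a warning on separation."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    C = len(np.unique(y))
    model = sm.Logit(y, design) if C == 2 else sm.MNLogit(y, design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(method="newton", maxiter=100, disp=0)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            warnings.simplefilter("default")
            warnings.warn("separation or singular Hessian; using bounded BFGS fit")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = model.fit(method="bfgs", maxiter=200, disp=0)
    return float(fit.llf)


def test_twostage(gamma: GammaMatrix, labels: np.ndarray, x: int, Z=()) -> CITestResult:
    """Likelihood-ratio test of feature ``x``'s trajectory summary given Z.

    Nested logistic (binary) or multinomial (C > 2 classes) models of the
    per-subject label on the intercept+slope column pairs of Z versus
    Z plus x; the statistic ``2 (ll1 - ll0)`` is calibrated against
    chi-square with 2 (C - 1) degrees of freedom (one intercept and one
    slope column per class contrast).
    """
    Z = _clean_z(x, Z, gamma.p)
    labels = np.asarray(labels)
    C = len(np.unique(labels))
    classes, counts = np.unique(labels, return_counts=True)
    if C < 2 or np.any(counts < 2):
        raise InsufficientSampleError("need >= 2 classes with >= 2 subjects each")
    base_cols = [np.ones(gamma.K)]
    for z in Z:
        ci, cs = gamma.columns_for(z)
        base_cols += [_std(gamma.values[:, ci]), _std(gamma.values[:, cs])]
    base = np.column_stack(base_cols)
    ci, cs = gamma.columns_for(x)
    xcols = np.column_stack([_std(gamma.values[:, ci]), _std(gamma.values[:, cs])])
    adds = [_adds_rank(base, xcols[:, 0]), _adds_rank(base, xcols[:, 1])]
    if not any(adds):
        return _degenerate("twostage_lrt")
    y = np.searchsorted(classes, labels)
    ll0 = _fit_categorical_ll(y, base)
    ll1 = _fit_categorical_ll(y, np.column_stack([base, xcols]))
    stat = max(0.0, 2.0 * (ll1 - ll0))
    df = 2 * (C - 1)
    log_p = float(stats.chi2.logsf(stat, df))
    return CITestResult(float(stat), float(np.exp(log_p)), (df,), "twostage_lrt", log_p)


# ====================================================================== #
# Distinct-design reductions
# ====================================================================== #
def test_distinct(ds: TemporalDataset, x: int, Z=()) -> CITestResult:
    """Nested-model test for one-measurement-per-subject (time-course) data.

    temporal-distinct: ordinary linear models ``T ~ 1 + tau + Z`` versus
    ``... + x`` compared with the partial F-test on (1, N - |Z| - 3)
    degrees of freedom.  static-distinct: the same covariates through a
    logit link, compared with a likelihood-ratio chi-square on C - 1
    degrees of freedom.
    """
    Z = _clean_z(x, Z, ds.p)
    if not ds.scenario.is_distinct:
        raise ConfigurationError("test_distinct requires a distinct-design scenario")
    if ds.N <= len(Z) + 3:
        raise InsufficientSampleError(
            f"need N > |Z| + 3 = {len(Z) + 3} measurements, got {ds.N}"
        )
    base = _fixed_design(ds, Z)
    xcol = _std(ds.features[:, x])
    if ds.scenario is Scenario.TEMPORAL_DISTINCT:
        if not _adds_rank(base, xcol):
            return _degenerate("linear_F")
        design = np.column_stack([base, xcol])
        y = ds.target
        c0, res0, *_ = np.linalg.lstsq(base, y, rcond=None)
        c1, res1, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss0 = float(np.sum((y - base @ c0) ** 2))
        rss1 = float(np.sum((y - design @ c1) ** 2))
        df_den = ds.N - len(Z) - 3
        if rss1 <= 0:
            return CITestResult(np.inf, 0.0, (1, df_den), "linear_F", -np.inf)
        F = (rss0 - rss1) / (rss1 / df_den)
        log_p = float(stats.f.logsf(F, 1, df_den))
        return CITestResult(float(F), float(np.exp(log_p)), (1, df_den), "linear_F", log_p)
    # static_distinct: logistic / multinomial LRT
    if not _adds_rank(base, xcol):
        return _degenerate("logistic_lrt")
    y = ds.row_target()
    classes = np.unique(y)
    C = len(classes)
    yi = np.searchsorted(classes, y)
    ll0 = _fit_categorical_ll(yi, base)
    ll1 = _fit_categorical_ll(yi, np.column_stack([base, xcol]))
    stat = max(0.0, 2.0 * (ll1 - ll0))
    df = C - 1
    log_p = float(stats.chi2.logsf(stat, df))
    return CITestResult(float(stat), float(np.exp(log_p)), (df,), "logistic_lrt", log_p)


# ====================================================================== #
def _clean_z(x: int, Z, p: int) -> tuple:
    Z = tuple(int(z) for z in Z)
    if int(x) in Z:
        raise ConfigurationError("tested feature x must not be in the conditioning set Z")
    if not (0 <= int(x) < p) or any(not (0 <= z < p) for z in Z):
        raise ConfigurationError("feature index out of range")
    return Z


_LONGITUDINAL_CHOICES = ("glmm", "gee_cs", "gee_ar1")


def make_test(scenario: Scenario, *, test: str | None = None, variance: str = "jackknife"):
    """Bind the appropriate conditional independence test for a scenario.

    Returns a closure ``fn(data, x, Z) -> CITestResult`` with the uniform
    signature the selection engine expects.  ``data`` is a
    :class:`TemporalDataset`; for the static-longitudinal scenario the
    trajectory-summary matrix is built lazily once per dataset and reused
    across calls (it may also be passed directly as a
    ``(GammaMatrix, labels)`` pair).

    ``test`` selects among ``glmm`` (default), ``gee_cs`` and ``gee_ar1``
    for temporal-longitudinal data; the other scenarios have a single
    canonical test and reject an incompatible explicit choice.
    """
    scenario = Scenario(scenario)
    if scenario is Scenario.TEMPORAL_LONGITUDINAL:
        choice = test or "glmm"
        if choice not in _LONGITUDINAL_CHOICES:
            raise ConfigurationError(
                f"temporal_longitudinal supports {_LONGITUDINAL_CHOICES}, got {choice!r}"
            )
        if choice == "glmm":
            fn = lambda ds, x, Z=(): test_glmm(ds, x, Z)  # noqa: E731
        else:
            corstr = choice.split("_", 1)[1]
            fn = lambda ds, x, Z=(): test_gee(ds, x, Z, corstr=corstr, variance=variance)  # noqa: E731
        fn.test_name = choice
        return fn
    if test is not None and test not in ("twostage", "distinct"):
        raise ConfigurationError(f"test {test!r} is incompatible with scenario {scenario.value}")
    if scenario is Scenario.STATIC_LONGITUDINAL:
        if test == "distinct":
            raise ConfigurationError("static_longitudinal requires the two-stage test")
        cache: dict[int, tuple[GammaMatrix, np.ndarray]] = {}

        def fn(data, x, Z=()):
            if isinstance(data, TemporalDataset):
                key = id(data)
                if key not in cache:
                    cache[key] = (build_gamma(data), data.target)
                gamma, labels = cache[key]
            else:
                gamma, labels = data
            return test_twostage(gamma, labels, x, Z)

        fn.test_name = "twostage"
        return fn
    if test == "twostage":
        raise ConfigurationError("distinct-design scenarios use the reduced nested-model test")
    fn = lambda ds, x, Z=(): test_distinct(ds, x, Z)  # noqa: E731
    fn.test_name = "distinct"
    return fn
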