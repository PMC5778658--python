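"""Seeded generators for the four temporal study designs.

Each generator draws data with exactly the statistical structure its
scenario's conditional independence test assumes — subject-level random
intercepts, CS or AR(1) within-subject residual correlation, class
differences carried by trajectory intercepts or slopes — and returns the
generating parameters alongside the data, so calibration, power and
recovery suites need no external datasets.

Feature trajectories deliberately contain subject-level structure (a
random per-subject level plus a mild common time trend), not i.i.d. noise:
without it, within-subject correlation would be irrelevant and the mixed
and marginal models would be indistinguishable from ordinary least squares.

Default dimensions mirror small longitudinal omics studies: a few dozen
subjects, 3-6 time points, and features in the hundreds to thousands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import Scenario, TemporalDataset
from .errors import ConfigurationError


@dataclass
class SyntheticTruth:
    """Generating parameters returned with every synthetic dataset."""

    relevant: list[int]
    beta: dict[int, float]
    sigma_b2: float = 0.0
    sigma2: float = 1.0
    rho: float = 0.0
    gamma_time: float = 0.0
    duplicates: dict[int, int] = field(default_factory=dict)
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "relevant": self.relevant,
            "beta": {str(k): v for k, v in self.beta.items()},
            "sigma_b2": self.sigma_b2,
            "sigma2": self.sigma2,
            "rho": self.rho,
            "gamma_time": self.gamma_time,
            "duplicates": {str(k): v for k, v in self.duplicates.items()},
            "seed": self.seed,
            **self.extra,
        }


def _residual_chol(d: int, rho: float, corstr: str) -> np.ndarray:
    if corstr == "cs":
        if d > 1 and rho <= -1.0 / (d - 1):
            raise ConfigurationError(
                f"CS correlation {rho} infeasible for {d} time points"
            )
        R = np.full((d, d), rho)
        np.fill_diagonal(R, 1.0)
    elif corstr == "ar1":
        if abs(rho) >= 1:
            raise ConfigurationError("AR(1) correlation must satisfy |rho| < 1")
        lag = np.abs(np.arange(d)[:, None] - np.arange(d)[None, :])
        R = rho ** lag.astype(float)
    else:
        raise ConfigurationError(f"unknown correlation structure {corstr!r}")
    return np.linalg.cholesky(R)


def _feature_block(rng: np.random.Generator, K: int, d: int, p: int) -> np.ndarray:
    """K*d x p features with subject-level structure: per-subject random
    level (var 0.3) + mild common linear time trend + i.i.d. noise."""
    tau = np.tile(np.arange(d, dtype=float), K)
    tau_c = (tau - tau.mean()) / max(tau.std(), 1.0)
    level = np.repeat(rng.normal(0.0, np.sqrt(0.3), size=(K, p)), d, axis=0)
    trend = np.outer(tau_c, rng.normal(0.0, 0.2, size=p))
    noise = rng.normal(0.0, np.sqrt(0.66), size=(K * d, p))
    return level + trend + noise


def gen_temporal_longitudinal(
    K: int = 20,
    d: int = 4,
    p: int = 100,
    s: int = 4,
    *,
    beta_scale: float = 1.0,
    sigma_b2: float = 0.5,
    sigma2: float = 1.0,
    rho: float = 0.3,
    corstr: str = "cs",
    gamma_time: float = 0.5,
    n_duplicates: int = 0,
    seed: int = 0,
) -> tuple[TemporalDataset, SyntheticTruth]:
    """Balanced longitudinal data with a continuous per-measurement target.

    The target follows the random-intercept model the temporal-longitudinal
    tests assume: ``T_ij = gamma * tau_j + sum_f beta_f X_ijf + b_i +
    eps_ij`` with ``b_i ~ N(0, sigma_b2)`` and residuals correlated within
    subject (CS or AR(1), parameter ``rho``).  The first ``s`` features are
    relevant with coefficient ``beta_scale``; ``n_duplicates`` exact copies
    of the first relevant features are appended as additional columns to
    engineer statistically equivalent signatures.
    """
    if s > p or d < 3 or K < 3:
        raise ConfigurationError("require s <= p, d >= 3, K >= 3")
    rng = np.random.default_rng(seed)
    X = _feature_block(rng, K, d, p)
    tau = np.tile(np.arange(d, dtype=float), K)
    subjects = np.repeat(np.arange(K), d)
    relevant = list(range(s))
    beta = {f: beta_scale for f in relevant}
    b = np.repeat(rng.normal(0.0, np.sqrt(sigma_b2), size=K), d)
    L = _residual_chol(d, rho, corstr)
    eps = (rng.normal(size=(K, d)) @ L.T).ravel() * np.sqrt(sigma2)
    signal = X[:, relevant] @ np.array([beta[f] for f in relevant]) if s else 0.0
    target = gamma_time * tau + signal + b + eps

    duplicates: dict[int, int] = {}
    if n_duplicates:
        if n_duplicates > s:
            raise ConfigurationError("cannot duplicate more features than are relevant")
        dup_cols = X[:, :n_duplicates]
        X = np.column_stack([X, dup_cols])
        for j in range(n_duplicates):
            duplicates[j] = p + j
    names = [f"V{j + 1}" for j in range(p)] + [f"V{duplicates[j] + 1}" for j in duplicates]
    ds = TemporalDataset(
        subject_ids=subjects,
        time=tau,
        features=X,
        target=target,
        scenario=Scenario.TEMPORAL_LONGITUDINAL,
        feature_names=names,
    )
    truth = SyntheticTruth(relevant, beta, sigma_b2, sigma2, rho, gamma_time,
                           duplicates, seed, extra={"corstr": corstr})
    return ds, truth


def gen_static_longitudinal(
    K: int = 20,
    d: int = 4,
    p: int = 50,
    s: int = 3,
    *,
    effect_kind: str = "slope_shift",
    effect_size: float = 2.0,
    seed: int = 0,
) -> tuple[TemporalDataset, SyntheticTruth]:
    """Two groups of longitudinal trajectories with a per-subject label.

    Every feature trajectory is a subject-specific line plus noise:
    ``G_ijf = a_if + b_if * tau_j + e``.  For the ``s`` relevant features
    the two classes differ in the per-subject intercepts
    (``intercept_shift``) or slopes (``slope_shift``) by ``effect_size``,
    so the signal lives exactly in the per-subject trajectory summaries the
    two-stage test operates on.  Irrelevant features are generated
    identically in both classes.
    """
    if K % 2:
        raise ConfigurationError("K must be even (two balanced classes)")
    if effect_kind not in ("intercept_shift", "slope_shift"):
        raise ConfigurationError(f"unknown effect_kind {effect_kind!r}")
    if s > p or d < 2 or K < 4:
        raise ConfigurationError("require s <= p, d >= 2, K >= 4")
    rng = np.random.default_rng(seed)
    tau = np.arange(d, dtype=float)
    labels = np.repeat([0, 1], K // 2)
    intercepts = rng.normal(0.0, 1.0, size=(K, p))
    slopes = rng.normal(0.0, 0.5, size=(K, p))
    shift = (labels - 0.5)[:, None] * effect_size  # -e/2 for class 0, +e/2 for class 1
    if s:
        if effect_kind == "intercept_shift":
            intercepts[:, :s] += shift
        else:
            slopes[:, :s] += shift
    noise = rng.normal(0.0, 0.5, size=(K, d, p))
    X = (intercepts[:, None, :] + slopes[:, None, :] * tau[None, :, None] + noise)
    ds = TemporalDataset(
        subject_ids=np.repeat(np.arange(K), d),
        time=np.tile(tau, K),
        features=X.reshape(K * d, p),
        target=labels,
        scenario=Scenario.STATIC_LONGITUDINAL,
    )
    truth = SyntheticTruth(list(range(s)), {f: effect_size for f in range(s)},
                           seed=seed, extra={"effect_kind": effect_kind})
    return ds, truth


def gen_distinct(
    N: int = 60,
    d: int = 4,
    p: int = 100,
    s: int = 3,
    *,
    target_kind: str = "continuous",
    n_classes: int = 2,
    beta_scale: float = 1.0,
    sigma2: float = 1.0,
    gamma_time: float = 0.5,
    seed: int = 0,
) -> tuple[TemporalDataset, SyntheticTruth]:
    """Time-course data: one measurement per subject, spread over ``d``
    time points.

    ``continuous`` targets follow a linear model in time and the ``s``
    relevant features (temporal-distinct design); ``binary`` /
    ``multinomial`` targets follow a logit model in the relevant features
    (static-distinct design).
    """
    if N < 2 * d:
        raise ConfigurationError("require N >= 2 d")
    if s > p:
        raise ConfigurationError("require s <= p")
    rng = np.random.default_rng(seed)
    tau = np.tile(np.arange(d, dtype=float), int(np.ceil(N / d)))[:N]
    X = rng.normal(size=(N, p))
    relevant = list(range(s))
    betas = np.full(s, beta_scale)
    eta = X[:, relevant] @ betas if s else np.zeros(N)
    if target_kind == "continuous":
        target = gamma_time * tau + eta + rng.normal(0.0, np.sqrt(sigma2), size=N)
        scenario = Scenario.TEMPORAL_DISTINCT
    elif target_kind in ("binary", "multinomial"):
        C = 2 if target_kind == "binary" else n_classes
        if C < 2:
            raise ConfigurationError("need >= 2 classes")
        scores = np.zeros((N, C))
        for c in range(1, C):
            w = rng.normal(size=s) if target_kind == "multinomial" else np.ones(s)
            scores[:, c] = (X[:, relevant] @ (beta_scale * w)) if s else 0.0
        probs = np.exp(scores - scores.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        target = np.array([rng.choice(C, p=pr) for pr in probs])
        # guarantee every class appears at least twice
        for c in range(C):
            short = 2 - int(np.sum(target == c))
            if short > 0:
                donors = [i for i in range(N) if np.sum(target == target[i]) > 2]
                target[donors[:short]] = c
        scenario = Scenario.STATIC_DISTINCT
    else:
        raise ConfigurationError(f"unknown target_kind {target_kind!r}")
    ds = TemporalDataset(
        subject_ids=np.arange(N),
        time=tau,
        features=X,
        target=target.astype(int) if scenario.is_static else target,
        scenario=scenario,
    )
    truth = SyntheticTruth(relevant, {f: beta_scale for f in relevant},
                           sigma2=sigma2, gamma_time=gamma_time, seed=seed,
                           extra={"target_kind": target_kind})
    return ds, truth
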