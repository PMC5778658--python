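"""Cross-validated model selection and evaluation.

Folds respect the dependence structure of the data: whole subjects are
held out in the static-longitudinal design and whole time points in the
other three designs, so no subject (or time point) is ever split between
training and test rows.

A grid of selection configurations is scored per fold; the winning
configuration's naive cross-validated performance is then corrected for
the optimism of having picked the winner inside the same cross-validation,
using the Tibshirani-Tibshirani estimate

    bias = (1/m) * sum_i [ e_i(best) - e_i(fold-best_i) ]

whose sign is interchanged when the metric rewards larger values.

Comparison utilities used when contrasting modeling approaches are also
here: a paired permutation t-test (within-pair sign flips) and the
one-sided asymptotic z-test on a proportion of wins.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import ci_tests
from .dataset import Scenario, TemporalDataset, fold_units, rows_for_unit, subset_rows
from .errors import ConfigurationError, InsufficientSampleError, TemposigError
from .ses import SESConfig, SESResult, rerun_with_config, run_ses

#: the standard hyper-parameter grid: k in {3,4,5} x a in {0.05, 0.1}
DEFAULT_GRID = [{"k": k, "a": a} for k, a in itertools.product((3, 4, 5), (0.05, 0.1))]


@dataclass
class CVReport:
    """Per-fold x per-configuration performances with the bias-corrected
    performance of the chosen configuration."""

    perf: np.ndarray  # m x C
    configs: list[dict]
    best_config: int
    fold_best: list[int]
    bias: float
    corrected: float
    metric: str  # "MSPE" | "PCC"
    direction: str  # "lower_better" | "higher_better"
    seed: int
    n_tests_total: int = 0
    n_univariate_tests: int = 0

    @property
    def naive(self) -> float:
        return float(self.perf[:, self.best_config].mean())

    def to_dict(self) -> dict:
        return {
            "perf": self.perf.tolist(),
            "configs": self.configs,
            "best_config": self.best_config,
            "fold_best": self.fold_best,
            "bias": self.bias,
            "naive": self.naive,
            "corrected": self.corrected,
            "metric": self.metric,
            "direction": self.direction,
            "seed": self.seed,
            "n_tests_total": self.n_tests_total,
            "n_univariate_tests": self.n_univariate_tests,
        }

    def to_tsv(self) -> str:
        lines = ["fold\tconfig\tmetric\tvalue"]
        for i in range(self.perf.shape[0]):
            for c in range(self.perf.shape[1]):
                lines.append(f"{i}\t{c}\t{self.metric}\t{self.perf[i, c]!r}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------- #
def make_folds(ds: TemporalDataset, m: int, seed: int) -> list[np.ndarray]:
    """Partition rows into ``m`` folds by shuffling the fold units
    (subjects or time points) and dealing them round-robin."""
    if m < 2:
        raise ConfigurationError("m must be >= 2")
    units = fold_units(ds)
    if len(units) < m:
        raise InsufficientSampleError(f"{len(units)} fold units cannot fill {m} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(units))
    folds: list[list] = [[] for _ in range(m)]
    for pos, ui in enumerate(order):
        folds[pos % m].append(units[ui])
    out = []
    for members in folds:
        rows = np.sort(np.concatenate([rows_for_unit(ds, u) for u in members]))
        if len(rows) < 2:
            raise InsufficientSampleError("every fold needs at least 2 measurements")
        out.append(rows)
    return out


# ---------------------------------------------------------------------- #
def _majority(labels: np.ndarray) -> int:
    vals, counts = np.unique(labels, return_counts=True)
    return int(vals[np.argmax(counts)])


def _categorical_predict(y, train_design, test_design):
    import statsmodels.api as sm

    C = len(np.unique(y))
    classes = np.unique(y)
    yi = np.searchsorted(classes, y)
    model = sm.Logit(yi, train_design) if C == 2 else sm.MNLogit(yi, train_design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(method="newton", maxiter=100, disp=0)
        except Exception:
            fit = model.fit(method="bfgs", maxiter=200, disp=0)
        pred = fit.predict(test_design)
    pred = np.asarray(pred)
    if C == 2:
        idx = (pred > 0.5).astype(int)
    else:
        idx = pred.argmax(axis=1)
    return classes[idx]


def fit_predict(
    train: TemporalDataset,
    test: TemporalDataset,
    signature,
    model_kind: str,
    *,
    corstr: str = "cs",
) -> np.ndarray:
    """Fit the mirror model of a conditional independence test on the
    training split and predict the test split's target.

    ``glmm`` predictions add the estimated per-subject intercept for test
    subjects seen in training (held-out time points of known subjects) and
    zero for unseen subjects; ``gee`` and ``linear`` predict the marginal
    mean; ``logistic``/``multinomial`` operate on [1, time, signature];
    ``gamma_logistic`` classifies per-subject trajectory summaries on the
    signature's intercept+slope columns.  An empty signature yields the
    baseline model (intercept + time, or the training majority class).
    """
    signature = sorted(int(j) for j in signature)
    if model_kind in ("glmm", "gee", "linear"):
        Xtr = np.column_stack([np.ones(train.N), train.time, train.features[:, signature]])
        Xte = np.column_stack([np.ones(test.N), test.time, test.features[:, signature]])
        y = train.target
        if model_kind == "glmm":
            groups = train.subject_row_indices()
            beta, _, sigma2, sigma_b2, _ = ci_tests.fit_random_intercept_ml(y, Xtr, groups)
            pred = Xte @ beta
            psi = sigma_b2 / sigma2 if sigma2 > 0 else 0.0
            resid = y - Xtr @ beta
            b_hat = {}
            for subj, idx in zip(train.subjects, groups):
                w = psi / (1.0 + len(idx) * psi)
                b_hat[subj] = w * float(resid[idx].sum())
            offsets = np.array([b_hat.get(s, 0.0) for s in test.subject_ids])
            return pred + offsets
        if model_kind == "gee":
            groups = train.subject_row_indices()
            occ = train.occasion_ranks()
            beta, *_ = ci_tests._gee_gaussian(y, Xtr, groups, occ, corstr)
            return Xte @ beta
        coef, *_ = np.linalg.lstsq(Xtr, y, rcond=None)
        return Xte @ coef
    if model_kind in ("logistic", "multinomial"):
        y = train.row_target()
        if not signature:
            return np.full(test.N, _majority(y))
        Xtr = np.column_stack([np.ones(train.N), train.time, train.features[:, signature]])
        Xte = np.column_stack([np.ones(test.N), test.time, test.features[:, signature]])
        return _categorical_predict(y, Xtr, Xte)
    if model_kind == "gamma_logistic":
        if not signature:
            return np.full(test.K, _majority(train.target))
        g_tr = ci_tests.build_gamma(train)
        g_te = ci_tests.build_gamma(test)
        cols = [c for j in signature for c in g_tr.columns_for(j)]
        Xtr = np.column_stack([np.ones(g_tr.K), g_tr.values[:, cols]])
        Xte = np.column_stack([np.ones(g_te.K), g_te.values[:, cols]])
        return _categorical_predict(train.target, Xtr, Xte)
    raise ConfigurationError(f"unknown model_kind {model_kind!r}")


def evaluate(pred: np.ndarray, truth: np.ndarray, metric: str) -> float:
    """MSPE (mean squared prediction error) or PCC (fraction of correct
    classifications, reported in [0, 1])."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if len(pred) == 0 or len(pred) != len(truth):
        raise ConfigurationError("predictions and truth must be equal-length, non-empty")
    if metric == "MSPE":
        return float(np.mean((pred.astype(float) - truth.astype(float)) ** 2))
    if metric == "PCC":
        return float(np.mean(pred == truth))
    raise ConfigurationError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------- #
def tt_bias(perf: np.ndarray, direction: str = "lower_better"):
    """Tibshirani-Tibshirani optimism estimate on an m x C fold-by-
    configuration performance matrix.

    Returns ``(bias, best_config, corrected)`` where ``best_config`` is the
    column with the best mean (ties -> lowest index), ``bias`` averages the
    per-fold gap between the overall winner and each fold's own winner, and
    ``corrected = naive + bias`` (the bias is >= 0 for error metrics and
    <= 0 for score metrics, so the correction always penalises).
    """
    perf = np.asarray(perf, dtype=float)
    if perf.ndim != 2 or perf.shape[0] < 2 or perf.shape[1] < 1:
        raise ConfigurationError("perf must be m x C with m >= 2, C >= 1")
    if not np.all(np.isfinite(perf)):
        raise ConfigurationError("non-finite performance entries")
    if direction not in ("lower_better", "higher_better"):
        raise ConfigurationError(f"unknown direction {direction!r}")
    pick = np.argmin if direction == "lower_better" else np.argmax
    best = int(pick(perf.mean(axis=0)))
    fold_best = [int(pick(row)) for row in perf]
    gaps = [perf[i, best] - perf[i, fb] for i, fb in enumerate(fold_best)]
    bias = float(np.mean(gaps))
    corrected = float(perf[:, best].mean() + bias)
    return bias, best, corrected, fold_best


_MIRROR_MODEL = {
    "glmm": "glmm",
    "gee_cs": "gee",
    "gee_ar1": "gee",
    "twostage": "gamma_logistic",
}


def cross_validate(
    ds: TemporalDataset,
    grid: list[dict] | None = None,
    m: int = 4,
    seed: int = 0,
    *,
    metric: str | None = None,
) -> CVReport:
    """m-fold cross-validation of a selection-configuration grid.

    Each grid entry is ``{"k": ..., "a": ...}`` plus an optional ``"test"``
    key (see :func:`~temposig.ci_tests.make_test`).  Per fold, the search
    runs once per configuration on the training rows — univariate test
    statistics are computed once per fold and test choice and reused across
    configurations — the mirror predictive model is fitted on the first
    signature, and the held-out fold is scored.  The report carries the
    TT-corrected performance of the winning configuration.
    """
    grid = grid if grid is not None else DEFAULT_GRID
    if not grid:
        raise ConfigurationError("empty configuration grid")
    if metric is None:
        metric = "MSPE" if ds.scenario.is_temporal else "PCC"
    direction = "lower_better" if metric == "MSPE" else "higher_better"
    folds = make_folds(ds, m, seed)
    all_rows = np.arange(ds.N)
    perf = np.zeros((m, len(grid)))
    n_tests_total = 0
    n_univariate = 0
    for i, hold in enumerate(folds):
        train = subset_rows(ds, np.setdiff1d(all_rows, hold))
        test = subset_rows(ds, hold, prediction_split=True)
        by_test: dict[str, SESResult] = {}
        for c, spec in enumerate(grid):
            choice = spec.get("test")
            cfg = SESConfig(k=spec.get("k", 3), a=spec.get("a", 0.05),
                            max_signatures=spec.get("max_signatures", 100))
            test_fn = ci_tests.make_test(ds.scenario, test=choice)
            key = test_fn.test_name
            try:
                if key in by_test:
                    res = rerun_with_config(by_test[key], cfg, train, test_fn)
                else:
                    res = run_ses(train, test_fn, cfg)
                    n_univariate += ds.p
                by_test[key] = res
                signature = res.signatures[0] if res.signatures else ()
                model_kind = _MIRROR_MODEL.get(key)
                if model_kind is None:  # distinct designs
                    model_kind = "linear" if ds.scenario.is_temporal else (
                        "logistic" if test.n_classes <= 2 else "multinomial")
                pred = fit_predict(train, test, signature, model_kind)
                if ds.scenario.is_temporal or model_kind == "gamma_logistic":
                    truth = test.target
                else:
                    truth = test.row_target()
                perf[i, c] = evaluate(pred, truth, metric)
                n_tests_total += res.n_tests
            except TemposigError as exc:
                raise type(exc)(f"fold {i}, config {c}: {exc}") from exc
    bias, best, corrected, fold_best = tt_bias(perf, direction)
    return CVReport(perf=perf, configs=list(grid), best_config=best,
                    fold_best=fold_best, bias=bias, corrected=corrected,
                    metric=metric, direction=direction, seed=seed,
                    n_tests_total=n_tests_total, n_univariate_tests=n_univariate)


# ---------------------------------------------------------------------- #
def _t_stat(d: np.ndarray) -> float:
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0 if d.mean() == 0 else np.inf
    return float(d.mean() / (sd / np.sqrt(len(d))))


def paired_permutation_ttest(a, b, n_perm: int = 10_000, seed: int = 0) -> float:
    """Two-sided p-value of the paired t statistic under within-pair sign
    flips.

    All 2^n sign patterns are enumerated when that is no more work than
    ``n_perm`` draws; otherwise a seeded Monte-Carlo approximation with the
    add-one convention (the observed statistic counts itself) is used.
    Identical inputs give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ConfigurationError("need two equal-length vectors with n >= 2")
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    d = a - b
    if np.all(d == 0):
        return 1.0
    t_obs = abs(_t_stat(d))
    n = len(d)
    tol = 1e-12
    if 2**n <= n_perm:
        count = 0
        for signs in itertools.product((1.0, -1.0), repeat=n):
            t = abs(_t_stat(d * np.array(signs)))
            if t >= t_obs - tol:
                count += 1
        return count / 2**n
    rng = np.random.default_rng(seed)
    signs = rng.choice((1.0, -1.0), size=(n_perm, n))
    count = 0
    for row in signs:
        if abs(_t_stat(d * row)) >= t_obs - tol:
            count += 1
    return (1 + count) / (n_perm + 1)


def proportion_ztest(successes: int, n: int) -> float:
    """One-sided asymptotic z-test that a proportion exceeds one half.

    Uses the estimated-variance form ``z = (p - 0.5) / sqrt(p (1 - p) / n)``
    and the upper-tail standard-normal p-value.  Degenerate proportions
    return the limit values (0 for all successes, 1 for none).
    """
    if not (0 <= successes <= n) or n < 1:
        raise ConfigurationError("need 0 <= successes <= n, n >= 1")
    phat = successes / n
    if phat == 1.0:
        return 0.0
    if phat == 0.0:
        return 1.0
    z = (phat - 0.5) / np.sqrt(phat * (1 - phat) / n)
    return float(stats.norm.sf(z))
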