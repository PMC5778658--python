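"""Statistically Equivalent Signatures (SES): a constraint-based forward
search returning multiple, statistically indistinguishable minimal feature
subsets.

The search interacts with the data exclusively through a conditional
independence test ``fn(data, x, Z) -> CITestResult``, so any of the
temporal tests (or a user-supplied one) plugs in unchanged.  A candidate X
is discarded as soon as some conditioning subset Z of the selected set
makes it independent of the target (p >= a); a candidate survives only if
no subset up to size ``k`` does, which bounds the test budget by
O(p * s^k) for a selected set of size s.

When X is eliminated by a witnessing subset Z, each member Y of Z is probed
with X swapped in for it; if Y is likewise dismissible, X is recorded as a
statistical substitute of Y.  Signatures are the cross-product of each
selected feature with its substitutes.

Univariate test results are cached in the result object; re-running with
different hyper-parameters (:func:`rerun_with_config`) starts from the
conditioning stage, performing zero new univariate tests.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .ci_tests import GammaMatrix
from .dataset import TemporalDataset
from .errors import ConfigurationError, StaleCacheError


@dataclass
class SESConfig:
    """Hyper-parameters of the search.

    k : maximum conditioning-set size (the standard grid is {3, 4, 5}).
    a : significance threshold for the independence tests ({0.05, 0.1}).
    max_signatures : cap on the enumerated equivalence cross-product.
    """

    k: int = 3
    a: float = 0.05
    max_signatures: int = 100

    def validate(self) -> None:
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if not (0.0 < self.a < 1.0):
            raise ConfigurationError("significance threshold a must be in (0, 1)")
        if self.max_signatures < 1:
            raise ConfigurationError("max_signatures must be >= 1")


@dataclass
class UnivariateCache:
    """Per-feature univariate statistics, reusable across configurations."""

    statistic: np.ndarray
    log_p: np.ndarray
    fingerprint: str
    test_name: str

    @property
    def p_values(self) -> np.ndarray:
        return np.exp(self.log_p)


@dataclass
class SESResult:
    selected: list[int]
    equivalence_sets: dict[int, list[int]]  # selected feature -> its substitutes
    signatures: list[tuple[int, ...]]
    n_signatures_total: int
    n_tests: int
    univariate_cache: UnivariateCache
    config: SESConfig
    trace: list[str] = field(default_factory=list)

    def to_dict(self, feature_names: list[str] | None = None) -> dict:
        name = (lambda j: feature_names[j]) if feature_names else (lambda j: j)
        return {
            "selected": [name(j) for j in self.selected],
            "equivalence_sets": {
                str(name(y)): [name(s) for s in subs]
                for y, subs in self.equivalence_sets.items()
            },
            "signatures": [[name(j) for j in sig] for sig in self.signatures],
            "n_signatures_total": self.n_signatures_total,
            "n_tests": self.n_tests,
            "config": {"k": self.config.k, "a": self.config.a,
                       "max_signatures": self.config.max_signatures},
            "test_name": self.univariate_cache.test_name,
        }


# ---------------------------------------------------------------------- #
def _n_features(data) -> int:
    if isinstance(data, TemporalDataset):
        return data.p
    if isinstance(data, GammaMatrix):
        return data.p
    if isinstance(data, tuple) and isinstance(data[0], GammaMatrix):
        return data[0].p
    raise ConfigurationError(f"unsupported input of type {type(data).__name__}")


def data_fingerprint(data, test_name: str) -> str:
    """Stable digest of the input arrays and test identity, used to detect
    a univariate cache presented together with different data."""
    h = hashlib.sha1()
    h.update(test_name.encode())
    if isinstance(data, TemporalDataset):
        arrays = [data.time, data.features, np.asarray(data.target, dtype=float)]
    elif isinstance(data, GammaMatrix):
        arrays = [data.values]
    else:
        arrays = [data[0].values, np.asarray(data[1], dtype=float)]
    for arr in arrays:
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


def _max_key(p_value: float, log_p: float) -> tuple[float, float]:
    # maximal test ranked by p, ties (e.g. underflow to 0) broken on log_p
    return (p_value, log_p)


def run_ses(
    data,
    test_fn,
    cfg: SESConfig | None = None,
    *,
    univariate_cache: UnivariateCache | None = None,
    backward: bool = False,
) -> SESResult:
    """Run the forward max-min search.

    ``data`` is a :class:`~temposig.dataset.TemporalDataset` (or, for the
    static-longitudinal two-stage test, a ``(GammaMatrix, labels)`` pair).
    ``test_fn`` has signature ``fn(data, x, Z) -> CITestResult`` (see
    :func:`~temposig.ci_tests.make_test`).

    All tie-breaks are total orders, so identical inputs produce identical
    results.  ``backward=True`` adds an optional final pruning pass that
    re-checks every selected feature against the conditioning subsets of
    the final selected set.
    """
    cfg = cfg or SESConfig()
    cfg.validate()
    p = _n_features(data)
    test_name = getattr(test_fn, "test_name", getattr(test_fn, "__name__", "test"))
    fp = data_fingerprint(data, test_name)
    trace: list[str] = []
    n_tests = 0

    if univariate_cache is None:
        stat = np.empty(p)
        logp = np.empty(p)
        for j in range(p):
            res = test_fn(data, j, ())
            stat[j] = res.statistic
            logp[j] = res.log_p
            n_tests += 1
        univariate_cache = UnivariateCache(stat, logp, fp, test_name)
    elif univariate_cache.fingerprint != fp:
        raise StaleCacheError("univariate cache does not match the presented data/test")

    uni_p = univariate_cache.p_values
    remaining = [j for j in range(p) if uni_p[j] < cfg.a]
    trace.append(f"univariate filter: {len(remaining)}/{p} candidates at a={cfg.a}")
    # per-candidate maximal p over tested conditioning subsets
    max_assoc = {j: _max_key(float(uni_p[j]), float(univariate_cache.log_p[j]))
                 for j in remaining}
    selected: list[int] = []
    substitutes: dict[int, set[int]] = {}

    def probe(x: int, Z: tuple) -> tuple[float, float]:
        nonlocal n_tests
        res = test_fn(data, x, Z)
        n_tests += 1
        return float(res.p_value), float(res.log_p)

    while remaining:
        if selected:
            newest = selected[-1]
            others = [s for s in selected if s != newest]
            new_subsets: list[tuple] = []
            for size in range(0, min(cfg.k, len(selected))):
                for combo in itertools.combinations(others, size):
                    new_subsets.append(tuple(sorted(combo + (newest,))))
            # smallest subsets first; lexicographic within a size
            new_subsets.sort(key=lambda z: (len(z), z))
            still: list[int] = []
            for x in remaining:
                dropped = False
                for Z in new_subsets:
                    pv, lp = probe(x, Z)
                    key = _max_key(pv, lp)
                    if key > max_assoc[x]:
                        max_assoc[x] = key
                    if pv >= cfg.a:
                        dropped = True
                        trace.append(f"drop {x}: p={pv:.4g} given Z={Z}")
                        for y in Z:
                            swap = tuple(sorted((set(Z) - {y}) | {x}))
                            pv2, _ = probe(y, swap)
                            if pv2 >= cfg.a:
                                substitutes.setdefault(y, set()).add(x)
                                trace.append(f"substitute: {x} can replace {y}")
                        break
                if not dropped:
                    still.append(x)
            remaining = still
            if not remaining:
                break
        # select the survivor with the minimal maximal association p
        best = min(remaining, key=lambda j: (max_assoc[j][0], max_assoc[j][1], j))
        selected.append(best)
        remaining.remove(best)
        trace.append(f"select {best}: max p={max_assoc[best][0]:.4g}")

    if backward and len(selected) > 1:
        kept: list[int] = []
        for x in selected:
            others = [s for s in selected if s != x]
            ok = True
            for size in range(0, min(cfg.k, len(others)) + 1):
                for combo in itertools.combinations(others, size):
                    pv, _ = probe(x, tuple(sorted(combo)))
                    if pv >= cfg.a:
                        ok = False
                        trace.append(f"backward drop {x}: p={pv:.4g} given {combo}")
                        break
                if not ok:
                    break
            if ok:
                kept.append(x)
        selected = kept

    eq_sets = {y: sorted(substitutes.get(y, set())) for y in selected}
    signatures, total = _enumerate(selected, eq_sets, cfg.max_signatures)
    trace.append(f"selected {selected}; {total} signature(s); {n_tests} tests")
    return SESResult(
        selected=selected,
        equivalence_sets=eq_sets,
        signatures=signatures,
        n_signatures_total=total,
        n_tests=n_tests,
        univariate_cache=univariate_cache,
        config=cfg,
        trace=trace,
    )


def _enumerate(selected, eq_sets, limit):
    if not selected:
        return [()], 1
    options = [sorted({y, *eq_sets.get(y, [])}) for y in sorted(selected)]
    total = math.prod(len(o) for o in options)
    out = []
    for combo in itertools.product(*options):
        if len(set(combo)) < len(combo):
            continue  # overlapping substitutes cannot appear twice
        out.append(tuple(sorted(combo)))
        if len(out) >= limit:
            break
    return out, total


def enumerate_signatures(res: SESResult, limit: int | None = None) -> list[tuple[int, ...]]:
    """Deterministic lexicographic enumeration of the equivalence
    cross-product, truncated at ``limit``."""
    limit = limit if limit is not None else res.config.max_signatures
    out, _ = _enumerate(res.selected, res.equivalence_sets, limit)
    return out


def rerun_with_config(
    prev: SESResult, cfg2: SESConfig, data, test_fn, **kwargs
) -> SESResult:
    """Re-run the search with new hyper-parameters, reusing the stored
    univariate statistics.

    The result is identical to a fresh run with ``cfg2`` except that
    ``n_tests`` excludes the p univariate tests — this is the source of the
    large savings when sweeping a configuration grid.  Raises
    :class:`~temposig.errors.StaleCacheError` if ``data``/``test_fn`` do not
    match the cached fingerprint.
    """
    return run_ses(data, test_fn, cfg2, univariate_cache=prev.univariate_cache, **kwargs)
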