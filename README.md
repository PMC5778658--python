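# temposig

Constraint-based feature selection for high-dimensional temporal data,
returning **multiple statistically equivalent signatures**.

Longitudinal and time-course omics studies routinely measure tens of
thousands of features (gene expression trajectories, metabolite levels) on
a few dozen subjects over a handful of time points. `temposig` finds the
minimal feature subsets that are jointly predictive of an outcome in that
regime, by running the SES (Statistically Equivalent Signatures) forward
search on top of conditional independence tests built for four temporal
study designs:

| design | target | subjects | test |
|---|---|---|---|
| temporal-longitudinal | continuous, per measurement | repeated | random-intercept mixed-model F, or GEE Wald (CS / AR(1), jackknife variance) |
| temporal-distinct | continuous, per measurement | one occasion each | nested linear models, partial F |
| static-longitudinal | one label per subject | repeated | two-stage: per-subject intercept/slope summaries + logistic/multinomial LRT |
| static-distinct | one label per subject | one occasion each | nested logistic/multinomial models, LRT |

## The method in brief

A conditional independence test Ind(X; T | **Z**) asks whether feature X
still informs the target T once the features in **Z** are known. All tests
here are nested-model coefficient tests. For the temporal-longitudinal
design the full model is the Gaussian random-intercept mixed model

    T_ij = a + b_i + γ τ_j + δ' Z_ij + β X_ij + e_ij,
    b_i ~ N(0, σ_b²),  e_ij ~ N(0, σ²),

fitted by maximum likelihood, and the hypothesis β = 0 is tested with
F = (β̂/se(β̂))² on (1, N − K − P + 1) degrees of freedom (N measurements,
K subjects, P fixed-effect parameters). The marginal alternative drops
b_i and fits the same mean by generalised estimating equations with an
exchangeable (CS) or AR(1) working correlation; β is tested by a Wald
statistic whose variance is the leave-one-subject-out jackknife,
appropriate when K ≤ 30.

The SES search keeps a feature only if **no** conditioning subset of the
already-selected set (up to size `k`) renders it independent of T at level
`a`, which bounds the number of tests by O(p·s^k) for a selected set of
size s. When a candidate X is eliminated by a witnessing subset Z, each
member Y of Z is probed with X swapped in for it; if Y is then likewise
dismissible, X is recorded as a *statistical substitute* of Y. Signatures
are the cross-product of every selected feature with its substitutes —
multiple minimal subsets with indistinguishable evidence.

Model selection over the hyper-parameter grid (k ∈ {3,4,5},
a ∈ {0.05,0.1}) uses m-fold cross-validation whose folds hold out whole
time points (or whole subjects in the static-longitudinal design), with
the Tibshirani–Tibshirani correction for the optimism of picking the
winning configuration inside the same cross-validation:

    bias = (1/m) Σ_i [ e_i(θ̂) − e_i(θ̂_i) ],   corrected = naive + bias.

## Worked example

Generate a longitudinal dataset with 25 subjects, 4 time points and 100
features of which the first three drive the target — plus one exact copy
of feature 0 appended as feature 100 — then search:

```python
import temposig as tp

ds, truth = tp.gen_temporal_longitudinal(K=25, d=4, p=100, s=3,
                                         n_duplicates=1, seed=7)
fn = tp.make_test(ds.scenario, test="glmm")
res = tp.run_ses(ds, fn, tp.SESConfig(k=3, a=0.05))
print(res.selected)          # [2, 0, 1]
print(res.equivalence_sets)  # {2: [], 0: [100], 1: []}
print(res.signatures)        # [(0, 1, 2), (1, 2, 100)]
print(res.n_tests)           # 127
```

The search recovers exactly the three generating features, detects that
feature 100 is a statistical substitute for feature 0 (it is its exact
copy), and therefore reports two equivalent signatures. It needed 127
conditional independence tests for 101 candidate features — 101 univariate
tests plus 26 conditional ones.

Cross-validated evaluation of the full six-configuration grid on the same
data:

```python
rep = tp.cross_validate(ds, [{"k": k, "a": a, "test": "glmm"}
                             for k in (3, 4, 5) for a in (0.05, 0.1)],
                        m=4, seed=0)
print(rep.naive, rep.bias, rep.corrected)   # 0.9722 0.0 0.9722
```

Here every fold prefers the same configuration, so the optimism estimate
is zero and the corrected mean squared prediction error equals the naive
one. Univariate test statistics are cached per fold, so the six
configurations cost one univariate sweep, not six.

The same operations are available from the shell:

```bash
temposig simulate --scenario temporal_longitudinal --output sim.csv \
    -K 25 -d 4 -p 100 -s 3 --seed 7
temposig select --input sim.csv --scenario temporal_longitudinal --test glmm
temposig cv     --input sim.csv --scenario temporal_longitudinal -m 4 --seed 0
temposig test   --input sim.csv --scenario temporal_longitudinal -x 0 -z 1
```

Input tables are long-format CSV/TSV with reserved columns `subject`,
`time`, `target`; every other column is a feature.

## Layout

- `temposig.dataset` — the `TemporalDataset` container, long-table I/O,
  fold units.
- `temposig.ci_tests` — the four families of conditional independence
  tests behind one `make_test` dispatch.
- `temposig.ses` — the forward max-min search, equivalence detection,
  signature enumeration, univariate caching.
- `temposig.evaluation` — folds, mirror predictive models, MSPE/PCC,
  TT bias correction, paired permutation t-test, proportion z-test.
- `temposig.synthetic` — seeded generators for all four designs with
  ground truth.
- `temposig.cli` — the `temposig` command.

See `docs/methods.md` for modeling assumptions, parameter defaults and
numerical conventions.
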