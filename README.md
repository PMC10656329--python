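# btrunk — Bradley–Terry regression trunks for preference data

`btrunk` analyzes *paired-comparison preference data*: each of `H` judges
ranks the same small set of `n_o` objects (3–6 of them), and we want to know
both which objects are preferred overall and **how those preferences depend on
who the judge is**. It combines:

* a **log-linear Bradley–Terry model** with judge covariates, and
* a **regression trunk** — a small, deviance-driven threshold tree over the
  judge covariates whose terminal regions enter the model as interaction
  terms — pruned by judge-level cross-validation.

The result is a single interpretable model: global "worth" parameters for the
objects, linear covariate effects on each worth, and a handful of
automatically discovered judge subgroups (e.g. *"x1 ≤ 0.3 and x2 > 25"*) whose
preferences deviate from the rest.

## The model

Each judge `h` assigns object `i` a worth

```
lambda_{i,h} = lambda_i + sum_p beta_{i,p} x_{p,h} + sum_t beta_{i,t} I(judge h in region t)
```

and prefers object `i` over `j` with probability
`P(i > j) = expit(2 * (lambda_{i,h} - lambda_{j,h}))`. The last object is the
reference: all of its parameters are fixed at zero, giving
`(n_o - 1) * (1 + P + (T - 1))` free structural parameters for `P` covariates
and `T` terminal regions (one region is the reference, reached from the root
by always taking the ">" branch).

The model is the profiled form of a log-linear (Poisson) representation with
two cells per comparison whose means sum to one; fitting is by iteratively
reweighted least squares on the profiled binomial likelihood, which yields
identical estimates and deviance. Overdispersion is estimated as Pearson
X²/df and used to correct the standard errors.

**Growing the trunk.** Starting from the main-effects model, every admissible
split of every terminal node is tried — each candidate threshold is a distinct
covariate value observed in the node (excluding the maximum), each side must
keep at least `min_bucket` judges — and the candidate model is fully refitted.
The split with the largest deviance decrease wins. In *one-split-only* (OSO)
mode each covariate may be used once in the whole trunk; *multiple-splitting*
(MS) mode allows reuse.

**Pruning.** Folds are assigned at the judge level (all comparisons of a
judge held out together). For every trunk size `t`, coefficients are refit per
training fold with the structure fixed, and the held-out comparisons give a
case-wise cross-validated deviance `Dcv[t]` with standard error `SEcv[t]`.
The selected size is the smallest `t` with
`Dcv[t] <= min_t' Dcv[t'] + c * SEcv[argmin]` — the classic `c·SE` rule
(`c = 0` picks the minimum).

**Consensus rankings.** Each terminal node is summarized by its *median
ranking*: the weak order (ties allowed) maximizing the mean tau_x rank
correlation with the node's members, found by exact exhaustive enumeration
(13, 75, 541 weak orders for 3, 4, 5 objects).

A built-in simulator generates synthetic studies from three scenarios (one
covariate; four covariates; four covariates plus a genuine
`I(x1 > 0 & x2 > 0.5)` threshold interaction) and estimates the type I error
and power of the pruning rule by Monte Carlo.

## Worked example

Simulate a study of 120 judges ranking 4 objects (A–D) under the interaction
scenario, then grow, cross-validate and prune a trunk:

```
$ btrunk simulate --scenario 3 --objects 4 --judges 120 --effect high --seed 42 --out sim
wrote 120 rankings of 4 objects to sim

$ btrunk trunk sim/rankings.csv sim/covariates.csv --max-terminals 4 --folds 10 --c 0 --seed 0 --out trunk0
split 1: node 1, x4 <= -0.0669532, deviance 554.74
split 2: node 3, x2 <= -0.989538, deviance 528.60
split 3: node 2, x1 <= -0.284364, deviance 510.92
selected size (c=0.0): 3 splits, 4 terminal nodes
```

The cross-validation profile written to `trunk0/cv_profile.tsv`:

| model | D      | Dcv    | SEcv   |
|-------|--------|--------|--------|
| mod0  | 583.54 | 0.4397 | 0.5143 |
| mod1  | 554.74 | 0.4301 | 0.5256 |
| mod2  | 528.60 | 0.4191 | 0.5243 |
| mod3  | 510.92 | 0.4159 | 0.5323 |

`Dcv` is minimized by mod3, so `c = 0` keeps all three splits. (Note that the
case-wise `SEcv` is of the same order as `Dcv` itself, so any appreciable
`c` collapses the trunk to the root; see `docs/methods.md`.) Per-node
consensus rankings of the pruned trunk:

```
$ btrunk consensus sim/rankings.csv sim/covariates.csv --max-terminals 4 --folds 10 --c 0 --seed 0 --out cons0
 node   H    C  tau_bar
    4  21 3421 0.380952
    5  34 1234 0.401961
    6  14 1234 0.238095
    7  51 1324 0.542484
```

`C = 3421` means the node's 21 judges rank object A third, B fourth, C second
and D first; `tau_bar` is the mean tau_x of the members with that consensus.
The same analysis from Python:

```python
from btrunk import ScenarioConfig, simulate_dataset, grow, cv_deviance, prune

comp, cov = simulate_dataset(ScenarioConfig(scenario=3, n_judges=120, effect="high", seed=42))
trunk = grow(comp, cov, mode="oso", max_T=4)
profile = cv_deviance(trunk, comp, V=10, seed=0)
size = prune(profile, c=0.0)        # -> 3
print(trunk.render())
print(trunk.fits[size].summary_frame())
```

The main-effects fit alone (`btrunk fit sim/rankings.csv sim/covariates.csv`)
reports `n design rows: 1440; deviance: 583.54; dispersion: 0.927` and a
coefficient table with raw and overdispersion-corrected standard errors, e.g.
`lambda[A] = 0.610 (se 0.243, corrected 0.216)`.

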