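# Methods

## The optimization model

`magpiefs` implements two population metaheuristics for continuous
minimization over a box, modelled on the foraging ecology of the
red-billed blue magpie, and wraps them into a binary feature selector.

**RBMO (baseline).** A population of `N` agents `X_i ∈ [lb, ub]^D` is
initialized uniformly. Each iteration applies, per agent:

- *search*: `X' = X_i + r·(mean(group) − X_rs)`, where the group is a
  random subset of the population (small group of 2–5 with probability
  `p`, otherwise a large group of 10–N) and `X_rs` is a random agent;
- *prey*: `X' = X_food + CF·r·(mean(group) − X_rs)`, where `X_food` is the
  incumbent best and `CF = (1 − t/T)^(2t/T)` decays from 1 to 0;
- *storage*: greedy selection — a candidate replaces the agent's retained
  position only if its fitness is strictly lower (ties keep the
  incumbent).

**IRBMO (improved).** Three behaviors per agent and iteration, each
candidate clamped to the box and passed through greedy selection:

1. *elite search* — with probability `S`: `X' = X₁ + r·(X_eq − X_R1)`
   (`X₁` the incumbent, `X_eq` the mean of the current top three);
   otherwise `X' = RS + rb·r·(X_best − X_R1)` with `RS` drawn uniformly
   from the elite pool (top three plus their mean) and `rb` a
   per-dimension N(0,1) Brownian factor.
2. *collaborative hunt* — with probability `S`:
   `X' = X_best + cv·(X_eq − X')` with `cv` a standard Cauchy scalar;
   otherwise `X' = (RS − X_best)·levy + r·RS·L` with a Mantegna Lévy step
   (β = 1.5) and moderator `L ~ U(0,1)`. The hunt acts on the elite-search
   candidate, then the result is greedily accepted against the agent's
   memory.
3. *memory compensation* — with food abundance `A = 1 − t/T`: if
   `A > r`, `X' = X_i + CF·(RS + r·(ub − lb))·E` with `E ~ N(0,1)`
   (elite-led perturbation, large early); else
   `X' = X_i + (A(1−r) + r)·(X_idx1 − X_idx2)` over two random agents
   (reserve recombination, dominant late). A second greedy acceptance
   follows.

Because every move is accepted greedily, the best-so-far curve is
monotone non-increasing for any objective; this is asserted by property
tests rather than assumed.

### Defaults for under-determined pieces

The behavioral narrative leaves several scalars open; the package fixes
them once as documented defaults: `S = p = 0.5` (unbiased branch choice),
`A = 1 − t/T` (abundance decays linearly), `E ~ N(0,1)` and `L ~ U(0,1)`
redrawn per update, `cv` a single Cauchy scalar per update (keeping the
contraction direction coherent), the Lévy step a scalar multiplying the
whole difference vector, and `rb` a per-dimension normal. Out-of-bounds
coordinates are clamped to the violated bound. Group sizes are redrawn
per update; group members are sampled without replacement, while `X_rs`
is drawn from the whole population and may coincide with a member. The
large-group lower end (nominally 10) is truncated to `N` for small
populations.

## Binarization

Feature subsets are bit vectors over the `D` features; the swarm operates
on `[0, 1]^D`. Three mappings are provided:

- **threshold** (default): bit `j = 1` iff `x_j > 0.5`; the boundary
  value maps to 0 (only strict inequalities are defined, so the boundary
  had to be assigned — measure-zero in practice).
- **S-family** `s1..s4` (sigmoids of decreasing steepness; `s2` is the
  reflected form): `TF(x_j)` is the probability the bit is *set*.
- **V-family** `v1..v4` (`|tanh|`, `|erf|`, algebraic, arctan forms):
  `TF(x_j)` is the probability the current bit is *flipped*. Flip
  semantics need a persistent per-agent mask; it is initialized from the
  threshold rule at the agent's first evaluation and carried across
  iterations. Threshold/S masks are re-derived from the continuous
  position at every evaluation.

## Wrapper fitness

A mask `m` is scored on a stratified hold-out split (75% train / 25%
test by default):

    fitness(m) = α·(1 − accuracy_test(m)) + (1 − α)·|m|/D,   α = 0.99

with a K-nearest-neighbour classifier (k = 5, Euclidean distance,
features min–max scaled to [0, 1] using *train-set* ranges only — no
test leakage; constant columns map to 0). The weighting is the dominant
convention in wrapper feature selection: error dominates, subset size
breaks near-ties toward parsimony. Both α and k are configuration.

KNN tie-breaks are fixed so runs are exactly reproducible: equal
distances resolve toward the lower training-row index (stable sort);
vote ties resolve toward the tied class with the smallest aggregate
neighbour distance, then the smallest class index. The implementation is
a direct numpy/scipy computation because these contracts are part of the
interface; tests cross-check it against scikit-learn's classifier where
the contracts do not bind.

An empty mask is never evaluated: the default policy scores it 1.0 (the
worst possible fitness); a `repair` policy that sets one uniformly
chosen bit is available.

Each independent run redraws its split from the run seed
(`base_seed + run_index`), so run-to-run standard deviations reflect
both search and split variability. One integer seed determines the
split, the swarm trajectory, and any stochastic binarization.

## Metrics and comparison procedures

Confusion-matrix rates use the standard one-vs-rest definitions;
multi-class problems are macro-averaged (accuracy stays the plain
fraction correct). A 0/0 rate is an undefined marker (NaN) and is
excluded from averages. Aggregation reports the mean and *sample*
(n−1) standard deviation per metric, the raw mean selected-feature
count, and the count normalized by `D`.

Algorithm comparisons use the two-sided Wilcoxon rank-sum test: exact
enumeration when the pooled size is ≤ 12 with no ties, the tie-corrected
normal approximation otherwise, and NaN when all pooled values are
identical (the test is uninformative). Win/tie/loss bookkeeping calls a
problem a tie at p ≥ 0.05 and otherwise decides by comparing means in
the metric's direction. Friedman mean ranks use mid-rank tie handling;
the chi-square statistic is attached when three or more algorithms are
ranked, but the headline output is the mean-rank ordering.

## Synthetic data

The generator plants known structure: informative columns are
class-conditional Gaussians with unit variance and class means
`class_sep` apart per feature; redundant columns are random
unit-norm linear combinations of the informative block plus Gaussian
noise (sd 0.05); noise columns are standard normal and independent of
the labels; labels are balanced, optionally flipped with probability
`label_noise`. The ground-truth informative mask is returned alongside.

What it does *not* emulate: categorical or ordinal attributes, missing
values, heavy-tailed or correlated measurement noise, and class
imbalance, all common in clinical tables. Passing tests therefore show
that the pipeline recovers planted linear-Gaussian structure and that
the improved optimizer beats its baseline under controlled conditions —
not that either holds on any particular real dataset.

A caveat the benchmark makes visible: with several strongly informative,
mutually redundant columns, the hold-out optimum often *excludes* some
informative columns (the parsimony term rejects features whose removal
does not raise hold-out error), and with ~75 test points a noise column
can lower the hold-out error by chance. Per-feature recovery rates are
therefore informative but not expected to reach 1 even for a perfect
optimizer of this objective; see the recovery figures the acceptance
script prints.

## Problem sizes

The package's benchmark protocol is 30 agents × 100 iterations per run
with 10 independent runs per dataset over three synthetic datasets of
decreasing separability (300×20, 200×15, 250×12; class separations 2.0,
1.5, 1.0). The experiment driver defaults to 30 runs for full studies;
the test suite and acceptance script use the 10-run protocol as the
package's standard benchmark size.

## Known limitations

- The single-hold-out wrapper fitness can overfit its 25% split; a
  cross-validated fitness would be less variable but is a different
  protocol and is out of scope.
- RBMO's prey move contracts onto the incumbent as `CF → 0`, so its
  late-stage exploration is weak; its slower convergence relative to
  IRBMO is expected behavior, not a defect.
- Competitor metaheuristics (GA, PSO, GWO, …) and continuous benchmark
  suites are out of scope; the comparison machinery accepts any
  per-run samples, so external results can be compared through
  `stats_compare` directly.
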