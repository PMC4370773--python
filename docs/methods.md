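# Methods

## The model

A multi-layered network with `L` interaction layers is a chain of matrices
`A(1) … A(L)`; the entry `A(l)[i, j]` is the interaction intensity from node
`j` in node layer `l` to node `i` in node layer `l+1`. Only feed-forward
connections between consecutive layers exist. The network's input-output
function is the product `P = A(L) … A(1)`, and evolution drives it towards a
goal matrix `G` through the fitness

    F = −‖P − G‖²  (sum of squared entries; 0 is a perfect match).

Goal matrices are built from 0 and `entry_value` (default 10) entries with a
prescribed rank `r`: `r` linearly independent 0/1 row patterns are sampled,
each of the `d_output` rows is assigned one pattern (each pattern used at
least once), and rejection sampling enforces that no row or column is all
zero, so every input and output node is constrained. A consequence worth
knowing: the only admissible rank-1 goal is the constant matrix.

Because matrix multiplication cannot increase rank, any factorization of `G`
through a layer with `k` active nodes requires `k ≥ rank(G)`: the rank is a
hard floor on the width of the narrowest layer (the *waist*). The scientific
question is whether evolutionary dynamics find the narrow factorizations.

## Evolutionary dynamics

Each generation: duplicate the population of `N` individuals; mutate each
matrix element of the copy independently with probability `p` (product rule:
multiply by `Normal(1, σ)`; sum rule: add `Normal(0, σ)`); evaluate all `2N`
individuals; fill the next generation by tournament selection (each of `N`
slots takes the fittest of `s` uniform draws from the pool, ties broken
uniformly). Reference parameters: `N = 100`, `s = 4`, `σ = 0.1`,
`p = 0.2/(L·D²)` (≈ 20% of individuals mutated per generation), convergence
when the mean population fitness is within 0.01 of the optimum, generation
cap 10⁵.

Exact zeros are fixed points of the product rule, which is what biases it
towards eliminating interactions; the sum rule has no such attractor and
serves as the control.

**Initialization.** Matrix entries are drawn uniformly from (0, 0.1) by
default. This choice matters and is deliberate: with entries of scale 0.1
the initial chain product (~10⁻³ per entry) sits far below the goal scale
(10), so the function must be built by selectively amplifying paths, and
multiplicative mutations preferentially amplify the strongest ones — this
growth-phase winner-take-all is what concentrates signal flow onto few nodes.
We verified empirically that an initialization whose product already matches
the goal scale (e.g. uniform (0, 1) at `D = 6, L = 4`, product ≈ 13.5)
produces no bow-tie within 10⁵ generations: post-convergence neutral drift
of log-weights (rate `p·σ²/2 ≈ 7·10⁻⁶` per generation) is far too slow to
carve zeros. The initialization range is exposed in `EvolutionConfig`.

**Stopping.** Linear-model runs stop at mean-fitness convergence (tolerance
0.01) or the generation cap; only converged runs enter the analysis. Retina
runs use a fixed budget of 10⁴ generations with no early stop, because the
sparsification that forms the bow-tie continues long after fitness has
converged; a retina run enters the analysis if its best individual ends
within 10⁻⁴ of the optimum.

**Temporal noise.** With temporal noise, every fitness evaluation perturbs
all matrices and the goal by fresh iid `Normal(0, σ_noise)` entries, drawn
per individual per generation (whether the original study shared noise
realizations across the population is not determinable; per-individual is
implemented). Fitness caching is invalid under noise, so all `2N`
individuals are re-evaluated each generation, and runs use a fixed budget.
The noise sets a fitness floor far below the 0.01 tolerance, so temporal
campaigns skip the converged-run filter and are judged by the fluctuation
magnitude (std/|mean| of the mean-fitness trajectory over the last 5000
generations) instead.

## Activity analysis

Evolved matrices hold small values rather than exact zeros, so layer widths
are functional: node `k` of layer `l+1` is knocked out by zeroing row `k` of
`A(l)` and column `k` of `A(l+1)` (boundary nodes: the single adjacent
matrix), and its effect is `dF = |F − F̃|`. Effects are compared within a
layer: a node is active iff `dF ≥ threshold · max(dF in its layer)`, with
threshold 10⁻³ for the linear model. Normalizing by the layer's dominant
effect rather than by `|F|` keeps the criterion meaningful for well-converged
networks, whose `|F|` is arbitrarily small while the signal carried by an
active node stays on the goal scale; dividing by `|F|` would mark every node
of a near-perfect network active and no bow-tie would ever be measured. The
waist is the minimum active count over internal layers; ties resolve to the
most central layer, then the lowest index, reflecting the symmetry argument
for why the waist forms mid-network.

For the retina the knockout is per weight (threshold 10⁻⁴, same within-layer
normalization); a node is inactive iff its entire set of outgoing weights is
negligible. Thresholds are never knocked out — a node without inputs can
still supply a constant bias. Output-layer nodes carry the outputs and are
always counted active.

## The retina problem

A 2×2 Boolean retina (pixel order: top-left, top-right, bottom-left,
bottom-right) feeds a 4-4-4-4 perceptron, `u(l+1) = f(A(l) u(l) − T(l+1))`
with `f(x) = (1 + tanh x)/2`. The four targets — left-column object,
right-column object, their AND, their OR — are functions of two Boolean
features, so the task's effective rank is 2. Fitness is the negative mean
over the 16 input patterns of the summed squared output errors (the
per-pattern sum-vs-mean choice is exposed as `pattern_reduction`; the
absolute fitness scale, and with it the 10⁻⁴ inclusion cut, depends on it).
Weights and thresholds are initialized uniformly on [−2, 2] and both mutate
(per-term probability 0.2, product multiplier `Normal(1, 0.5)`, which goes
negative — flips a sign — with probability Φ(−2) ≈ 0.02; the sum-rule
control adds `Normal(0, 0.5)`).

**Numerical choice.** The squared output errors are evaluated as
`|f(z) − t| = expit(∓2z)` for Boolean targets `t`, which is exact
algebraically and representable down to `e^(−745)`. Computing
`(1 + tanh z)/2 − t` directly rounds to exactly 0 once `|z| ≳ 19`, making
saturated networks float-perfect and erasing the selection gradient the
mathematical model actually has; the stable form preserves the model
property that fitness is strictly negative for finite weights.

## What the simulations do and do not show

The generator produces exactly the study conditions above — no external
data is involved. Desk-scale ensembles (tens of runs per condition instead
of hundreds to thousands) reproduce: the rank floor (no converged run ever
compresses below rank, in any condition); full-rank goals yielding full
6-node layers in every run; rank-deficient goals with product mutations
yielding modal waist = rank with roughly a fifth of runs above it; sum-rule
runs almost always above rank, with median waist ≈ 3 for a rank-1 goal; a
~1% mean noise level for U[0, 0.1]-perturbed 0/10 goals; and temporal-noise
runs keeping waist 1 while fitness fluctuations stay below ~0.3.

The retina *fractions* do not reproduce at their printed values: the share
of product-rule runs with a 2-node internal layer comes out at roughly a
third rather than three quarters, and the sum-rule share at roughly a
quarter to a third rather than ~45%. We explored the protocol space
(fitness evaluation variants, mutation-rate readings, longer budgets,
knockout thresholds) without reaching the printed values and ship the
faithful protocol; the plausible cause is an implementation-specific detail
of the original simulation's numerics in the saturated regime. The
qualitative nonlinear claims hold throughout: internal layers are never
narrower than the effective rank 2, are frequently exactly 2, and are
narrower than the input/output layers in most runs.

Scaled-down ensemble sizes mean the percentage statistics carry binomial
error of a few points; the medians and extremes (min waist, full-rank width)
are stable. Nothing here models real biological networks directly: the
simulations show that the rank/product-rule mechanism *can* produce
bow-ties, not that any particular biological bow-tie arose this way.

## Degenerate inputs and edge cases

- A population whose mean fitness already meets the tolerance converges at
  generation 0 with an empty trajectory.
- `noise_level` is undefined (raises) for an all-zero clean goal.
- A knockout layer whose every effect is 0 (a fully disconnected layer)
  counts 0 active nodes via a 10⁻¹² denominator floor.
- Goal construction signals failure after a bounded number of rejection
  rounds if no 0/10 pattern of the requested rank exists.
- Ensemble runs are bit-reproducible: each replicate consumes its own seeded
  stream in fixed-size blocks, so a run's results are identical whether it
  is executed alone or batched with others, and campaign outputs are a pure
  function of the campaign spec.
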