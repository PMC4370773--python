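# bowtieevo

Evolutionary simulations of **bow-tie (hourglass) architectures** in
multi-layered networks — the common biological motif in which many inputs
and many outputs communicate through a narrow intermediate layer (metabolism
through ~12 precursor metabolites, signaling through a handful of pathways,
10⁸ photoreceptors through 10⁶ optic-nerve fibers).

The package asks: under what conditions does a bow-tie *evolve by itself*?
It evolves populations of layered networks towards an input-output goal and
measures the width of each evolved layer, showing that a bow-tie emerges
exactly when

1. the **goal is rank deficient** — the target input-output map
   `G` (`D_out × D_in`) satisfies `r = rank(G) < D`, so the signal can be
   compressed; and
2. **mutations act multiplicatively** (`A_ij → A_ij · N(1, σ)`, the
   "product rule"), which makes zero interactions an evolutionary attractor.

The narrowest evolved layer — the *waist* — is then bounded below by `r`
(because `rank(AB) ≤ min(rank A, rank B)`, any chain realizing `G` needs at
least `r` active nodes in every layer) and in most runs equals it. Additive
("sum-rule") mutations, the control, leave wide middle layers instead.

## Models

- **Linear chain**: `L` matrices `A(1)…A(L)` (all `D × D`), fitness
  `F = −‖A(L)…A(1) − G‖²` (sum of squares); goals built from 0/10 entries at
  a prescribed rank, optionally perturbed once per run by uniform noise, or
  fluctuating every generation (temporal white noise).
- **Retina perceptron**: a 4-4-4-4 nonlinear network
  `u(l+1) = f(A(l)u(l) − T(l+1))`, `f(x) = (1+tanh x)/2`, evolved to report
  whether a 2×2 Boolean image has an object in its left column, its right
  column, both, or either — four outputs that depend on just two features
  (effective rank 2).

Evolution is a standard mutation–selection loop: duplicate the `N = 100`
individuals, mutate one copy element-wise with probability `p = 0.2/(L·D²)`,
evaluate all `2N`, keep `N` by tournament selection (`s = 4`). Activity of
an evolved node is measured by knockout: zero all its incident interactions
and compare the fitness change with the other nodes of its layer (nodes
below 0.1% of the layer's dominant effect are inactive; the retina scores
per weight at 10⁻⁴).

## Worked example

`examples/01_rank_deficient_bowtie.py` evolves eight replicate populations
(`D = 6`, `L = 4`) towards a rank-1 goal and prints:

```
converged runs: 8/8
goal rank: 1
  active nodes per layer: (6, 3, 1, 1, 6)  waist 1 @ layer 3
  active nodes per layer: (6, 1, 1, 2, 6)  waist 1 @ layer 3
  active nodes per layer: (6, 1, 1, 3, 6)  waist 1 @ layer 3
  active nodes per layer: (6, 2, 2, 2, 6)  waist 2 @ layer 3
  active nodes per layer: (6, 2, 1, 1, 6)  waist 1 @ layer 3
  active nodes per layer: (6, 2, 1, 1, 6)  waist 1 @ layer 3
  active nodes per layer: (6, 2, 1, 2, 6)  waist 1 @ layer 3
  active nodes per layer: (6, 3, 1, 1, 6)  waist 1 @ layer 3
median waist: 1.0
fraction of runs with waist == rank: 0.88
```

Each row is one evolved network: the boundary layers keep all 6 nodes (the
goal constrains every input and output), while the middle layers are carved
down to the goal's rank — a bow-tie. With a full-rank goal every layer stays
at 6 nodes in every run; with sum-rule mutations the median waist for this
goal is ~3, not 1.

Other examples: `02_noisy_goals.py` (approximately-rank-deficient goals,
~1% noise), `03_retina.py` (the nonlinear task), `04_parameter_sweep.py`
(robustness to evolutionary parameters).

A thin CLI wraps the same machinery:

```bash
bowtieevo evolve --config run.json --out outdir/
bowtieevo retina-evolve --rule product --seeds 0:50 --out retina/
bowtieevo analyze --runs outdir/runs --out analysis/
bowtieevo sweep --config sweep.json --out sweep.csv
```

## Library layout

| module | contents |
| --- | --- |
| `bowtieevo.goals` | `GoalSpec`, `make_goal`, fixed noise, numerical rank |
| `bowtieevo.network` | `LayeredLinearNetwork`, `propagate`, `transfer_matrix`, `fitness` |
| `bowtieevo.evolution` | `EvolutionConfig`, mutation/selection operators, `run_evolution`, batched `run_ensemble`, temporal noise |
| `bowtieevo.analysis` | knockout `active_nodes`, `waist`, `summarize_ensemble`, bootstrap errors |
| `bowtieevo.retina` | the nonlinear model: forward pass, truth table, evolution, per-weight knockouts |
| `bowtieevo.campaigns` | seeded multi-run campaigns, parameter sweeps, persistence |
| `bowtieevo.plotting` | layer-width histogram and median-width figures |

All randomness flows through per-run `numpy` generator streams: a run is
bit-identical whether executed alone or inside a batched ensemble, and
campaigns are pure functions of their spec.

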