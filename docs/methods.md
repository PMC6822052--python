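# Methods

## Model overview

`floodnest` couples two views of the same question — how populations adapt
to rare, severe environmental events — at different levels of abstraction.

The **analytical layer** (`theory`) works with a pair of fitness functions
`W_M(z)`, `W_E(z)` for moderate and extreme conditions and three long-term
mean-fitness functionals: geometric (`W_M^(1-p) · W_E^p`), arithmetic
(`(1-p)·W_M + p·W_E`) and mixed
(`W_M^(1-p) · [(1-s)·W_M + s·W_E]^p`), where `p` is the per-generation
probability of an extreme event and `s` its scope (fraction of the
population affected). The bundled toy landscape uses skew-normal curves
with locations 0.1 (moderate) and 0.6 (extreme), scale 0.3 and slant 5;
the skew-normal "shape" is interpreted as the scale ω and "skew" as the
slant α of the standard (ξ, ω, α) parameterization. Curves are used as raw
densities — normalization changes no argmax — with an optional
peak-normalization flag for plotting.

The **mechanistic layer** (`abm`) is a forward-time, individual-based model
of a riparian nesting bird: haploid, asexual, discrete non-overlapping
generations (a lifespan of one year), heritable nest height `z ∈ [0, 1]`.
Per breeding attempt, success is `1 - z` (linear predation cost) unless a
flood of height `h` strikes the nest (`z < h` → 0). A generation consists
of `n` attempts; each attempt floods population-wide with probability `p`
(so several floods can hit one season); within a flooded attempt each nest
is independently affected with probability `s`. Lifetime reproductive
success is

    w_i = round( Σ_{k=1..n} c · W(z_i; h_ik) ),

rounded **once** over the lifetime sum, half up. Offspring inherit `z`,
mutating with probability `m` by a Normal(0, `m_size`) deviate clamped to
[0, 1]; recruitment is capped at `K` by uniform random removal (no
competitive differences between attempts). Extinction is population size
zero and is absorbing.

## Parameters

| name | meaning | default | units |
|---|---|---|---|
| `p` | flood probability per breeding attempt | 0.1 | probability |
| `s` | scope: per-nest probability of being affected given a flood | 1.0 | probability |
| `h` | flood height | 0.4 | phenotype units |
| `n` | breeding attempts per lifetime | 1 | count |
| `c` | maximum clutch size (intrinsic rate of increase) | 5 | offspring/attempt |
| `n0` | founding population size (z ~ Uniform(0,1)) | 5,000 | individuals |
| `k` | carrying capacity | 5,000 | individuals |
| `m` | per-offspring mutation probability | 0.001 | probability |
| `m_size` | mutation step standard deviation | 0.05 | phenotype units |
| `generations` | run length | 2,000 | generations |

`p` and `s` have no single canonical value — the experiments sweep them —
so the bare defaults (0.1, 1.0) simply name a coarse-grained baseline.
Variants, all off by default: `flood_height_sd` (per-event flood heights
from a truncated normal on [0, 1] centred on `h`; truncation by redraw, so
no mass piles at the boundaries), `overlap` with `adult_survival` (adults
persist between years and count against `K`; recruits fill the remaining
room), `adult_mortality` (under overlap, adults whose nest was destroyed
die with it), and larger `m_size` (stands in for valley-crossing
mutations).

## Randomness and reproducibility

Each replicate consumes a single `numpy.random.Generator` in a fixed
order: flood indicators (one uniform per attempt), variant flood heights,
per-attempt scope masks (one uniform vector per flooded attempt), the
mutation mask then deviates for mutants only, the adult-survival draw
(overlap variant), and recruitment. A seed therefore fixes a run
bit-for-bit, and trajectory CSVs re-written from the same config and seed
are byte-identical. Sweep replicates derive child seeds via
`SeedSequence([base_seed, cell_index, replicate])`; the derived integers
are logged in the output tables. In the two-stage experiments, each
perturbation branch restores the generator state snapshotted at the change
point, so stage 1 is bit-identical to an unperturbed run and branches are
comparable across targets.

## Experiments

`run_sweep` covers a `(p, s, n)` grid (default p ∈ 0.05–0.30, s ∈
{0.8, 0.9, 1.0}, n ∈ 1–5, 100 replicates per cell) and classifies each
surviving replicate by final mean phenotype: *low* below 0.05, *high*
above `h`, *intermediate* otherwise (boundaries fall in intermediate).

`run_vulnerability_profile` evolves each replicate for
`change_generation` generations (default 2,000), raises one regime
parameter by `delta` (default 0.1; `p`, `s` and `h` cap at 1), and follows
stage-1 survivors for `followup_generations` (default 200). *Relative
survival* is measured among stage-1 survivors only. Survivors are
classified against both the pre-change `h` (the regime they evolved
under — the primary report) and the post-change `h`.

The vulnerability studies in the tests and acceptance script probe three
cells chosen from the default grid where each regime evolves robustly:
high-nesting at (p=0.25, s=1, n=1); low-nesting at (p=0.10, s=0.9, n=1)
for the scope perturbation and at (p=0.05, s=1, n=3) for the frequency
perturbation. The split mirrors how the two axes act: at s=1 a scope
increase caps out (a no-op by design), so scope vulnerability is only
meaningful from s ≤ 0.9; conversely a frequency increase can only
extinguish a ground-nesting population when floods are population-wide
(s=1), where a season with all `n` attempts flooded wipes it — at s ≤ 0.9
every flood leaves `(1-s)·N` unaffected nests whose clutches rebound at
rate ~`c` within a generation.

## Numerical choices

* `0^0 := 1` in the geometric and mixed functionals (numpy's convention),
  making the `p = 0` and `p = 1` limits exact.
* Optima are located by dense grid search (step 1e-4) over the phenotype
  domain followed by bounded scalar maximisation inside the bracketing
  cell; the mean-fitness surfaces are bimodal, so the global grid pass is
  not optional. Exact ties resolve to the smallest phenotype.
* Rounding of `w_i` is half-up via `floor(w + 0.5)`, applied once to the
  lifetime sum. Any consistent rule would do; this one is fixed and
  documented, and the flood-free closed form `w = round(n·c·(1-z))` is the
  test oracle.
* Stepping an extinct population is the identity (plus the generation
  counter), so trajectories truncate cleanly at extinction.

## Consequences of integer clutch sizes

Because `w_i` is a deterministic integer, fitness is piecewise constant in
`z` with bands of width `1/(n·c)`. Two consequences matter when reading
results:

1. **Ground-nesting plateaus.** Without floods, all `z` in
   `[0, 1/(2nc))` share the top integer fitness, so the evolved mean
   settles near the middle of that neutral band rather than at 0. At
   `n = 1, c = 5` the band is [0, 0.1) and the mean hovers near the 0.05
   classification threshold; from `n = 2` upward the band is narrow and
   "low nesting" is unambiguous. Mechanistic tests of the
   selection-for-ground-nesting prediction therefore use `n ≥ 2`.
2. **Attenuated height vulnerability.** For high nesters at
   `n = 1, c = 5` the band [0.4, 0.5] is selectively neutral, so the
   uniform founding population keeps a standing tail up to z ≈ 0.5 for of
   order `K` generations — much longer than the 2,000-generation protocol.
   After a +0.1 height increase any individual at or above the new water
   line survives, and with deterministic clutches (`w ≥ 2`) a handful of
   survivors rebounds without demographic risk. High-nesting populations
   are therefore *less* vulnerable to intensity increases here than the
   sharp signature the fully continuous theory suggests: the measured
   relative survival under +0.1 height sits well below the 1.0 observed
   for scope/frequency changes in some cells but reflects frequent
   evolutionary rescue from standing variation. A fitness realization with
   stochastic clutch survival would deplete within-band variation and
   recover the sharp signature; it is deliberately not used because the
   lifetime-sum-then-round contract above is the model definition.

## What the synthetic populations do and do not emulate

The generator produces exactly the study conditions of the model: uniform
founding phenotypes, shared flood schedules, per-nest scope draws, rare
small mutations, a hard cap. It does not emulate sexual reproduction,
diploidy, spatial structure beyond the scope parameter, density dependence
other than the cap, phenotypic plasticity, or measurement noise — so
passing tests certify the model's internal logic and its qualitative
regime structure, not quantitative predictions for any real population.

## Problem sizes

The test suite and acceptance script run the landmark cells at 20
replicates × 2,000 generations (sweeps) and 20 replicates × 2,200
generations (two-stage experiments), with full-size populations
(`n0 = K = 5,000`); the default 100-replicate grids are available through
the library and CLI. The beneficial-change check (frequency increase
rescuing bet-hedgers at p=0.05, s=1, n=1) moves the change point to
generation 300 with a 400-generation follow-up so that enough stage-1
survivors exist at 40 replicates for the comparison to be meaningful.

## Known limitations

* Integer-clutch neutral bands (above) blur the low/intermediate boundary
  at `n = 1` and damp intensity-change vulnerability.
* The truncated-normal law for variable flood heights and the
  adult-survival parameterization of the overlap variant are reasonable
  choices, not canonical ones.
* Scope and frequency increases cap at probability 1; a scope
  perturbation from s = 1 is a no-op rather than an error.
* Relative survival from 20 replicates carries binomial noise of order
  ±0.1; the assertions in the tests are set accordingly.
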