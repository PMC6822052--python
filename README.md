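# floodnest

Evolutionary simulation of adaptation to rare extreme events, built around a
riparian nest-height model, together with the analytical mean-fitness theory
that predicts which adaptive response evolves and which aspect of a changing
climate each response is vulnerable to.

## The scientific problem

Populations exposed to rare environmental extremes (floods, fires, heatwaves)
can respond to selection in two qualitatively different ways. If fitness
accumulates **multiplicatively** across events — the whole population
experiences each extreme simultaneously and individuals reproduce once — a
single zero-fitness generation annihilates a lineage, and selection favours
conservative *bet-hedging* phenotypes that sacrifice performance under
typical conditions to survive the extremes. If fitness accumulates
**additively** — many independent breeding attempts per lifetime, or extremes
that touch only part of the population — selection simply maximises
performance under typical conditions and ignores the extremes.

For a phenotype `z` with fitness `W_M(z)` under moderate and `W_E(z)` under
extreme conditions, occurring with probability `p` and *scope* `s` (the
fraction of the population affected per event), long-term mean fitness is

```
W̄_G(z)   = W_M(z)^(1-p) · W_E(z)^p                          (multiplicative)
W̄_A(z)   = (1-p)·W_M(z) + p·W_E(z)                          (additive)
W̄_A,G(z) = W_M(z)^(1-p) · [(1-s)·W_M(z) + s·W_E(z)]^p       (mixed)
```

The individual-based model realises this with a riparian nesting bird:
nest height `z ∈ [0, 1]` is heritable; predation makes per-attempt success
`1 - z`; floods of height `h` destroy every nest below water
(`W(z; h) = 1 - z` if `z ≥ h`, else 0). Each of `n` breeding attempts per
lifetime floods independently with probability `p`; an affected nest is
drawn per individual with probability `s`; lifetime reproductive success is
`w_i = round(Σ_k c · W(z_i; h_ik))` with maximum clutch size `c`. Haploid,
asexual populations of 5,000 evolve under mutation (`m = 0.001`,
step SD 0.05) and a hard carrying capacity `K = 5,000`.

Two experiments are built in:

* a **sweep** over `(p, s, n)` cells classifying each surviving replicate as
  low-nesting (mean z < 0.05), high-nesting (mean z > h) or intermediate;
* a **two-stage climate-change experiment**: evolve for 2,000 generations,
  abruptly raise flood height, scope, or frequency by 0.1, and measure
  *relative survival* — among populations alive at the change, the
  proportion still extant 200 generations later.

## Worked example

Where do the three mean-fitness functionals place the optimal nest height on
the bundled skew-Gaussian toy landscape?

```
$ floodnest theory --p 0.05 --p 0.15 --p 0.25 --s 1.0 --out-dir theory_out
$ head -4 theory_out/summary.csv
p,s,argmax_geometric,argmax_arithmetic,argmax_mixed
0.05,1.0,0.3975137001741566,0.21115054884710513,0.3975137001741566
0.15,1.0,0.5345698472742536,0.21115054885448842,0.5345698472742536
0.25,1.0,0.585251712316026,0.21115054886003357,0.585251712316026
```

The additive optimum stays pinned at the moderate-conditions peak
(z ≈ 0.211) no matter how frequent the extremes, while the multiplicative
optimum climbs toward the extreme-conditions peak (z ≈ 0.711) as floods get
more frequent — the analytical signature of bet-hedging.

The simulator reproduces this: with one breeding attempt and
population-wide floods a quarter of the years,

```
$ floodnest simulate --p 0.25 --s 1.0 --n 1 --generations 2000 --seed 42 --out-dir sim_out
simulate: p=0.25 s=1.0 h=0.4 n=1 c=5.0 generations=2000 seed=42
done: final mean z = 0.4582, size 5000; outputs in sim_out
```

the population evolves to nest just above the flood line (mean z = 0.458 >
h = 0.4, a "high-nesting" outcome), accepting higher predation in exchange
for surviving every flood. Re-running with `--p 0 --n 5` instead drives the
mean to the ground (z < 0.05): with no floods, or enough independent
attempts, only the predation gradient matters.

## Layout

```
src/floodnest/theory.py       mean-fitness functionals, skew-Gaussian toy landscape
src/floodnest/abm.py          the individual-based simulator
src/floodnest/experiments.py  sweep + two-stage climate-change orchestration
src/floodnest/io.py           YAML/JSON configs, CSV tables, run manifests
src/floodnest/cli.py          the floodnest command
docs/methods.md               model description, design choices, limitations
```
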