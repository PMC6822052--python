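"""Orchestration of the evolutionary-outcome sweep and the two-stage
climate-change experiments.

The sweep runs seeded replicates over a (p, s, n) grid, classifies each
surviving population as low-nesting (mean z below 0.05), high-nesting (mean
z above the flood height h) or intermediate, and aggregates survival and
class proportions per grid cell.

The climate-change experiment lets each replicate evolve for
``change_generation`` generations, then raises either the flood height,
the scope, or the frequency of floods by ``delta`` (probabilities cap at 1)
and follows stage-1 survivors for ``followup_generations`` more.  The
headline quantity is the *relative survival*: among populations alive at
the change point, the proportion still extant at the end of the follow-up.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .abm import ReplicateResult, SimulationConfig, run_replicate

__all__ = [
    "LOW_NEST_THRESHOLD",
    "CLIMATE_TARGETS",
    "SweepGrid",
    "ClimateChangeSpec",
    "classify_outcome",
    "replicate_seed",
    "run_sweep",
    "summarize_outcomes",
    "apply_climate_change",
    "run_staged_replicate",
    "run_climate_experiment",
    "run_vulnerability_profile",
    "summarize_climate",
]

#: Mean phenotype below which a surviving population counts as low-nesting.
LOW_NEST_THRESHOLD = 0.05

CLIMATE_TARGETS = ("height", "scope", "frequency")


def classify_outcome(mean_z: float, h: float) -> str:
    """Evolutionary outcome of a surviving population.

    ``low`` if mean z < 0.05, ``high`` if mean z > h, ``intermediate``
    otherwise (boundary values fall in intermediate).
    """
    if not 0.0 <= mean_z <= 1.0:
        raise ValueError(f"mean_z must lie in [0, 1], got {mean_z}")
    if mean_z < LOW_NEST_THRESHOLD:
        return "low"
    if mean_z > h:
        return "high"
    return "intermediate"


@dataclass(frozen=True)
class SweepGrid:
    """A (p, s, n) parameter grid with a replicate count and base config.

    The default grid spans the regimes where additive versus multiplicative
    fitness accumulation dominates: flood probabilities 0.05-0.30, scopes
    0.8-1.0 and one to five breeding attempts per lifetime.
    """

    p_values: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)
    s_values: tuple[float, ...] = (0.8, 0.9, 1.0)
    n_values: tuple[int, ...] = (1, 2, 3, 4, 5)
    replicates: int = 100
    base_config: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")
        for p in self.p_values:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p value out of range: {p}")
        for s in self.s_values:
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"s value out of range: {s}")
        for n in self.n_values:
            if n < 1:
                raise ValueError(f"n value out of range: {n}")

    def cells(self) -> list[tuple[float, float, int]]:
        """Grid cells in deterministic (p, s, n) product order."""
        return list(product(self.p_values, self.s_values, self.n_values))

    def cell_config(self, p: float, s: float, n: int, seed: int) -> SimulationConfig:
        base = self.base_config
        return base.replace(
            regime=dataclasses.replace(base.regime, p=p, s=s),
            life_history=dataclasses.replace(base.life_history, n=int(n)),
            seed=seed,
        )


def replicate_seed(base_seed: int, cell_index: int, replicate: int) -> int:
    """Derive an independent, reproducible child seed for one replicate.

    Uses numpy's SeedSequence so replicate streams are statistically
    independent across cells and replicates; the derived integer is logged
    in the output tables.
    """
    ss = np.random.SeedSequence([int(base_seed), int(cell_index), int(replicate)])
    return int(ss.generate_state(1)[0])


@dataclass(frozen=True)
class ClimateChangeSpec:
    """An abrupt increase of one flooding-regime parameter.

    ``target`` is one of ``height``, ``scope``, ``frequency``; the targeted
    parameter grows by ``delta`` at ``change_generation`` (capping at 1),
    and populations are followed for ``followup_generations`` more.
    """

    target: str
    delta: float = 0.1
    change_generation: int = 2000
    followup_generations: int = 200

    def __post_init__(self) -> None:
        if self.target not in CLIMATE_TARGETS:
            raise ValueError(
                f"unknown climate-change target {self.target!r}; "
                f"expected one of {CLIMATE_TARGETS}"
            )
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.change_generation < 1:
            raise ValueError("change_generation must be at least 1")
        if self.followup_generations < 0:
            raise ValueError("followup_generations must be non-negative")


def apply_climate_change(
    config: SimulationConfig, spec: ClimateChangeSpec
) -> SimulationConfig:
    """Return a config with the targeted regime parameter increased by delta.

    Probabilities (p, s) and the flood height cap at 1.0; every other field
    is untouched.
    """
    regime = config.regime
    if spec.target == "height":
        regime = dataclasses.replace(regime, h=min(regime.h + spec.delta, 1.0))
    elif spec.target == "scope":
        regime = dataclasses.replace(regime, s=min(regime.s + spec.delta, 1.0))
    elif spec.target == "frequency":
        regime = dataclasses.replace(regime, p=min(regime.p + spec.delta, 1.0))
    else:  # pragma: no cover - guarded by ClimateChangeSpec validation
        raise ValueError(f"unknown climate-change target {spec.target!r}")
    return config.replace(regime=regime)


def run_sweep(
    grid: SweepGrid, base_seed: int = 0, progress: bool = False
) -> pd.DataFrame:
    """Run every grid cell for ``grid.replicates`` seeded replicates.

    Returns one row per replicate: cell parameters, derived seed, survival,
    extinction generation, final population size, final mean phenotype and
    its outcome class.  Aggregate with :func:`summarize_outcomes`.
    """
    rows = []
    for cell_index, (p, s, n) in enumerate(grid.cells()):
        for r in range(grid.replicates):
            seed = replicate_seed(base_seed, cell_index, r)
            config = grid.cell_config(p, s, n, seed)
            res = run_replicate(config)
            rows.append(_sweep_row(p, s, n, r, seed, res))
        if progress:  # pragma: no cover - cosmetic
            print(f"cell p={p} s={s} n={n} done")
    return pd.DataFrame(rows)


def _sweep_row(p, s, n, r, seed, res: ReplicateResult) -> dict:
    survived = not res.extinct
    return {
        "p": p,
        "s": s,
        "n": n,
        "replicate": r,
        "seed": seed,
        "survived": survived,
        "extinction_generation": res.extinction_generation,
        "final_pop_size": int(res.pop_size[-1]),
        "final_mean_z": res.final_mean_z if survived else np.nan,
        "outcome": classify_outcome(res.final_mean_z, res.config.regime.h)
        if survived
        else None,
    }


def summarize_outcomes(replicate_rows: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-replicate rows into per-cell survival and class
    proportions.

    Among survivors the low/high/intermediate proportions sum to one; cells
    with no survivors carry NaN class proportions.
    """
    if replicate_rows.empty:
        return pd.DataFrame(
            columns=[
                "p", "s", "n", "n_replicates", "n_survived", "prop_survived",
                "prop_low", "prop_high", "prop_intermediate", "mean_final_z",
            ]
        )
    rows = []
    for (p, s, n), grp in replicate_rows.groupby(["p", "s", "n"], sort=True):
        survivors = grp[grp["survived"]]
        n_surv = len(survivors)
        row = {
            "p": p,
            "s": s,
            "n": n,
            "n_replicates": len(grp),
            "n_survived": n_surv,
            "prop_survived": n_surv / len(grp),
            "mean_final_z": survivors["final_mean_z"].mean() if n_surv else np.nan,
        }
        for label in ("low", "high", "intermediate"):
            row[f"prop_{label}"] = (
                (survivors["outcome"] == label).sum() / n_surv if n_surv else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def run_staged_replicate(
    config: SimulationConfig,
    specs: Sequence[ClimateChangeSpec],
    rng: Optional[np.random.Generator] = None,
) -> tuple[ReplicateResult, dict[ClimateChangeSpec, Optional[ReplicateResult]]]:
    """Run stage 1 once, then branch one follow-up run per perturbation.

    All specs must share ``change_generation``; stage 1 is bit-identical to
    an unperturbed run with the same seed.  Each branch restores the random
    generator to its state at the change point, so follow-ups are comparable
    across perturbations; a stage-1 extinction yields ``None`` branches.
    The returned dict is keyed by the (hashable) specs themselves.
    """
    if not specs:
        raise ValueError("at least one ClimateChangeSpec is required")
    if len(set(specs)) != len(specs):
        raise ValueError("specs must be distinct")
    change_gens = {spec.change_generation for spec in specs}
    if len(change_gens) != 1:
        raise ValueError("all specs must share change_generation")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    stage1 = run_replicate(config, rng, generations=specs[0].change_generation)
    branches: dict[ClimateChangeSpec, Optional[ReplicateResult]] = {}
    if stage1.extinct:
        for spec in specs:
            branches[spec] = None
        return stage1, branches
    snapshot = copy.deepcopy(rng.bit_generator.state)
    for spec in specs:
        branch_rng = np.random.default_rng()
        branch_rng.bit_generator.state = copy.deepcopy(snapshot)
        changed = apply_climate_change(config, spec)
        branches[spec] = run_replicate(
            changed,
            branch_rng,
            initial_state=stage1.final_state,
            generations=spec.followup_generations,
        )
    return stage1, branches


def run_vulnerability_profile(
    grid: SweepGrid,
    specs: Sequence[ClimateChangeSpec],
    base_seed: int = 0,
) -> pd.DataFrame:
    """Two-stage climate-change experiment over a grid, one row per
    (replicate, perturbation target).

    Stage 1 is shared across targets within a replicate.  Final phenotypes
    are classified against both the pre-change flood height (the regime the
    population evolved under) and the post-change one.
    """
    rows = []
    for cell_index, (p, s, n) in enumerate(grid.cells()):
        for r in range(grid.replicates):
            seed = replicate_seed(base_seed, cell_index, r)
            config = grid.cell_config(p, s, n, seed)
            stage1, branches = run_staged_replicate(config, specs)
            for spec in specs:
                res = branches[spec]
                row = {
                    "p": p,
                    "s": s,
                    "n": n,
                    "replicate": r,
                    "seed": seed,
                    "target": spec.target,
                    "delta": spec.delta,
                    "stage1_survived": not stage1.extinct,
                    "stage1_mean_z": stage1.final_mean_z
                    if not stage1.extinct
                    else np.nan,
                }
                if res is None:
                    row.update(
                        stage2_survived=False,
                        final_mean_z=np.nan,
                        outcome_pre_h=None,
                        outcome_post_h=None,
                    )
                else:
                    survived = not res.extinct
                    changed = apply_climate_change(config, spec)
                    row.update(
                        stage2_survived=survived,
                        final_mean_z=res.final_mean_z if survived else np.nan,
                        outcome_pre_h=classify_outcome(
                            res.final_mean_z, config.regime.h
                        )
                        if survived
                        else None,
                        outcome_post_h=classify_outcome(
                            res.final_mean_z, changed.regime.h
                        )
                        if survived
                        else None,
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def run_climate_experiment(
    grid: SweepGrid, spec: ClimateChangeSpec, base_seed: int = 0
) -> pd.DataFrame:
    """Single-target convenience wrapper around
    :func:`run_vulnerability_profile`."""
    return run_vulnerability_profile(grid, [spec], base_seed=base_seed)


def summarize_climate(rows: pd.DataFrame) -> pd.DataFrame:
    """Per (cell, target) relative survival and survivor classifications.

    Relative survival is computed among stage-1 survivors only, matching the
    definition used for the vulnerability summaries: the proportion of
    populations alive at the change point that are still extant at the end
    of the follow-up.  Cells with no stage-1 survivors carry NaN.
    """
    if rows.empty:
        return pd.DataFrame(
            columns=[
                "p", "s", "n", "target", "delta", "n_replicates",
                "n_stage1_survivors", "relative_survival",
                "prop_low_pre_h", "prop_high_pre_h", "prop_intermediate_pre_h",
            ]
        )
    out = []
    for (p, s, n, target, delta), grp in rows.groupby(
        ["p", "s", "n", "target", "delta"], sort=True
    ):
        alive1 = grp[grp["stage1_survived"]]
        n1 = len(alive1)
        alive2 = alive1[alive1["stage2_survived"]]
        row = {
            "p": p,
            "s": s,
            "n": n,
            "target": target,
            "delta": delta,
            "n_replicates": len(grp),
            "n_stage1_survivors": n1,
            "relative_survival": len(alive2) / n1 if n1 else np.nan,
        }
        for label in ("low", "high", "intermediate"):
            row[f"prop_{label}_pre_h"] = (
                (alive2["outcome_pre_h"] == label).sum() / len(alive2)
                if len(alive2)
                else np.nan
            )
        out.append(row)
    return pd.DataFrame(out)
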