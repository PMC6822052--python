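"""Long-term mean fitness in environments punctuated by rare extreme events.

When an extreme event (a flood, a fire, a heatwave) recurs with probability
``p`` per generation, the long-run success of a fixed phenotype ``z`` depends
on *how* fitness accumulates across events:

* If the whole population experiences each event simultaneously (coarse
  environmental grain), lineage growth is multiplicative across generations
  and the appropriate average is the geometric mean

      W_G(z) = W_M(z)**(1 - p) * W_E(z)**p,

  where ``W_M`` and ``W_E`` are the fitness functions under moderate and
  extreme conditions.  A single zero-fitness generation drives ``W_G`` to
  zero, so conservative (bet-hedging) phenotypes are favoured.

* If reproductive events are independent in time or space (many breeding
  attempts, or extreme events that touch only some individuals), fitness
  accumulates additively and the arithmetic mean applies:

      W_A(z) = (1 - p) * W_M(z) + p * W_E(z).

* Intermediate cases are captured by the *scope* ``s`` of the event — the
  fraction of the population affected when it strikes:

      W_AG(z) = W_M(z)**(1 - p) * ((1 - s) * W_M(z) + s * W_E(z))**p,

  which reduces to the geometric form at ``s = 1`` and to ``W_M`` at
  ``s = 0``.

The module evaluates these functionals for arbitrary fitness-function pairs
and locates their optima numerically.  The bundled toy landscape uses a pair
of skew-Gaussian curves whose peaks favour opposite phenotypes under moderate
versus extreme conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SkewGaussianParams",
    "FitnessPair",
    "MeanFitnessSpec",
    "skew_gaussian_fitness",
    "geometric_mean_fitness",
    "arithmetic_mean_fitness",
    "mixed_mean_fitness",
    "optimal_phenotype",
    "default_toy_pair",
    "fitness_table",
    "optima_table",
]


@dataclass(frozen=True)
class SkewGaussianParams:
    """Parameters of a skew-normal fitness curve.

    ``location`` (xi) and ``scale`` (omega) are in phenotype units, ``skew``
    (alpha) is the dimensionless slant; ``skew = 0`` recovers a plain
    Gaussian.  The curve is the skew-normal density
    ``(2/omega) * phi((z - xi)/omega) * Phi(alpha * (z - xi)/omega)``.
    """

    location: float
    scale: float
    skew: float

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    def __call__(self, z):
        return skew_gaussian_fitness(z, self)

    @property
    def mode(self) -> float:
        """Phenotype at which the curve peaks (numerically located)."""
        span = (self.location - 6.0 * self.scale, self.location + 6.0 * self.scale)
        return optimal_phenotype(self, domain=span)


def skew_gaussian_fitness(z, params: SkewGaussianParams, *, normalize: bool = False):
    """Skew-normal fitness curve evaluated at phenotype(s) ``z``.

    With ``normalize=True`` the curve is rescaled so its peak equals 1,
    which changes nothing about optima but eases visual comparison of
    curves with different scales.
    """
    if not isinstance(params, SkewGaussianParams):
        params = SkewGaussianParams(*params)
    val = stats.skewnorm.pdf(z, params.skew, loc=params.location, scale=params.scale)
    if normalize:
        val = val / stats.skewnorm.pdf(
            params.mode, params.skew, loc=params.location, scale=params.scale
        )
    if np.isscalar(z):
        return float(val)
    return val


@dataclass(frozen=True)
class FitnessPair:
    """A pair of fitness functions for moderate and extreme conditions.

    Both callables must be defined and non-negative on ``domain`` (a closed
    phenotype interval) and accept numpy arrays.
    """

    w_moderate: Callable
    w_extreme: Callable
    domain: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not hi >= lo:
            raise ValueError(f"empty phenotype domain {self.domain}")


def default_toy_pair(domain: tuple[float, float] = (0.0, 1.0)) -> FitnessPair:
    """Skew-Gaussian toy landscape: moderate conditions favour low phenotypes,
    extremes favour high ones.

    Moderate curve: location 0.1, extreme curve: location 0.6; both with
    scale 0.3 and slant 5.
    """
    return FitnessPair(
        w_moderate=SkewGaussianParams(0.1, 0.3, 5.0),
        w_extreme=SkewGaussianParams(0.6, 0.3, 5.0),
        domain=domain,
    )


@dataclass(frozen=True)
class MeanFitnessSpec:
    """A fitness pair together with event frequency ``p`` and scope ``s``."""

    pair: FitnessPair
    p: float
    s: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must lie in [0, 1], got {self.p}")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"s must lie in [0, 1], got {self.s}")

    def geometric(self, z):
        return geometric_mean_fitness(z, self)

    def arithmetic(self, z):
        return arithmetic_mean_fitness(z, self)

    def mixed(self, z):
        return mixed_mean_fitness(z, self)


def _evaluate_pair(z, spec: MeanFitnessSpec):
    zv = np.asarray(z, dtype=float)
    wm = np.asarray(spec.pair.w_moderate(zv), dtype=float)
    we = np.asarray(spec.pair.w_extreme(zv), dtype=float)
    if np.any(wm < 0) or np.any(we < 0):
        raise ValueError("fitness functions must be non-negative")
    return wm, we


def _as_input_shape(out, z):
    return float(out) if np.isscalar(z) else out


def geometric_mean_fitness(z, spec: MeanFitnessSpec):
    """Multiplicative long-term fitness ``W_M(z)**(1-p) * W_E(z)**p``.

    ``0**0`` is taken as 1, so the ``p = 0`` and ``p = 1`` limits are exact;
    a zero of the relevant curve annihilates the mean whenever its exponent
    is positive.
    """
    wm, we = _evaluate_pair(z, spec)
    # numpy defines 0.0 ** 0.0 == 1.0, which is exactly the convention needed
    out = wm ** (1.0 - spec.p) * we ** spec.p
    return _as_input_shape(out, z)


def arithmetic_mean_fitness(z, spec: MeanFitnessSpec):
    """Additive long-term fitness ``(1-p) * W_M(z) + p * W_E(z)``."""
    wm, we = _evaluate_pair(z, spec)
    out = (1.0 - spec.p) * wm + spec.p * we
    return _as_input_shape(out, z)


def mixed_mean_fitness(z, spec: MeanFitnessSpec):
    """Long-term fitness with both additive and multiplicative components.

    ``W_M(z)**(1-p) * ((1-s) * W_M(z) + s * W_E(z))**p`` — the scope ``s``
    interpolates between the arithmetic-within-event regime (``s < 1``, part
    of the population escapes each event) and the fully multiplicative
    regime (``s = 1``, everyone is hit).
    """
    wm, we = _evaluate_pair(z, spec)
    inner = (1.0 - spec.s) * wm + spec.s * we
    out = wm ** (1.0 - spec.p) * inner ** spec.p
    return _as_input_shape(out, z)


def optimal_phenotype(
    meanfn: Callable,
    domain: tuple[float, float] = (0.0, 1.0),
    grid_step: float = 1e-4,
) -> float:
    """Argmax of ``meanfn`` over ``domain``.

    The mean-fitness surfaces here are typically bimodal, so a dense uniform
    grid search locates the global peak first and a bounded scalar
    maximisation then polishes it within the bracketing grid cell.  Exact
    ties resolve to the smallest phenotype.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    lo, hi = float(domain[0]), float(domain[1])
    if hi < lo:
        raise ValueError(f"empty phenotype domain {domain!r}")
    if hi == lo:
        return lo
    npts = max(int(round((hi - lo) / grid_step)) + 1, 2)
    zs = np.linspace(lo, hi, npts)
    try:
        vals = np.asarray(meanfn(zs), dtype=float)
        if vals.shape != zs.shape:
            raise TypeError
    except (TypeError, ValueError):
        vals = np.array([float(meanfn(z)) for z in zs])
    if not np.all(np.isfinite(vals)):
        raise ValueError("mean fitness must be finite on the domain")
    best = int(np.argmax(vals))
    left = zs[max(best - 1, 0)]
    right = zs[min(best + 1, npts - 1)]
    res = optimize.minimize_scalar(
        lambda zz: -float(meanfn(zz)),
        bounds=(left, right),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if np.isfinite(res.fun) and -res.fun > vals[best]:
        return float(res.x)
    return float(zs[best])


def fitness_table(spec: MeanFitnessSpec, grid_step: float = 1e-3) -> pd.DataFrame:
    """Tabulate the fitness pair and all three mean-fitness functionals.

    Columns: ``z, w_moderate, w_extreme, geometric, arithmetic, mixed``.
    """
    lo, hi = spec.pair.domain
    npts = max(int(round((hi - lo) / grid_step)) + 1, 2)
    zs = np.linspace(lo, hi, npts)
    wm, we = _evaluate_pair(zs, spec)
    return pd.DataFrame(
        {
            "z": zs,
            "w_moderate": wm,
            "w_extreme": we,
            "geometric": geometric_mean_fitness(zs, spec),
            "arithmetic": arithmetic_mean_fitness(zs, spec),
            "mixed": mixed_mean_fitness(zs, spec),
        }
    )


def optima_table(
    pair: FitnessPair,
    p_values: Sequence[float],
    s_values: Sequence[float] = (1.0,),
    grid_step: float = 1e-4,
) -> pd.DataFrame:
    """Optimal phenotypes of the three mean-fitness functionals over a
    (p, s) grid.

    ``argmax_geometric`` and ``argmax_arithmetic`` depend on ``p`` only;
    they are repeated across ``s`` rows for convenience.
    """
    rows = []
    for p in p_values:
        for s in s_values:
            spec = MeanFitnessSpec(pair=pair, p=p, s=s)
            rows.append(
                {
                    "p": p,
                    "s": s,
                    "argmax_geometric": optimal_phenotype(
                        spec.geometric, pair.domain, grid_step
                    ),
                    "argmax_arithmetic": optimal_phenotype(
                        spec.arithmetic, pair.domain, grid_step
                    ),
                    "argmax_mixed": optimal_phenotype(
                        spec.mixed, pair.domain, grid_step
                    ),
                }
            )
    return pd.DataFrame(rows)
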