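"""Fitting the cluster-growth model to measured intensity curves.

The measured observable is the relative fluorescence intensity of a
forming cluster, Rel Intensity(t) = (I(t) − Δ)/(I(0) − Δ), where the
background offset Δ is chosen so the intensity fold change matches the
fold increase in single-particle track counts.  The model observable is
the relative dynamin density from the ODE network.  Parameters are
estimated by minimizing the χ² distance weighted by the per-timepoint
experimental SEM, searched with a seeded real-coded genetic algorithm
(tournament selection, two-point crossover, Gaussian mutation, elitism).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (Geometry, ModelState, RateParams, equilibrium_kb,
                    observables, simulate_ode)

__all__ = [
    "FitConfig",
    "FitResult",
    "chi2_objective",
    "rel_intensity",
    "choose_offset",
    "fit_ga",
    "fit_rates_ga",
]


def chi2_objective(model_curve: np.ndarray, data_curve: np.ndarray,
                   sem: np.ndarray) -> float:
    """χ² = Σ (model − data)² / sem², on a common time grid."""
    model_curve = np.asarray(model_curve, float)
    data_curve = np.asarray(data_curve, float)
    sem = np.asarray(sem, float)
    if not (len(model_curve) == len(data_curve) == len(sem)):
        raise ValueError("curves and sem must share one time grid")
    if (sem == 0).any():
        raise ValueError("sem contains zeros; floor the errors first")
    return float(np.sum(((model_curve - data_curve) / sem) ** 2))


def rel_intensity(intensity: np.ndarray, delta: float) -> np.ndarray:
    """(I(t) − Δ) / (I(0) − Δ); requires I(0) > Δ."""
    intensity = np.asarray(intensity, float)
    if intensity[0] <= delta:
        raise ValueError("offset must be below the initial intensity")
    return (intensity - delta) / (intensity[0] - delta)


def choose_offset(intensity: np.ndarray, fold_target: float) -> float:
    """Background offset Δ making the peak relative intensity equal the
    fold increase in single-particle tracks.

    (I_max − Δ)/(I_0 − Δ) is continuous and strictly increasing in Δ on
    (−inf, I_0), so the matching condition has the unique root
    Δ = (fold_target·I_0 − I_max)/(fold_target − 1), which is returned in
    closed form.  Targets at or below the raw fold I_max/I_0 are
    unreachable with a non-negative background.
    """
    intensity = np.asarray(intensity, float)
    i0 = float(intensity[0])
    imax = float(intensity.max())
    if imax <= i0:
        raise ValueError("intensity never rises above its initial value")
    raw_fold = imax / i0
    if fold_target <= raw_fold:
        raise ValueError(
            f"fold target {fold_target} not above the raw fold {raw_fold:.3f}")
    return (fold_target * i0 - imax) / (fold_target - 1.0)


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Search ranges and GA settings.

    ``ranges`` maps parameter name → (low, high); ``log_scale`` names the
    parameters searched in log10 space (natural for rate constants).
    """

    ranges: dict[str, tuple[float, float]]
    log_scale: tuple[str, ...] = ()
    population: int = 50
    generations: int = 100
    cx_prob: float = 0.6          # two-point crossover probability
    mut_prob: float = 0.2         # per-individual Gaussian mutation prob
    mut_sigma: float = 0.1        # mutation SD as a fraction of the range
    tournament: int = 3
    elitism: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required for a reproducible fit")
        for name, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"degenerate range for {name!r}")


@dataclass
class FitResult:
    best_params: dict[str, float]
    best_chi2: float
    history: np.ndarray           # best χ² per generation
    n_evaluations: int = 0


def _decode(z: np.ndarray, names: list[str], cfg: FitConfig) -> dict[str, float]:
    out = {}
    for i, name in enumerate(names):
        lo, hi = cfg.ranges[name]
        if name in cfg.log_scale:
            out[name] = 10 ** (math.log10(lo)
                               + z[i] * (math.log10(hi) - math.log10(lo)))
        else:
            out[name] = lo + z[i] * (hi - lo)
    return out


def fit_ga(objective, config: FitConfig) -> FitResult:
    """Minimize ``objective(params_dict)`` over the configured ranges.

    Individuals are unit-box vectors decoded to the parameter ranges
    (log10 for rate-like parameters).  Each generation applies tournament
    selection, two-point crossover, per-gene Gaussian mutation, and
    carries the elite through unchanged.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    names = list(config.ranges)
    dim = len(names)
    pop = rng.random((config.population, dim))
    fit = np.array([objective(_decode(z, names, config)) for z in pop])
    n_eval = len(pop)
    history = np.empty(config.generations)
    for gen in range(config.generations):
        order = np.argsort(fit)
        elite = pop[order[:config.elitism]].copy()
        # tournament selection
        idx = rng.integers(0, config.population,
                           size=(config.population, config.tournament))
        winners = idx[np.arange(config.population),
                      np.argmin(fit[idx], axis=1)]
        new = pop[winners].copy()
        # two-point crossover on consecutive pairs
        for i in range(0, config.population - 1, 2):
            if rng.random() < config.cx_prob and dim > 1:
                a, b = sorted(rng.integers(0, dim + 1, size=2))
                if a != b:
                    tmp = new[i, a:b].copy()
                    new[i, a:b] = new[i + 1, a:b]
                    new[i + 1, a:b] = tmp
        # Gaussian mutation, clipped to the unit box
        mutate = rng.random(config.population) < config.mut_prob
        noise = rng.normal(0.0, config.mut_sigma, size=new.shape)
        new[mutate] = np.clip(new[mutate] + noise[mutate], 0.0, 1.0)
        new[:config.elitism] = elite
        pop = new
        fit = np.array([objective(_decode(z, names, config)) for z in pop])
        n_eval += len(pop)
        history[gen] = fit.min()
    best = int(np.argmin(fit))
    return FitResult(best_params=_decode(pop[best], names, config),
                     best_chi2=float(fit[best]), history=history,
                     n_evaluations=n_eval)


def fit_rates_ga(
    data_times: np.ndarray,
    data_curve: np.ndarray,
    sem: np.ndarray,
    base_state: ModelState,
    geom: Geometry,
    config: FitConfig,
    k_frev: float = 0.09,
    fixed: dict[str, float] | None = None,
) -> FitResult:
    """Fit rate/concentration parameters of the ODE model to a relative
    density growth curve.

    Free parameters may include ``k_mem``, ``k_dyn``, ``d_sol``,
    ``d_mem``; everything else comes from ``base_state``/``fixed``.  k_b
    is recomputed from the equilibrium condition for every candidate so
    each trial starts from a stationary pre-cluster pool.
    """
    fixed = dict(fixed or {})
    data_times = np.asarray(data_times, float)

    def objective(params: dict[str, float]) -> float:
        p = {**fixed, **params}
        state = ModelState(
            d_sol=p.get("d_sol", base_state.d_sol),
            r_mem=p.get("r_mem", base_state.r_mem),
            d_mem=p.get("d_mem", base_state.d_mem),
            a_clus=p.get("a_clus", base_state.a_clus),
        )
        k_b = equilibrium_kb(state.d_sol, state.r_mem, state.d_mem, k_frev)
        rates = RateParams(k_frev=k_frev, k_b=k_b,
                           k_mem=p.get("k_mem", 0.01),
                           k_dyn=p.get("k_dyn", 0.01))
        try:
            series = simulate_ode(state, rates, geom,
                                  t_end=float(data_times[-1]),
                                  t_eval=data_times)
        except RuntimeError:
            return 1e12
        model_curve = observables(series).rel_density
        return chi2_objective(model_curve, data_curve, sem)

    return fit_ga(objective, config)
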