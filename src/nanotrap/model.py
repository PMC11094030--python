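"""Reaction-diffusion model of dynamin recruitment to membrane nanoclusters.

A minimal three-component scheme: dynamin in solution (D_sol), a uniform
membrane recruiter (R_mem), and a cluster-restricted activator (A_clus).
Six tracked species and seven reactions::

    1.  D_sol + R_mem   <->  D_mem                 k_frev, k_b
    2.  D_mem + A_clus   ->  D_2dclus              k_mem/h   (2D)
    3.  D_sol + A_clus   ->  D_clus                k_mem
    4.  D_mem + D_2dclus ->  2 D_2dclus            k_dyn/h   (2D)
    5.  D_sol + D_clus   ->  2 D_clus              k_dyn
    6.  D_mem + D_clus   ->  D_2dclus + D_clus     k_dyn/h   (2D)
    7.  D_sol + D_2dclus ->  D_2dclus + D_clus     k_dyn

D_clus and D_2dclus are identical except for their arrival route (3D
solution vs lateral 2D diffusion), kept separate to quantify dimensional
reduction.  The system is reduced to a single cluster in a periodic
membrane patch whose side is set by the measured cluster density; the
cytosol is a column of height V/A above the patch.  The well-mixed ODE
works in volume concentration (µM) with 2D reactions multiplied by the
dimensionality factor DF = V/(A·h); the stochastic variant is an exact
Gillespie simulation in copy numbers; the spatial variant diffuses the
membrane species on a 2D grid coupled to a well-mixed solution bath.

Before a cluster appears the solution/recruiter/membrane pool is held at
equilibrium by choosing the off-rate k_b = k_frev·[D_sol]·[R_mem]/[D_mem],
so all cluster growth is driven by the appearance of activator density.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "NA_UM",
    "Geometry",
    "RateParams",
    "ModelState",
    "StateTimeSeries",
    "Observables",
    "build_geometry",
    "equilibrium_kb",
    "convert_units",
    "simulate_ode",
    "apply_stimulation",
    "simulate_ssa",
    "ssa_dyn_copies",
    "simulate_membrane_pde",
    "membrane_grid",
    "PDEResult",
    "observables",
    "DYN1BB",
    "dyn1bb_states",
]

#: copies per µm³ corresponding to 1 µM (Avogadro's number × 1e-21 L/µm³).
NA_UM = 602.214

SPECIES = ["d_sol", "r_mem", "d_mem", "a_clus", "d_clus", "d_2dclus"]


# ---------------------------------------------------------------------------
# Geometry and parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Geometry:
    """Single-cluster membrane domain derived from the cluster density.

    Clusters at density ρ are assumed evenly distributed, so each owns a
    periodic square patch of side L = 1/√ρ and area A = L², with the
    cluster a central disk of radius ``r_clus``.  The solution volume is
    the column V = A·(V/A); ``h`` is the nanoscopic length converting 3D
    rate constants to 2D, giving the dimensionality factor DF = V/(A·h).
    """

    cluster_density: float          # µm⁻²
    r_clus: float                   # µm
    v_over_a: float = 1.9           # µm
    h: float = 0.01                 # µm

    def __post_init__(self) -> None:
        for name in ("cluster_density", "r_clus", "v_over_a", "h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.a_clus >= self.area:
            raise ValueError("cluster disk exceeds the membrane patch")

    @property
    def side(self) -> float:
        return 1.0 / math.sqrt(self.cluster_density)

    @property
    def area(self) -> float:
        return self.side ** 2

    @property
    def a_clus(self) -> float:
        return math.pi * self.r_clus ** 2

    @property
    def volume(self) -> float:
        return self.area * self.v_over_a

    @property
    def df(self) -> float:
        return self.v_over_a / self.h   # identically V/(A·h)


def build_geometry(density: float, v_over_a: float = 1.9,
                   r_clus: float = 0.083, h: float = 0.01) -> Geometry:
    """Construct the per-cluster domain from a measured cluster density."""
    return Geometry(cluster_density=density, r_clus=r_clus,
                    v_over_a=v_over_a, h=h)


@dataclass(frozen=True)
class RateParams:
    """Rate constants; ``k_mem`` is the current (pre- or post-stimulation)
    activator-binding rate.  2D counterparts are k/h."""

    k_frev: float      # µM⁻¹ s⁻¹
    k_b: float         # s⁻¹
    k_mem: float       # µM⁻¹ s⁻¹
    k_dyn: float       # µM⁻¹ s⁻¹

    def __post_init__(self) -> None:
        for name in ("k_frev", "k_b", "k_mem", "k_dyn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def k_mem_2d(self, h: float) -> float:
        return self.k_mem / h

    def k_dyn_2d(self, h: float) -> float:
        return self.k_dyn / h


@dataclass(frozen=True)
class ModelState:
    """Initial species values in the measurement units of the experiment:
    µM in solution, copies/µm² on the membrane (cluster species defined
    over the cluster area A_clus, membrane species over A)."""

    d_sol: float = 10.0       # µM
    r_mem: float = 4.85       # copies/µm² over A
    d_mem: float = 30.0       # copies/µm² over A
    a_clus: float = 207.0     # copies/µm² over A_clus
    d_clus: float = 0.0       # copies/µm² over A_clus
    d_2dclus: float = 0.0     # copies/µm² over A_clus

    def __post_init__(self) -> None:
        for name in SPECIES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_conc(self, geom: Geometry) -> np.ndarray:
        """All species as volume concentrations (µM): surface densities →
        copies (× A or A_clus) → / (V · NA_UM)."""
        f_mem = geom.area / (geom.volume * NA_UM)
        f_clus = geom.a_clus / (geom.volume * NA_UM)
        return np.array([
            self.d_sol,
            self.r_mem * f_mem,
            self.d_mem * f_mem,
            self.a_clus * f_clus,
            self.d_clus * f_clus,
            self.d_2dclus * f_clus,
        ])

    @classmethod
    def from_conc(cls, y: np.ndarray, geom: Geometry) -> "ModelState":
        f_mem = geom.area / (geom.volume * NA_UM)
        f_clus = geom.a_clus / (geom.volume * NA_UM)
        y = np.maximum(np.asarray(y, float), 0.0)
        return cls(d_sol=y[0], r_mem=y[1] / f_mem, d_mem=y[2] / f_mem,
                   a_clus=y[3] / f_clus, d_clus=y[4] / f_clus,
                   d_2dclus=y[5] / f_clus)


def equilibrium_kb(d_sol: float, r_mem: float, d_mem: float,
                   k_frev: float) -> float:
    """Off-rate holding the pre-cluster pool stationary:
    k_b = k_frev · [D]_sol · [R]_mem / [D]_mem (the surface-density ratio
    R/D is dimensionless, so k_b carries units of k_frev × µM = s⁻¹)."""
    if d_mem <= 0:
        raise ValueError("d_mem must be positive")
    return k_frev * d_sol * r_mem / d_mem


def convert_units(value: float, from_unit: str, to_unit: str,
                  geometry: Geometry | None = None) -> float:
    """Exact linear conversions between the model's unit systems.

    Units: ``uM``, ``copies/um3``, ``copies``, ``copies/um2@A``,
    ``copies/um2@Aclus``.  Conversions through copies require a Geometry.
    """
    def to_copies(v: float, unit: str) -> float:
        if unit == "copies":
            return v
        if unit == "copies/um3":
            return v * _geom(geometry).volume
        if unit == "uM":
            return v * NA_UM * _geom(geometry).volume
        if unit == "copies/um2@A":
            return v * _geom(geometry).area
        if unit == "copies/um2@Aclus":
            return v * _geom(geometry).a_clus
        raise ValueError(f"unknown unit {unit!r}")

    def from_copies(v: float, unit: str) -> float:
        return v / to_copies(1.0, unit)

    if from_unit == to_unit:
        return value
    # volume-free fast path
    if {from_unit, to_unit} == {"uM", "copies/um3"}:
        return value * NA_UM if from_unit == "uM" else value / NA_UM
    return from_copies(to_copies(value, from_unit), to_unit)


def _geom(g: Geometry | None) -> Geometry:
    if g is None:
        raise ValueError("this unit conversion requires a Geometry")
    return g


# ---------------------------------------------------------------------------
# Deterministic (well-mixed) model
# ---------------------------------------------------------------------------

@dataclass
class StateTimeSeries:
    """Solution of a model run: concentrations (µM) per time point."""

    times: np.ndarray
    conc: pd.DataFrame            # columns = SPECIES, µM
    geometry: Geometry
    info: dict = field(default_factory=dict)

    def density(self, species: str) -> np.ndarray:
        """Species time course as copies/µm² over its defining area."""
        g = self.geometry
        c = self.conc[species].to_numpy()
        if species in ("r_mem", "d_mem"):
            return c * g.volume * NA_UM / g.area
        if species in ("a_clus", "d_clus", "d_2dclus"):
            return c * g.volume * NA_UM / g.a_clus
        return c   # d_sol stays µM

    def total_dynamin_copies(self) -> np.ndarray:
        g = self.geometry
        return ((self.conc["d_sol"] + self.conc["d_mem"]
                 + self.conc["d_clus"] + self.conc["d_2dclus"]).to_numpy()
                * g.volume * NA_UM)


def _rhs(t: float, y: np.ndarray, r: RateParams, df: float) -> np.ndarray:
    d_sol, r_mem, d_mem, a_clus, d_clus, d_2d = y
    f1 = r.k_frev * d_sol * r_mem          # reaction 1 forward
    b1 = r.k_b * d_mem                     # reaction 1 back
    f2 = df * r.k_mem * d_mem * a_clus     # 2D
    f3 = r.k_mem * d_sol * a_clus
    f4 = df * r.k_dyn * d_mem * d_2d       # 2D
    f5 = r.k_dyn * d_sol * d_clus
    f6 = df * r.k_dyn * d_mem * d_clus     # 2D
    f7 = r.k_dyn * d_sol * d_2d
    return np.array([
        -f1 + b1 - f3 - f5 - f7,           # d_sol
        -f1 + b1,                          # r_mem
        f1 - b1 - f2 - f4 - f6,            # d_mem
        -f2 - f3,                          # a_clus
        f3 + f5 + f7,                      # d_clus
        f2 + f4 + f6,                      # d_2dclus
    ])


def simulate_ode(
    state0: ModelState,
    rates: RateParams,
    geom: Geometry,
    t_end: float,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> StateTimeSeries:
    """Integrate the 7-reaction network (stiff-capable LSODA).

    All species are propagated in volume concentration (µM); 2D reactions
    (2, 4, 6) are multiplied by DF = V/(A·h).  Negative excursions beyond
    tolerance abort with a diagnostic.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    y0 = state0.to_conc(geom)
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 201)
    sol = solve_ivp(_rhs, (0.0, t_end), y0, method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol,
                    args=(rates, geom.df))
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    y = sol.y
    if y.min() < -100 * atol:
        raise RuntimeError(
            f"negative concentration {y.min():.3e} µM beyond tolerance")
    conc = pd.DataFrame(np.clip(y.T, 0.0, None), columns=SPECIES)
    return StateTimeSeries(times=sol.t, conc=conc, geometry=geom,
                           info={"nfev": sol.nfev, "rtol": rtol, "atol": atol})


def apply_stimulation(
    state: ModelState,
    geom: Geometry,
    rates: RateParams,
    membrane_density_scale: float,
    post_density: float,
    k_mem_post: float,
    post_r_clus: float | None = None,
) -> tuple[ModelState, Geometry, RateParams]:
    """The three post-stimulation changes, applied together.

    (1) the cluster density rises, shrinking the per-cluster patch;
    (2) the initial membrane dynamin density is scaled up by the measured
    factor with the solution pool reduced so total dynamin copies per
    unit membrane area are conserved; (3) the activator-binding rate
    switches from its pre- to its post-stimulation value.  k_dyn, k_frev,
    R_mem and A_clus densities are unchanged.
    """
    if membrane_density_scale < 1:
        raise ValueError("membrane_density_scale must be >= 1")
    new_geom = build_geometry(post_density, v_over_a=geom.v_over_a,
                              r_clus=post_r_clus or geom.r_clus, h=geom.h)
    added = (membrane_density_scale - 1.0) * state.d_mem   # copies/µm² of A
    d_sol_new = state.d_sol - added / (geom.v_over_a * NA_UM)
    if d_sol_new < 0:
        raise ValueError("copy conservation would drive [D]_sol negative")
    new_state = replace(state,
                        d_mem=membrane_density_scale * state.d_mem,
                        d_sol=d_sol_new)
    new_rates = replace(rates, k_mem=k_mem_post)
    return new_state, new_geom, new_rates


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------

@dataclass
class Observables:
    """Cluster-growth observables derived from a model run."""

    times: np.ndarray
    rel_density: np.ndarray    # ([D]_mem+[D]_clus+[D]_2dclus)(t)/[D]_mem(0)
    dyn_copies: np.ndarray     # cluster-localized copies = density × A_clus
    fraction_2d: np.ndarray    # lateral share of cluster dynamin

    @property
    def peak_copies(self) -> float:
        return float(np.max(self.dyn_copies))


def observables(series: StateTimeSeries) -> Observables:
    """Relative density, cluster copy number and 2D-arrival fraction.

    Densities are per-area: [D]_mem over the patch area, cluster species
    over the cluster area; their sum over [D]_mem(0) is the relative
    density, and times A_clus it is the copy number within one cluster.
    """
    rho_mem = series.density("d_mem")
    rho_c = series.density("d_clus")
    rho_2d = series.density("d_2dclus")
    if rho_mem[0] <= 0:
        raise ValueError("[D]_mem(0) must be positive")
    total = rho_mem + rho_c + rho_2d
    clustered = rho_c + rho_2d
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(clustered > 0, rho_2d / np.maximum(clustered, 1e-300), 0.0)
    return Observables(
        times=series.times,
        rel_density=total / rho_mem[0],
        dyn_copies=total * series.geometry.a_clus,
        fraction_2d=frac,
    )


# ---------------------------------------------------------------------------
# Stochastic (Gillespie) variant
# ---------------------------------------------------------------------------

def simulate_ssa(
    state0: ModelState,
    rates: RateParams,
    geom: Geometry,
    t_end: float,
    seed: int,
    oligomer_valence: int = 4,
    titration: tuple[float, float] | None = None,
    record_dt: float = 0.05,
) -> pd.DataFrame:
    """Exact stochastic simulation of the network in copy numbers.

    Initial densities are converted to (rounded) copies via the geometry.
    Dynamin–dynamin reactions are dispatched over ``oligomer_valence``
    independent binding sites, each reacting at k_dyn/valence — a
    well-mixed bookkeeping of the 4-site oligomerization; the summed
    propensity equals the mass-action rate.  ``titration`` = (rate µM/s,
    degradation s⁻¹) optionally pins the solution pool near its initial
    concentration, mimicking an open cytosol; without it total dynamin is
    conserved exactly.  Returns copy numbers sampled on a regular grid.
    """
    if seed is None:
        raise ValueError("seed is required")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    rng = np.random.default_rng(seed)
    V = geom.volume
    # copies
    n = np.array([
        round(state0.d_sol * NA_UM * V),
        round(state0.r_mem * geom.area),
        round(state0.d_mem * geom.area),
        round(state0.a_clus * geom.a_clus),
        round(state0.d_clus * geom.a_clus),
        round(state0.d_2dclus * geom.a_clus),
    ], dtype=np.int64)
    c3 = 1.0 / (NA_UM * V)           # per-pair factor for 3D bimolecular
    c2 = geom.df * c3                # 2D reactions carry DF
    k_site = rates.k_dyn / oligomer_valence
    titrate = titration is not None
    if titrate:
        k_tit = titration[0] * NA_UM * V     # copies/s, 0th order
        k_deg = titration[1]                 # s⁻¹

    grid = np.arange(0.0, t_end + record_dt / 2, record_dt)
    out = np.empty((len(grid), 6), dtype=np.int64)
    gi = 0
    t = 0.0
    props = np.empty(10 if titrate else 8)
    while True:
        d_sol, r_mem, d_mem, a_clus, d_clus, d_2d = n
        props[0] = rates.k_frev * c3 * d_sol * r_mem        # 1 forward
        props[1] = rates.k_b * d_mem                        # 1 back
        props[2] = rates.k_mem * c2 * d_mem * a_clus        # 2
        props[3] = rates.k_mem * c3 * d_sol * a_clus        # 3
        props[4] = k_site * oligomer_valence * c2 * d_mem * d_2d   # 4
        props[5] = k_site * oligomer_valence * c3 * d_sol * d_clus # 5
        props[6] = k_site * oligomer_valence * c2 * d_mem * d_clus # 6
        props[7] = k_site * oligomer_valence * c3 * d_sol * d_2d   # 7
        if titrate:
            props[8] = k_tit
            props[9] = k_deg * d_sol
        total = props.sum()
        if not np.isfinite(total):
            raise OverflowError("propensity overflow")
        if total <= 0:
            tau = math.inf
        else:
            tau = rng.exponential(1.0 / total)
        t_next = t + tau
        while gi < len(grid) and grid[gi] <= t_next:
            out[gi] = n
            gi += 1
        if gi >= len(grid) or t_next > t_end:
            break
        t = t_next
        u = rng.random() * total
        j = int(np.searchsorted(np.cumsum(props), u))
        if j == 0:
            n[0] -= 1; n[1] -= 1; n[2] += 1
        elif j == 1:
            n[0] += 1; n[1] += 1; n[2] -= 1
        elif j == 2:
            n[2] -= 1; n[3] -= 1; n[5] += 1
        elif j == 3:
            n[0] -= 1; n[3] -= 1; n[4] += 1
        elif j == 4:
            n[2] -= 1; n[5] += 1
        elif j == 5:
            n[0] -= 1; n[4] += 1
        elif j == 6:
            n[2] -= 1; n[5] += 1
        elif j == 7:
            n[0] -= 1; n[4] += 1
        elif j == 8:
            n[0] += 1
        else:
            n[0] -= 1
    df = pd.DataFrame(out, columns=SPECIES)
    df.insert(0, "time", grid)
    return df


def ssa_dyn_copies(run: pd.DataFrame, geom: Geometry) -> np.ndarray:
    """Cluster-localized dynamin copies from an SSA run: copies of the
    cluster species plus the share of membrane dynamin over the cluster
    footprint."""
    rho_mem = run["d_mem"].to_numpy() / geom.area
    return (run["d_clus"] + run["d_2dclus"]).to_numpy() + rho_mem * geom.a_clus


# ---------------------------------------------------------------------------
# Reduced spatial variant: 2D membrane + well-mixed bath
# ---------------------------------------------------------------------------

@dataclass
class PDEResult:
    times: np.ndarray
    totals: pd.DataFrame          # domain totals in µM, columns = SPECIES
    geometry: Geometry
    radial_r: np.ndarray          # µm, bin centers
    radial_d_mem: np.ndarray      # copies/µm², final-time profile
    fields: dict                  # final-time 2D fields, copies/µm²

    def as_series(self) -> StateTimeSeries:
        return StateTimeSeries(times=self.times, conc=self.totals,
                               geometry=self.geometry)


def membrane_grid(geom: Geometry, grid: float = 0.015
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Cell-center coordinates (X, Y) of the periodic membrane patch,
    matching the discretization of :func:`simulate_membrane_pde`."""
    L = geom.side
    nx = max(8, int(round(L / grid)))
    dx = L / nx
    xs = (np.arange(nx) + 0.5) * dx - L / 2
    return np.meshgrid(xs, xs)


def simulate_membrane_pde(
    state0: ModelState,
    rates: RateParams,
    geom: Geometry,
    d_mem: float = 0.045,
    t_end: float = 4.0,
    grid: float = 0.015,
    dt_max: float = 0.1,
    n_record: int = 81,
    r_outside_cluster: bool = False,
    initial_fields: dict[str, np.ndarray] | None = None,
) -> PDEResult:
    """Reaction-diffusion on the periodic membrane patch.

    Membrane species (D_mem, R_mem) diffuse at ``d_mem`` on the L×L
    periodic domain; cluster species live only on the central disk and do
    not diffuse; the solution is a single well-mixed bath of volume V
    coupled to every surface cell (solution diffusion is ~100× faster
    than membrane transport over this patch, so the 3D column is
    effectively equilibrated).  Operator splitting: Heun (2nd-order)
    reactions + exact spectral diffusion per step, dt ≤ ``dt_max``.
    ``r_outside_cluster`` initializes the recruiter outside the disk only.
    """
    L = geom.side
    nx = max(8, int(round(L / grid)))
    if geom.r_clus / (L / nx) < 2.5:
        raise ValueError("grid too coarse to resolve the cluster disk "
                         f"({nx} cells across {L:.3f} µm)")
    dx = L / nx
    cell_area = dx * dx
    xs = (np.arange(nx) + 0.5) * dx - L / 2
    X, Y = np.meshgrid(xs, xs)
    mask = (X ** 2 + Y ** 2) <= geom.r_clus ** 2
    mask_area = mask.sum() * cell_area
    if mask_area == 0:
        raise ValueError("cluster disk not resolved by the grid")

    # fields in copies/µm²; activator scaled so total copies are exact
    rho = {
        "d_mem": np.full((nx, nx), state0.d_mem),
        "r_mem": np.full((nx, nx), state0.r_mem),
        "a_clus": np.where(mask, state0.a_clus * geom.a_clus / mask_area, 0.0),
        "d_clus": np.where(mask, state0.d_clus * geom.a_clus / mask_area, 0.0),
        "d_2dclus": np.where(mask, state0.d_2dclus * geom.a_clus / mask_area, 0.0),
    }
    if r_outside_cluster:
        outside_area = geom.area - mask_area
        rho["r_mem"] = np.where(
            mask, 0.0, state0.r_mem * geom.area / outside_area)
    if initial_fields:
        for key, val in initial_fields.items():
            val = np.asarray(val, float)
            if val.shape != (nx, nx):
                raise ValueError(f"initial field {key!r} must be {nx}×{nx}")
            rho[key] = val.copy()
    d_sol = state0.d_sol   # µM, well-mixed bath

    kx = 2 * math.pi * np.fft.fftfreq(nx, d=dx)
    k2 = kx[None, :] ** 2 + kx[:, None] ** 2
    # stability of the split: resolve the fastest local linear rate
    k2d_mem = rates.k_mem / (NA_UM * geom.h)   # µm²/s per pair
    k2d_dyn = rates.k_dyn / (NA_UM * geom.h)
    rate_scale = max(
        rates.k_b,
        rates.k_frev * state0.d_sol,
        k2d_mem * rho["a_clus"].max(),
        k2d_dyn * max(state0.d_mem, state0.a_clus),
        1e-6,
    )
    dt = min(dt_max, 0.02 / rate_scale, t_end / 40)
    n_steps = int(math.ceil(t_end / dt))
    dt = t_end / n_steps
    decay = np.exp(-d_mem * k2 * dt)

    def reaction_rhs(rho, d_sol):
        f1 = rates.k_frev * d_sol * rho["r_mem"]
        b1 = rates.k_b * rho["d_mem"]
        f2 = k2d_mem * rho["d_mem"] * rho["a_clus"]
        f3 = rates.k_mem * d_sol * rho["a_clus"]
        f4 = k2d_dyn * rho["d_mem"] * rho["d_2dclus"]
        f5 = rates.k_dyn * d_sol * rho["d_clus"]
        f6 = k2d_dyn * rho["d_mem"] * rho["d_clus"]
        f7 = rates.k_dyn * d_sol * rho["d_2dclus"]
        drho = {
            "d_mem": f1 - b1 - f2 - f4 - f6,
            "r_mem": -f1 + b1,
            "a_clus": -f2 - f3,
            "d_clus": f3 + f5 + f7,
            "d_2dclus": f2 + f4 + f6,
        }
        sol_flux = ((f1 - b1 + f3 + f5 + f7).sum() * cell_area)  # copies/s
        dd_sol = -sol_flux / (geom.volume * NA_UM)
        return drho, dd_sol

    rec_times = np.linspace(0.0, t_end, n_record)
    totals = np.empty((n_record, 6))
    ri = 0

    def record(i, rho, d_sol):
        totals[i] = [
            d_sol,
            rho["r_mem"].sum() * cell_area / (geom.volume * NA_UM),
            rho["d_mem"].sum() * cell_area / (geom.volume * NA_UM),
            rho["a_clus"].sum() * cell_area / (geom.volume * NA_UM),
            rho["d_clus"].sum() * cell_area / (geom.volume * NA_UM),
            rho["d_2dclus"].sum() * cell_area / (geom.volume * NA_UM),
        ]

    record(ri, rho, d_sol)
    ri += 1
    t = 0.0
    for step in range(n_steps):
        # Heun for reactions
        d1, ds1 = reaction_rhs(rho, d_sol)
        pred = {k: rho[k] + dt * d1[k] for k in rho}
        ds_pred = d_sol + dt * ds1
        d2, ds2 = reaction_rhs(pred, ds_pred)
        for k in rho:
            rho[k] = np.clip(rho[k] + 0.5 * dt * (d1[k] + d2[k]), 0.0, None)
        d_sol = max(d_sol + 0.5 * dt * (ds1 + ds2), 0.0)
        # exact diffusion for the mobile species
        for k in ("d_mem", "r_mem"):
            rho[k] = np.real(np.fft.ifft2(np.fft.fft2(rho[k]) * decay))
        t += dt
        while ri < n_record and rec_times[ri] <= t + 1e-12:
            record(ri, rho, d_sol)
            ri += 1
    while ri < n_record:
        record(ri, rho, d_sol)
        ri += 1

    rr = np.sqrt(X ** 2 + Y ** 2).ravel()
    nbins = 24
    edges = np.linspace(0.0, L / 2, nbins + 1)
    which = np.digitize(rr, edges) - 1
    prof = np.full(nbins, np.nan)
    dm = rho["d_mem"].ravel()
    for b in range(nbins):
        sel = which == b
        if sel.any():
            prof[b] = dm[sel].mean()
    centers = 0.5 * (edges[:-1] + edges[1:])

    return PDEResult(
        times=rec_times,
        totals=pd.DataFrame(totals, columns=SPECIES),
        geometry=geom,
        radial_r=centers,
        radial_d_mem=prof,
        fields={k: v.copy() for k, v in rho.items()},
    )


# ---------------------------------------------------------------------------
# Published optimal parameter preset (Dyn1bb)
# ---------------------------------------------------------------------------

#: Optimal Dyn1bb model: concentrations, rates and the pre/post geometries.
DYN1BB = {
    "d_sol": 10.0,          # µM
    "d_mem": 30.0,          # copies/µm²
    "r_mem": 4.85,          # copies/µm²
    "a_clus": 207.0,        # copies/µm²
    "k_mem": 0.017,         # µM⁻¹s⁻¹ (pre-stimulation)
    "k_mem_post": 0.0024,   # µM⁻¹s⁻¹
    "k_dyn": 0.035,         # µM⁻¹s⁻¹
    "k_frev": 0.09,         # µM⁻¹s⁻¹
    "h": 0.01,              # µm
    "v_over_a": 1.9,        # µm
    "density_pre": 0.54,    # clusters/µm²
    "density_post": 3.1,
    "r_clus_pre": 0.083,    # µm
    "r_clus_post": 0.096,
    # Membrane-density increase after stimulation measured by SPT; the
    # exact factor is dataset-specific, 2.0 keeps the initial membrane
    # pool inside the physical 10–80 copies/µm² range.
    "stim_scale": 2.0,
}


def dyn1bb_states(stimulated: bool = True):
    """(state, geometry, rates) for the optimal Dyn1bb preset.

    ``stimulated`` applies the three post-stimulation changes (higher
    cluster density with radius 0.096 µm, stimulation-scaled membrane
    density with copy conservation, k_memPost).
    """
    p = DYN1BB
    state = ModelState(d_sol=p["d_sol"], r_mem=p["r_mem"], d_mem=p["d_mem"],
                       a_clus=p["a_clus"])
    geom = build_geometry(p["density_pre"], v_over_a=p["v_over_a"],
                          r_clus=p["r_clus_pre"], h=p["h"])
    k_b = equilibrium_kb(p["d_sol"], p["r_mem"], p["d_mem"], p["k_frev"])
    rates = RateParams(k_frev=p["k_frev"], k_b=k_b, k_mem=p["k_mem"],
                       k_dyn=p["k_dyn"])
    if stimulated:
        return apply_stimulation(state, geom, rates,
                                 membrane_density_scale=p["stim_scale"],
                                 post_density=p["density_post"],
                                 k_mem_post=p["k_mem_post"],
                                 post_r_clus=p["r_clus_post"])
    return state, geom, rates
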