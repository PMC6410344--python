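"""Nanoparticle diffusion and Pennes bioheat transfer on a 1-D spherical domain.

The domain is a sphere of radius ``r_max`` with a tumor core of radius
``tumor_radius`` and healthy tissue outside, discretized with a conservative
finite-volume scheme on a uniform radial grid (symmetry at r = 0).  Two
transport problems share the machinery:

* nanoparticle diffusion  dc/dt = D (1/r^2) d/dr(r^2 dc/dr) + R_gen,
* Pennes bioheat          rho Cp dT/dt = div(k grad T) + Q
                           + rho_b Cp_b w_b (T_b - T) + Q_met,

where the perfusion sink pulls tissue toward the arterial blood temperature
T_b and Q_met is the volumetric metabolic heat production [W/m^3].  Heating by
an illuminated nanoparticle distribution enters as Q(r) = c(r) sigma_abs I
(beam attenuation through the tissue is neglected).  Time stepping is implicit
(backward Euler, unconditionally stable) with a tridiagonal solve per step.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "TissueProperties",
    "BloodProperties",
    "BLOOD",
    "TISSUES",
    "T_BODY",
    "RadialGrid",
    "LaserNPSource",
    "DiffusionResult",
    "PennesResult",
    "gaussian_bolus",
    "mass_to_number_density",
    "solve_np_diffusion",
    "np_heat_source",
    "solve_pennes",
]

T_BODY = 37.0  # arterial blood / baseline tissue temperature [degC]

#: default nanoparticle diffusivity in tissue [m^2/s]
DEFAULT_NP_DIFFUSIVITY = 6.2e-11

GOLD_DENSITY = 19300.0  # kg/m^3


@dataclass(frozen=True)
class BloodProperties:
    rho: float = 1050.0  # kg/m^3
    cp: float = 3617.0  # J/kg/degC
    temperature: float = T_BODY  # degC


BLOOD = BloodProperties()


@dataclass(frozen=True)
class TissueProperties:
    """Pennes coefficients of one tissue.

    ``w_b`` is the volumetric blood perfusion rate (m^3 blood per m^3 tissue
    per second, i.e. 1/s) and ``q_met`` the volumetric metabolic heat
    production in W/m^3.
    """

    name: str
    cp: float  # J/kg/degC
    rho: float  # kg/m^3
    k: float  # W/m/degC
    w_b: float  # 1/s
    q_met: float  # W/m^3
    diffusivity: float = DEFAULT_NP_DIFFUSIVITY  # nanoparticle D [m^2/s]

    def __post_init__(self) -> None:
        if min(self.cp, self.rho, self.k) <= 0 or self.w_b < 0 or self.q_met < 0:
            raise ValueError(f"non-physical tissue parameters for {self.name!r}")


TISSUES: dict[str, TissueProperties] = {
    t.name: t
    for t in (
        TissueProperties("dermis", 3300.0, 1200.0, 0.45, 1.25e-3, 1200.0),
        TissueProperties("epidermis", 3590.0, 1200.0, 0.23, 0.0, 1200.0),
        TissueProperties("fat", 2348.0, 911.0, 0.21, 1.25e-3, 464.0),
        TissueProperties("tumor", 3421.0, 1090.0, 0.49, 1.65e-3, 991.0),
        TissueProperties("muscle", 3421.0, 1090.0, 0.49, 1.65e-3, 991.0),
    )
}


@dataclass(frozen=True)
class RadialGrid:
    """Uniform radial grid over [0, r_max] with a tumor core of radius
    ``tumor_radius`` (both in meters)."""

    r: np.ndarray
    tumor_radius: float

    @classmethod
    def make(cls, r_max: float = 6e-3, tumor_radius: float = 3e-3, n_nodes: int = 241):
        if not 0 < tumor_radius < r_max:
            raise ValueError("need 0 < tumor_radius < r_max")
        if n_nodes < 50:
            raise ValueError("need at least 50 radial nodes")
        return cls(np.linspace(0.0, r_max, n_nodes), float(tumor_radius))

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        dr = np.diff(r)
        if r[0] != 0 or r.size < 50 or not np.allclose(dr, dr[0]):
            raise ValueError("grid must be uniform, start at r=0 and have >=50 nodes")
        object.__setattr__(self, "r", r)

    @property
    def dr(self) -> float:
        return float(self.r[1] - self.r[0])

    @property
    def r_max(self) -> float:
        return float(self.r[-1])

    @property
    def in_tumor(self) -> np.ndarray:
        return self.r <= self.tumor_radius + 1e-15

    @property
    def shell_volumes(self) -> np.ndarray:
        """Control-volume sizes [m^3] (half cells at the two boundaries)."""
        r, dr = self.r, self.dr
        faces_out = np.minimum(r + dr / 2, self.r_max)
        faces_in = np.maximum(r - dr / 2, 0.0)
        return 4 / 3 * np.pi * (faces_out**3 - faces_in**3)


@dataclass(frozen=True)
class LaserNPSource:
    """Continuous-wave plane illumination of a nanoparticle distribution."""

    irradiance: float = 20e4  # W/m^2 (20 W/cm^2)
    sigma_abs_m2: float = 0.0  # per-particle absorption cross section [m^2]
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        if self.irradiance < 0 or self.sigma_abs_m2 < 0:
            raise ValueError("irradiance and cross section must be non-negative")


def mass_to_number_density(
    mass_concentration_kg_m3: float,
    particle_radius_m: float,
    particle_density: float = GOLD_DENSITY,
) -> float:
    """Convert a mass concentration (e.g. 40 ug/mL = 0.04 kg/m^3) to a particle
    number density [1/m^3] for solid spheres of the given radius and density."""
    if min(mass_concentration_kg_m3, particle_radius_m, particle_density) < 0:
        raise ValueError("inputs must be non-negative")
    particle_mass = particle_density * 4 / 3 * np.pi * particle_radius_m**3
    return mass_concentration_kg_m3 / particle_mass


def gaussian_bolus(grid: RadialGrid, total_particles: float, sigma_m: float) -> np.ndarray:
    """Gaussian concentration profile centred at r = 0 holding
    ``total_particles`` in the full domain (an injection at the tumor centre
    shortly after delivery)."""
    c = np.exp(-grid.r**2 / (2 * sigma_m**2))
    total = np.sum(c * grid.shell_volumes)
    return c * (total_particles / total)


# ---------------------------------------------------------------------------
# finite-volume machinery
# ---------------------------------------------------------------------------


def _flux_matrix(grid: RadialGrid, k_node: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tridiagonal divergence-of-flux operator (per unit volume).

    Returns (lower, diag, upper) such that (M c)_i approximates
    div(k grad c) at node i, conservative across the interior faces.  The
    outer boundary row is left zeroed; boundary handling is applied by the
    callers.  Face conductivities are harmonic means (exact for piecewise
    constant k).
    """
    r, dr = grid.r, grid.dr
    n = r.size
    vol = grid.shell_volumes
    area = 4 * np.pi * (r[:-1] + dr / 2) ** 2  # interior face areas
    ksum = k_node[:-1] + k_node[1:]
    with np.errstate(invalid="ignore"):
        kf = np.where(ksum > 0, 2 * k_node[:-1] * k_node[1:] / np.where(ksum > 0, ksum, 1.0), 0.0)
    g = kf * area / dr  # face conductances [W/K] or [m^3/s]

    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    # node i exchanges with i+1 through face i (i = 0..n-2)
    diag[:-1] -= g / vol[:-1]
    upper[:-1] += g / vol[:-1]
    diag[1:] -= g / vol[1:]
    lower[1:] += g / vol[1:]
    # outer node handled by boundary condition
    lower[-1] = diag[-1] = upper[-1] = 0.0
    return lower, diag, upper


def _implicit_step_matrix(lower, diag, upper, coef, dt, dirichlet_outer: bool):
    """Banded matrix for (I - dt/coef * M) with the outer-boundary row set to
    identity (Dirichlet) or left as assembled (Neumann rows are pre-assembled
    by the caller)."""
    n = diag.size
    ab = np.zeros((3, n))
    ab[0, 1:] = -dt * upper[:-1] / coef[:-1]
    ab[1, :] = 1 - dt * diag / coef
    ab[2, :-1] = -dt * lower[1:] / coef[1:]
    if dirichlet_outer:
        ab[1, -1] = 1.0
        ab[2, -2] = 0.0  # the boundary row couples to nothing
    return ab


@dataclass(frozen=True)
class DiffusionResult:
    grid: RadialGrid
    times: np.ndarray
    concentration: np.ndarray  # shape (n_times, n_nodes), [1/m^3]

    def total_particles(self) -> np.ndarray:
        return self.concentration @ self.grid.shell_volumes

    @property
    def final(self) -> np.ndarray:
        return self.concentration[-1]


def solve_np_diffusion(
    grid: RadialGrid,
    c0: np.ndarray,
    diffusivity: float = DEFAULT_NP_DIFFUSIVITY,
    t_end: float = 3600.0,
    dt: float | None = None,
    generation_rate: float = 0.0,
    n_snapshots: int = 25,
    outer_bc: str = "dirichlet",
) -> DiffusionResult:
    """Diffuse an initial nanoparticle profile for ``t_end`` seconds.

    Zero flux at r = 0 (symmetry); the outer boundary is an absorbing sink
    (``dirichlet``, c = 0: particles reaching r_max are cleared) or sealed
    (``neumann``).  ``generation_rate`` adds a uniform source [1/m^3/s].
    Backward-Euler stepping; ``dt`` defaults to t_end/400.
    """
    c = np.asarray(c0, dtype=float).copy()
    if c.shape != grid.r.shape:
        raise ValueError("initial profile must live on the grid nodes")
    if np.any(c < 0) or diffusivity < 0 or t_end < 0:
        raise ValueError("concentration, diffusivity and t_end must be non-negative")
    if outer_bc not in ("dirichlet", "neumann"):
        raise ValueError("outer_bc must be 'dirichlet' or 'neumann'")
    if t_end == 0:
        return DiffusionResult(grid, np.array([0.0]), c[None, :])
    if dt is None:
        dt = t_end / 400

    k_node = np.full(grid.r.size, diffusivity)
    lower, diag, upper = _flux_matrix(grid, k_node)
    dirichlet = outer_bc == "dirichlet"
    if not dirichlet:  # assemble the sealed outer half-cell
        vol = grid.shell_volumes
        area = 4 * np.pi * (grid.r[-1] - grid.dr / 2) ** 2
        g = diffusivity * area / grid.dr
        diag = diag.copy()
        lower = lower.copy()
        diag[-1] = -g / vol[-1]
        lower[-1] = g / vol[-1]
    ones = np.ones_like(c)
    ab = _implicit_step_matrix(lower, diag, upper, ones, dt, dirichlet)

    n_steps = int(np.ceil(t_end / dt))
    snap_every = max(1, n_steps // max(1, n_snapshots - 1))
    times = [0.0]
    snaps = [c.copy()]
    t = 0.0
    for step in range(1, n_steps + 1):
        rhs = c + dt * generation_rate
        if dirichlet:
            rhs[-1] = 0.0
        c = solve_banded((1, 1), ab, rhs)
        np.clip(c, 0.0, None, out=c)
        t = min(step * dt, t_end)
        if step % snap_every == 0 or step == n_steps:
            times.append(t)
            snaps.append(c.copy())
    return DiffusionResult(grid, np.array(times), np.array(snaps))


def np_heat_source(concentration: np.ndarray, source: LaserNPSource) -> np.ndarray:
    """Volumetric heating Q(r) = c(r) * sigma_abs * I [W/m^3]."""
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    return c * source.sigma_abs_m2 * source.irradiance


@dataclass(frozen=True)
class PennesResult:
    grid: RadialGrid
    times: np.ndarray
    temperature: np.ndarray  # (n_times, n_nodes) [degC]
    threshold_times: dict[float, np.ndarray]  # degC -> first-crossing time per node (nan = never)

    @property
    def final(self) -> np.ndarray:
        return self.temperature[-1]

    @property
    def peak_temperature(self) -> float:
        return float(np.max(self.temperature))


def solve_pennes(
    grid: RadialGrid,
    source: np.ndarray | Callable[[float], np.ndarray] | None = None,
    tissue_inside: TissueProperties | str = "tumor",
    tissue_outside: TissueProperties | str = "muscle",
    t_end: float = 600.0,
    dt: float = 0.1,
    blood: BloodProperties = BLOOD,
    include_metabolic: bool = True,
    outer_bc: str = "dirichlet",
    thresholds: Sequence[float] = (42.0, 47.0, 50.0),
    T0: np.ndarray | None = None,
    n_snapshots: int = 25,
) -> PennesResult:
    """Transient Pennes solve with a tumor core and a healthy-tissue surround.

    ``source`` is a volumetric heating field [W/m^3] on the grid nodes (or a
    callable of time returning one); the initial and far-field temperature is
    the arterial blood temperature.  ``outer_bc='dirichlet'`` clamps T(r_max)
    to T_b, ``'neumann'`` seals the outer boundary.  Besides the temperature
    history the result reports, per node and per threshold, the first time the
    local temperature crosses the hyperthermia/ablation thresholds.
    """
    if isinstance(tissue_inside, str):
        tissue_inside = TISSUES[tissue_inside]
    if isinstance(tissue_outside, str):
        tissue_outside = TISSUES[tissue_outside]
    if outer_bc not in ("dirichlet", "neumann"):
        raise ValueError("outer_bc must be 'dirichlet' or 'neumann'")
    if dt <= 0 or t_end < 0:
        raise ValueError("need dt > 0 and t_end >= 0")

    inside = grid.in_tumor
    pick = lambda a, b: np.where(inside, a, b)
    rho = pick(tissue_inside.rho, tissue_outside.rho)
    cp = pick(tissue_inside.cp, tissue_outside.cp)
    k_node = pick(tissue_inside.k, tissue_outside.k)
    w_b = pick(tissue_inside.w_b, tissue_outside.w_b)
    q_met = pick(tissue_inside.q_met, tissue_outside.q_met) if include_metabolic else 0.0

    Tb = blood.temperature
    T = np.full(grid.r.size, Tb) if T0 is None else np.asarray(T0, dtype=float).copy()
    if T.shape != grid.r.shape:
        raise ValueError("T0 must live on the grid nodes")

    lower, diag, upper = _flux_matrix(grid, k_node)
    dirichlet = outer_bc == "dirichlet"
    if not dirichlet:
        vol = grid.shell_volumes
        area = 4 * np.pi * (grid.r[-1] - grid.dr / 2) ** 2
        g_face = (
            2 * k_node[-1] * k_node[-2] / (k_node[-1] + k_node[-2]) * area / grid.dr
        )
        diag = diag.copy()
        lower = lower.copy()
        diag[-1] = -g_face / vol[-1]
        lower[-1] = g_face / vol[-1]

    coef = rho * cp
    perf = blood.rho * blood.cp * w_b  # W/m^3/degC
    # fold the linear perfusion sink into the implicit matrix
    n = grid.r.size
    ab = np.zeros((3, n))
    ab[0, 1:] = -dt * upper[:-1] / coef[:-1]
    ab[1, :] = 1 + dt * (perf / coef) - dt * diag / coef
    ab[2, :-1] = -dt * lower[1:] / coef[1:]
    if dirichlet:
        ab[1, -1] = 1.0
        ab[2, -2] = 0.0

    static_source = source if (source is None or not callable(source)) else None
    if static_source is not None:
        static_source = np.asarray(static_source, dtype=float)
        if static_source.shape != grid.r.shape:
            raise ValueError("source must live on the grid nodes")

    if t_end == 0:
        return PennesResult(
            grid, np.array([0.0]), T[None, :], {th: np.full(n, np.nan) for th in thresholds}
        )

    n_steps = int(np.ceil(t_end / dt))
    snap_every = max(1, n_steps // max(1, n_snapshots - 1))
    times = [0.0]
    snaps = [T.copy()]
    cross = {float(th): np.where(T >= th, 0.0, np.nan) for th in thresholds}
    t = 0.0
    for step in range(1, n_steps + 1):
        t = min(step * dt, t_end)
        Q = static_source if static_source is not None else (source(t) if source else 0.0)
        rhs = T + dt * (np.asarray(Q) + q_met + perf * Tb) / coef
        if dirichlet:
            rhs[-1] = Tb
        T = solve_banded((1, 1), ab, rhs)
        for th, first in cross.items():
            hit = np.isnan(first) & (T >= th)
            first[hit] = t
        if step % snap_every == 0 or step == n_steps:
            times.append(t)
            snaps.append(T.copy())
    return PennesResult(grid, np.array(times), np.array(snaps), cross)
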