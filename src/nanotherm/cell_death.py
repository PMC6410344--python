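"""Three-state (alive/vulnerable/dead) hyperthermic cell-death kinetics.

During heating ("fast" death, necrosis-like) the populations follow

    dA/dt = -kf A + kb V,      dD/dt = kf V,      V = 1 - A - D,

with the self-catalytic forward rate kf = kf_bar * exp(T/Tk) * (1 - A): the
rate grows exponentially with temperature (T in degC, Tk a temperature scale
in degC) and accelerates as the live fraction drops.  After treatment ("slow"
death, apoptosis-like) there is no vulnerable pool (kf = kb = 0) and

    dD/dt = ks (1 - D),        ks = ks_bar * D (1 - D) (D - D_tau)^2.

Because A = 1 is a fixed point of the fast model, simulations default to a
seed vulnerable fraction V0 = 1e-3.  Rate parameters for melanoma and prostate
carcinoma are shipped as presets; the prostate slow-phase pair is flagged
unverified (published without supporting data).  Parameter estimation is
bound-constrained least squares on viability readouts with seeded log-uniform
multistarts.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "DeathModelParams",
    "MELANOMA",
    "PROSTATE",
    "CellStateTrajectory",
    "fast_death",
    "slow_death",
    "FitResult",
    "fit_death_params",
    "DEFAULT_BOUNDS",
]

#: default seed vulnerable fraction (A0 = 1 is a fixed point of the fast model)
DEFAULT_V0 = 1e-3


@dataclass(frozen=True)
class DeathModelParams:
    """Rate parameters of the three-state model.

    kf_bar, kb in 1/min (fast phase); Tk in degC; ks_bar in 1/h (slow phase);
    D_tau a dead-fraction threshold in [0, 1).
    """

    kf_bar: float
    kb: float
    Tk: float
    ks_bar: float
    D_tau: float
    label: str = ""
    provenance: str = "fitted"

    def __post_init__(self) -> None:
        if min(self.kf_bar, self.kb, self.Tk, self.ks_bar) < 0 or not 0 <= self.D_tau < 1:
            raise ValueError("rates must be >= 0 and D_tau in [0, 1)")

    def kf(self, T: float, A) -> float:
        return self.kf_bar * np.exp(T / self.Tk) * (1.0 - A)

    def ks(self, D):
        return self.ks_bar * D * (1.0 - D) * (D - self.D_tau) ** 2


MELANOMA = DeathModelParams(
    0.25481, 0.66477, 40.1513, 0.59547, 0.45003e-3, label="melanoma"
)
PROSTATE = DeathModelParams(
    0.18946, 0.23063, 39.678, 0.316e-3, 0.208, label="prostate",
    provenance="unverified",  # slow-phase pair published without data
)


@dataclass(frozen=True)
class CellStateTrajectory:
    """Time series of the three cell-state fractions; A + V + D = 1 throughout."""

    times: np.ndarray  # minutes (fast) or hours (slow)
    A: np.ndarray
    V: np.ndarray
    D: np.ndarray
    time_unit: str = "min"
    metadata: dict = None

    @property
    def final_dead_fraction(self) -> float:
        return float(self.D[-1])

    @property
    def survival(self) -> np.ndarray:
        return self.A


def _fast_rhs(params: DeathModelParams, temperature: Callable[[float], float]):
    def rhs(t, y):
        A, D = y
        V = 1.0 - A - D
        kf = params.kf(temperature(t), A)
        return (-kf * A + params.kb * V, kf * V)

    return rhs


def fast_death(
    params: DeathModelParams,
    temperature: float | Callable[[float], float],
    duration_min: float,
    init: tuple[float, float, float] | None = None,
    n_points: int = 121,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    t_eval: np.ndarray | None = None,
) -> CellStateTrajectory:
    """Integrate the fast (during-heating) kinetics for ``duration_min`` minutes.

    ``temperature`` is a constant in degC or a callable of time-in-minutes
    (e.g. resampled from a bioheat solution).  ``init`` is (A0, V0, D0),
    defaulting to (1 - 1e-3, 1e-3, 0).  ``t_eval`` overrides the uniform
    output grid (its last entry sets the integration span).
    """
    if init is None:
        init = (1.0 - DEFAULT_V0, DEFAULT_V0, 0.0)
    A0, V0, D0 = init
    if abs(A0 + V0 + D0 - 1.0) > 1e-9 or min(A0, V0, D0) < -1e-12:
        raise ValueError("initial fractions must be non-negative and sum to 1")
    temp = temperature if callable(temperature) else (lambda t, T=float(temperature): T)
    if t_eval is not None:
        times = np.asarray(t_eval, dtype=float)
        duration_min = float(times[-1])
    else:
        times = np.linspace(0.0, duration_min, n_points)
    if duration_min == 0:
        A = np.full(1, A0)
        D = np.full(1, D0)
        times = times[:1]
    else:
        sol = solve_ivp(
            _fast_rhs(params, temp),
            (0.0, duration_min),
            (A0, D0),
            method="LSODA",
            t_eval=times,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"fast-death integration failed: {sol.message}")
        # integrator overshoot can leave fractions marginally outside [0, 1]
        A = np.clip(sol.y[0], 0.0, 1.0)
        D = np.clip(sol.y[1], 0.0, 1.0)
    V = 1.0 - A - D
    return CellStateTrajectory(
        times, A, V, D, "min",
        {"mode": "fast", "params": params, "init": init},
    )


def slow_death(
    params: DeathModelParams,
    D0: float,
    t_end_h: float,
    n_points: int = 121,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    t_eval: np.ndarray | None = None,
) -> CellStateTrajectory:
    """Integrate the slow (post-treatment) kinetics from dead fraction ``D0``
    for ``t_end_h`` hours.  There is no vulnerable pool: V = 0, A = 1 - D."""
    if not 0.0 <= D0 <= 1.0:
        raise ValueError("D0 must lie in [0, 1]")
    if t_eval is not None:
        times = np.asarray(t_eval, dtype=float)
        t_end_h = float(times[-1])
    else:
        times = np.linspace(0.0, t_end_h, n_points)
    if t_end_h == 0 or D0 in (0.0, 1.0):  # fixed points of ks = ks_bar*D(1-D)(...)^2
        D = np.full_like(times, D0)
    else:
        sol = solve_ivp(
            lambda t, y: (params.ks(y[0]) * (1.0 - y[0]),),
            (0.0, t_end_h),
            (D0,),
            method="LSODA",
            t_eval=times,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"slow-death integration failed: {sol.message}")
        D = np.clip(sol.y[0], D0, 1.0)
    A = 1.0 - D
    return CellStateTrajectory(
        times, A, np.zeros_like(D), D, "h",
        {"mode": "slow", "params": params, "D0": D0},
    )


# ---------------------------------------------------------------------------
# fast fixed-step forward models (used inside the fitting loops)
# ---------------------------------------------------------------------------


def _fast_survival_rk4(params, T, times_min, init, steps_per_min=8):
    """A(t) at the requested times, fixed-step RK4 (smooth non-stiff system).

    Scalar arithmetic on the 2-state system keeps a single evaluation cheap
    enough for multistart fitting; the step count scales with the fastest rate
    in play so the explicit scheme stays stable even for the extreme corners
    of the fitting bounds.
    """
    t_end = float(np.max(times_min)) if np.max(times_min) > 0 else 1.0
    ekT = params.kf_bar * float(np.exp(T / params.Tk))
    kb = params.kb
    rate_scale = ekT + kb  # 1/min; RK4 stable for h*rate < ~2.7
    n = max(20, int(np.ceil(t_end * max(steps_per_min, rate_scale))) + 1)
    grid = np.linspace(0.0, t_end, n)
    h = grid[1] - grid[0]
    A, D = float(init[0]), float(init[2])
    outA = np.empty(n)
    outA[0] = A

    def f(A, D):
        V = 1.0 - A - D
        kf = ekT * (1.0 - A)
        return -kf * A + kb * V, kf * V

    for i in range(1, n):
        a1, d1 = f(A, D)
        a2, d2 = f(A + h / 2 * a1, D + h / 2 * d1)
        a3, d3 = f(A + h / 2 * a2, D + h / 2 * d2)
        a4, d4 = f(A + h * a3, D + h * d3)
        A += h / 6 * (a1 + 2 * a2 + 2 * a3 + a4)
        D += h / 6 * (d1 + 2 * d2 + 2 * d3 + d4)
        outA[i] = A
    return np.interp(times_min, grid, outA)


def _slow_dead_rk4(params, D0, times_h, steps_per_h=20):
    t_end = float(np.max(times_h)) if np.max(times_h) > 0 else 1.0
    ksb, Dt = params.ks_bar, params.D_tau
    n = max(20, int(np.ceil(t_end * max(steps_per_h, ksb))) + 1)
    grid = np.linspace(0.0, t_end, n)
    h = grid[1] - grid[0]
    f = lambda D: ksb * D * (1.0 - D) * (D - Dt) ** 2 * (1.0 - D)
    D = float(D0)
    out = np.empty(n)
    out[0] = D
    for i in range(1, n):
        d1 = f(D)
        d2 = f(D + h / 2 * d1)
        d3 = f(D + h / 2 * d2)
        d4 = f(D + h * d3)
        D += h / 6 * (d1 + 2 * d2 + 2 * d3 + d4)
        out[i] = D
    return np.interp(times_h, grid, out)


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------

DEFAULT_BOUNDS = {
    "kf_bar": (1e-4, 10.0),
    "kb": (1e-4, 10.0),
    "Tk": (30.0, 60.0),
    "ks_bar": (1e-4, 10.0),
    "D_tau": (0.0, 0.999),
}


@dataclass(frozen=True)
class FitResult:
    params: DeathModelParams
    objective: float  # sum of squared residuals at the optimum
    mode: str
    n_starts: int
    per_start: tuple  # (start vector, objective) per multistart
    seed: int


def fit_death_params(
    data: pd.DataFrame,
    mode: str,
    bounds: dict | None = None,
    seed: int = 0,
    n_starts: int = 20,
    init: tuple[float, float, float] | None = None,
) -> FitResult:
    """Estimate rate parameters from viability observations.

    ``data`` has columns ``time_min``, ``temperature_C``, ``survival``.  In
    ``fast`` mode the free parameters are (kf_bar, kb, Tk) and survival is
    modelled as A(t); in ``slow`` mode they are (ks_bar, D_tau) and survival is
    1 - D(t) with D0 inferred from the earliest observation.  Starting points
    are drawn log-uniformly (rates) / uniformly (Tk, D_tau) within the bounds
    with a fixed seed; the best of ``n_starts`` local bound-constrained
    least-squares solutions is returned.
    """
    if mode not in ("fast", "slow"):
        raise ValueError("mode must be 'fast' or 'slow'")
    required = {"time_min", "temperature_C", "survival"}
    if not required.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    if len(data) == 0:
        raise ValueError("no observations to fit")
    min_obs = 4 if mode == "fast" else 3
    if len(data) < min_obs:
        raise ValueError(f"{mode} mode needs at least {min_obs} observations")
    b = {**DEFAULT_BOUNDS, **(bounds or {})}
    if init is None:
        init = (1.0 - DEFAULT_V0, DEFAULT_V0, 0.0)

    rng = np.random.default_rng(seed)
    df = data.sort_values("time_min")
    obs = df["survival"].to_numpy(dtype=float)

    if mode == "fast":
        names = ("kf_bar", "kb", "Tk")
        groups = [
            (float(T), g["time_min"].to_numpy(dtype=float), g["survival"].to_numpy(dtype=float))
            for T, g in df.groupby("temperature_C")
        ]

        def residuals(theta):
            p = DeathModelParams(theta[0], theta[1], theta[2], 1.0, 0.0)
            res = [
                _fast_survival_rk4(p, T, t, init) - y for T, t, y in groups
            ]
            return np.concatenate(res)

    else:
        names = ("ks_bar", "D_tau")
        t_h = df["time_min"].to_numpy(dtype=float) / 60.0
        D0 = float(np.clip(1.0 - obs[0], 0.0, 1.0))
        t_rel = t_h - t_h[0]

        def residuals(theta):
            p = DeathModelParams(0.0, 0.0, 1.0, theta[0], theta[1])
            model = 1.0 - _slow_dead_rk4(p, D0, t_rel)
            return model - df["survival"].to_numpy(dtype=float)

    lo = np.array([b[n][0] for n in names])
    hi = np.array([b[n][1] for n in names])

    def draw_start():
        x = np.empty(len(names))
        for i, n in enumerate(names):
            if n in ("Tk", "D_tau"):
                x[i] = rng.uniform(lo[i], hi[i])
            else:
                x[i] = np.exp(rng.uniform(np.log(max(lo[i], 1e-12)), np.log(hi[i])))
        return x

    per_start = []
    best = None
    for _ in range(n_starts):
        x0 = draw_start()
        try:
            sol = least_squares(
                residuals, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, max_nfev=300
            )
        except Exception:  # a pathological start must not sink the multistart
            continue
        obj = float(2 * sol.cost)
        per_start.append((tuple(x0), obj))
        if best is None or obj < best[1]:
            best = (sol.x, obj)
    if best is None:
        raise RuntimeError("all optimization starts failed")

    x, obj = best
    if mode == "fast":
        params = DeathModelParams(x[0], x[1], x[2], 1.0, 0.0, label="fitted-fast")
    else:
        params = DeathModelParams(0.0, 0.0, 1.0, x[0], x[1], label="fitted-slow")
    return FitResult(params, obj, mode, n_starts, tuple(per_start), seed)
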