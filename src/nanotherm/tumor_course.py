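"""Multi-session hyperthermia treatment courses coupled to exponential regrowth.

Between sessions the tumor volume follows dV/dt = a0 V, i.e. the closed form
V(t) = V0 exp(a0 t) with a0 in 1/day.  A session at temperature T runs the
fast cell-death kinetics for the heating interval, then the slow kinetics over
a post-treatment window (default 48 h, truncated when the next session comes
sooner); the surviving-volume coupling V_post = V_pre * (1 - D_final) removes
the dead fraction, and regrowth restarts from the viable volume.  Growth is
suspended during the slow-death window (death and growth are treated as
sequential phases).

Calibrated growth rates are shipped for melanoma with and without HSP90
(heat-shock protein 90) inhibition and for prostate carcinoma; pharmacologic
HSP90 inhibition enters purely as a reduced regrowth rate.  The printed source
unit for these rates is per second, which would double a tumor within seconds;
they are interpreted as 1/day, the only reading compatible with multi-day
growth curves.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cell_death import DeathModelParams, MELANOMA, PROSTATE, fast_death, slow_death

__all__ = [
    "GrowthParams",
    "GROWTH_VARIANTS",
    "TreatmentSchedule",
    "SessionOutcome",
    "TumorTrajectory",
    "grow",
    "apply_session",
    "simulate_course",
    "fit_growth_rate",
    "DEFAULT_V0_MM3",
]

#: default initial tumor volume: a 3 mm-radius sphere, 4/3*pi*27 ~ 113 mm^3
DEFAULT_V0_MM3 = 4 / 3 * np.pi * 27.0

#: floor on the viable fraction after a session so regrowth stays defined
VIABLE_FLOOR = 1e-6


@dataclass(frozen=True)
class GrowthParams:
    """Exponential growth rate a0 [1/day] and its variant label."""

    a0: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.a0 < 0:
            raise ValueError("growth rate must be non-negative")


GROWTH_VARIANTS = {
    "melanoma": GrowthParams(0.328, "melanoma"),
    "melanoma_hsp90i": GrowthParams(0.237, "melanoma_hsp90i"),
    "prostate": GrowthParams(0.243, "prostate"),
}


@dataclass(frozen=True)
class TreatmentSchedule:
    """Session days with a common temperature/duration/slow-death window.

    Defaults follow the melanoma protocol: seven sessions every 4 days at
    48 degC, 30 min of heating, 48 h of slow death.  The prostate protocol is
    sessions on days 0, 2 and 6 at 50 degC for 15 min.
    """

    session_days: tuple = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0)
    temperature_C: float = 48.0
    heating_min: float = 30.0
    slow_death_h: float = 48.0
    label: str = "melanoma"
    truncate_slow_window: bool = True

    @classmethod
    def melanoma(cls, n_sessions: int = 7):
        return cls(tuple(4.0 * i for i in range(n_sessions)))

    @classmethod
    def prostate(cls):
        return cls((0.0, 2.0, 6.0), 50.0, 15.0, 48.0, "prostate")

    def __post_init__(self) -> None:
        days = tuple(float(d) for d in self.session_days)
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("session days must be strictly increasing")
        if self.heating_min <= 0 or self.slow_death_h < 0:
            raise ValueError("durations must be positive")
        object.__setattr__(self, "session_days", days)

    def slow_window_h(self, i: int) -> float:
        """Slow-death window after session i, truncated to the inter-session
        gap when the next session comes sooner (unless truncation is off)."""
        if i + 1 < len(self.session_days):
            gap_h = 24.0 * (self.session_days[i + 1] - self.session_days[i])
            if gap_h < self.slow_death_h:
                if not self.truncate_slow_window:
                    raise ValueError(
                        f"sessions {i} and {i+1} are closer than the slow-death "
                        "window; enable truncate_slow_window or shorten it"
                    )
                return gap_h
        return self.slow_death_h


@dataclass(frozen=True)
class SessionOutcome:
    day: float
    volume_pre_mm3: float
    volume_post_mm3: float
    kill_fraction: float
    fast_dead_fraction: float


@dataclass(frozen=True)
class TumorTrajectory:
    """Volume-versus-time curve across sessions, plus per-session summaries."""

    days: np.ndarray
    volume_mm3: np.ndarray
    sessions: tuple

    @property
    def final_volume_mm3(self) -> float:
        return float(self.volume_mm3[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.days, "volume_mm3": self.volume_mm3})


def grow(V0_mm3: float, params: GrowthParams, t_days) -> np.ndarray | float:
    """Closed-form exponential growth V(t) = V0 exp(a0 t)."""
    if V0_mm3 <= 0:
        raise ValueError("volume must be positive")
    t = np.asarray(t_days, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = V0_mm3 * np.exp(params.a0 * t)
    return float(out) if np.isscalar(t_days) else out


def apply_session(
    V_pre_mm3: float,
    death_params: DeathModelParams,
    temperature_C: float,
    heating_min: float,
    slow_h: float,
    coupling: str = "dead_fraction",
) -> SessionOutcome:
    """Run one heating session and return the post-session viable volume.

    Fast kinetics for ``heating_min`` minutes at ``temperature_C``, then slow
    kinetics over ``slow_h`` hours starting from the fast-phase dead fraction.
    ``coupling='dead_fraction'`` keeps V_post = V_pre*(1 - D_final) (vulnerable
    cells may still recover); ``'alive_fraction'`` keeps only A_final.
    """
    if V_pre_mm3 <= 0:
        raise ValueError("volume must be positive")
    if coupling not in ("dead_fraction", "alive_fraction"):
        raise ValueError("coupling must be 'dead_fraction' or 'alive_fraction'")
    fast = fast_death(death_params, temperature_C, heating_min)
    slow = slow_death(death_params, fast.final_dead_fraction, slow_h)
    D_final = slow.final_dead_fraction
    if coupling == "dead_fraction":
        viable = 1.0 - D_final
    else:
        viable = fast.A[-1] * (1.0 - (D_final - fast.final_dead_fraction))
    viable = max(viable, VIABLE_FLOOR)
    return SessionOutcome(
        np.nan, V_pre_mm3, V_pre_mm3 * viable, D_final, fast.final_dead_fraction
    )


def simulate_course(
    V0_mm3: float = DEFAULT_V0_MM3,
    schedule: TreatmentSchedule | None = None,
    growth: GrowthParams | str = "melanoma",
    death: DeathModelParams | None = None,
    t_end_days: float | None = None,
    points_per_day: int = 8,
    coupling: str = "dead_fraction",
) -> TumorTrajectory:
    """Simulate a full treatment course.

    Each session applies its volume drop at the session day; growth then
    resumes after the slow-death window and follows the closed form until the
    next session (no integrator drift).  With an empty schedule the result is
    pure exponential growth.  ``t_end_days`` defaults to one inter-session
    interval past the last session (or 28 days untreated).
    """
    if schedule is None:
        schedule = TreatmentSchedule()
    if isinstance(growth, str):
        growth = GROWTH_VARIANTS[growth]
    if death is None:
        death = PROSTATE if schedule.label == "prostate" else MELANOMA

    days_list = list(schedule.session_days)
    if t_end_days is None:
        if days_list:
            gaps = [b - a for a, b in zip(days_list, days_list[1:])] or [4.0]
            t_end_days = days_list[-1] + gaps[-1]
        else:
            t_end_days = 28.0
    if days_list and days_list[0] < 0:
        raise ValueError("session days must be non-negative")

    days_out: list[float] = []
    vol_out: list[float] = []
    sessions: list[SessionOutcome] = []

    def emit_growth(t0, V_t0, t1):
        """Append the closed-form growth segment on [t0, t1]."""
        n = max(2, int(np.ceil((t1 - t0) * points_per_day)) + 1)
        seg = np.linspace(t0, t1, n)
        days_out.extend(seg.tolist())
        vol_out.extend((V_t0 * np.exp(growth.a0 * (seg - t0))).tolist())
        return float(vol_out[-1])

    t, V = 0.0, float(V0_mm3)
    if V <= 0:
        raise ValueError("V0 must be positive")
    for i, day in enumerate(days_list):
        if day > t:
            V = emit_growth(t, V, day)
            t = day
        elif not days_out:
            days_out.append(t)
            vol_out.append(V)
        slow_h = schedule.slow_window_h(i)
        out = apply_session(
            V, death, schedule.temperature_C, schedule.heating_min, slow_h, coupling
        )
        out = SessionOutcome(
            day, out.volume_pre_mm3, out.volume_post_mm3, out.kill_fraction,
            out.fast_dead_fraction,
        )
        sessions.append(out)
        V = out.volume_post_mm3
        # growth stays suspended through the slow-death window
        t_resume = min(day + slow_h / 24.0, t_end_days)
        days_out.extend([day, t_resume])
        vol_out.extend([V, V])
        t = t_resume
    if t < t_end_days:
        V = emit_growth(t, V, t_end_days)
    return TumorTrajectory(np.array(days_out), np.array(vol_out), tuple(sessions))


def fit_growth_rate(data: pd.DataFrame) -> tuple[float, float]:
    """Recover (a0 [1/day], V0 [mm^3]) from a volume-versus-day dataset by
    least squares on log volume (exact for noise-free exponential data)."""
    if not {"day", "volume_mm3"}.issubset(data.columns):
        raise ValueError("data must have columns 'day' and 'volume_mm3'")
    if len(data) < 2:
        raise ValueError("need at least two observations")
    if np.any(data["volume_mm3"] <= 0):
        raise ValueError("volumes must be positive")
    a0, logv0 = np.polyfit(data["day"], np.log(data["volume_mm3"]), 1)
    return float(a0), float(np.exp(logv0))
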