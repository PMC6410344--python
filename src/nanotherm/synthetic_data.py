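"""Synthetic viability and tumor-growth datasets for calibration exercises.

The fitting operations in this package were designed for external experimental
datasets (cell viability after heating at a fixed temperature; tumor volume
versus day in untreated animals).  These generators emulate the *structure* of
such data — sampling design, noise scale, value ranges — so parameter recovery
can be exercised end-to-end without any download: additive Gaussian noise with
clipping for viability fractions, multiplicative log-normal noise for volumes
(which span decades).  Every generator takes a mandatory seed and records the
generating parameters in ``DataFrame.attrs``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cell_death import (
    DEFAULT_V0,
    DeathModelParams,
    fast_death,
    slow_death,
)
from .tumor_course import GrowthParams, grow

__all__ = ["NoiseSpec", "gen_viability", "gen_growth"]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: distribution name, standard deviation and mandatory seed."""

    sd: float
    seed: int
    distribution: str = "gaussian"  # gaussian (additive) | lognormal (multiplicative)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.distribution not in ("gaussian", "lognormal"):
            raise ValueError("distribution must be 'gaussian' or 'lognormal'")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_viability(
    params: DeathModelParams,
    temperature_C: float = 48.0,
    times_min: Sequence[float] | None = None,
    mode: str = "fast",
    noise: NoiseSpec | None = None,
) -> pd.DataFrame:
    """Surviving-fraction measurements from the three-state model plus noise.

    The default design mirrors a necrosis-range heating assay: 10 time points
    over 30 min at 48 degC.  For ``mode='slow'`` pass post-treatment times (in
    minutes) and the model survival is 1 - D(t) starting from the fast-phase
    endpoint at the same temperature.  Noise is additive Gaussian on the
    fraction, clipped to [0, 1].
    """
    if noise is None:
        noise = NoiseSpec(0.02, 0)
    if times_min is None:
        times_min = np.linspace(0.0, 30.0, 10)
    t = np.asarray(times_min, dtype=float)
    if np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ValueError("times must be non-negative and sorted")

    if mode == "fast":
        traj = fast_death(params, temperature_C, float(t.max()), t_eval=t)
        surv = traj.A
    elif mode == "slow":
        D0 = fast_death(params, temperature_C, 30.0).final_dead_fraction
        traj = slow_death(params, D0, float(t.max()) / 60.0, t_eval=t / 60.0)
        surv = 1.0 - traj.D
    else:
        raise ValueError("mode must be 'fast' or 'slow'")

    noisy = surv + noise.rng().normal(0.0, noise.sd, surv.size) if noise.sd > 0 else surv
    df = pd.DataFrame(
        {
            "time_min": t,
            "temperature_C": float(temperature_C),
            "survival": np.clip(noisy, 0.0, 1.0),
        }
    )
    df.attrs = {
        "generator": "gen_viability",
        "mode": mode,
        "params": params,
        "noise_sd": noise.sd,
        "seed": noise.seed,
        "model_survival": surv,
        "init_V0": DEFAULT_V0,
    }
    return df


def gen_growth(
    params: GrowthParams,
    V0_mm3: float = 113.0,
    days: Sequence[float] | None = None,
    noise: NoiseSpec | None = None,
) -> pd.DataFrame:
    """Tumor volume versus day for untreated exponential growth plus log-normal
    multiplicative noise (sd on the log scale)."""
    if V0_mm3 <= 0:
        raise ValueError("V0 must be positive")
    if noise is None:
        noise = NoiseSpec(0.05, 0, "lognormal")
    if days is None:
        days = np.arange(0.0, 15.0, 2.0)
    d = np.asarray(days, dtype=float)
    vol = grow(V0_mm3, params, d)
    if noise.sd > 0:
        vol = vol * np.exp(noise.rng().normal(0.0, noise.sd, d.size))
    df = pd.DataFrame({"day": d, "volume_mm3": vol})
    df.attrs = {
        "generator": "gen_growth",
        "params": params,
        "V0_mm3": V0_mm3,
        "noise_sd": noise.sd,
        "seed": noise.seed,
    }
    return df
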