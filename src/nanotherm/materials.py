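"""Wavelength-tabulated optical constants and the surface-scattering correction.

Materials are shipped as CSV fixture tables (``wavelength_nm,n,k``) covering at
least 400-1100 nm and loaded on first use.  All dielectric functions returned by
this module follow the physics convention ``eps = eps1 + i*eps2`` with
``eps2 >= 0`` for absorbing media; the engineering convention ``n = n' - j n''``
used by some tabulations is converted at the single point where a table row is
squared into a dielectric value.

For metal structures with a dimension below the conduction-electron mean free
path, the bulk dielectric function is corrected for electron-surface scattering
by swapping the bulk Drude damping rate for an effective one that includes a
``v_F / L_eff`` collision term (``L_eff`` = reduced mean free path, e.g. the
gold layer thickness of a nanoshell).
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "OpticalMaterial",
    "DrudeCorrectionConstants",
    "GOLD_DRUDE",
    "get_material",
    "available_materials",
    "bulk_dielectric",
    "size_corrected_dielectric",
]

SPEED_OF_LIGHT = 2.99792458e8  # m/s


@dataclass(frozen=True)
class OpticalMaterial:
    """Tabulated complex refractive index of one material.

    ``n`` is the real refractive index and ``k`` the extinction coefficient, on
    a strictly increasing vacuum-wavelength grid in nm.
    """

    name: str
    wavelengths_nm: np.ndarray
    n: np.ndarray
    k: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths_nm, dtype=float)
        n = np.asarray(self.n, dtype=float)
        k = np.asarray(self.k, dtype=float)
        if lam.ndim != 1 or lam.size < 2:
            raise ValueError("material table needs at least two wavelength rows")
        if np.any(np.diff(lam) <= 0):
            raise ValueError(f"{self.name}: wavelengths must be strictly increasing")
        if np.any(n <= 0) or np.any(k < 0):
            raise ValueError(f"{self.name}: requires n > 0 and k >= 0")
        object.__setattr__(self, "wavelengths_nm", lam)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "k", k)

    @property
    def valid_range_nm(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def _check_range(self, wavelength_nm: np.ndarray) -> None:
        lo, hi = self.valid_range_nm
        lam = np.asarray(wavelength_nm, dtype=float)
        if np.any(lam < lo) or np.any(lam > hi):
            raise ValueError(
                f"wavelength outside the tabulated range of {self.name!r} "
                f"({lo:g}-{hi:g} nm)"
            )

    def refractive_index(self, wavelength_nm):
        """Complex index ``n + i*k`` (physics convention), linearly interpolated.

        Interpolation is linear in ``n`` and ``k`` separately, not in eps.
        """
        self._check_range(wavelength_nm)
        lam = np.asarray(wavelength_nm, dtype=float)
        n = np.interp(lam, self.wavelengths_nm, self.n)
        k = np.interp(lam, self.wavelengths_nm, self.k)
        out = n + 1j * k
        return complex(out) if np.isscalar(wavelength_nm) else out


@dataclass(frozen=True)
class DrudeCorrectionConstants:
    """Free-electron constants entering the surface-scattering correction.

    Defaults are the standard values for gold: plasma frequency
    1.37e16 rad/s, Fermi velocity 1.4e6 m/s, bulk mean free path 4.2e-8 m and
    proportionality constant A = 1.
    """

    omega_p: float = 1.37e16  # plasma angular frequency [rad/s]
    v_F: float = 1.4e6  # Fermi velocity [m/s]
    L_inf: float = 4.2e-8  # bulk electron mean free path [m]
    A: float = 1.0  # dimensionless geometry constant

    def __post_init__(self) -> None:
        if min(self.omega_p, self.v_F, self.L_inf, self.A) <= 0:
            raise ValueError("all Drude correction constants must be positive")


GOLD_DRUDE = DrudeCorrectionConstants()

_CACHE: dict[str, OpticalMaterial] = {}
_ALIASES = {
    "au": "gold",
    "sio2": "silica",
    "h2o": "water",
    "tio2": "titania",
}


def available_materials() -> list[str]:
    files = resources.files("nanotherm.data")
    return sorted(p.name[:-4] for p in files.iterdir() if p.name.endswith(".csv"))


def get_material(name: str) -> OpticalMaterial:
    """Load a bundled material table by name (``gold``, ``silica``, ``water``,
    ``titania``; a few chemical aliases are accepted)."""
    key = _ALIASES.get(name.lower(), name.lower())
    if key not in _CACHE:
        ref = resources.files("nanotherm.data") / f"{key}.csv"
        try:
            text = ref.read_text()
        except FileNotFoundError:
            raise KeyError(
                f"unknown material {name!r}; available: {available_materials()}"
            ) from None
        rows = np.loadtxt(text.splitlines(), delimiter=",", skiprows=1)
        _CACHE[key] = OpticalMaterial(key, rows[:, 0], rows[:, 1], rows[:, 2])
    return _CACHE[key]


def _as_material(material) -> OpticalMaterial:
    return material if isinstance(material, OpticalMaterial) else get_material(material)


def bulk_dielectric(material, wavelength_nm):
    """Bulk complex dielectric ``eps1 + i*eps2`` at a vacuum wavelength in nm.

    Computed as the square of the interpolated complex index; the tabulated
    (n, k) pair enters as n - j k (engineering convention) and the result is
    conjugated once so that eps2 = 2 n k >= 0.
    """
    mat = _as_material(material)
    m = mat.refractive_index(wavelength_nm)
    return np.conjugate(np.conjugate(m) ** 2)  # (n - jk)^2 then flip to eps2 >= 0


def size_corrected_dielectric(
    material,
    wavelength_nm,
    L_eff_m: float,
    constants: DrudeCorrectionConstants = GOLD_DRUDE,
):
    """Dielectric function corrected for electron scattering at the surface.

    The bulk Drude damping contribution (collision rate ``v_F/L_inf``) is
    replaced by one with the enhanced rate ``v_F/L_inf + A*v_F/L_eff``:

        eps = eps_bulk + wp^2/(w^2 + i w g0) - wp^2/(w^2 + i w g_eff)

    ``L_eff_m`` is in meters; the correction vanishes as L_eff -> infinity.
    """
    if L_eff_m <= 0:
        raise ValueError("L_eff must be strictly positive")
    eps = bulk_dielectric(material, wavelength_nm)
    lam = np.asarray(wavelength_nm, dtype=float)
    omega = 2 * np.pi * SPEED_OF_LIGHT / (lam * 1e-9)
    g0 = constants.v_F / constants.L_inf
    g_eff = g0 + constants.A * constants.v_F / L_eff_m
    wp2 = constants.omega_p**2
    # in the eps2 >= 0 convention the +g0 term removes the bulk Drude loss and
    # the -g_eff term re-adds it with the enhanced collision rate
    out = eps + wp2 / (omega**2 + 1j * omega * g0) - wp2 / (omega**2 + 1j * omega * g_eff)
    return complex(out) if np.isscalar(wavelength_nm) else out
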