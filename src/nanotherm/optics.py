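"""Absorption of plasmonic nanoparticles: Mie spheres/nanoshells and Gans ellipsoids.

The Mie part evaluates the absorption efficiency of a concentric core-shell
particle,

    Qabs = (2/x2^2) * sum_n (2n+1) ( Re[a_n + b_n] - |a_n|^2 - |b_n|^2 ),

with the shell coefficients a_n, b_n written in terms of the Riccati-Bessel
functions psi, chi, xi and the auxiliary core terms A_n, B_n; a solid sphere is
the A_n = B_n = 0 special case.  Size parameters use the vacuum wavelength and
the (real) medium index; relative indices are particle index / medium index.
The series is truncated at the Wiscombe order nmax = ceil(x + 4 x^(1/3) + 2).

The Gans part evaluates the quasi-static absorption cross section of a prolate
spheroid (semiaxes lA > lB = lC) via the depolarization factors P_A, P_B, P_C;
for axis ratio r = 1 it reduces exactly to the Rayleigh dipole absorption of a
small sphere.  No retardation correction is applied, so the spheroid result is
quantitative only for particles well below the wavelength.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy import special as _sp
from scipy.optimize import curve_fit

from .materials import (
    GOLD_DRUDE,
    OpticalMaterial,
    bulk_dielectric,
    get_material,
    size_corrected_dielectric,
)

__all__ = [
    "SphereSpec",
    "ShellSpec",
    "EllipsoidSpec",
    "AbsorptionSpectrum",
    "PowerLawFit",
    "qabs_sphere",
    "qabs_shell",
    "gans_absorption",
    "depolarization_factors",
    "absorption_cross_section",
    "absorption_spectrum",
    "size_scaling",
    "fit_power_law",
]


# ---------------------------------------------------------------------------
# particle specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SphereSpec:
    """Solid sphere: diameter in nm, particle and medium material names."""

    diameter_nm: float
    material: Union[str, OpticalMaterial] = "gold"
    medium: Union[str, OpticalMaterial] = "water"

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0:
            raise ValueError("diameter must be positive")

    @property
    def radius_nm(self) -> float:
        return self.diameter_nm / 2


@dataclass(frozen=True)
class ShellSpec:
    """Concentric core-shell particle (radii in nm, core_radius < outer_radius)."""

    core_radius_nm: float
    outer_radius_nm: float
    core: Union[str, OpticalMaterial] = "silica"
    shell: Union[str, OpticalMaterial] = "gold"
    medium: Union[str, OpticalMaterial] = "water"

    def __post_init__(self) -> None:
        if not 0 < self.core_radius_nm < self.outer_radius_nm:
            raise ValueError("need 0 < core radius < outer radius")

    @property
    def shell_thickness_nm(self) -> float:
        return self.outer_radius_nm - self.core_radius_nm


@dataclass(frozen=True)
class EllipsoidSpec:
    """Prolate spheroid with semiaxes lA >= lB = lC, in nm."""

    semi_major_nm: float
    semi_minor_nm: float
    material: Union[str, OpticalMaterial] = "gold"
    medium: Union[str, OpticalMaterial] = "water"

    def __post_init__(self) -> None:
        if self.semi_minor_nm <= 0 or self.semi_major_nm < self.semi_minor_nm:
            raise ValueError("need semi_major >= semi_minor > 0 (prolate spheroid)")

    @property
    def axis_ratio(self) -> float:
        return self.semi_major_nm / self.semi_minor_nm

    @property
    def volume_nm3(self) -> float:
        return 4 / 3 * np.pi * self.semi_major_nm * self.semi_minor_nm**2


ParticleSpec = Union[SphereSpec, ShellSpec, EllipsoidSpec]


# ---------------------------------------------------------------------------
# Riccati-Bessel machinery (complex arguments)
# ---------------------------------------------------------------------------


def _psi(n, z):
    return z * _sp.spherical_jn(n, z)


def _dpsi(n, z):
    return _sp.spherical_jn(n, z) + z * _sp.spherical_jn(n, z, derivative=True)


def _chi(n, z):
    return -z * _sp.spherical_yn(n, z)


def _dchi(n, z):
    return -(_sp.spherical_yn(n, z) + z * _sp.spherical_yn(n, z, derivative=True))


def _xi(n, z):
    return _psi(n, z) - 1j * _chi(n, z)


def _dxi(n, z):
    return _dpsi(n, z) - 1j * _dchi(n, z)


def _nmax(x: float) -> int:
    """Wiscombe truncation order for size parameter x."""
    return int(np.ceil(x + 4 * x ** (1 / 3) + 2))


def _mie_coefficients(x1, x2, m1, m2, nmax):
    """Shell scattering coefficients a_n, b_n for n = 1..nmax.

    ``x1, x2`` are core/outer size parameters (medium-referenced), ``m1, m2``
    the core/shell indices relative to the medium.  ``x1 = 0`` or ``m1 == m2``
    selects the solid-sphere limit A_n = B_n = 0.
    """
    n = np.arange(1, nmax + 1)
    solid = x1 == 0 or m1 == m2
    if solid:
        An = Bn = np.zeros(nmax)
    else:
        u1, u2 = m1 * x1, m2 * x1
        An = (m2 * _psi(n, u2) * _dpsi(n, u1) - m1 * _dpsi(n, u2) * _psi(n, u1)) / (
            m2 * _chi(n, u2) * _dpsi(n, u1) - m1 * _dchi(n, u2) * _psi(n, u1)
        )
        Bn = (m2 * _psi(n, u1) * _dpsi(n, u2) - m1 * _dpsi(n, u1) * _psi(n, u2)) / (
            m2 * _dchi(n, u2) * _psi(n, u1) - m1 * _chi(n, u2) * _dpsi(n, u1)
        )
    w = m2 * x2
    pw, dpw = _psi(n, w), _dpsi(n, w)
    cw, dcw = _chi(n, w), _dchi(n, w)
    px, dpx = _psi(n, x2), _dpsi(n, x2)
    xx, dxx = _xi(n, x2), _dxi(n, x2)
    fa, dfa = pw - An * cw, dpw - An * dcw
    fb, dfb = pw - Bn * cw, dpw - Bn * dcw
    an = (px * dfa - m2 * dpx * fa) / (xx * dfa - m2 * dxx * fa)
    bn = (m2 * px * dfb - dpx * fb) / (m2 * xx * dfb - dxx * fb)
    return an, bn


def _qabs_qext_from_coeffs(an, bn, x2):
    n = np.arange(1, an.size + 1)
    w = 2 * n + 1
    qext = 2 / x2**2 * np.sum(w * (an + bn).real)
    qsca = 2 / x2**2 * np.sum(w * (np.abs(an) ** 2 + np.abs(bn) ** 2))
    return qext - qsca, qext


def _medium_index(medium, wavelength_nm) -> float:
    mat = medium if isinstance(medium, OpticalMaterial) else get_material(medium)
    nm = mat.refractive_index(wavelength_nm)
    if abs(complex(nm).imag) > 1e-12:
        raise ValueError("the surrounding medium must be lossless (real index)")
    return float(np.real(nm))


#: metals for which free-electron surface-scattering constants are known
METAL_DRUDE = {"gold": GOLD_DRUDE}


def _particle_index(material, wavelength_nm, size_correction, L_eff_nm):
    mat = material if isinstance(material, OpticalMaterial) else get_material(material)
    constants = METAL_DRUDE.get(mat.name)
    if size_correction and constants is not None:
        eps = size_corrected_dielectric(mat, wavelength_nm, L_eff_nm * 1e-9, constants)
    else:
        eps = bulk_dielectric(mat, wavelength_nm)
    return np.sqrt(eps)  # principal root keeps Im >= 0


def _qabs_sphere_scalar(spec: SphereSpec, lam: float, size_correction: bool):
    nm = _medium_index(spec.medium, lam)
    m = _particle_index(spec.material, lam, size_correction, spec.radius_nm) / nm
    x = 2 * np.pi * spec.radius_nm * nm / lam
    an, bn = _mie_coefficients(0.0, x, m, m, _nmax(x))
    return _qabs_qext_from_coeffs(an, bn, x)


def qabs_sphere(spec: SphereSpec, wavelength_nm, size_correction: bool = True):
    """Absorption efficiency of a solid sphere at one or many wavelengths.

    With ``size_correction`` the particle dielectric is surface-scattering
    corrected using L_eff = particle radius (only meaningful for metals; for
    lossless dielectrics leave it off).
    """
    if np.isscalar(wavelength_nm):
        return _qabs_sphere_scalar(spec, float(wavelength_nm), size_correction)[0]
    return np.array(
        [_qabs_sphere_scalar(spec, float(l), size_correction)[0] for l in wavelength_nm]
    )


def _qabs_shell_scalar(spec: ShellSpec, lam: float, size_correction: bool):
    nm = _medium_index(spec.medium, lam)
    # the surface correction applies to metal layers only: L_eff = layer
    # thickness for the shell, core radius for a metallic core
    m1 = _particle_index(spec.core, lam, size_correction, spec.core_radius_nm) / nm
    m2 = _particle_index(spec.shell, lam, size_correction, spec.shell_thickness_nm) / nm
    x1 = 2 * np.pi * spec.core_radius_nm * nm / lam
    x2 = 2 * np.pi * spec.outer_radius_nm * nm / lam
    an, bn = _mie_coefficients(x1, x2, m1, m2, _nmax(x2))
    return _qabs_qext_from_coeffs(an, bn, x2)


def qabs_shell(spec: ShellSpec, wavelength_nm, size_correction: bool = True):
    """Absorption efficiency of a core-shell particle (Qabs referenced to the
    outer geometric cross section)."""
    if np.isscalar(wavelength_nm):
        return _qabs_shell_scalar(spec, float(wavelength_nm), size_correction)[0]
    return np.array(
        [_qabs_shell_scalar(spec, float(l), size_correction)[0] for l in wavelength_nm]
    )


# ---------------------------------------------------------------------------
# Gans (prolate spheroid, quasi-static)
# ---------------------------------------------------------------------------


def depolarization_factors(axis_ratio: float) -> tuple[float, float, float]:
    """Depolarization factors (P_A, P_B, P_C) of a prolate spheroid.

    ``axis_ratio = lA/lB >= 1``; P_A + P_B + P_C = 1 exactly, with
    P_B = P_C = (1 - P_A)/2 and P_A <= 1/3 (equality at the sphere).
    """
    r = float(axis_ratio)
    if r < 1:
        raise ValueError("axis ratio must be >= 1 for a prolate spheroid")
    e2 = 1 - 1 / r**2
    if e2 < 0.0225:  # near-sphere: series in e^2 avoids cancellation in the log form
        pa = (1 - e2) * (
            1 / 3 + e2 / 5 + e2**2 / 7 + e2**3 / 9 + e2**4 / 11 + e2**5 / 13
        )
    else:
        e = np.sqrt(e2)
        pa = (1 - e2) / e2 * (np.log((1 + e) / (1 - e)) / (2 * e) - 1)
    pb = (1 - pa) / 2
    return (float(pa), float(pb), float(pb))


def _gans_scalar(spec: EllipsoidSpec, lam: float) -> float:
    nm = _medium_index(spec.medium, lam)
    eps_m = nm**2
    eps = bulk_dielectric(spec.material, lam)
    e1, e2 = eps.real, eps.imag
    total = 0.0
    for p in depolarization_factors(spec.axis_ratio):
        denom = (e1 + (1 - p) / p * eps_m) ** 2 + e2**2
        total += e2 / (p**2 * denom)
    return 2 * np.pi * spec.volume_nm3 * eps_m**1.5 / (3 * lam) * total


def gans_absorption(spec: EllipsoidSpec, wavelength_nm):
    """Quasi-static absorption cross section [nm^2] of a prolate spheroid."""
    if np.isscalar(wavelength_nm):
        return _gans_scalar(spec, float(wavelength_nm))
    return np.array([_gans_scalar(spec, float(l)) for l in wavelength_nm])


# ---------------------------------------------------------------------------
# spectra and size scaling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AbsorptionSpectrum:
    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str  # "efficiency" | "cross_section"

    @property
    def peak_wavelength_nm(self) -> float:
        return float(self.wavelengths_nm[int(np.argmax(self.values))])

    @property
    def peak_value(self) -> float:
        return float(np.max(self.values))

    def value_at(self, wavelength_nm: float) -> float:
        return float(np.interp(wavelength_nm, self.wavelengths_nm, self.values))


def absorption_cross_section(spec: ParticleSpec, wavelength_nm, size_correction=True):
    """Absorption cross section in nm^2 for any particle specification."""
    if isinstance(spec, SphereSpec):
        q = qabs_sphere(spec, wavelength_nm, size_correction)
        return q * np.pi * spec.radius_nm**2
    if isinstance(spec, ShellSpec):
        q = qabs_shell(spec, wavelength_nm, size_correction)
        return q * np.pi * spec.outer_radius_nm**2
    if isinstance(spec, EllipsoidSpec):
        return gans_absorption(spec, wavelength_nm)
    raise TypeError(f"unsupported particle spec {type(spec).__name__}")


def absorption_spectrum(
    spec: ParticleSpec,
    wavelengths_nm: Sequence[float],
    kind: str = "efficiency",
    size_correction: bool = True,
) -> AbsorptionSpectrum:
    """Scan Qabs (or sigma_abs) over a sorted wavelength grid; the peak is the
    grid argmax (no sub-grid interpolation)."""
    lam = np.asarray(wavelengths_nm, dtype=float)
    if lam.size == 0:
        raise ValueError("wavelength grid is empty")
    if np.any(np.diff(lam) <= 0):
        raise ValueError("wavelength grid must be sorted ascending")
    if kind not in ("efficiency", "cross_section"):
        raise ValueError("kind must be 'efficiency' or 'cross_section'")
    if isinstance(spec, EllipsoidSpec):
        if kind == "efficiency":
            raise ValueError("the spheroid model yields cross sections only")
        vals = gans_absorption(spec, lam)
    elif kind == "cross_section":
        vals = absorption_cross_section(spec, lam, size_correction)
    elif isinstance(spec, SphereSpec):
        vals = qabs_sphere(spec, lam, size_correction)
    else:
        vals = qabs_shell(spec, lam, size_correction)
    return AbsorptionSpectrum(lam, np.asarray(vals, dtype=float), kind)


def size_scaling(
    diameters_nm: Sequence[float] | None = None,
    wavelength_nm: float = 532.0,
    material="gold",
    medium="water",
    size_correction: bool = True,
):
    """sigma_abs(d) at a fixed wavelength for a family of solid spheres.

    Defaults follow the common green-laser benchmark: 25 log-spaced diameters
    from 10 to 1000 nm at 532 nm.  Returns (diameters, cross sections [nm^2]).
    """
    if diameters_nm is None:
        diameters_nm = np.logspace(1, 3, 25)
    d = np.asarray(diameters_nm, dtype=float)
    sig = np.array(
        [
            absorption_cross_section(
                SphereSpec(dd, material, medium), wavelength_nm, size_correction
            )
            for dd in d
        ]
    )
    return d, sig


@dataclass(frozen=True)
class PowerLawFit:
    alpha: float
    exponent: float
    residual_rms: float  # RMS of log-residuals
    space: str


def fit_power_law(
    diameters_nm: Sequence[float],
    cross_sections: Sequence[float],
    space: str = "linear",
) -> PowerLawFit:
    """Least-squares fit of sigma = alpha * d^exponent.

    ``space='linear'`` fits y = alpha*x^p directly on the linear scale (the
    absolute-residual objective, dominated by the largest particles, as
    produced by a plain nonlinear curve fit of data spanning decades);
    ``space='log'`` fits log sigma = log alpha + p log d with uniform weights.
    The residual RMS is always reported in log space so the two variants are
    comparable.
    """
    d = np.asarray(diameters_nm, dtype=float)
    y = np.asarray(cross_sections, dtype=float)
    if d.size < 3:
        raise ValueError("need at least 3 points for a power-law fit")
    if np.any(d <= 0) or np.any(y <= 0):
        raise ValueError("diameters and cross sections must be positive")
    if space == "log":
        p, loga = np.polyfit(np.log(d), np.log(y), 1)
        alpha = float(np.exp(loga))
        expo = float(p)
    elif space == "linear":
        p0, loga0 = np.polyfit(np.log(d), np.log(y), 1)  # log fit as start point
        popt, _ = curve_fit(
            lambda x, a, p: a * x**p, d, y, p0=[np.exp(loga0), p0], maxfev=20000
        )
        alpha, expo = float(popt[0]), float(popt[1])
    else:
        raise ValueError("space must be 'linear' or 'log'")
    resid = np.log(y) - (np.log(alpha) + expo * np.log(d))
    return PowerLawFit(alpha, expo, float(np.sqrt(np.mean(resid**2))), space)
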