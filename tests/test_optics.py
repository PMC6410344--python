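"""Mie sphere/nanoshell absorption, Gans spheroids, spectra and scaling fits."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanotherm.materials import bulk_dielectric
from nanotherm.optics import (
    AbsorptionSpectrum,
    EllipsoidSpec,
    ShellSpec,
    SphereSpec,
    absorption_cross_section,
    absorption_spectrum,
    depolarization_factors,
    fit_power_law,
    gans_absorption,
    qabs_shell,
    qabs_sphere,
    size_scaling,
)
from nanotherm.optics import _mie_coefficients, _nmax, _qabs_qext_from_coeffs

from _mie_oracle import bhmie_efficiencies


# ---------------------------------------------------------------------------
# Mie sphere
# ---------------------------------------------------------------------------


def test_lossless_particle_does_not_absorb():
    spec = SphereSpec(50.0, material="titania", medium="water")
    for lam in (450.0, 600.0, 800.0):
        assert abs(qabs_sphere(spec, lam, size_correction=False)) < 1e-10


def test_rayleigh_dipole_limit_small_gold_sphere():
    # closed-form small-particle oracle: Qabs = 4x Im[(m^2-1)/(m^2+2)]
    spec = SphereSpec(2.0)
    for lam in (450.0, 532.0, 650.0):
        nm = 1.33
        m = np.sqrt(bulk_dielectric("gold", lam)) / nm
        x = 2 * np.pi * 1.0 * nm / lam
        rayleigh = 4 * x * ((m**2 - 1) / (m**2 + 2)).imag
        got = qabs_sphere(spec, lam, size_correction=False)
        assert got == pytest.approx(rayleigh, rel=0.01)


def test_agrees_with_independent_mie_oracle(rng):
    # 10 random (diameter, wavelength) pairs vs the Bohren-Huffman-style code
    for _ in range(10):
        d = float(rng.uniform(5.0, 1000.0))
        lam = float(rng.uniform(420.0, 1050.0))
        spec = SphereSpec(d)
        nm = 1.33
        m = np.sqrt(bulk_dielectric("gold", lam)) / nm
        x = 2 * np.pi * (d / 2) * nm / lam
        _, _, q_oracle = bhmie_efficiencies(x, m)
        q = qabs_sphere(spec, lam, size_correction=False)
        assert q == pytest.approx(q_oracle, rel=1e-6)


def test_absorption_never_exceeds_extinction():
    for d, lam in [(40.0, 532.0), (200.0, 650.0), (1000.0, 532.0)]:
        nm = 1.33
        m = np.sqrt(bulk_dielectric("gold", lam)) / nm
        x = 2 * np.pi * (d / 2) * nm / lam
        an, bn = _mie_coefficients(0.0, x, m, m, _nmax(x))
        qabs, qext = _qabs_qext_from_coeffs(an, bn, x)
        assert 0.0 <= qabs <= qext


def test_series_is_converged_at_wiscombe_order():
    nm = 1.33
    lam = 532.0
    for d in (40.0, 1000.0, 3000.0):  # x up to ~20
        m = np.sqrt(bulk_dielectric("gold", lam)) / nm
        x = 2 * np.pi * (d / 2) * nm / lam
        q1, _ = _qabs_qext_from_coeffs(*_mie_coefficients(0.0, x, m, m, _nmax(x)), x)
        q2, _ = _qabs_qext_from_coeffs(*_mie_coefficients(0.0, x, m, m, _nmax(x) + 5), x)
        assert abs(q2 - q1) < 1e-8


# ---------------------------------------------------------------------------
# nanoshell
# ---------------------------------------------------------------------------


def test_degenerate_shell_equals_solid_sphere():
    shell = ShellSpec(10.0, 20.0, core="gold", shell="gold")
    sphere = SphereSpec(40.0)
    lam = np.arange(450.0, 801.0, 10.0)
    qs = qabs_shell(shell, lam, size_correction=False)
    qq = qabs_sphere(sphere, lam, size_correction=False)
    assert np.max(np.abs(qs - qq) / qq) < 1e-8


def test_vanishing_core_reduces_to_solid_sphere():
    shell = ShellSpec(1e-3, 15.0, core="silica", shell="gold")
    sphere = SphereSpec(30.0)
    lam = np.arange(450.0, 801.0, 10.0)
    qs = qabs_shell(shell, lam, size_correction=False)
    qq = qabs_sphere(sphere, lam, size_correction=False)
    assert np.max(np.abs(qs - qq) / qq) < 1e-4


def test_silica_gold_nanoshell_resonates_red_of_solid_sphere():
    lam = np.arange(450.0, 801.0, 1.0)
    shell_peak = absorption_spectrum(ShellSpec(10.0, 15.0), lam).peak_wavelength_nm
    sphere_peak = absorption_spectrum(SphereSpec(40.0), lam).peak_wavelength_nm
    assert shell_peak > sphere_peak + 30.0


def test_thinner_gold_shell_red_shifts_resonance():
    # 30 nm outer diameter, shell thickness from 10 nm down to 2 nm
    lam = np.arange(450.0, 1001.0, 1.0)
    peaks = []
    for thickness in (10.0, 7.0, 5.0, 3.0, 2.0):
        spec = ShellSpec(15.0 - thickness, 15.0)
        peaks.append(absorption_spectrum(spec, lam).peak_wavelength_nm)
    assert np.all(np.diff(peaks) > 0)


def test_invalid_shell_geometry_rejected():
    with pytest.raises(ValueError):
        ShellSpec(20.0, 15.0)


# ---------------------------------------------------------------------------
# Gans spheroids
# ---------------------------------------------------------------------------


def test_depolarization_factors_sphere_and_frozen_r2():
    assert depolarization_factors(1.0) == pytest.approx((1 / 3, 1 / 3, 1 / 3))
    pa, pb, pc = depolarization_factors(2.0)
    # scalar evaluation with e = sqrt(1 - 1/4): PA = 0.173564, PB = PC
    assert pa == pytest.approx(0.173564, abs=1e-6)
    assert pb == pc == pytest.approx(0.413218, abs=1e-6)


def test_depolarization_needle_limit():
    pa, pb, pc = depolarization_factors(1e6)
    assert pa == pytest.approx(0.0, abs=1e-9)
    assert pb == pytest.approx(0.5, abs=1e-9)


@settings(deadline=None, derandomize=True)
@given(st.floats(min_value=1.0, max_value=100.0))
def test_depolarization_factors_sum_to_one(r):
    pa, pb, pc = depolarization_factors(r)
    assert pa + pb + pc == pytest.approx(1.0, abs=1e-12)
    assert 0.0 <= pa <= 1 / 3 + 1e-12
    assert pb == pc


def test_sphere_limit_matches_rayleigh_absorption():
    spec = EllipsoidSpec(10.0, 10.0)
    for lam in (500.0, 600.0, 800.0):
        eps = bulk_dielectric("gold", lam)
        eps_m = 1.33**2
        v = spec.volume_nm3
        # quasi-static dipole absorption of a small sphere
        sigma = (
            18 * np.pi * v * eps_m**1.5 / lam * eps.imag / abs(eps + 2 * eps_m) ** 2
        )
        assert gans_absorption(spec, lam) == pytest.approx(sigma, rel=1e-6)


def test_long_axis_resonance_red_shifts_with_aspect_ratio():
    lam = np.arange(450.0, 1101.0, 1.0)
    peaks = []
    for r in (1.0, 2.0, 3.0, 4.0, 5.0):
        spec = EllipsoidSpec(10.0 * r, 10.0)
        s = absorption_spectrum(spec, lam, kind="cross_section")
        peaks.append(s.peak_wavelength_nm)
    assert np.all(np.diff(peaks) > 0)


def test_oblate_ratio_rejected():
    with pytest.raises(ValueError):
        EllipsoidSpec(5.0, 10.0)
    with pytest.raises(ValueError):
        depolarization_factors(0.5)


# ---------------------------------------------------------------------------
# spectra and power-law fit
# ---------------------------------------------------------------------------


def test_single_point_spectrum_peak_is_that_point():
    s = absorption_spectrum(SphereSpec(40.0), [532.0])
    assert s.peak_wavelength_nm == 532.0


def test_empty_or_unsorted_grid_rejected():
    with pytest.raises(ValueError):
        absorption_spectrum(SphereSpec(40.0), [])
    with pytest.raises(ValueError):
        absorption_spectrum(SphereSpec(40.0), [600.0, 500.0])


def test_sphere_peak_never_red_shifts_out_of_green_region():
    # the dipole resonance sits near 520 nm for small spheres; very large
    # spheres flatten and absorb preferentially toward the blue, so the argmax
    # may sit at the blue edge but never wanders red
    lam = np.arange(450.0, 701.0, 2.0)
    for d in (10.0, 40.0, 100.0, 400.0, 1000.0):
        peak = absorption_spectrum(SphereSpec(d), lam).peak_wavelength_nm
        assert 450.0 <= peak <= 620.0
    for d in (10.0, 40.0, 100.0):
        peak = absorption_spectrum(SphereSpec(d), lam).peak_wavelength_nm
        assert 480.0 <= peak <= 620.0


def test_power_law_exact_recovery():
    d = np.logspace(0.5, 2.5, 12)
    y = 2.0 * d**1.5
    for space in ("linear", "log"):
        fit = fit_power_law(d, y, space=space)
        assert fit.alpha == pytest.approx(2.0, rel=1e-8)
        assert fit.exponent == pytest.approx(1.5, rel=1e-8)
        assert fit.residual_rms < 1e-9


def test_small_particle_scaling_is_cubic():
    d, sig = size_scaling(np.logspace(np.log10(2), np.log10(20), 8), 532.0,
                          size_correction=False)
    fit = fit_power_law(d, sig, space="log")
    assert fit.exponent == pytest.approx(3.0, rel=0.10)


def test_decade_scaling_exponent_near_three_halves():
    d, sig = size_scaling()
    assert fit_power_law(d, sig).exponent == pytest.approx(1.46, abs=0.15)
    # the uniform log-log weighting sees the small-d cubic regime more
    assert fit_power_law(d, sig, space="log").exponent > 1.8


def test_power_law_input_validation():
    with pytest.raises(ValueError):
        fit_power_law([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        fit_power_law([1.0, 2.0, -3.0], [1.0, 2.0, 3.0])
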