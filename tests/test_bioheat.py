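"""Radial diffusion and Pennes solver against analytic and balance oracles."""
import numpy as np
import pytest

from nanotherm.bioheat import (
    BLOOD,
    LaserNPSource,
    RadialGrid,
    TISSUES,
    TissueProperties,
    gaussian_bolus,
    mass_to_number_density,
    np_heat_source,
    solve_np_diffusion,
    solve_pennes,
)


# ---------------------------------------------------------------------------
# grids and sources
# ---------------------------------------------------------------------------


def test_grid_validation():
    with pytest.raises(ValueError):
        RadialGrid.make(r_max=2e-3, tumor_radius=3e-3)
    with pytest.raises(ValueError):
        RadialGrid.make(n_nodes=10)


def test_shell_volumes_fill_the_sphere(small_grid):
    total = small_grid.shell_volumes.sum()
    assert total == pytest.approx(4 / 3 * np.pi * small_grid.r_max**3, rel=1e-12)


def test_mass_to_number_density_conversion():
    # 40 ug/mL of 40 nm-diameter gold spheres, by hand:
    # c = 0.04 / (19300 * 4/3 pi (20e-9)^3)
    per_particle = 19300 * 4 / 3 * np.pi * (20e-9) ** 3
    assert mass_to_number_density(0.04, 20e-9) == pytest.approx(
        0.04 / per_particle, rel=1e-12
    )


def test_heat_source_is_direct_product(small_grid):
    c = np.full(small_grid.r.size, 1e15)
    src = LaserNPSource(2e5, 1e-14)
    assert np_heat_source(c, src) == pytest.approx(2e6)
    assert np.all(np_heat_source(np.zeros_like(c), src) == 0.0)
    with pytest.raises(ValueError):
        np_heat_source(-c, src)


# ---------------------------------------------------------------------------
# nanoparticle diffusion
# ---------------------------------------------------------------------------


def test_zero_diffusivity_freezes_profile(small_grid):
    c0 = gaussian_bolus(small_grid, 1e9, 0.5e-3)
    res = solve_np_diffusion(small_grid, c0, 0.0, t_end=100.0)
    assert np.max(np.abs(res.final - c0)) < 1e-10 * c0.max()


def test_particle_number_conserved_without_generation(small_grid):
    c0 = gaussian_bolus(small_grid, 1e9, 0.5e-3)
    res = solve_np_diffusion(small_grid, c0, 6.2e-11, t_end=3600.0, outer_bc="neumann")
    totals = res.total_particles()
    assert np.max(np.abs(totals - totals[0])) / totals[0] < 1e-3


def test_gaussian_bolus_matches_heat_kernel_solution():
    # free diffusion of a Gaussian: stays Gaussian with variance s^2 + 2 D t
    D, sig, t = 1e-9, 0.5e-3, 200.0
    grid = RadialGrid.make(r_max=10e-3, tumor_radius=3e-3, n_nodes=401)
    c0 = np.exp(-grid.r**2 / (2 * sig**2))
    res = solve_np_diffusion(grid, c0, D, t_end=t, dt=0.25)
    s2 = sig**2 + 2 * D * t
    exact = (sig**2 / s2) ** 1.5 * np.exp(-grid.r**2 / (2 * s2))
    rms = np.sqrt(np.mean((res.final - exact) ** 2)) / exact.max()
    assert rms < 0.01


def test_concentration_stays_nonnegative(small_grid):
    c0 = gaussian_bolus(small_grid, 1e9, 0.2e-3)
    res = solve_np_diffusion(small_grid, c0, 1e-9, t_end=3600.0)
    assert np.all(res.concentration >= 0.0)


def test_generation_term_adds_particles(small_grid):
    c0 = np.zeros(small_grid.r.size)
    res = solve_np_diffusion(
        small_grid, c0, 0.0, t_end=10.0, generation_rate=30.0, outer_bc="neumann"
    )
    # 30 particles per m^3 per second over 10 s, uniform
    assert res.final == pytest.approx(300.0, rel=1e-9)


def test_diffusion_input_validation(small_grid):
    with pytest.raises(ValueError):
        solve_np_diffusion(small_grid, np.full(small_grid.r.size, -1.0))
    with pytest.raises(ValueError):
        solve_np_diffusion(small_grid, np.zeros(3))


# ---------------------------------------------------------------------------
# Pennes bioheat
# ---------------------------------------------------------------------------


def test_equilibrium_is_exact_without_sources(small_grid):
    res = solve_pennes(
        small_grid, None, t_end=120.0, dt=0.5, include_metabolic=False, n_snapshots=5
    )
    assert np.max(np.abs(res.temperature - BLOOD.temperature)) < 1e-9


def test_uniform_source_perfusion_balance(small_grid):
    # sealed boundary, uniform tissue: steady T = Tb + (Q0 + q_met)/(rho_b cp_b w_b)
    Q0 = 5e3
    res = solve_pennes(
        small_grid,
        np.full(small_grid.r.size, Q0),
        tissue_inside="muscle",
        tissue_outside="muscle",
        t_end=8000.0,
        dt=1.0,
        outer_bc="neumann",
    )
    mus = TISSUES["muscle"]
    expected = BLOOD.temperature + (Q0 + mus.q_met) / (BLOOD.rho * BLOOD.cp * mus.w_b)
    assert res.final[0] == pytest.approx(expected, rel=5e-3)
    assert np.ptp(res.final) < 1e-6  # spatially uniform


def test_maximum_principle_with_nonnegative_sources(small_grid, rng):
    Q = rng.uniform(0.0, 1e5, small_grid.r.size)
    res = solve_pennes(small_grid, Q, t_end=300.0, dt=1.0)
    assert res.temperature.min() >= BLOOD.temperature - 1e-9


def test_grid_convergence_of_centre_temperature():
    Q_of = lambda g: np.where(g.in_tumor, 5e4, 0.0)
    g1 = RadialGrid.make(n_nodes=121)
    g2 = RadialGrid.make(n_nodes=241)
    T1 = solve_pennes(g1, Q_of(g1), t_end=300.0, dt=0.5).final[0]
    T2 = solve_pennes(g2, Q_of(g2), t_end=300.0, dt=0.5).final[0]
    assert abs(T2 - T1) / abs(T1 - 37.0) < 0.005 / 0.37  # <0.5% of the rise


def test_more_perfusion_never_raises_peak_temperature(small_grid):
    Q = np.where(small_grid.in_tumor, 1e5, 0.0)
    peaks = []
    for scale in (0.5, 1.0, 2.0, 4.0):
        tum = TISSUES["tumor"]
        hot = TissueProperties(
            "tumor-scaled", tum.cp, tum.rho, tum.k, tum.w_b * scale, tum.q_met
        )
        res = solve_pennes(small_grid, Q, hot, hot, t_end=300.0, dt=1.0)
        peaks.append(res.peak_temperature)
    assert np.all(np.diff(peaks) <= 1e-9)


def test_np_heating_exceeds_damage_threshold_inside_tumor(small_grid):
    # the headline treatment scenario: 40 ug/mL bolus, 1 h diffusion,
    # 20 W/cm^2 at the plasmon peak for 10 min
    n_density = mass_to_number_density(0.04, 20e-9)
    total = n_density * 4 / 3 * np.pi * small_grid.tumor_radius**3
    c0 = gaussian_bolus(small_grid, total, 0.5e-3)
    dif = solve_np_diffusion(small_grid, c0, t_end=3600.0)
    src = np_heat_source(dif.final, LaserNPSource(20e4, 3.3e-15, 525.0))
    res = solve_pennes(small_grid, src, t_end=600.0, dt=1.0)
    inside = res.final[small_grid.in_tumor]
    assert inside.max() > 47.0  # ablation threshold crossed intratumorally
    assert inside.max() > res.final[-1]  # decays toward baseline with radius
    assert res.final[-1] == pytest.approx(37.0, abs=0.5)
    # threshold-crossing bookkeeping: the centre crosses 42 degC at some time
    assert np.isfinite(res.threshold_times[42.0][0])


def test_pennes_input_validation(small_grid):
    with pytest.raises(ValueError):
        solve_pennes(small_grid, None, t_end=-1.0)
    with pytest.raises(ValueError):
        TissueProperties("bad", -1.0, 1000.0, 0.5, 1e-3, 100.0)
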