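"""Regenerate the optical-constant fixture tables under src/nanotherm/data/.

Gold is the Lorentz-Drude analytic model of Rakic et al. (1998) evaluated on a
1 nm vacuum-wavelength grid; silica is the Malitson (1965) Sellmeier dispersion;
water and titania are constant real indices. Run from the repository root:

    python scripts/generate_optical_tables.py
"""
from __future__ import annotations

import pathlib

import numpy as np

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "nanotherm" / "data"

EV_PER_NM = 1239.841984  # photon energy [eV] = EV_PER_NM / wavelength [nm]

# Rakic et al. (1998) Lorentz-Drude oscillator parameters for Au, energies in eV
AU_WP = 9.03
AU_F = (0.760, 0.024, 0.010, 0.071, 0.601, 4.384)
AU_GAMMA = (0.053, 0.241, 0.345, 0.870, 2.494, 2.214)
AU_OMEGA = (0.000, 0.415, 0.830, 2.969, 4.304, 13.32)


def eps_gold(wavelength_nm: np.ndarray) -> np.ndarray:
    """Complex dielectric function of bulk gold, eps1 + i*eps2 with eps2 >= 0."""
    w = EV_PER_NM / np.asarray(wavelength_nm, dtype=float)
    eps = 1 - AU_F[0] * AU_WP**2 / (w * (w + 1j * AU_GAMMA[0]))
    for f, g, w0 in zip(AU_F[1:], AU_GAMMA[1:], AU_OMEGA[1:]):
        eps = eps + f * AU_WP**2 / ((w0**2 - w**2) - 1j * w * g)
    return eps


def n_silica(wavelength_nm: np.ndarray) -> np.ndarray:
    """Real refractive index of fused silica (Malitson 1965 Sellmeier fit)."""
    l2 = (np.asarray(wavelength_nm, dtype=float) / 1000.0) ** 2
    n2 = (
        1
        + 0.6961663 * l2 / (l2 - 0.0684043**2)
        + 0.4079426 * l2 / (l2 - 0.1162414**2)
        + 0.8974794 * l2 / (l2 - 9.896161**2)
    )
    return np.sqrt(n2)


def write_csv(name: str, lam: np.ndarray, n: np.ndarray, k: np.ndarray) -> None:
    path = OUT / f"{name}.csv"
    with open(path, "w") as fh:
        fh.write("wavelength_nm,n,k\n")
        for row in zip(lam, n, k):
            fh.write(f"{row[0]:.1f},{row[1]:.6f},{row[2]:.6f}\n")
    print(f"wrote {path} ({path.stat().st_size} bytes)")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    lam = np.arange(400.0, 1100.0 + 0.5, 1.0)
    m = np.sqrt(eps_gold(lam))  # principal root: Im >= 0 for eps2 >= 0
    write_csv("gold", lam, m.real, m.imag)

    lam_coarse = np.arange(400.0, 1100.0 + 0.5, 10.0)
    write_csv("silica", lam_coarse, n_silica(lam_coarse), np.zeros_like(lam_coarse))

    ends = np.array([400.0, 1100.0])
    write_csv("water", ends, np.full(2, 1.33), np.zeros(2))
    write_csv("titania", ends, np.full(2, 2.49), np.zeros(2))


if __name__ == "__main__":
    main()
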