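"""Independent Mie reference for a homogeneous sphere.

Bohren-Huffman-style algorithm: the logarithmic derivative D_n = psi_n'/psi_n
is built by downward recurrence and the Riccati-Bessel functions of the real
size parameter by upward recurrence.  This shares no code path (and no Bessel
routine) with the package implementation, which evaluates the Riccati-Bessel
functions directly at complex argument, so it serves as an algorithmically
independent oracle.
"""
from __future__ import annotations

import numpy as np


def bhmie_efficiencies(x: float, m: complex) -> tuple[float, float, float]:
    """(Qext, Qsca, Qabs) of a sphere with size parameter ``x`` and relative
    refractive index ``m`` (particle index / medium index, Im(m) >= 0)."""
    nmax = int(np.ceil(x + 4 * x ** (1 / 3) + 2))
    mx = m * x
    nmx = int(max(nmax, abs(mx)) + 16)
    D = np.zeros(nmx + 1, dtype=complex)
    for n in range(nmx, 0, -1):
        D[n - 1] = n / mx - 1.0 / (D[n] + n / mx)
    psi0, psi1 = np.cos(x), np.sin(x)  # psi_{-1}, psi_0
    chi0, chi1 = -np.sin(x), np.cos(x)
    xi1 = psi1 - 1j * chi1
    qext = qsca = 0.0
    for n in range(1, nmax + 1):
        psi = (2 * n - 1) / x * psi1 - psi0
        chi = (2 * n - 1) / x * chi1 - chi0
        xi = psi - 1j * chi
        an = ((D[n] / m + n / x) * psi - psi1) / ((D[n] / m + n / x) * xi - xi1)
        bn = ((D[n] * m + n / x) * psi - psi1) / ((D[n] * m + n / x) * xi - xi1)
        qext += (2 * n + 1) * (an + bn).real
        qsca += (2 * n + 1) * (abs(an) ** 2 + abs(bn) ** 2)
        psi0, psi1 = psi1, psi
        chi0, chi1 = chi1, chi
        xi1 = xi
    qext *= 2 / x**2
    qsca *= 2 / x**2
    return qext, qsca, qext - qsca
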