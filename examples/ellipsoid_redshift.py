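"""Red shift of the long-axis resonance of prolate gold spheroids.

Elongating a nanoparticle splits its resonance; the long-axis mode shifts red
roughly linearly with the axis ratio (quasi-static treatment via
depolarization factors), which is an alternative to core-shell layering for
tuning the absorption into the near infrared.
"""
import numpy as np

from nanotherm.optics import EllipsoidSpec, absorption_spectrum, depolarization_factors

lam = np.arange(450.0, 1100.0 + 0.5, 1.0)

print("axis ratio   P_A     peak [nm]")
for r in (1.0, 2.0, 3.0, 4.0, 5.0):
    spec = EllipsoidSpec(semi_major_nm=10.0 * r, semi_minor_nm=10.0)
    s = absorption_spectrum(spec, lam, kind="cross_section")
    pa = depolarization_factors(r)[0]
    print(f"   {r:.0f}       {pa:.4f}    {s.peak_wavelength_nm:.0f}")
# P_A < 1/3 weakens the restoring field along the long axis, so the resonance
# condition eps1 = -(1-P_A)/P_A * eps_m moves to longer wavelengths as r grows.
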