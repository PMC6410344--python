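"""Locate the plasmon resonance of a solid gold sphere and a silica-gold nanoshell.

The absorption efficiency Qabs is scanned over the visible band for the two
treatment-relevant particles: a 40 nm gold sphere and a 30 nm particle made of
a 20 nm silica core under a 5 nm gold shell, both in water.  The shell moves
the resonance ~70 nm to the red, which is what makes thin nanoshells
attractive for reaching the tissue transparency window.
"""
import numpy as np

from nanotherm.optics import ShellSpec, SphereSpec, absorption_spectrum

lam = np.arange(450.0, 800.0 + 0.5, 1.0)

sphere = absorption_spectrum(SphereSpec(diameter_nm=40.0), lam)
shell = absorption_spectrum(ShellSpec(core_radius_nm=10.0, outer_radius_nm=15.0), lam)

print(f"40 nm Au sphere      : peak {sphere.peak_wavelength_nm:.0f} nm, "
      f"Qabs = {sphere.peak_value:.3f}")
print(f"20 nm SiO2 + 5 nm Au : peak {shell.peak_wavelength_nm:.0f} nm, "
      f"Qabs = {shell.peak_value:.3f}")
print(f"red shift from the shell geometry: "
      f"{shell.peak_wavelength_nm - sphere.peak_wavelength_nm:.0f} nm")
# Qabs is the absorption cross section over the geometric cross section; the
# peak wavelength is where a continuous-wave laser couples heat most efficiently.
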