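"""Optical energy-loss function of liquid water and proton stopping power.

Builds the bundled Drude dielectric model, locates the collective
resonance of the optical ELF, verifies the f-sum electron count, and
evaluates the RPWBA stopping power at a few proton energies.
"""

import numpy as np

from microyd import build_dielectric_model, stopping_power

model = build_dielectric_model()

w = np.geomspace(8.0, 200.0, 5000)
elf = model.optical_elf(w)
print(f"optical ELF peak: {elf.max():.3f} at W = {w[np.argmax(elf)]:.1f} eV")
print(f"f-sum effective electrons/molecule: {model.effective_electrons():.3f}")
print(f"effective mean excitation energy:   {model.mean_excitation_energy_eV():.1f} eV")

print("\nproton stopping power (unrestricted LET) of liquid water:")
for T in (1.0, 10.0, 100.0, 1000.0):
    print(f"  T = {T:7.1f} MeV ->  SP = {stopping_power(model, T):7.4f} keV/um")

# The ELF peak near 21 eV is the collective valence resonance of liquid
# water that dominates soft proton energy losses; the stopping power falls
# roughly as 1/T up to ~1 GeV where the relativistic rise sets in.
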