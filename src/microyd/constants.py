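"""Physical constants and canonical model parameters.

All cross-section internals work in eV and cm; quantities cross module
boundaries in the units stated in the docstrings (MeV for proton kinetic
energy, keV for deposit-scale energies, keV/um for LET-like quantities).
"""

# Rest energies (eV)
ELECTRON_MC2_EV = 0.511e6
PROTON_MC2_EV = 938.272e6

# Bohr radius (cm)
BOHR_RADIUS_CM = 5.29177210903e-9

# hbar*c (eV cm) and classical electron radius (cm), used for the plasma energy
HBARC_EV_CM = 1.973269804e-5
ELECTRON_RADIUS_CM = 2.8179403262e-13

# Molecular density of unit-density liquid water (molecules / cm^3)
WATER_MOLECULAR_DENSITY_CM3 = 3.343e22

# Electrons per water molecule (f-sum target)
WATER_ELECTRONS_PER_MOLECULE = 10.0

# Mean excitation energy of liquid water (keV)
I_WATER_KEV = 0.078

# Chord-length relative variance of a sphere under mu-randomness
V_S_SPHERE = 0.125

# Electron cut-off energies Delta (keV) whose CSDA-like range equals the
# mean chord length 2d/3, per sphere diameter (nm).  Obtained from electron
# penetration-depth track-structure data; treated as bundled constants.
CANONICAL_DELTA_KEV = {10.0: 0.180, 100.0: 1.37, 1000.0: 5.56}

# Published summary fits for the straggling factor delta2(Delta) (keV in/out)
DELTA2_FIT_A = 0.0074
DELTA2_FIT_B = 0.174
DELTA2_FIT_C = 0.651
DELTA2_XAPSOS_B = 0.195
DELTA2_XAPSOS_C = 0.610


def kev_per_um_from_ev_cm2(sp_ev_cm2: float, n_per_cm3: float) -> float:
    """Convert a per-molecule stopping cross section (eV cm^2) to keV/um."""
    return sp_ev_cm2 * n_per_cm3 * 1.0e-7
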