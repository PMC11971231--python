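# Methods

This note records the model, its assumptions, the numerical choices, and
what the synthetic inputs do and do not establish.

## Model overview

The package computes single-event dose-mean lineal energies y_D for
monoenergetic protons (1 MeV–1 GeV) crossing spherical liquid-water sites
of diameter 10–1000 nm, and derives the low-dose TDRA quality factor
Q(T) = y_D(T)/y_D(T_ref) with T_ref = 100 MeV. The chain is:

1. **Dielectric response.** The energy-loss function ELF(W, q) =
   Im[−1/ε] of unit-density liquid water is written directly as a sum of
   Drude channel terms (a Ritchie–Howie-style optical-data model): five
   ionization shells (1b1, 3a1, 1b2, 2a1, 1a1) and five discrete
   excitation bands (A¹B₁, B¹A₁, Rydberg A+B, Rydberg C+D, diffuse band).
   Parameterizing the ELF per channel (rather than ε₂ and then dividing
   by |ε|²) makes the per-shell decomposition exactly additive, which the
   cross-section formulas require. Ionization channels disperse as
   E_res(q) = E_res + q in recoil-energy units, putting the channel
   maximum on the free-electron (Bethe) ridge W ≈ q at large q;
   excitation bands do not disperse and are cut off at a configurable
   recoil energy (default 100 eV), consistent with treating them as
   small-momentum-transfer collisions.

2. **Cross sections (RPWBA).** The differential ionization cross section
   per shell is the sum of a longitudinal term — the recoil integral of
   the shell ELF weighted by (q + mc²)/(q(q + 2mc²)) between the exact
   relativistic recoil limits — and a transverse term using the optical
   ELF with the factor ln(1/(1−β²)) − β². The stopping power is the first
   W-moment over all channels plus B_k·σ_k for the excitation bands,
   with B_k the band's transition (resonance) energy. The exact maximum
   δ-electron energy (with the 1 + 2γm/M + (m/M)² recoil denominator) is
   used throughout; the common 2mc²β²γ² approximation is exposed
   alongside.

3. **Microdosimetric assembly.** A site of diameter d has mean chord
   l̄ = 2d/3 and chord pdf c(l) = 2l/d² (μ-randomness), giving the
   constant chord relative variance V_s = 1/8. LET fluctuations across
   the site are neglected (V_LET = 0): the proton's energy loss over
   ≤1 μm is negligible compared with T ≥ 1 MeV. The mean deposit is
   ε̄ = f_ion·LET·l̄ and the total single-event relative variance
   V = V_s + δ₂/ε̄. A parametric straggling law with these two moments
   (Log-normal, Gamma, or zero-truncated Logistic) models the deposit
   distribution; y_D follows from its first two moments.

4. **Indirect events.** δ-electrons from protons passing outside the
   site contribute a toucher term: the mean of electron y_D(E, d) values
   weighted by the ionization cross-section frequency over E ∈ [Δ, E_max]
   (a Spencer–Attix-style lower cut-off). The electron y_D(E, d) surface
   is an explicit plug-in table; the bundled generator is synthetic (see
   below).

## Parameters and units

| quantity | value / default | unit | role |
|---|---|---|---|
| N (molecular density) | 3.343×10²² | cm⁻³ | converts per-molecule cross sections to macroscopic quantities |
| mc², Mc² | 0.511, 938.272 | MeV | electron/proton rest energies |
| I | 0.078 | keV | mean excitation energy (f_ion, Kellerer comparator) |
| V_s | 0.125 | — | spherical chord relative variance |
| Δ(d) | 0.180 / 1.37 / 5.56 at d = 10 / 100 / 1000 nm | keV | electron cut-off whose range equals l̄; bundled constants from track-structure penetration-depth data. Other diameters use log-log interpolation through the anchors (flagged by a warning — the electron-range inversion itself is not modelled) |
| excitation q cut-off | 100 | eV | recoil cap for excitation bands |

Internal units are eV and cm inside the dielectric/cross-section layer;
keV, nm and keV/μm at the microdosimetric surface.

### The Drude coefficient set

The coefficients live in `src/microyd/data/water_drude.yaml` and an
alternative parameterization is a config swap. The bundled set was
calibrated once against optical constraints: the f-sum recovers 10.00
electrons per molecule over [threshold, 10 keV] (in the one-electron-per-
molecule plasma-energy normalization, ħω_p = 6.789 eV); the optical ELF
peaks at 21.4 eV with height 1.10, in the band of the measured liquid-
water collective resonance; the K shell carries 1.75 effective electrons
in this window, reflecting the slow convergence of its dipole strength,
with the remainder assigned to the valence shells; excitations carry 0.45
electrons. The resulting effective mean excitation energy is 67 eV and
the stopping power agrees with Bethe theory (I = 78 eV) to within a few
per cent over 5–200 MeV. At 1 GeV the model runs ~12% above standard
tabulations: the printed small-angle transverse term carries no density-
effect correction and the longitudinal kernel exceeds the Møller result
for transfers above mc²; both are inherent to the adopted formulas, and
no corrections beyond the first-order Born treatment are applied.

## Straggling factor δ₂

δ₂ is the ratio of the second to the first (E + B_n)-weighted restricted
moments of the ionization cross sections, summed over shells, with the
ejected-electron energy restricted to E ≤ Δ (the cut-off is an electron
*range* criterion, so it caps the electron energy, not the total energy
transfer). Where Δ exceeds the kinematic maximum (T = 2 MeV with the
1000 nm site) the cut-off is clipped to E_max — the spectrum vanishes
beyond it — under an explicit `clip=True`; the strict contract rejects
it. Three closed-form comparators are exposed: Kellerer's
Δ/(2 ln(Δ/I)), the published Xapsos power law 0.195·Δ^0.610, and the
summary fit 0.0074 + 0.174·Δ^0.651 of the first-principles values.

With the bundled parameterization the energy-averaged δ₂ over
{2…1000} MeV is 0.058 / 0.234 / 0.600 keV at Δ = 0.180 / 1.37 / 5.56 keV:
below Kellerer's values at every cut-off (his 1/E² spectrum misses soft
collisions), nearly energy-independent for d ≤ 100 nm (spreads of 8% and
4%), and fitted by a + b·Δ^c with c = 0.665. Comparisons with the
Kellerer curve are made on the energy-averaged values, matching the use
of a single summary curve per cut-off.

## Direct-event moments: two readings of the chord convolution

The deposit distribution over chords can be read two ways, both
implemented:

- `single` (default): one straggling law with mean ε̄ = f_ion·LET·l̄ and
  the *total* V = V_s + V_δ — the reading in which the variance budget
  feeds the distribution parameters directly;
- `chord_convolved`: a mixture over chords, per-chord mean f_ion·LET·l
  and per-chord relative variance δ₂/(f_ion·LET·l), mixed against c(l).

For untruncated families both yield exactly
y_D,dir = f_ion·LET·(1 + V_s) + δ₂/l̄, which is why the choice is a flag
rather than a commitment. For the zero-truncated Logistic they differ
slightly (truncation before vs after mixing); the Monte-Carlo twin
follows the chord-convolved reading (chord first, then deposit) and is
checked against it. The truncated Logistic is the one family whose y_D
departs from the closed form — truncation removes the negative-deposit
tail and lowers the dose-mean — which is precisely what distinguishes it
from the practically identical Log-normal/Gamma pair.

f_ion appears both inside ε̄ and as the direct/indirect mixing weight, as
the model defines it; this possible double-counting is inherited
deliberately and not "corrected".

## Indirect term and the synthetic electron table

The upper limit of the indirect integral is the proton-kinematics E_max
(the printed electron-projectile convention (E + B_n)/2 is circular for
proton impact). The electron y_D(E, d) input is a pluggable CSV table.
The bundled generator is **synthetic**: an electron-LET-flavoured
magnitude curve through CSDA-like anchors, converted with the idealized
crosser relation y_D = (9/8)·y_F, a mild (d/100 nm)^−0.12 size factor,
and a seeded smooth multiplicative perturbation. It reproduces the
*structure* of the real input (positive, smooth, decreasing, covering
[Δ, E_max]) so the weighting, coverage checking and mixing logic can be
exercised reproducibly; it does **not** reproduce track-structure
electron microdosimetry, so total-y_D magnitudes that include the
indirect term are mechanics demonstrations, not predictions. No
acceptance quantity depends on the table's scale (Q at the reference is
scale-free; δ₂ and the chord statistics do not involve it).

The synthetic track-structure baseline generator plays the same role for
the comparison statistics: six smooth decreasing curves with per-source
multiplicative perturbations, four valid to 300 MeV and two to 1000 MeV,
so the baseline-membership switch at 300 MeV is exercised exactly.

## Numerics

- **Recoil integral.** The q-range spans up to twelve decades while the
  dispersing-channel ELF at fixed W is a Lorentzian ridge of half-width
  γ/2 near q = W − E_res. The integral is split into a log-grid piece
  below the ridge (exact for the 1/q plateau), an arctan-stretched ridge
  window (exact for the Lorentzian core in the trapezoid limit), and a
  log-grid tail; rows whose ridge centre sits within 4γ of zero use a
  plain log grid, which resolves the then-broad feature. Validated
  against adaptive quadrature over (T, W, shell) to ≲2% pointwise at the
  default 256 nodes; SP and δ₂ integrals are converged to ~0.3%
  (doubling all resolutions moves SP(100 MeV) by <0.1%).
- **Outer integrals.** Log-grid trapezoids (500 nodes for SP, 600 for
  δ₂) with an adaptive-quadrature alternative (`method="adaptive"`,
  rtol 10⁻⁴, integrated in ln E); the two schemes agree to 0.4% at
  100 MeV.
- **Spectra.** f(y) on 2048 log-spaced points; normalization and moments
  are taken in ln y so the Gamma family's integrable x^(κ−1) singularity
  at zero (κ = 1/V < 1 for realistic V) is handled.
- **Chord mixture.** 64-point Gauss–Legendre nodes against c(l).
- **Stability.** Recoil limits use cancellation-free forms
  (pc² − pc′² = W(2(T + Mc²) − W) and √(x²+m²) − m = x²/(√(x²+m²)+m)),
  accurate down to q_min ~ meV.
- **Truncated-Logistic moments** by quadrature over [0, μ + 60s];
  sampling by rejection of negatives, never clipping (clipping would
  bias the moments).
- **Determinism.** One counted generator per Monte-Carlo run keyed by
  the seed; sampling order fixed (chord, then deposit).

## Erlang → Gamma

The Erlang shape κ = 1/V is non-integer for every realistic V (V ≥ V_s =
0.125 gives κ ≤ 8 non-integral in general), so (κ−1)! is generalized to
Γ(κ); for integer κ the printed factorial-form density is recovered
bit-for-bit.

## Known limitations

- The dielectric coefficients are this package's own calibrated set; any
  published alternative can be swapped in via the YAML config, and
  quantities sensitive to the spectrum's shape (δ₂, SP) shift at the
  few-per-cent level across reasonable parameterizations.
- No Barkas/Bloch/shell corrections, no density-effect correction, no
  nuclear stopping: stopping powers are first-order Born, least accurate
  at the extreme ends of the 1 MeV–1 GeV range (≈ +12% at 1 GeV).
- Protons are assumed crossers with straight trajectories and constant
  LET across the site (V_LET = 0); no stopper/starter classes.
- Electron transport is entirely delegated to the y_D(E, d) table; with
  the synthetic table, indirect-term magnitudes are illustrative.
- Δ for non-canonical diameters is a log-log interpolation between three
  anchors, not an electron-range inversion.
- Kellerer's closed form is non-monotonic below Δ = e·I ≈ 0.21 keV;
  monotonicity claims for δ₂(Δ) apply above that.
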