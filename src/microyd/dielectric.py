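"""Dielectric response of liquid water as a sum of Drude oscillator channels.

The energy-loss function ELF(W, q) = Im[-1/eps(W, q)] is parameterized
directly as a sum of Drude-type channel terms, one per ionization shell and
per discrete excitation band (the Ritchie-Howie style of optical-data
model).  Each channel j contributes

    ELF_j(W, q) = A_j * g_j * W / [ (E_j(q)^2 - W^2)^2 + (g_j W)^2 ]   (W >= B_j)

with amplitude A_j (eV^2), width g_j (eV), resonance E_j(q) (eV) and onset
threshold B_j (eV).  Ionization channels disperse quadratically in momentum,
which in recoil-energy units is the linear shift E_j(q) = E_j + q placing
the channel maximum on the Bethe ridge W ~ q at large q; excitation bands
do not disperse and are meant to be restricted to small q by the caller.

Total ELF is the exact sum of per-channel terms, so the per-shell
decomposition needed by the cross-section module is additive by
construction.  A model instance is validated once at construction: the
optical f-sum must recover the nominal 10 electrons per water molecule
within the configured tolerance, and the ELF must be non-negative on a
coarse grid (guaranteed by non-negative amplitudes, still asserted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    ELECTRON_RADIUS_CM,
    HBARC_EV_CM,
    WATER_ELECTRONS_PER_MOLECULE,
    WATER_MOLECULAR_DENSITY_CM3,
)

IONIZATION = "ionization"
EXCITATION = "excitation"

#: upper limit (eV) of the optical f-sum quadrature; channels are
#: amplitude-normalized against this window, so the effective electron
#: count is evaluated over the same range.
FSUM_UPPER_EV = 1.0e4


@dataclass(frozen=True)
class OscillatorChannel:
    """One Drude channel of the liquid-water response.

    ``threshold_eV`` is the binding energy B_n for ionization shells and
    the band onset for excitations; the channel ELF vanishes below it.
    """

    kind: str
    label: str
    threshold_eV: float
    resonance_eV: float
    gamma_eV: float
    amplitude_eV2: float
    dispersion: str = "quadratic"  # "quadratic" | "none"

    def __post_init__(self) -> None:
        if self.kind not in (IONIZATION, EXCITATION):
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if self.threshold_eV <= 0:
            raise ValueError(f"{self.label}: threshold must be > 0")
        if self.gamma_eV <= 0:
            raise ValueError(f"{self.label}: width must be > 0")
        if self.amplitude_eV2 < 0:
            raise ValueError(f"{self.label}: amplitude must be >= 0")
        if self.dispersion not in ("quadratic", "none"):
            raise ValueError(f"{self.label}: unknown dispersion {self.dispersion!r}")

    def elf(self, W, q=0.0):
        """Channel ELF at energy transfer W (eV) and recoil energy q (eV).

        Vectorized over broadcastable ``W`` and ``q`` arrays.
        """
        W = np.asarray(W, dtype=float)
        q = np.asarray(q, dtype=float)
        if np.any(q < 0):
            raise ValueError("recoil energy q must be >= 0")
        if self.dispersion == "quadratic":
            e_res = self.resonance_eV + q
        else:
            e_res = np.broadcast_to(np.asarray(self.resonance_eV, float), q.shape)
        num = self.amplitude_eV2 * self.gamma_eV * W
        den = (e_res**2 - W**2) ** 2 + (self.gamma_eV * W) ** 2
        out = num / den
        return np.where(W >= self.threshold_eV, out, 0.0)


class DielectricModel:
    """Liquid-water dielectric model: channel set plus molecular density.

    Parameters
    ----------
    channels:
        Ordered oscillator channels; at least one ionization shell and one
        excitation band are required, labels must be unique.
    molecular_density_per_cm3:
        Number density N of water molecules.
    sum_rule_tolerance:
        Allowed fractional deviation of the optical f-sum effective
        electron count from 10 per molecule.
    """

    def __init__(
        self,
        channels: list[OscillatorChannel],
        molecular_density_per_cm3: float = WATER_MOLECULAR_DENSITY_CM3,
        sum_rule_tolerance: float = 0.10,
    ) -> None:
        if molecular_density_per_cm3 <= 0:
            raise ValueError("molecular density must be positive")
        labels = [c.label for c in channels]
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        kinds = {c.kind for c in channels}
        if IONIZATION not in kinds or EXCITATION not in kinds:
            raise ValueError("model needs >=1 ionization and >=1 excitation channel")
        self.channels = tuple(channels)
        self.molecular_density_per_cm3 = float(molecular_density_per_cm3)
        self.sum_rule_tolerance = float(sum_rule_tolerance)
        self._cache: dict = {}
        self._validate()

    # -- derived quantities -------------------------------------------------

    @property
    def ionization_channels(self) -> tuple[OscillatorChannel, ...]:
        return tuple(c for c in self.channels if c.kind == IONIZATION)

    @property
    def excitation_channels(self) -> tuple[OscillatorChannel, ...]:
        return tuple(c for c in self.channels if c.kind == EXCITATION)

    @property
    def min_threshold_eV(self) -> float:
        return min(c.threshold_eV for c in self.channels)

    @property
    def plasma_energy_eV(self) -> float:
        """Plasma energy hbar*omega_p (eV) at one electron per molecule;
        the f-sum in this normalization counts electrons per molecule."""
        return HBARC_EV_CM * math.sqrt(
            4.0 * math.pi * self.molecular_density_per_cm3 * ELECTRON_RADIUS_CM
        )

    # -- ELF ----------------------------------------------------------------

    def optical_elf(self, W, per_channel: bool = False):
        """ELF at q = 0 for energy transfer W (eV); total or per channel."""
        return self.elf(W, 0.0, per_channel=per_channel)

    def elf(self, W, q, per_channel: bool = False):
        """ELF(W, q), the exact sum of per-channel Drude terms.

        ``W`` must be positive (eV), ``q`` non-negative (eV); both may be
        broadcastable arrays.  With ``per_channel=True`` returns a dict
        label -> contribution alongside the total.
        """
        W_arr = np.asarray(W, dtype=float)
        if np.any(W_arr <= 0):
            raise ValueError("energy transfer W must be > 0")
        parts = {c.label: c.elf(W_arr, q) for c in self.channels}
        total = sum(parts.values())
        if per_channel:
            return total, parts
        return total

    # -- sum rule -----------------------------------------------------------

    def effective_electrons(self, w_max_ev: float = FSUM_UPPER_EV, n: int = 20000) -> float:
        """Optical f-sum electron count  (2 / pi Wp^2) Int W ELF(W,0) dW."""
        w0 = max(self.min_threshold_eV * 0.999, 1e-3)
        w = np.geomspace(w0, w_max_ev, n)
        integrand = w * self.optical_elf(w) * w  # extra w: d(ln w) measure
        integral = np.trapezoid(integrand, np.log(w))
        return 2.0 / (math.pi * self.plasma_energy_eV**2) * integral

    def mean_excitation_energy_eV(self) -> float:
        """Effective mean excitation energy I from the optical ELF,
        ln I = Int W ln(W) ELF dW / Int W ELF dW (dipole-Bethe definition)."""
        w0 = max(self.min_threshold_eV * 0.999, 1e-3)
        w = np.geomspace(w0, FSUM_UPPER_EV, 20000)
        elf = self.optical_elf(w)
        lnw = np.log(w)
        num = np.trapezoid(w * lnw * elf * w, lnw)
        den = np.trapezoid(w * elf * w, lnw)
        return math.exp(num / den)

    def _validate(self) -> None:
        z_eff = self.effective_electrons()
        z0 = WATER_ELECTRONS_PER_MOLECULE
        if abs(z_eff - z0) > self.sum_rule_tolerance * z0:
            raise ValueError(
                f"optical f-sum gives {z_eff:.3f} electrons/molecule, outside "
                f"{self.sum_rule_tolerance:.0%} of {z0:g}"
            )
        w = np.geomspace(max(self.min_threshold_eV, 1.0), 1e4, 64)
        q = np.linspace(0.0, 1e4, 64)
        grid = self.elf(w[:, None], q[None, :])
        if np.any(grid < 0) or not np.all(np.isfinite(grid)):
            raise ValueError("ELF is negative or non-finite on the validation grid")
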