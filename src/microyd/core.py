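"""Microdosimetric core: site geometry and chord statistics, the
straggling factor delta2, the restricted-LET fraction f_ion, the relative
variance budget, and the parametric energy-loss straggling distributions.

Energies at this module's boundary are in keV, site dimensions in nm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from . import born
from .born import ProtonKinematics
from .constants import (
    CANONICAL_DELTA_KEV,
    DELTA2_FIT_A,
    DELTA2_FIT_B,
    DELTA2_FIT_C,
    DELTA2_XAPSOS_B,
    DELTA2_XAPSOS_C,
    I_WATER_KEV,
    V_S_SPHERE,
)
from .dielectric import DielectricModel

# ---------------------------------------------------------------------------
# geometry


def delta_for_diameter(d_nm: float, table: dict[float, float] | None = None) -> float:
    """Electron cut-off energy Delta (keV) whose range equals the mean
    chord length of a sphere of diameter ``d_nm``.

    The three canonical diameters use bundled constants; other diameters
    are served by log-log interpolation through them (an approximation of
    the electron-range inversion, flagged with a warning outside and
    between the anchors).
    """
    table = dict(table or CANONICAL_DELTA_KEV)
    if d_nm in table:
        return table[d_nm]
    d_anchor = np.array(sorted(table))
    delta_anchor = np.array([table[d] for d in d_anchor])
    warnings.warn(
        f"Delta for d = {d_nm:g} nm interpolated log-log between bundled "
        "anchors (electron-range inversion not modelled)",
        stacklevel=2,
    )
    logd = math.log(d_nm)
    return float(
        np.exp(
            np.interp(
                logd, np.log(d_anchor), np.log(delta_anchor)
            )
        )
    )


@dataclass(frozen=True)
class TargetSphere:
    """Spherical water site of diameter d (nm) with its cut-off Delta (keV)."""

    d_nm: float
    delta_keV: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.d_nm > 0:
            raise ValueError("diameter must be > 0")
        if self.delta_keV is None:
            object.__setattr__(self, "delta_keV", delta_for_diameter(self.d_nm))
        if not self.delta_keV > 0:
            raise ValueError("Delta must be > 0")

    @property
    def lbar_nm(self) -> float:
        """Mean chord length 2d/3 under mu-randomness."""
        return 2.0 * self.d_nm / 3.0

    @property
    def lbar_um(self) -> float:
        return self.lbar_nm * 1.0e-3


class ChordDistribution:
    """Chord-length distribution c(l) = 2l/d^2 of a sphere under
    mu-randomness, supported on (0, d].

    Closed-form moments: mean 2d/3, relative variance 1/8 (independent of
    d); inverse-CDF sampling is l = d * sqrt(u).
    """

    def __init__(self, sphere: TargetSphere) -> None:
        self.sphere = sphere
        self.d = sphere.d_nm

    def pdf(self, l_nm):
        l_arr = np.asarray(l_nm, dtype=float)
        out = 2.0 * l_arr / self.d**2
        return np.where((l_arr > 0) & (l_arr <= self.d), out, 0.0)

    @property
    def mean(self) -> float:
        return 2.0 * self.d / 3.0

    @property
    def relative_variance(self) -> float:
        return 0.125

    def moment(self, k: int, n_quad: int = 20001) -> float:
        """k-th raw moment by quadrature of the pdf (cross-check of the
        closed forms; exact values are d^k * 2/(k+2))."""
        l = np.linspace(0.0, self.d, n_quad)
        return float(np.trapezoid(l**k * self.pdf(l), l))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """n inverse-CDF samples l = d * sqrt(u)."""
        return self.d * np.sqrt(rng.random(n))


# ---------------------------------------------------------------------------
# straggling factor delta2


def delta2_from_shell_spectra(shells, delta_keV: float) -> float:
    """delta2 (keV) from per-shell collision spectra: the ratio of the
    second to the first (E + B_n)-weighted moments of the DICS with the
    ejected-electron energy restricted to E <= Delta.

    ``shells`` is an iterable of (B_eV, E_eV, dsde) triples; E grids need
    not be shared.  The toy single-channel spectra used for validation go
    through the same code path.
    """
    d_ev = delta_keV * 1.0e3
    num = den = 0.0
    for b_ev, e_ev, dsde in shells:
        mask = e_ev <= d_ev
        if mask.sum() < 2:
            continue
        w = e_ev[mask] + b_ev
        num += float(np.trapezoid(w**2 * dsde[mask], e_ev[mask]))
        den += float(np.trapezoid(w * dsde[mask], e_ev[mask]))
    if den <= 0:
        raise ValueError("restricted collision spectrum has no support")
    return num / den * 1.0e-3


def delta2(
    model: DielectricModel | None,
    kin: ProtonKinematics | None,
    delta_keV: float,
    method: str = "rpwba",
    clip: bool = False,
    n_e: int = 600,
    n_q: int = 256,
) -> float:
    """Straggling factor delta2 (keV): dose-weighted mean energy deposited
    in a single collision, restricted to the cut-off Delta.

    Methods
    -------
    ``rpwba``
        First-principles moments of the ionization DICS (needs ``model``
        and ``kin``).  Delta must not exceed the maximum delta-electron
        energy unless ``clip=True``, which clips the cut-off to E_max
        (the spectrum vanishes beyond it anyway).
    ``kellerer``
        Delta / (2 ln(Delta/I)), the 1/E^2-spectrum closed form.
    ``xapsos``
        0.195 * Delta^0.610 (published summary fit).
    ``fitted``
        0.0074 + 0.174 * Delta^0.651 (the summary fit of the rpwba values).
    """
    if not delta_keV > 0:
        raise ValueError("Delta must be > 0")
    if method == "kellerer":
        if delta_keV <= I_WATER_KEV:
            raise ValueError("Kellerer's form needs Delta > I")
        return delta_keV / (2.0 * math.log(delta_keV / I_WATER_KEV))
    if method == "xapsos":
        return DELTA2_XAPSOS_B * delta_keV**DELTA2_XAPSOS_C
    if method == "fitted":
        return DELTA2_FIT_A + DELTA2_FIT_B * delta_keV**DELTA2_FIT_C
    if method != "rpwba":
        raise ValueError(f"unknown delta2 method {method!r}")
    if model is None or kin is None:
        raise ValueError("method 'rpwba' needs a dielectric model and kinematics")
    if delta_keV * 1e3 > kin.emax_eV:
        if not clip:
            raise ValueError(
                f"Delta = {delta_keV:g} keV exceeds E_max = {kin.emax_keV:.3g} keV "
                "(pass clip=True to clip the cut-off to E_max)"
            )
        delta_keV = kin.emax_eV * 1e-3
    cache = getattr(model, "_delta2_cache", None)
    if cache is None:
        cache = model._delta2_cache = {}
    key = (kin.T_MeV, round(delta_keV, 9), n_e, n_q)
    if key not in cache:
        shells = []
        for ch in model.ionization_channels:
            e_hi = min(delta_keV * 1e3, kin.emax_eV - ch.threshold_eV)
            if e_hi <= 0:
                continue
            e_grid = np.geomspace(1e-2, e_hi, n_e)
            e_grid[0] = 0.0
            dsde = born.dics(model, kin, e_grid, n_q=n_q).shells[ch.label].total
            shells.append((ch.threshold_eV, e_grid, dsde))
        cache[key] = delta2_from_shell_spectra(shells, delta_keV)
    return cache[key]


# ---------------------------------------------------------------------------
# restricted-LET fraction


def f_ion(kin: ProtonKinematics, delta_keV: float, i_keV: float = I_WATER_KEV) -> float:
    """Fraction of the proton energy loss retained inside the site: the
    restricted-to-unrestricted LET ratio with delta-ray corrections,

        f_ion = ln[E_max (Delta + Delta1 + Delta2) / I^2] / (2 ln[E_max/I])

    with Delta1 + Delta2 = (1 - Delta/E_max)(I + Delta).  Equals 1 exactly
    at Delta = E_max.
    """
    emax_keV = kin.emax_keV
    if not 0 < delta_keV <= emax_keV:
        raise ValueError(
            f"Delta must lie in (0, E_max]; got {delta_keV:g} keV with "
            f"E_max = {emax_keV:.4g} keV"
        )
    d12 = (1.0 - delta_keV / emax_keV) * (i_keV + delta_keV)
    val = math.log(emax_keV * (delta_keV + d12) / i_keV**2) / (
        2.0 * math.log(emax_keV / i_keV)
    )
    return min(val, 1.0)


# ---------------------------------------------------------------------------
# variance budget


@dataclass(frozen=True)
class VarianceBudget:
    """Relative-variance budget of the single-event deposit in the site.

    V = V_delta + V_s with the chord-length term V_s = 0.125 and LET
    fluctuations neglected (V_LET = 0 for thin sites); the straggling term
    is V_delta = delta2 / eps_bar with eps_bar = f_ion * LET * lbar.
    """

    sphere: TargetSphere
    f_ion: float
    let_keV_um: float
    delta2_keV: float
    V_s: float = V_S_SPHERE
    V_LET: float = 0.0

    @property
    def eps_bar_keV(self) -> float:
        return self.f_ion * self.let_keV_um * self.sphere.lbar_um

    @property
    def V_delta(self) -> float:
        return self.delta2_keV / self.eps_bar_keV

    @property
    def V(self) -> float:
        return self.V_delta + self.V_s


def variance_budget(
    sphere: TargetSphere,
    kin: ProtonKinematics,
    let_keV_um: float,
    delta2_keV: float,
) -> VarianceBudget:
    """Assemble the variance budget for a site crossed by protons of the
    given kinematics, unrestricted LET (keV/um) and straggling factor (keV)."""
    if let_keV_um <= 0 or delta2_keV < 0:
        raise ValueError("LET must be > 0 and delta2 >= 0")
    fi = f_ion(kin, min(sphere.delta_keV, kin.emax_keV))
    return VarianceBudget(
        sphere=sphere, f_ion=fi, let_keV_um=let_keV_um, delta2_keV=delta2_keV
    )


# ---------------------------------------------------------------------------
# straggling distributions

FAMILIES = ("lognormal", "erlang_gamma", "logistic")


@dataclass
class EnergyLossDistribution:
    """Parametric single-event energy-loss distribution with target mean
    eps_bar (keV) and relative variance V.

    Parameter identities (for the untruncated laws):
      lognormal     sigma = sqrt(ln(1+V)),  mu = ln(eps_bar) - sigma^2/2
      erlang_gamma  kappa = 1/V, lambda = 1/(V*eps_bar); (kappa-1)! is
                    generalized to Gamma(kappa) for non-integer shape
      logistic      mu = eps_bar, s = (sqrt(3)/pi) * eps_bar * sqrt(V),
                    truncated at 0 and renormalized (its support would
                    otherwise include negative deposits)
    """

    family: str
    eps_bar_keV: float
    V: float
    _frozen: object = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not (np.isfinite(self.eps_bar_keV) and np.isfinite(self.V)):
            raise ValueError("non-finite distribution parameters")
        if self.eps_bar_keV <= 0 or self.V <= 0:
            raise ValueError("eps_bar and V must be > 0")
        m, v = self.eps_bar_keV, self.V
        if self.family == "lognormal":
            sigma = math.sqrt(math.log1p(v))
            mu = math.log(m) - 0.5 * sigma**2
            self._frozen = stats.lognorm(s=sigma, scale=math.exp(mu))
        elif self.family == "erlang_gamma":
            kappa = 1.0 / v
            lam = 1.0 / (v * m)
            self._frozen = stats.gamma(a=kappa, scale=1.0 / lam)
        else:
            s = math.sqrt(3.0) / math.pi * m * math.sqrt(v)
            self._frozen = stats.logistic(loc=m, scale=s)

    # -- parameters ---------------------------------------------------------

    @property
    def truncated(self) -> bool:
        return self.family == "logistic"

    @property
    def params(self) -> dict[str, float]:
        m, v = self.eps_bar_keV, self.V
        if self.family == "lognormal":
            sigma = math.sqrt(math.log1p(v))
            return {"mu_lgn": math.log(m) - 0.5 * sigma**2, "sigma_lgn": sigma}
        if self.family == "erlang_gamma":
            return {"kappa": 1.0 / v, "lambda": 1.0 / (v * m)}
        return {"mu_log": m, "s": math.sqrt(3.0) / math.pi * m * math.sqrt(v)}

    @property
    def _trunc_norm(self) -> float:
        """Probability mass on x > 0 of the untruncated law."""
        return float(self._frozen.sf(0.0)) if self.truncated else 1.0

    # -- densities and moments ---------------------------------------------

    def pdf(self, x):
        x_arr = np.asarray(x, dtype=float)
        out = self._frozen.pdf(x_arr) / self._trunc_norm
        return np.where(x_arr >= 0, out, 0.0)

    def cdf(self, x):
        x_arr = np.asarray(x, dtype=float)
        if not self.truncated:
            return self._frozen.cdf(x_arr)
        out = (self._frozen.cdf(x_arr) - self._frozen.cdf(0.0)) / self._trunc_norm
        return np.clip(np.where(x_arr >= 0, out, 0.0), 0.0, 1.0)

    def moment(self, k: int) -> float:
        """k-th raw moment of the (truncated, renormalized) distribution."""
        if not self.truncated:
            if k == 1:
                return self.eps_bar_keV
            if k == 2:
                return self.eps_bar_keV**2 * (1.0 + self.V)
            return float(self._frozen.moment(k))
        mu = self.eps_bar_keV
        s = self.params["s"]
        hi = mu + 60.0 * s
        val, _ = integrate.quad(
            lambda x: x**k * self._frozen.pdf(x), 0.0, hi, limit=300
        )
        return val / self._trunc_norm

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """n deposits; the logistic is sampled by inverse CDF with
        rejection of negatives (exact truncated sampling, not clipping)."""
        if self.family == "lognormal":
            p = self.params
            return rng.lognormal(p["mu_lgn"], p["sigma_lgn"], n)
        if self.family == "erlang_gamma":
            p = self.params
            return rng.gamma(p["kappa"], 1.0 / p["lambda"], n)
        p = self.params
        out = np.empty(n)
        need = np.ones(n, dtype=bool)
        while need.any():
            m = int(need.sum())
            draw = rng.logistic(p["mu_log"], p["s"], m)
            out[need] = draw
            need[need] = draw <= 0.0
        return out


def make_straggling_distribution(
    family: str, eps_bar_keV: float, V: float
) -> EnergyLossDistribution:
    """Construct the straggling law of the requested family with mean
    eps_bar (keV) and relative variance V (moment-matched before any
    truncation)."""
    return EnergyLossDistribution(family=family, eps_bar_keV=eps_bar_keV, V=V)
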