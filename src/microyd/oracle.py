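"""Seeded Monte-Carlo twin of the direct-event analytics.

Per history: draw a chord l from c(l) = 2l/d^2 (inverse CDF l = d sqrt(u)),
draw a deposit x from the per-chord straggling distribution (mean
f_ion*LET*l, relative variance delta2/(f_ion*LET*l); the logistic is
rejection-sampled above zero), and record y = x / lbar.  Empirical y_F and
y_D with delta-method standard errors verify the analytic moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import core
from .born import ProtonKinematics
from .core import TargetSphere


@dataclass
class OracleRun:
    """One seeded direct-event simulation with its empirical moments."""

    seed: int
    n: int
    sphere: TargetSphere
    family: str
    y: np.ndarray
    y_F: float
    y_F_se: float
    y_D: float
    y_D_se: float

    def summary(self) -> dict:
        return {
            "seed": self.seed,
            "n": self.n,
            "d_nm": self.sphere.d_nm,
            "family": self.family,
            "y_F": self.y_F,
            "y_F_se": self.y_F_se,
            "y_D": self.y_D,
            "y_D_se": self.y_D_se,
        }


def _ratio_se(y: np.ndarray) -> tuple[float, float, float, float]:
    """(y_F, se(y_F), y_D, se(y_D)) with the delta-method error on the
    ratio y_D = <y^2>/<y>."""
    n = y.size
    m1 = y.mean()
    y2 = y * y
    m2 = y2.mean()
    v1 = y.var(ddof=1)
    v2 = y2.var(ddof=1)
    c12 = np.cov(y, y2, ddof=1)[0, 1]
    yd = m2 / m1
    var_yd = (v2 / m1**2 + m2**2 * v1 / m1**4 - 2.0 * m2 * c12 / m1**3) / n
    return float(m1), float(np.sqrt(v1 / n)), float(yd), float(np.sqrt(max(var_yd, 0.0)))


def simulate_direct(
    sphere: TargetSphere,
    kin: ProtonKinematics,
    let_keV_um: float,
    family: str,
    delta2_keV: float,
    seed: int,
    n: int,
) -> OracleRun:
    """Simulate ``n`` direct-event histories (n >= 1000) with one counted
    generator keyed by ``seed``; sampling order is fixed (chord first,
    then deposit) so runs replay bit-for-bit."""
    if n < 1000:
        raise ValueError("need at least 1000 histories")
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        raise ValueError("seed must be a non-negative integer")
    budget = core.variance_budget(sphere, kin, let_keV_um, delta2_keV)
    fl = budget.f_ion * let_keV_um
    rng = np.random.default_rng(seed)
    chords_nm = core.ChordDistribution(sphere).sample(rng, n)
    eps_l = fl * chords_nm * 1e-3  # per-chord mean deposit, keV
    v_l = delta2_keV / eps_l
    if family == "lognormal":
        sigma = np.sqrt(np.log1p(v_l))
        mu = np.log(eps_l) - 0.5 * sigma**2
        x = rng.lognormal(mu, sigma)
    elif family == "erlang_gamma":
        kappa = 1.0 / v_l
        x = rng.gamma(kappa, v_l * eps_l)
    elif family == "logistic":
        s = np.sqrt(3.0) / np.pi * eps_l * np.sqrt(v_l)
        x = rng.logistic(eps_l, s)
        neg = x <= 0.0
        while neg.any():
            x[neg] = rng.logistic(eps_l[neg], s[neg])
            neg = x <= 0.0
    else:
        raise ValueError(f"unknown family {family!r}")
    y = x / sphere.lbar_um
    y_f, y_f_se, y_d, y_d_se = _ratio_se(y)
    return OracleRun(
        seed=int(seed),
        n=n,
        sphere=sphere,
        family=family,
        y=y,
        y_F=y_f,
        y_F_se=y_f_se,
        y_D=y_d,
        y_D_se=y_d_se,
    )
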