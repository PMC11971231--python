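"""TDRA radiation quality from y_D curves, and model-comparison
statistics (per-energy relative difference RD and mean percentage
deviation MPD) against track-structure baselines.

In the Theory of Dual Radiation Action site model the RBE of a test
radiation against a reference is

    RBE = [sqrt((c yD_ref)^2 + 4 D (c yD_test + D)) - c yD_ref] / (2 D)

and in the low-dose limit the quality factor is the plain ratio
Q = yD_test / yD_ref.  The reference is a proton energy (100 MeV by
convention here), so Q(T) = yD(T) / yD(T_ref) with Q(T_ref) = 1.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_CSV_HEADER = ["energy_MeV", "yD_keV_per_um"]


@dataclass
class YdDataset:
    """A tabulated y_D(T) curve from one source with its validity range.

    Some track-structure codes are applicable only up to a maximum proton
    energy (e.g. 300 MeV); the baseline construction below drops a source
    at energies beyond its ``max_valid_energy_MeV``.
    """

    source: str
    energies_MeV: np.ndarray
    yd_keV_um: np.ndarray
    max_valid_energy_MeV: float = math.inf

    def __post_init__(self) -> None:
        self.energies_MeV = np.asarray(self.energies_MeV, dtype=float)
        self.yd_keV_um = np.asarray(self.yd_keV_um, dtype=float)
        if np.any(np.diff(self.energies_MeV) <= 0):
            raise ValueError(f"{self.source}: energies must be strictly increasing")
        if np.any(self.yd_keV_um <= 0):
            raise ValueError(f"{self.source}: y_D values must be positive")
        grid_max = self.energies_MeV[self.energies_MeV <= self.max_valid_energy_MeV]
        if grid_max.size == 0:
            raise ValueError(f"{self.source}: no grid point inside the valid range")

    def valid_at(self, T_MeV: float) -> bool:
        return (
            self.energies_MeV[0] <= T_MeV <= min(
                self.max_valid_energy_MeV, self.energies_MeV[-1]
            )
        )

    def interp(self, T_MeV: float) -> float:
        """Log-log linear interpolation inside the valid range only."""
        if not self.valid_at(T_MeV):
            raise ValueError(
                f"{self.source}: T = {T_MeV:g} MeV outside the valid range"
            )
        return float(
            np.exp(
                np.interp(
                    math.log(T_MeV),
                    np.log(self.energies_MeV),
                    np.log(self.yd_keV_um),
                )
            )
        )

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# source={self.source}\n")
            if math.isfinite(self.max_valid_energy_MeV):
                fh.write(f"# max_valid_energy_MeV={self.max_valid_energy_MeV:g}\n")
            pd.DataFrame(
                {_CSV_HEADER[0]: self.energies_MeV, _CSV_HEADER[1]: self.yd_keV_um}
            ).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "YdDataset":
        source = "unspecified"
        max_valid = math.inf
        lines = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    if "source=" in line:
                        source = line.split("source=", 1)[1].strip()
                    elif "max_valid_energy_MeV=" in line:
                        max_valid = float(line.split("=", 1)[1])
                    continue
                lines.append(line)
        try:
            df = pd.read_csv(io.StringIO("".join(lines)), float_precision="round_trip")
        except Exception as exc:
            raise ValueError(f"malformed y_D dataset: {exc}") from exc
        if list(df.columns) != _CSV_HEADER:
            raise ValueError(
                f"y_D dataset must have columns {_CSV_HEADER}, got {list(df.columns)}"
            )
        return cls(
            source=source,
            energies_MeV=df[_CSV_HEADER[0]].to_numpy(),
            yd_keV_um=df[_CSV_HEADER[1]].to_numpy(),
            max_valid_energy_MeV=max_valid,
        )


# ---------------------------------------------------------------------------
# TDRA


def rbe_tdra(yd_test: float, yd_ref: float, c: float, d_test_Gy: float) -> float:
    """TDRA site-model RBE of the test radiation at dose ``d_test_Gy``."""
    if yd_test <= 0 or yd_ref <= 0 or c <= 0:
        raise ValueError("y_D values and c must be positive")
    if d_test_Gy < 0:
        raise ValueError("dose must be non-negative")
    if d_test_Gy == 0.0:
        return yd_test / yd_ref
    a = c * yd_ref
    return (
        math.sqrt(a**2 + 4.0 * d_test_Gy * (c * yd_test + d_test_Gy)) - a
    ) / (2.0 * d_test_Gy)


def q_tdra(dataset: YdDataset, ref_energy_MeV: float = 100.0) -> pd.DataFrame:
    """Quality-factor curve Q(T) = y_D(T) / y_D(T_ref) on the dataset grid.

    The reference must lie inside the dataset's valid range; an off-grid
    reference is served by explicit log-log interpolation with a logged
    notice (never silent extrapolation).
    """
    if not dataset.valid_at(ref_energy_MeV):
        raise ValueError(
            f"reference energy {ref_energy_MeV:g} MeV outside the valid range "
            f"of {dataset.source}"
        )
    if ref_energy_MeV in dataset.energies_MeV:
        yd_ref = float(
            dataset.yd_keV_um[dataset.energies_MeV == ref_energy_MeV][0]
        )
    else:
        yd_ref = dataset.interp(ref_energy_MeV)
        log.warning(
            "reference %g MeV off the %s grid; log-log interpolated",
            ref_energy_MeV,
            dataset.source,
        )
    return pd.DataFrame(
        {"energy_MeV": dataset.energies_MeV, "Q": dataset.yd_keV_um / yd_ref}
    )


# ---------------------------------------------------------------------------
# baselines and comparison statistics


def mcts_baseline(datasets: list[YdDataset], T_MeV: float) -> tuple[float, list[str]]:
    """Arithmetic-mean y_D of the sources whose validity range covers
    ``T_MeV``, with the contributing source labels."""
    members = [ds for ds in datasets if ds.valid_at(T_MeV)]
    if not members:
        raise ValueError(f"no dataset valid at T = {T_MeV:g} MeV")
    vals = [ds.interp(T_MeV) for ds in members]
    return float(np.mean(vals)), [ds.source for ds in members]


@dataclass
class ComparisonResult:
    """Per-energy RD (%) and the aggregate MPD (%) of a candidate curve
    against the mean-of-sources baseline."""

    energies_MeV: np.ndarray
    rd_percent: np.ndarray
    baseline: np.ndarray
    membership: list[list[str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(self.energies_MeV.size)

    @property
    def mpd_percent(self) -> float:
        return float(np.mean(np.abs(self.rd_percent)))


def rd_mpd(
    candidate: YdDataset, datasets: list[YdDataset], energies_MeV=None
) -> ComparisonResult:
    """RD(T_i) = (y_D - ybar)/ybar * 100% per energy and MPD = mean |RD|,
    with ybar the arithmetic mean of the sources valid at each T_i."""
    if energies_MeV is None:
        energies_MeV = [T for T in candidate.energies_MeV if candidate.valid_at(T)]
    energies_MeV = np.asarray(energies_MeV, dtype=float)
    rd = np.empty_like(energies_MeV)
    base = np.empty_like(energies_MeV)
    membership = []
    for i, T in enumerate(energies_MeV):
        ybar, members = mcts_baseline(datasets, float(T))
        y = candidate.interp(float(T))
        rd[i] = (y - ybar) / ybar * 100.0
        base[i] = ybar
        membership.append(members)
    return ComparisonResult(
        energies_MeV=energies_MeV, rd_percent=rd, baseline=base, membership=membership
    )


# ---------------------------------------------------------------------------
# synthetic track-structure-like fixtures


def synth_mcts_datasets(
    seed: int,
    d_nm: float = 1000.0,
    energies_MeV=None,
    n_short: int = 4,
    n_long: int = 2,
    rel_spread: float = 0.08,
) -> list[YdDataset]:
    """Synthetic stand-ins for track-structure y_D(T) curves.

    Each source is one smooth decreasing y_D(T) curve (an LET-flavoured
    power-law shape with a relativistic flattening) times a per-source
    multiplicative perturbation; ``n_short`` sources are valid to 300 MeV
    and ``n_long`` to 1000 MeV, emulating the codes' stated energy limits.
    Synthetic data: fixture material, not physics output.
    """
    if energies_MeV is None:
        energies_MeV = np.geomspace(1.0, 1000.0, 25)
    energies_MeV = np.asarray(energies_MeV, dtype=float)
    rng = np.random.default_rng(seed)
    base = 20.0 * energies_MeV**-0.75 + 0.9 + 0.12 * np.log10(energies_MeV)
    base *= (1000.0 / d_nm) ** 0.15
    out = []
    for i in range(n_short + n_long):
        factor = rng.lognormal(0.0, rel_spread)
        tilt = rng.normal(0.0, 0.03)
        curve = base * factor * (energies_MeV / 100.0) ** tilt
        max_valid = 300.0 if i < n_short else 1000.0
        out.append(
            YdDataset(
                source=f"synthetic-mcts-{i}(seed={seed})",
                energies_MeV=energies_MeV,
                yd_keV_um=curve,
                max_valid_energy_MeV=max_valid,
            )
        )
    return out
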