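import numpy as np
import pytest

from microyd import born, core
from microyd.config import build_dielectric_model

#: proton energy set used for the straggling-factor systematics
DELTA2_ENERGIES_MEV = [2, 5, 10, 20, 50, 100, 400, 600, 800, 1000]
CANONICAL_DELTAS_KEV = [0.180, 1.37, 5.56]


@pytest.fixture(scope="session")
def model():
    """Bundled liquid-water dielectric model (validated at construction)."""
    return build_dielectric_model()


@pytest.fixture(scope="session")
def kin100():
    return born.proton_kinematics(100.0)


@pytest.fixture(scope="session")
def delta2_grid(model):
    """First-principles delta2 (keV) on the canonical (T, Delta) grid.

    Computed once per session; the cut-off is clipped to E_max where the
    kinematics demand it (T = 2 MeV at Delta = 5.56 keV).
    """
    out = {}
    for d_kev in CANONICAL_DELTAS_KEV:
        for t_mev in DELTA2_ENERGIES_MEV:
            kin = born.proton_kinematics(float(t_mev))
            out[(t_mev, d_kev)] = core.delta2(
                model, kin, d_kev, method="rpwba", clip=True
            )
    return out


@pytest.fixture(scope="session")
def delta2_averages(delta2_grid):
    """Energy-averaged delta2 per canonical cut-off."""
    return {
        d: float(np.mean([delta2_grid[(t, d)] for t in DELTA2_ENERGIES_MEV]))
        for d in CANONICAL_DELTAS_KEV
    }
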