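import numpy as np
import pytest

from cycbind.structure import ParamStructure
from cycbind.synth import build_toy_complex
from cycbind.thermo import ThermoState


@pytest.fixture(scope="session")
def thermo300():
    return ThermoState(300.0)


@pytest.fixture(scope="session")
def toy_complex():
    return build_toy_complex(30, 10, 4, seed=7)


def make_atoms(coords, charges=None, radii=None, lj_eps=None, lj_rmin_half=None,
               chains=None, names=None, res_ids=None):
    """Minimal ParamStructure builder for hand-constructed fixtures."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = coords.shape[0]
    if names is None:
        names = [f"X{i}" for i in range(n)]
    if res_ids is None:
        res_ids = np.arange(1, n + 1)
    return ParamStructure(
        serial=np.arange(1, n + 1),
        name=names,
        res_name=["TOY"] * n,
        res_id=res_ids,
        chain_id=chains if chains is not None else ["A"] * n,
        coord=coords,
        element=["C"] * n,
        charge=np.zeros(n) if charges is None else np.asarray(charges, float),
        gb_radius=np.full(n, 1.5) if radii is None else np.asarray(radii, float),
        lj_eps=np.zeros(n) if lj_eps is None else np.asarray(lj_eps, float),
        lj_rmin_half=np.full(n, 1.8) if lj_rmin_half is None else np.asarray(lj_rmin_half, float),
    )
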