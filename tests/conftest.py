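import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from gensmr.data import SMRData
from gensmr.geometry import StateSpace, TrapArray, build_exposure
from gensmr.model import ModelSpec, Parameters


@pytest.fixture
def rng():
    return np.random.default_rng(20170701)


@pytest.fixture
def tiny_geometry():
    """Two cameras, one live-trap, a 6x6 km state space."""
    ss = StateSpace(0.0, 6.0, 0.0, 6.0)
    cam = TrapArray("camera", [[2.0, 3.0], [4.0, 3.0]], np.ones((2, 3)))
    live = TrapArray("live", [[3.0, 3.0]], np.full((1, 1), 5.0))
    return ss, cam, live


@pytest.fixture
def tiny_dataset(tiny_geometry):
    """One marked individual, three unmarked records, A = 4; the enumerable
    instance used to validate the sampler against brute force."""
    ss, cam, live = tiny_geometry
    y_mark = np.array([[1]])
    y_res = np.zeros((1, 2, 3), dtype=int)
    y_res[0, 0, 0] = 1
    unmarked = pd.DataFrame(
        {"trap": [1, 1, 0], "occasion": [1, 2, 3], "obs_sex": [-1, -1, -1]}
    )
    exposure = build_exposure(live, cam, 1)
    data = SMRData(
        cameras=cam,
        live=live,
        exposure=exposure,
        y_mark=y_mark,
        y_resight_marked=y_res,
        marked_sex=[0],
        unmarked=unmarked,
    )
    params = Parameters(lam0_m=0.3, lam0_r=0.4, sigma_d=1.5, psi=0.6, p_sex=0.5)
    spec = ModelSpec(
        generalized=True,
        use_telemetry=False,
        use_transience=False,
        use_sex_constraint=False,
        A=4,
    )
    return ss, data, params, spec
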