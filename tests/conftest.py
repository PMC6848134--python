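import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from carbfact import default_params
from carbfact import synthetic_world as sw
from carbfact.grid_io import Grid, EnvStack


@pytest.fixture(scope="session")
def params_all():
    return default_params()


@pytest.fixture(scope="session")
def world():
    """Default 120x240 synthetic world plus its truth map."""
    env, masks = sw.generate_env(sw.WorldConfig(seed=11))
    truth = sw.generate_truth(env, default_params(), masks)
    return env, masks, truth


def make_env(
    sst_summer,
    sst_winter,
    sss_class=5.0,
    prod=0.015,
    depth=20.0,
    terrigenous=0,
    sss_class_winter=None,
    prod_winter=None,
):
    """Tiny EnvStack from scalars or arrays (broadcast to a common shape)."""
    arrs = [np.atleast_2d(np.asarray(a, dtype=float))
            for a in (sst_summer, sst_winter, sss_class, prod, depth)]
    shape = np.broadcast_shapes(*(a.shape for a in arrs))
    lat = 0.5 + np.arange(shape[0])
    lon = 0.5 + np.arange(shape[1])

    def g(v, dtype=float):
        return Grid(np.broadcast_to(np.atleast_2d(np.asarray(v, dtype=dtype)), shape).copy(),
                    lat, lon)

    return EnvStack(
        sst_summer=g(sst_summer),
        sst_winter=g(sst_winter),
        sss_class_summer=g(sss_class),
        sss_class_winter=g(sss_class if sss_class_winter is None else sss_class_winter),
        prod_summer=g(prod),
        prod_winter=g(prod if prod_winter is None else prod_winter),
        bathymetry=g(depth),
        terrigenous=g(terrigenous, dtype=np.int16),
    )
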