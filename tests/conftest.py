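import numpy as np
import pytest

from canopyflux.leaf import JarvisParams, LeafFunctionSet
from canopyflux.reconstruction import AngleDistribution, assemble_canopy
from canopyflux.synthetic import TruthConfig, default_allometry, gen_shoot_skeleton


@pytest.fixture(scope="session")
def truth_noiseless():
    return TruthConfig(seed=7, noise_sd={"aci": 0.0, "gs": 0.0,
                                         "allometry_area": 0.0})


@pytest.fixture(scope="session")
def allom():
    return default_allometry()


@pytest.fixture(scope="session")
def angles():
    return AngleDistribution.planophile()


@pytest.fixture(scope="session")
def funcs():
    return LeafFunctionSet(
        treatment="VD Fuji",
        na_vs_ppfdd=(0.025, 1.2),
        vcmax_vs_na=(30.0, 5.0),
        jmax_vs_na=(55.0, 20.0),
        rd_vs_na=(-0.3, 2.0),
        gsmax_vs_na=(0.15, 0.05),
        jarvis=JarvisParams(g_smax=0.4, K_ppfd=150.0, T_opt=27.0,
                            T_breadth=12.0, vpd0=1.6, vpd_slope=0.35))


@pytest.fixture(scope="session")
def small_scene(allom, angles):
    shoots = gen_shoot_skeleton(
        {"counts": {"long": 15, "short": 25}}, seed=11)
    return assemble_canopy(shoots, allom, angles, seed=11)


@pytest.fixture(scope="session")
def spherical_normals():
    rng = np.random.default_rng(123)
    v = rng.normal(size=(40000, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)
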