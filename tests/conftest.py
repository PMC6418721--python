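import numpy as np
import pytest

import monofilm as mf


@pytest.fixture(scope="session")
def lipid_params():
    return mf.fdppc_like_params()


@pytest.fixture(scope="session")
def lipid_curve(lipid_params):
    curve, _ = mf.simulate_lipid_isotherm(lipid_params, n_points=600)
    return curve


@pytest.fixture(scope="session")
def lipid_mono(lipid_curve):
    return mf.monotonize(lipid_curve)


@pytest.fixture(scope="session")
def gp_curve():
    curve, _ = mf.simulate_polymer_isotherm(mf.gp_like_params(), n_points=400)
    return curve


@pytest.fixture(scope="session")
def gp_mono(gp_curve):
    return mf.monotonize(gp_curve)


@pytest.fixture(scope="session")
def fgp_mono():
    curve, _ = mf.simulate_polymer_isotherm(mf.fgp_like_params(), n_points=400)
    return mf.monotonize(curve)


@pytest.fixture
def mix_10_1():
    return mf.mole_fractions(10, 1)


def random_noisy_curve(seed: int, n: int = 50) -> mf.IsothermCurve:
    """A compression run with injected pressure dips, for monotonize tests."""
    rng = np.random.default_rng(seed)
    areas = np.sort(rng.uniform(30, 150, n))[::-1]
    base = np.linspace(0, 40, n) ** 1.2
    dips = rng.normal(0, 2.0, n)
    pressures = np.maximum(base + dips, -0.5)
    return mf.IsothermCurve(areas=areas, pressures=pressures)
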