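
import pytest

import kappabind as kb
from kappabind.anisotropy import LabelConfig


@pytest.fixture(scope="session")
def fixture_constructs():
    return kb.fixtures()


@pytest.fixture(scope="session")
def hiv_emsa(fixture_constructs):
    return fixture_constructs["hiv_ltr_emsa"]


@pytest.fixture(scope="session")
def hiv_labeled(fixture_constructs):
    return fixture_constructs["hiv_ltr_labeled"]


@pytest.fixture(scope="session")
def nfkbia_labeled(fixture_constructs):
    return fixture_constructs["nfkbia_labeled"]


@pytest.fixture(scope="session")
def default_series():
    return kb.default_concentration_series()


def make_tandem_curves(construct, truth, seed, d_total=5.0, sigma=0.003, conc=None):
    """Forward + reverse labeled replicate triplets for a tandem construct."""
    conc = kb.default_concentration_series() if conc is None else conc
    fw = kb.generate_titration(
        truth,
        construct,
        LabelConfig.for_construct(construct, "forward"),
        d_total,
        conc,
        kb.NoiseModel(sigma=sigma, seed=seed),
    )
    rv = kb.generate_titration(
        truth,
        construct,
        LabelConfig.for_construct(construct, "reverse"),
        d_total,
        conc,
        kb.NoiseModel(sigma=sigma, seed=seed + 500),
    )
    return fw, rv
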