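import numpy as np
import pytest

from ribpet.beam import BeamConfig, build_sobp, implanted_activity_profile, sobp_pristine_set
from ribpet.decay import DecayMixture, Isotope, c11_beam_mixture


@pytest.fixture(scope="session")
def mix():
    return c11_beam_mixture()


@pytest.fixture(scope="session")
def pure_c11():
    return DecayMixture((Isotope("11C", 20.34 * 60.0, 1.0),))


@pytest.fixture(scope="session")
def beam_cfg():
    return BeamConfig()


@pytest.fixture(scope="session")
def sobp_pair(beam_cfg):
    """Matched SOBP dose profile and implanted-activity profile (defaults)."""
    pristines = sobp_pristine_set(beam_cfg, 12.0)
    weights, sobp = build_sobp(pristines, 12.0)
    components = [
        (w, beam_cfg.range_mm - k) for k, w in enumerate(weights) if w > 0
    ]
    activity = implanted_activity_profile(
        beam_cfg, sobp.depths, components=components
    )
    return {
        "pristines": pristines,
        "weights": weights,
        "sobp": sobp,
        "activity": activity,
    }


@pytest.fixture(scope="session")
def washout_times():
    """60-s PET frame centres over the 30 min after the end of irradiation."""
    return np.arange(30.0, 1800.0, 60.0)
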