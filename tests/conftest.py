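import numpy as np
import pytest

from swallowfnirs import nirs_core, synthgen


@pytest.fixture(scope="session")
def small_protocol():
    """One block, three positions, 8 swallows each — fast but complete."""
    return synthgen.ProtocolSpec(n_blocks=1, inter_block_rest=0.0)


@pytest.fixture(scope="session")
def tiny_protocol():
    """Two swallows per segment; epochs and ordinals still well defined."""
    return synthgen.ProtocolSpec(n_blocks=1,
                                 swallows_per_position_per_block=2,
                                 inter_block_rest=0.0)


@pytest.fixture(scope="session")
def small_session(small_protocol):
    return synthgen.generate_session(protocol=small_protocol, seed=42)


@pytest.fixture(scope="session")
def silent_conc(tiny_protocol):
    """Noise-free concentrations plus ground truth for oracle checks."""
    schedule = synthgen.make_schedule(tiny_protocol, seed=7)
    channels = synthgen.default_channels()
    conc, truth = synthgen.simulate_concentrations(
        schedule, channels, synthgen.HRFParams(),
        synthgen.NoiseParams.silent(), seed=7)
    return schedule, channels, conc, truth


@pytest.fixture(scope="session")
def optics():
    return nirs_core.default_optics()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
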