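import numpy as np
import pytest

from aptafret.fluorometry import ChannelSet, CrosstalkFactors, IntensityTable


@pytest.fixture
def channels() -> ChannelSet:
    return ChannelSet()


@pytest.fixture
def factors() -> CrosstalkFactors:
    return CrosstalkFactors(donor_leak=0.05, acceptor_direct=0.2)


@pytest.fixture
def double_table(channels) -> IntensityTable:
    """Double-labelled readings forward-built so the corrected output is 0.37."""
    i_aa, i_dd = 100.0, 63.0
    i_da = 37.0 + 0.2 * i_aa + 0.05 * i_dd
    return IntensityTable.from_records(
        [
            ("double", channels.ex_donor, channels.em_acceptor, i_da),
            ("double", channels.ex_acceptor, channels.em_acceptor, i_aa),
            ("double", channels.ex_donor, channels.em_donor, i_dd),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231)
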