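import numpy as np
import pytest

from nirspress.optics import HbSeries, SubjectMeta
from nirspress.protocol import (StimulusProtocol, build_default_layout,
                                generate_stimulus_sequence)


@pytest.fixture(scope="session")
def layout():
    return build_default_layout()


@pytest.fixture(scope="session")
def short_protocol():
    """A reduced protocol (30 s baseline, 5 trials/condition) for fast tests."""
    return generate_stimulus_sequence(
        StimulusProtocol(baseline_s=30.0, trials_per_condition=5), seed=7
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(layout, protocol, o2hb=None, hhb=None, rng=None, scale=0.1):
    """A HbSeries over the protocol's duration; random if arrays not given."""
    fs = layout.sampling_rate
    n = int(round(protocol.total_duration_s * fs))
    n_ch = len(layout.channels)
    if o2hb is None:
        r = rng or np.random.default_rng(0)
        o2hb = r.normal(0.0, scale, (n_ch, n))
    o2hb = np.asarray(o2hb, dtype=float)
    if hhb is None:
        hhb = -o2hb / 3.0  # typical antiphase companion; non-degenerate for SSR
    return HbSeries(
        o2hb=np.asarray(o2hb, dtype=float),
        hhb=np.asarray(hhb, dtype=float),
        time=np.arange(n) / fs,
        layout=layout,
        protocol=protocol,
        subject=SubjectMeta("test", "HC", 30.0),
    )
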