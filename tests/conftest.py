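import numpy as np
import pytest

from seizurewaves.recordings import ElectrodeLayout, Recording, micro_layout


@pytest.fixture
def small_layout():
    """3x3 micro grid, 0.4 mm pitch."""
    return micro_layout(n_side=3, pitch_mm=0.4)


@pytest.fixture
def two_channel_layout():
    return ElectrodeLayout(
        ids=("a", "b"), scale="micro",
        positions=np.array([[0.0, 0.0], [0.4, 0.0]]),
    )


def make_recording(samples, rate=500.0, onset=None, offset=None, layout=None):
    n, c = samples.shape
    dur = n / rate
    if layout is None:
        layout = ElectrodeLayout(
            ids=tuple(f"c{i}" for i in range(c)), scale="micro",
            positions=np.column_stack([np.arange(c) * 0.4, np.zeros(c)]),
        )
    return Recording(
        samples=samples, rate=rate,
        onset=dur * 0.25 if onset is None else onset,
        offset=dur if offset is None else offset,
        layout=layout,
    )
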