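import numpy as np
import pandas as pd
import pytest

from rsvperp.simulate import EventTable


def make_event_table(onset_times, classes, sampling_rate=100.0,
                     presentation_rate=10.0, session_ids=None, block_ids=None):
    """Hand-built event table for labeling / epoching tests."""
    onset_times = np.asarray(onset_times, dtype=float)
    n = len(onset_times)
    frame = pd.DataFrame({
        "onset_sample": np.round(onset_times * sampling_rate).astype(int),
        "onset_time": onset_times,
        "class": list(classes),
        "picture_id": np.arange(n),
        "block_id": block_ids if block_ids is not None else np.ones(n, dtype=int),
        "session_id": session_ids if session_ids is not None else np.ones(n, dtype=int),
    })
    return EventTable(frame, sampling_rate, presentation_rate)


@pytest.fixture
def rsvp_block_events():
    """A 100-stimulus 10 Hz block with two well-separated targets."""
    classes = ["nontarget"] * 100
    classes[30] = "target"
    classes[70] = "target"
    times = 1.0 + 0.1 * np.arange(100)
    return make_event_table(times, classes)
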