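from datetime import datetime, timedelta

import numpy as np
import pytest

from hrvidh.time_domain import RRISeries, Segment

MIDNIGHT = datetime(2022, 1, 1, 0, 0, 0)


def make_segment(intervals_ms, start=MIDNIGHT, excluded=None):
    """A single analysis segment spanning exactly the given intervals."""
    series = RRISeries.from_intervals(intervals_ms, start, excluded=excluded)
    end = start + timedelta(seconds=float(series.beat_times[-1]))
    return Segment(series, start, end, np.arange(len(intervals_ms)))


@pytest.fixture
def midnight():
    return MIDNIGHT


@pytest.fixture
def segment_factory():
    return make_segment
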