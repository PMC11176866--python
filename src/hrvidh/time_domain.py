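"""Time-domain HRV analysis of RR-interval series.

The chain implemented here mirrors standard short-term HRV practice:
ectopic exclusion by the >20 % rule, clock-aligned 5-minute segmentation
restricted to the night window (00:00-04:00 by default), per-segment
time-domain statistics (mean HR, SDNN, RMSSD, NN50, pNN50), and an
unweighted average across the night's segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime, time, timedelta
from typing import Optional, Sequence

import numpy as np

ECTOPIC_THRESHOLD = 0.20  # relative deviation from last accepted interval
SEGMENT_SECONDS = 300.0
NIGHT_START = time(0, 0)
NIGHT_END = time(4, 0)
MIN_SEGMENT_COMPLETENESS = 0.8


@dataclass
class RRISeries:
    """A beat-interval series with exclusion flags.

    ``beat_times[k]`` is the time (seconds from ``start_clock``) of the beat
    that *ends* interval ``k``; ``intervals[k]`` is that interval in ms.
    Exclusion never deletes data: flags mark intervals out of the analysis.
    """

    start_clock: datetime
    beat_times: np.ndarray          # seconds, strictly increasing
    intervals: np.ndarray           # ms, > 0
    excluded: np.ndarray = field(default=None)      # bool per interval
    exclusion_reason: np.ndarray = field(default=None)  # '', 'ectopic', 'artefact'
    ectopic_truth: Optional[np.ndarray] = None      # ground truth (synthetic only)

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.beat_times.shape != self.intervals.shape:
            raise ValueError("beat_times and intervals must have equal length")
        if len(self.intervals) and np.any(self.intervals <= 0):
            raise ValueError("intervals must be positive")
        if len(self.beat_times) > 1 and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if self.excluded is None:
            self.excluded = np.zeros(len(self.intervals), dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.exclusion_reason is None:
            self.exclusion_reason = np.array([""] * len(self.intervals), dtype=object)
        else:
            self.exclusion_reason = np.asarray(self.exclusion_reason, dtype=object)

    def __len__(self) -> int:
        return len(self.intervals)

    @classmethod
    def from_intervals(
        cls, intervals_ms: Sequence[float], start_clock: datetime, **kw
    ) -> "RRISeries":
        """Build a series from successive intervals; beat k ends at the
        cumulative sum of intervals 0..k."""
        iv = np.asarray(intervals_ms, dtype=float)
        return cls(start_clock=start_clock, beat_times=np.cumsum(iv) / 1000.0,
                   intervals=iv, **kw)

    @property
    def n_accepted(self) -> int:
        return int((~self.excluded).sum())


@dataclass
class Segment:
    """One clock-aligned analysis window of a parent series."""

    series: RRISeries
    window_start: datetime
    window_end: datetime
    indices: np.ndarray  # indices into series.intervals falling in the window

    @property
    def accepted_indices(self) -> np.ndarray:
        idx = self.indices
        return idx[~self.series.excluded[idx]]

    @property
    def duration_s(self) -> float:
        return (self.window_end - self.window_start).total_seconds()


@dataclass
class HRVParams:
    """The per-record HRV statistics; spectral fields are filled by
    :mod:`hrvidh.spectral`."""

    mean_hr: float = np.nan       # beats/min
    sdnn: float = np.nan          # ms
    rmssd: float = np.nan         # ms
    nn50: float = np.nan          # count
    pnn50: float = np.nan         # %
    tp: float = np.nan            # ms^2
    vlf: float = np.nan           # ms^2
    lf: float = np.nan            # ms^2
    hf: float = np.nan            # ms^2
    lf_hf_ratio: Optional[float] = None
    n_segments_averaged: int = 1

    FIELDS = ("mean_hr", "sdnn", "rmssd", "nn50", "pnn50",
              "tp", "vlf", "lf", "hf", "lf_hf_ratio")

    def as_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.FIELDS}


class NightCoverageError(Exception):
    """Recording does not cover any complete night segment."""


@dataclass
class NightSegmentation:
    segments: list
    n_dropped_incomplete: int
    status: str  # 'ok' or 'no_night_coverage'


def filter_ectopic(
    series: RRISeries,
    threshold: float = ECTOPIC_THRESHOLD,
    max_consecutive: int = 5,
) -> RRISeries:
    """Flag ectopic intervals: an interval deviating by more than
    ``threshold`` (default 20 %) from the most recent *accepted* interval is
    marked ``ectopic``.  The first interval has no predecessor and is never
    flagged.  Data are never removed, only flagged.

    Comparing against the last accepted interval prevents a single ectopic
    from cascading into the next normal beat, but leaves one failure mode:
    a corrupted interval at the very start would poison the reference and
    flag the entire recording.  As a safeguard, after ``max_consecutive``
    flags in a row the filter re-anchors by accepting the current interval.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    excluded = series.excluded.copy()
    reason = series.exclusion_reason.copy()
    if len(series) < 2:
        warnings.warn("series shorter than 2 intervals; nothing to filter")
        return replace(series, excluded=excluded, exclusion_reason=reason)
    iv = series.intervals
    ref = iv[0]
    run = 0
    for k in range(1, len(iv)):
        if excluded[k]:  # pre-existing artefact flag stays
            continue
        if abs(iv[k] - ref) / ref > threshold and run < max_consecutive:
            excluded[k] = True
            reason[k] = "ectopic"
            run += 1
        else:
            ref = iv[k]
            run = 0
    return replace(series, excluded=excluded, exclusion_reason=reason)


def _clock_at(series: RRISeries, seconds: float) -> datetime:
    return series.start_clock + timedelta(seconds=seconds)


def night_segments(
    series: RRISeries,
    night_start: time = NIGHT_START,
    night_end: time = NIGHT_END,
    segment_s: float = SEGMENT_SECONDS,
    min_completeness: float = MIN_SEGMENT_COMPLETENESS,
) -> NightSegmentation:
    """Cut the recording into consecutive clock-aligned ``segment_s`` windows
    lying entirely inside [night_start, night_end) and inside the recording.

    Windows start on multiples of ``segment_s`` past midnight, so segment
    boundaries are reproducible across devices and start times.  Segments
    with fewer accepted beats than ``min_completeness`` x the expected count
    (expected = window length / median accepted interval of the series) are
    dropped and counted.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    # recording span: from the start of the first interval to the last beat
    rec_start = _clock_at(
        series, float(series.beat_times[0]) - float(series.intervals[0]) / 1000.0
    )
    rec_end = _clock_at(series, float(series.beat_times[-1]))

    # candidate night windows for each calendar date the recording touches
    windows = []
    day = rec_start.date()
    while datetime.combine(day, time(0)) <= rec_end:
        night0 = datetime.combine(day, night_start)
        night1 = datetime.combine(day, night_end)
        t = night0
        while t + timedelta(seconds=segment_s) <= night1:
            w0, w1 = t, t + timedelta(seconds=segment_s)
            if w1 > rec_start and w0 < rec_end:  # overlaps the recording at all
                windows.append((w0, w1))
            t = w1
        day = day + timedelta(days=1)

    if not windows:
        return NightSegmentation([], 0, "no_night_coverage")

    accepted_iv = series.intervals[~series.excluded]
    median_nn_s = float(np.median(accepted_iv)) / 1000.0 if len(accepted_iv) else np.inf
    expected = segment_s / median_nn_s

    beat_clock_s = series.beat_times  # seconds from start_clock
    segs, dropped = [], 0
    for w0, w1 in windows:
        lo = (w0 - series.start_clock).total_seconds()
        hi = (w1 - series.start_clock).total_seconds()
        idx = np.where((beat_clock_s >= lo) & (beat_clock_s < hi))[0]
        seg = Segment(series, w0, w1, idx)
        # the completeness rule doubles as the coverage rule: a window only
        # partially covered by the recording cannot reach the beat quota
        if len(seg.accepted_indices) < min_completeness * expected:
            dropped += 1
            continue
        segs.append(seg)
    return NightSegmentation(segs, dropped, "ok" if segs else "no_night_coverage")


def time_domain(segment: Segment) -> HRVParams:
    """Time-domain statistics of one segment's accepted N-N intervals.

    Successive-difference statistics (RMSSD, NN50, pNN50) use only pairs of
    intervals that were adjacent in the original recording; an exclusion
    breaks the chain rather than bridging it.  SDNN is the population SD.
    """
    idx = segment.accepted_indices
    if len(idx) < 2:
        raise ValueError("segment needs at least 2 accepted intervals")
    nn = segment.series.intervals[idx]
    # originally-adjacent accepted pairs
    adjacent = np.diff(idx) == 1
    diffs = np.diff(nn)[adjacent]

    mean_nn = float(np.mean(nn))
    nn50 = int(np.sum(np.abs(diffs) > 50.0)) if len(diffs) else 0
    return HRVParams(
        mean_hr=60000.0 / mean_nn,
        sdnn=float(np.std(nn)),  # population SD
        rmssd=float(np.sqrt(np.mean(diffs ** 2))) if len(diffs) else 0.0,
        nn50=nn50,
        pnn50=100.0 * nn50 / len(nn),
        n_segments_averaged=1,
    )


def aggregate_night(per_segment: Sequence[HRVParams]) -> HRVParams:
    """Unweighted arithmetic mean of per-segment parameters.

    The LF:HF ratio is averaged as the mean of per-segment ratios (segments
    with an undefined ratio are skipped), not as the ratio of pooled band
    powers.
    """
    if not per_segment:
        raise ValueError("no segments to aggregate")
    out = HRVParams(n_segments_averaged=len(per_segment))
    for f in HRVParams.FIELDS:
        if f == "lf_hf_ratio":
            vals = [p.lf_hf_ratio for p in per_segment if p.lf_hf_ratio is not None]
            out.lf_hf_ratio = float(np.mean(vals)) if vals else None
        else:
            vals = [getattr(p, f) for p in per_segment]
            setattr(out, f, float(np.mean(vals)))
    return out
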