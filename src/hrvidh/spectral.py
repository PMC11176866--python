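"""Frequency-domain HRV: tachogram resampling, Welch PSD, band powers.

Settings follow short-term HRV convention: the accepted N-N intervals are
linearly interpolated onto a uniform 4-Hz grid, a Welch periodogram is
computed with 64-s Hann windows at 75 % overlap and per-window mean removal,
and band powers are Riemann bin sums of the one-sided density over

    VLF 0.003-0.04 Hz,  LF 0.04-0.15 Hz,  HF 0.15-0.40 Hz,

each band half-open ``[low, high)`` so shared edges are counted once.
Total power is the band-limited integral over [0.003, 0.40); because the
frequency bins partition that range, TP = VLF + LF + HF holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal

from .time_domain import HRVParams, Segment

SAMPLE_RATE_HZ = 4.0
WELCH_WINDOW_S = 64.0
WELCH_OVERLAP = 0.75
VLF_BAND = (0.003, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
TP_BAND = (0.003, 0.40)
MAX_GAP_S = 5.0


@dataclass
class Tachogram:
    """The RR signal on a uniform time grid (ms values, 4 Hz default)."""

    sample_rate: float
    samples: np.ndarray          # ms
    grid_times: np.ndarray       # s, relative to the segment window start
    low_quality: bool = False    # a gap between anchors exceeded MAX_GAP_S


@dataclass
class PSD:
    frequencies: np.ndarray      # Hz
    density: np.ndarray          # ms^2 / Hz, one-sided
    window_s: float = WELCH_WINDOW_S
    overlap: float = WELCH_OVERLAP
    taper: str = "hann"
    detrend: str = "constant"

    def total_power(self) -> float:
        """Trapezoidal integral of the density over the full grid."""
        return float(np.trapezoid(self.density, self.frequencies))


def resample_rri(
    segment: Segment,
    sample_rate: float = SAMPLE_RATE_HZ,
    max_gap_s: float = MAX_GAP_S,
) -> Tachogram:
    """Linearly interpolate the accepted intervals onto a uniform grid.

    Each accepted interval anchors the RR function at the time of the beat
    that ends it; excluded intervals contribute no anchors, so interpolation
    bridges them.  A bridged gap longer than ``max_gap_s`` marks the
    tachogram low-quality.
    """
    idx = segment.accepted_indices
    if len(idx) < 2:
        raise ValueError("need at least 2 accepted intervals to resample")
    series = segment.series
    t0 = (segment.window_start - series.start_clock).total_seconds()
    anchors_t = series.beat_times[idx] - t0
    anchors_v = series.intervals[idx]
    n = int(round(segment.duration_s * sample_rate))
    grid = np.arange(n) / sample_rate
    samples = np.interp(grid, anchors_t, anchors_v)
    low_q = bool(np.max(np.diff(anchors_t)) > max_gap_s) if len(idx) > 1 else False
    return Tachogram(sample_rate=sample_rate, samples=samples,
                     grid_times=grid, low_quality=low_q)


def welch_psd(
    tachogram: Tachogram,
    window_s: float = WELCH_WINDOW_S,
    overlap: float = WELCH_OVERLAP,
    taper: str = "hann",
) -> PSD:
    """Welch periodogram of the tachogram (one-sided density, ms^2/Hz).

    Mean removal per window; the density normalisation satisfies Parseval:
    the integral of the density over frequency approximates the variance of
    the detrended signal.
    """
    nperseg = int(round(window_s * tachogram.sample_rate))
    if len(tachogram.samples) < nperseg:
        raise ValueError(
            f"tachogram shorter than one Welch window ({nperseg} samples)"
        )
    freqs, dens = signal.welch(
        tachogram.samples,
        fs=tachogram.sample_rate,
        window=taper,
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)),
        detrend="constant",
        scaling="density",
    )
    return PSD(frequencies=freqs, density=dens,
               window_s=window_s, overlap=overlap, taper=taper)


def _band_integral(psd: PSD, low: float, high: float) -> float:
    """Riemann bin sum over the half-open band: each frequency bin with
    low <= f < high contributes density * bin width.  Bins partition the
    spectrum, so the three bands sum exactly to the [0.003, 0.40) total —
    a trapezoid would leave the gaps at band boundaries in no band."""
    mask = (psd.frequencies >= low) & (psd.frequencies < high)
    if not mask.any():
        return 0.0
    df = float(np.mean(np.diff(psd.frequencies)))
    return float(np.sum(psd.density[mask]) * df)


def band_powers(psd: PSD) -> HRVParams:
    """Integrate the PSD over the standard HRV bands.

    Returns a partial :class:`HRVParams` with tp, vlf, lf, hf and the LF:HF
    ratio filled in; the ratio is ``None`` (missing) when HF is zero.
    """
    if psd.frequencies[-1] < HF_BAND[1]:
        raise ValueError("PSD does not cover the HF band up to 0.40 Hz")
    vlf = _band_integral(psd, *VLF_BAND)
    lf = _band_integral(psd, *LF_BAND)
    hf = _band_integral(psd, *HF_BAND)
    tp = _band_integral(psd, *TP_BAND)
    ratio: Optional[float] = (lf / hf) if hf > 0 else None
    return HRVParams(tp=tp, vlf=vlf, lf=lf, hf=hf, lf_hf_ratio=ratio)


def spectral_params(segment: Segment, **kw) -> HRVParams:
    """Convenience: resample -> Welch -> band powers for one segment."""
    return band_powers(welch_psd(resample_rri(segment), **kw))
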