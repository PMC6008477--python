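"""Inter-beat interval estimation by short-term autocorrelation.

For each 2.5 s sub-segment ``u``, its first 1.5 s prefix ``u15`` is
cross-correlated against forward shifts of ``u``:

    R(i) = sum_j u15[j] * u[j + i],    i = 0 .. len(u) - 1,

with the sum truncated where ``j + i`` leaves the sub-segment.  The interval
estimate is the lag of the global maximum of ``R`` over lags strictly greater
than ``i0 = fs / 3`` samples (periods shorter than 1/3 s - heart rates of
180 bpm and above - are not searched), divided by the sampling rate.  An
episode yields up to eight interval estimates, one per sub-segment; the heart
rate is 60 over their median.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import PipelineConfig
from .preprocess import AxisSegment, SubSegment, subsegment

__all__ = [
    "RRSeries",
    "short_term_ac",
    "first_side_peak",
    "episode_rr",
    "heart_rate",
]


@dataclass
class RRSeries:
    """Inter-beat intervals recovered from one axis of one episode."""

    rr: np.ndarray  # seconds; only the sub-segments that produced a peak
    valid_count: int
    axis: str = ""
    episode_index: int = 0

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        if self.valid_count != self.rr.size:
            raise ValueError("valid_count must equal len(rr)")


def short_term_ac(
    u: np.ndarray, fs: float, prefix_s: float = 1.5
) -> np.ndarray:
    """Correlate the leading ``prefix_s`` seconds of ``u`` with ``u``.

    Returns ``R`` over non-negative lags 0 .. len(u)-1; overlap truncates
    naturally at the end of ``u``.
    """
    u = np.asarray(u, dtype=float)
    fs = float(fs)
    n15 = int(round(prefix_s * fs))
    if u.size < int(round(2.0 * fs)):
        raise ValueError("sub-segment must be at least 2 s long")
    u15 = u[:n15]
    # full cross-correlation; keep lags >= 0
    return np.correlate(u, u15, mode="full")[n15 - 1 :]


def first_side_peak(
    r: np.ndarray,
    fs: float,
    min_rr_s: float = 1.0 / 3.0,
    peak_frac: float = 0.5,
) -> Optional[float]:
    """Locate the first significant side peak of a correlation vector.

    Searches lags strictly greater than ``min_rr_s * fs`` samples and returns
    (in seconds) the smallest lag that is a strict local maximum of ``r`` and
    reaches at least ``peak_frac`` times the admissible-range maximum.  A
    period of ``T`` makes ``r`` peak near every multiple of ``T`` with nearly
    equal height, so the earliest significant peak - not the global argmax -
    identifies the fundamental.  Returns ``None`` when no admissible lag
    exists or the correlation is non-positive everywhere in the admissible
    range (e.g. an all-zero segment).
    """
    r = np.asarray(r, dtype=float)
    if r.size == 0:
        raise ValueError("empty correlation vector")
    i0 = fs * min_rr_s
    lags = np.arange(r.size)
    admissible = lags > i0
    if not admissible.any():
        return None
    r_adm = np.where(admissible, r, -np.inf)
    top = float(np.max(r_adm))
    if top <= 0:
        return None
    inner = r[1:-1]
    is_peak = np.zeros(r.size, dtype=bool)
    is_peak[1:-1] = (inner > r[:-2]) & (inner > r[2:])
    candidates = np.nonzero(is_peak & admissible & (r >= peak_frac * top))[0]
    best = int(candidates[0]) if candidates.size else int(np.argmax(r_adm))
    if r[best] <= 0:
        return None
    return best / fs


def episode_rr(
    seg: AxisSegment, config: Optional[PipelineConfig] = None
) -> RRSeries:
    """Estimate up to eight inter-beat intervals from one axis segment."""
    config = config or PipelineConfig()
    rr: list[float] = []
    for sub in subsegment(
        seg, config.sub_segment_s, config.sub_segment_overlap_s
    ):
        r = short_term_ac(sub.samples, sub.fs, config.ac_prefix_s)
        peak = first_side_peak(r, sub.fs, config.min_rr_s)
        if peak is not None:
            rr.append(peak)
    return RRSeries(
        rr=np.asarray(rr),
        valid_count=len(rr),
        axis=seg.axis,
        episode_index=seg.episode_index,
    )


def heart_rate(rr: RRSeries) -> float:
    """Heart rate in bpm: 60 over the median recovered interval.

    Returns ``nan`` when no sub-segment produced an interval; the feature
    assembly imputes missing rhythm features downstream.
    """
    if rr.valid_count < 1:
        return float("nan")
    return 60.0 / float(np.median(rr.rr))
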