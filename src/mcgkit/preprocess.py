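"""Signal conditioning and fixed-grid segmentation.

The conditioning chain is: brick-wall FFT band-pass (1-40 Hz) over the whole
recording, then subtraction of a 50-sample moving average to suppress the
residual breathing component.  Conditioned recordings are cut into
non-overlapping 10 s episodes; each episode is further cut into 2.5 s
sub-segments overlapping by 1.5 s (eight per episode at the nominal rate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import PipelineConfig
from .io import AXES, Condition, InertialRecording

__all__ = [
    "AxisSegment",
    "SubSegment",
    "Episode",
    "bandpass_brickwall",
    "remove_breathing",
    "preprocess_recording",
    "segment_episodes",
    "episode_axis_segments",
    "subsegment",
]


@dataclass
class Episode:
    """One 10 s, 6-axis window of a conditioned recording."""

    samples: np.ndarray  # (n, 6)
    fs: float
    index: int
    subject_id: str
    label: Optional[Condition] = None


@dataclass
class AxisSegment:
    """A single axis of one episode."""

    samples: np.ndarray  # 1-D
    fs: float
    axis: str
    episode_index: int
    subject_id: str


@dataclass
class SubSegment:
    """A 2.5 s window within an episode, used for periodicity estimation."""

    samples: np.ndarray  # 1-D
    fs: float
    episode_index: int
    sub_index: int


def bandpass_brickwall(
    x: np.ndarray, fs: float, lo: float, hi: float
) -> np.ndarray:
    """Brick-wall FFT band-pass: zero every bin with |f| < lo or |f| > hi.

    Output has the same length as the input.  The operation is idempotent and
    linear by construction.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if x.size < 2:
        raise ValueError("input must have at least 2 samples")
    if not (0 <= lo < hi < fs / 2):
        raise ValueError(f"need 0 <= lo < hi < fs/2; got lo={lo}, hi={hi}, fs={fs}")
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    spectrum[(freqs < lo) | (freqs > hi)] = 0.0
    return np.fft.irfft(spectrum, n=x.size)


def remove_breathing(x: np.ndarray, window: int = 50) -> np.ndarray:
    """Subtract a length-``window`` moving average (unit-sum all-ones kernel).

    Edges ('same' convolution support) divide by the actual number of samples
    under the kernel instead of ``window``, so a constant input maps to zero
    everywhere; the first and last ``window // 2`` samples remain
    edge-affected but are retained so downstream fixed-size operators see
    full-length segments.  The operator is linear.
    """
    x = np.asarray(x, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if x.size < window:
        raise ValueError(f"input shorter than the {window}-sample window")
    kernel = np.ones(window)
    coverage = np.convolve(np.ones_like(x), kernel, mode="same")
    return x - np.convolve(x, kernel, mode="same") / coverage


def preprocess_recording(
    rec: InertialRecording, config: Optional[PipelineConfig] = None
) -> InertialRecording:
    """Condition every axis of a recording (band-pass, then mean-subtract)."""
    config = config or PipelineConfig()
    out = np.empty_like(rec.samples)
    for k in range(rec.samples.shape[1]):
        filtered = bandpass_brickwall(
            rec.samples[:, k], rec.fs, config.band_lo_hz, config.band_hi_hz
        )
        out[:, k] = remove_breathing(filtered, config.mean_filter_len)
    return rec.with_samples(out)


def segment_episodes(
    rec: InertialRecording, episode_s: float = 10.0
) -> list[Episode]:
    """Cut a recording into consecutive non-overlapping episodes.

    The trailing partial window is dropped.
    """
    n_ep = int(round(episode_s * rec.fs))
    if rec.n_samples < n_ep:
        raise ValueError(
            f"recording has {rec.n_samples} samples; "
            f"one episode needs {n_ep}"
        )
    count = rec.n_samples // n_ep
    return [
        Episode(
            samples=rec.samples[i * n_ep : (i + 1) * n_ep],
            fs=rec.fs,
            index=i,
            subject_id=rec.subject_id,
            label=rec.label,
        )
        for i in range(count)
    ]


def episode_axis_segments(ep: Episode) -> list[AxisSegment]:
    """Split an episode into its six per-axis segments, in canonical order."""
    return [
        AxisSegment(
            samples=ep.samples[:, k],
            fs=ep.fs,
            axis=name,
            episode_index=ep.index,
            subject_id=ep.subject_id,
        )
        for k, name in enumerate(AXES)
    ]


def subsegment(
    seg: AxisSegment, sub_s: float = 2.5, overlap_s: float = 1.5
) -> list[SubSegment]:
    """Cut an axis segment into overlapping sub-segments.

    Windows of ``sub_s`` seconds start every ``sub_s - overlap_s`` seconds;
    every full window is kept (eight for a 10 s episode with the defaults).
    """
    if overlap_s >= sub_s:
        raise ValueError("overlap must be shorter than the sub-segment")
    n_sub = int(round(sub_s * seg.fs))
    step = int(round((sub_s - overlap_s) * seg.fs))
    n = seg.samples.size
    if n < n_sub:
        raise ValueError("segment shorter than one sub-segment")
    out = []
    sub_index = 0
    for start in range(0, n - n_sub + 1, step):
        out.append(
            SubSegment(
                samples=seg.samples[start : start + n_sub],
                fs=seg.fs,
                episode_index=seg.episode_index,
                sub_index=sub_index,
            )
        )
        sub_index += 1
    return out
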