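"""Rhythm features: HR, HRV indices, entropies and turning-point ratios.

Eighteen features are computed per axis segment:

====== =====================================================================
hr     60 / median of the recovered inter-beat intervals
hrv1   median absolute first-order difference of the intervals
hrv2   median absolute second-order difference of the intervals
hrv3   median absolute difference of the absolute first-order differences
apent  approximate entropy of the (downsampled) segment
spent  spectral entropy of the 1-11 Hz band after noise-floor removal
tpr01..tpr11  turning-point ratios of the segment through a filter bank
rritpr turning-point ratio of the interval series itself
====== =====================================================================

Missing values (episodes where too few intervals were recovered) are imputed
as 0 so the per-axis feature count stays fixed.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from .config import PipelineConfig
from .heartrate import RRSeries, episode_rr, heart_rate
from .preprocess import AxisSegment, bandpass_brickwall

__all__ = [
    "RHYTHM_FEATURE_NAMES",
    "hrv_features",
    "approximate_entropy",
    "spectral_entropy",
    "turning_point_ratio",
    "rri_tpr",
    "rhythm_block",
]

RHYTHM_FEATURE_NAMES: tuple[str, ...] = (
    ("hr", "hrv1", "hrv2", "hrv3", "apent", "spent")
    + tuple(f"tpr{m:02d}" for m in range(1, 12))
    + ("rritpr",)
)


def hrv_features(rr: RRSeries) -> tuple[float, float, float]:
    """Median-based variability indices of an interval series.

    Requires at least three recovered intervals; raises otherwise.
    """
    if rr.valid_count < 3:
        raise ValueError("need at least 3 intervals for HRV features")
    x = rr.rr
    d1 = np.diff(x)
    hrv1 = float(np.median(np.abs(d1)))
    hrv2 = float(np.median(np.abs(np.diff(x, n=2))))
    hrv3 = float(np.median(np.abs(np.diff(np.abs(d1)))))
    return hrv1, hrv2, hrv3


def approximate_entropy(x: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Approximate entropy ApEn(m, r) in the Pincus convention.

    Chebyshev distance, self-matches included:
    ``ApEn = Phi_m(r) - Phi_{m+1}(r)`` with ``Phi`` the average log fraction
    of templates within tolerance ``r``.
    """
    x = np.asarray(x, dtype=float)
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    n = x.size
    if n < 10 * m:
        raise ValueError(f"need at least {10 * m} samples for m={m}")

    dist = np.abs(x[:, None] - x[None, :])

    def phi(mm: int) -> float:
        k = n - mm + 1
        # Chebyshev distance between length-mm templates via running maxima
        d = dist[:k, :k].copy()
        for offset in range(1, mm):
            np.maximum(d, dist[offset : offset + k, offset : offset + k], out=d)
        counts = (d <= r).sum(axis=1)
        return float(np.mean(np.log(counts / k)))

    return phi(m) - phi(m + 1)


def spectral_entropy(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = (1.0, 11.0),
    noise_floor_frac: float = 1.0 / 6.0,
) -> float:
    """Shannon entropy (nats) of the normalized in-band power spectrum.

    The FFT periodogram is restricted to ``band``; bins below
    ``noise_floor_frac * max`` are discarded; the survivors are normalized to
    unit sum before the entropy is taken (so the value is invariant to
    amplitude scaling of the input).
    """
    x = np.asarray(x, dtype=float)
    if x.size < fs:
        raise ValueError("need at least 1 s of signal")
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    p = power[in_band]
    if p.size == 0 or p.max() <= 0:
        warnings.warn("all-zero spectrum in band; spectral entropy set to 0")
        return 0.0
    p = np.where(p < noise_floor_frac * p.max(), 0.0, p)
    p = p / p.sum()
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def _count_turning_points(x: np.ndarray) -> int:
    """Number of interior samples that are strict local extrema."""
    d = np.diff(x)
    return int(np.sum(d[:-1] * d[1:] < 0))


def turning_point_ratio(
    x: np.ndarray,
    band: Optional[tuple[float, float]] = None,
    fs: Optional[float] = None,
) -> float:
    """Fraction of interior samples that are strict turning points.

    ``band`` selects an optional brick-wall band-pass applied first (requires
    ``fs``); ``None`` is the identity scheme.  For an i.i.d. continuous series
    the expected value is 2/3.
    """
    x = np.asarray(x, dtype=float)
    if band is not None:
        if fs is None:
            raise ValueError("fs required when a band is given")
        x = bandpass_brickwall(x, fs, band[0], band[1])
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    return _count_turning_points(x) / (n - 2)


def rri_tpr(rr: RRSeries) -> float:
    """Turning-point ratio of the recovered interval series (identity filter)."""
    if rr.valid_count < 3:
        raise ValueError("need at least 3 intervals")
    return turning_point_ratio(rr.rr)


def rhythm_block(
    seg: AxisSegment, config: Optional[PipelineConfig] = None
) -> dict[str, float]:
    """Compute all 18 rhythm features for one axis segment.

    Interval-derived features that cannot be computed (silent segments) are
    imputed as 0; a warning is emitted.
    """
    config = config or PipelineConfig()
    rr = episode_rr(seg, config)

    out: dict[str, float] = {}
    if rr.valid_count >= 1:
        out["hr"] = heart_rate(rr)
    else:
        warnings.warn(
            f"{seg.subject_id} ep{seg.episode_index} {seg.axis}: "
            "no interval recovered; rhythm features imputed as 0"
        )
        out["hr"] = 0.0
    if rr.valid_count >= 3:
        out["hrv1"], out["hrv2"], out["hrv3"] = hrv_features(rr)
        out["rritpr"] = rri_tpr(rr)
    else:
        out["hrv1"] = out["hrv2"] = out["hrv3"] = 0.0
        out["rritpr"] = 0.0

    x = seg.samples
    xd = x[:: config.apent_downsample]
    sd = float(np.std(xd))
    if sd > 0:
        out["apent"] = approximate_entropy(
            xd, config.apent_m, config.apent_r_frac * sd
        )
    else:
        out["apent"] = 0.0

    out["spent"] = spectral_entropy(
        x, seg.fs, config.spent_band, config.spent_noise_floor_frac
    )
    for m, band in enumerate(config.tpr_bands, start=1):
        out[f"tpr{m:02d}"] = turning_point_ratio(x, band, seg.fs)

    return {name: out[name] for name in RHYTHM_FEATURE_NAMES}
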