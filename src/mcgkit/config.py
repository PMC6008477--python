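"""Pipeline configuration.

All tunable constants of the processing chain live in :class:`PipelineConfig`
so that every stage (preprocessing, segmentation, rhythm and morphology
feature extraction, classification) reads from a single, serialisable source
of truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

Band = tuple[float, float]

#: Ten band-pass tiles covering the 1-40 Hz pass band.  Scheme 1 of the
#: turning-point-ratio bank is the identity (no filtering); schemes 2-11 use
#: these tiles in order.
DEFAULT_BAND_TILES: tuple[Band, ...] = (
    (1.0, 5.0),
    (5.0, 10.0),
    (10.0, 15.0),
    (15.0, 20.0),
    (20.0, 25.0),
    (25.0, 30.0),
    (30.0, 35.0),
    (35.0, 40.0),
    (1.0, 20.0),
    (20.0, 40.0),
)

FOUR_CLASS = "four_class"
THREE_CLASS = "three_class"


@dataclass
class PipelineConfig:
    """Constants of the feature-extraction and evaluation pipeline.

    Durations are seconds, frequencies Hz, filter lengths samples.
    """

    # conditioning
    band_lo_hz: float = 1.0
    band_hi_hz: float = 40.0
    mean_filter_len: int = 50

    # segmentation
    episode_s: float = 10.0
    sub_segment_s: float = 2.5
    sub_segment_overlap_s: float = 1.5

    # heart-rate estimation
    ac_prefix_s: float = 1.5
    min_rr_s: float = 1.0 / 3.0  # lag floor: periods shorter than this rejected

    # spectral entropy
    spent_band: Band = (1.0, 11.0)
    spent_noise_floor_frac: float = 1.0 / 6.0

    # approximate entropy
    apent_m: int = 2
    apent_r_frac: float = 0.2  # tolerance as a fraction of the segment SD
    apent_downsample: int = 4

    # turning-point-ratio filter bank: None = identity, else band-pass
    tpr_bands: tuple[Optional[Band], ...] = (None,) + DEFAULT_BAND_TILES

    # energy filter bank: ten tiles plus the full pass band; schemes listed in
    # ``energy_smoothed`` are rectified and triangularly smoothed before the
    # energy is taken
    energy_bands: tuple[Band, ...] = DEFAULT_BAND_TILES + ((1.0, 40.0),)
    energy_smoothed: tuple[int, ...] = (5, 6, 7, 8, 9, 10)  # 0-based scheme ids
    energy_smooth_len: int = 101

    # local binary patterns
    lbp_spacings: tuple[int, ...] = (3, 21)

    # feature-set mode
    mode: str = FOUR_CLASS

    # classifiers
    svm_c_grid: tuple[float, ...] = (1.0, 10.0, 100.0)
    svm_gamma: str = "scale"
    svm_inner_cv: int = 3
    rf_n_estimators: int = 500

    def __post_init__(self) -> None:
        if self.band_lo_hz >= self.band_hi_hz:
            raise ValueError("band_lo_hz must be < band_hi_hz")
        for name in ("episode_s", "sub_segment_s", "ac_prefix_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sub_segment_overlap_s >= self.sub_segment_s:
            raise ValueError("overlap must be shorter than the sub-segment")
        if self.mean_filter_len < 1:
            raise ValueError("mean_filter_len must be >= 1")
        if any(s < 1 for s in self.lbp_spacings):
            raise ValueError("LBP spacings must be >= 1")
        if self.mode not in (FOUR_CLASS, THREE_CLASS):
            raise ValueError(f"mode must be {FOUR_CLASS!r} or {THREE_CLASS!r}")
        for band in self.energy_bands + tuple(b for b in self.tpr_bands if b):
            if band[0] >= band[1]:
                raise ValueError(f"invalid band {band}: low must be < high")

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        coerced = dict(data)
        for key in ("spent_band",):
            if key in coerced and coerced[key] is not None:
                coerced[key] = tuple(coerced[key])
        for key in ("tpr_bands", "energy_bands"):
            if key in coerced:
                coerced[key] = tuple(
                    tuple(b) if b is not None else None for b in coerced[key]
                )
        for key in ("energy_smoothed", "lbp_spacings", "svm_c_grid"):
            if key in coerced:
                coerced[key] = tuple(coerced[key])
        return cls(**coerced)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
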