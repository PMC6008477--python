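"""Assembly of per-axis feature blocks into per-segment feature vectors.

Per axis: 18 rhythm features, 11 energy features (four-class mode only) and
4 x 59 LBP histogram bins - 265 values in four-class mode, 254 in
three-class mode.  A segment vector concatenates the six axes in canonical
order (1590 / 1524 values), prefixing each column name with the axis.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .config import FOUR_CLASS, PipelineConfig
from .io import AXES, InertialRecording
from .morphology import N_LBP_BINS, energy_features, morphology_block
from .preprocess import (
    AxisSegment,
    Episode,
    episode_axis_segments,
    preprocess_recording,
    segment_episodes,
)
from .rhythm import RHYTHM_FEATURE_NAMES, rhythm_block

__all__ = [
    "axis_feature_names",
    "segment_feature_names",
    "build_axis_vector",
    "build_segment_vector",
    "extract_features",
]

META_COLUMNS = ("subject_id", "episode", "label")


def _lbp_block_names(config: PipelineConfig) -> list[str]:
    names = []
    for integrated in ("raw", "int"):
        for spacing in config.lbp_spacings:
            names.extend(
                f"lbp_{integrated}{spacing}_{b:02d}" for b in range(1, N_LBP_BINS + 1)
            )
    return names


def axis_feature_names(config: Optional[PipelineConfig] = None) -> list[str]:
    """Ordered feature names for one axis (265 or 254 entries)."""
    config = config or PipelineConfig()
    names = list(RHYTHM_FEATURE_NAMES)
    if config.mode == FOUR_CLASS:
        names += [f"ene{m:02d}" for m in range(1, len(config.energy_bands) + 1)]
    names += _lbp_block_names(config)
    return names


def segment_feature_names(config: Optional[PipelineConfig] = None) -> list[str]:
    """Ordered, axis-prefixed feature names for a full segment vector."""
    config = config or PipelineConfig()
    per_axis = axis_feature_names(config)
    return [f"{axis}_{name}" for axis in AXES for name in per_axis]


def build_axis_vector(
    seg: AxisSegment, config: Optional[PipelineConfig] = None
) -> np.ndarray:
    """Feature vector of one preprocessed axis segment."""
    config = config or PipelineConfig()
    parts = [np.array(list(rhythm_block(seg, config).values()))]
    if config.mode == FOUR_CLASS:
        parts.append(energy_features(seg, config))
    parts.extend(h.bins.astype(float) for h in morphology_block(seg, config))
    vec = np.concatenate(parts)
    if not np.all(np.isfinite(vec)):
        warnings.warn(
            f"{seg.subject_id} ep{seg.episode_index} {seg.axis}: "
            "non-finite features replaced by 0"
        )
        vec = np.nan_to_num(vec, nan=0.0, posinf=0.0, neginf=0.0)
    return vec


def build_segment_vector(
    episode: Episode, config: Optional[PipelineConfig] = None
) -> np.ndarray:
    """Concatenated 6-axis feature vector of one episode."""
    config = config or PipelineConfig()
    return np.concatenate(
        [build_axis_vector(seg, config) for seg in episode_axis_segments(episode)]
    )


def extract_features(
    recordings: Iterable[InertialRecording],
    config: Optional[PipelineConfig] = None,
    preprocess: bool = True,
) -> pd.DataFrame:
    """Feature table: one row per 10 s episode of each recording.

    Columns: ``subject_id``, ``episode``, ``label`` plus the axis-prefixed
    feature columns.  ``preprocess=False`` skips conditioning (for signals
    conditioned elsewhere).
    """
    config = config or PipelineConfig()
    columns = segment_feature_names(config)
    rows = []
    meta = []
    for rec in recordings:
        conditioned = preprocess_recording(rec, config) if preprocess else rec
        for ep in segment_episodes(conditioned, config.episode_s):
            rows.append(build_segment_vector(ep, config))
            meta.append(
                (
                    ep.subject_id,
                    ep.index,
                    ep.label.value if ep.label is not None else None,
                )
            )
    df = pd.DataFrame(rows, columns=columns)
    for k, name in enumerate(META_COLUMNS):
        df.insert(k, name, [m[k] for m in meta])
    return df
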