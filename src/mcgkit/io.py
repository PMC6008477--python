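"""Reading and writing sensor logs, labels and manifests.

Recordings are plain CSV files with a header ``t,accx,accy,accz,gyrox,gyroy,
gyroz`` (the timestamp column is optional).  Axis order inside the package is
always (AccX, AccY, AccZ, GyroX, GyroY, GyroZ).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

#: Canonical axis names, in the fixed column order used everywhere.
AXES: tuple[str, ...] = ("accx", "accy", "accz", "gyrox", "gyroy", "gyroz")

#: Sampling rates accepted by the pipeline (nominal 200 Hz).
FS_RANGE = (150.0, 250.0)

#: Minimum admissible recording duration (one full episode).
MIN_DURATION_S = 10.0


class Condition(enum.Enum):
    """Cardiac condition class labels."""

    NORMAL = "normal"
    AFIB = "afib"
    CAD = "cad"
    STEMI = "stemi"

    @classmethod
    def parse(cls, text: str) -> "Condition":
        key = str(text).strip().lower().replace("-", "").replace("_", "")
        aliases = {
            "normal": cls.NORMAL,
            "sr": cls.NORMAL,
            "sinus": cls.NORMAL,
            "afib": cls.AFIB,
            "af": cls.AFIB,
            "cad": cls.CAD,
            "prepci": cls.CAD,
            "stemi": cls.STEMI,
        }
        try:
            return aliases[key]
        except KeyError:
            accepted = sorted({k for k in aliases})
            raise ValueError(
                f"unknown class label {text!r}; accepted labels: {accepted}"
            ) from None


@dataclass
class InertialRecording:
    """A 6-axis inertial time series with metadata.

    Parameters
    ----------
    samples
        Array of shape ``(n_samples, 6)``, columns ordered as :data:`AXES`
        (accelerometer axes in m/s^2, gyroscope axes in rad/s; units are not
        enforced).
    fs
        Sampling rate in Hz.
    subject_id
        Identifier of the measured person; drives subject-wise CV.
    label
        Optional condition label.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = "unknown"
    label: Optional[Condition] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != len(AXES):
            raise ValueError(
                f"samples must have shape (n, {len(AXES)}); "
                f"got {self.samples.shape}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def axis(self, name: str) -> np.ndarray:
        """Return one axis as a 1-D view, by canonical name."""
        return self.samples[:, AXES.index(name.lower())]

    def with_samples(self, samples: np.ndarray) -> "InertialRecording":
        return InertialRecording(samples, self.fs, self.subject_id, self.label)


def write_recording(rec: InertialRecording, path: str | Path) -> None:
    """Write a recording as CSV with a timestamp column."""
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"t": t})
    for k, name in enumerate(AXES):
        df[name] = rec.samples[:, k]
    df.to_csv(path, index=False, float_format="%.12g")


def _infer_fs(t: np.ndarray) -> tuple[float, float]:
    """Return (fs, max relative jitter) from a timestamp vector."""
    dt = np.diff(t)
    if len(dt) == 0 or np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    med = float(np.median(dt))
    jitter = float(np.max(np.abs(dt - med)) / med)
    return 1.0 / med, jitter


def read_recording(
    path: str | Path,
    fs_override: Optional[float] = None,
    subject_id: Optional[str] = None,
    label: Optional[Condition] = None,
    min_duration_s: float = MIN_DURATION_S,
    jitter_tol: float = 0.01,
) -> InertialRecording:
    """Read a CSV sensor log into an :class:`InertialRecording`.

    The sampling rate is inferred from the timestamp column when present
    (median inter-sample interval), otherwise ``fs_override`` is required.
    Timestamp jitter above ``jitter_tol`` (relative) triggers a warning and a
    linear-interpolation resample to the uniform inferred rate.
    """
    path = Path(path)
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [a for a in AXES if a not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing axis column(s) {missing}")

    data = df[list(AXES)].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    bad = ~np.isfinite(data)
    if bad.any():
        rows = np.unique(np.nonzero(bad)[0])[:5]
        raise ValueError(
            f"{path}: non-numeric or missing values in rows {rows.tolist()}"
        )

    if "t" in df.columns:
        t = pd.to_numeric(df["t"], errors="coerce").to_numpy(float)
        if not np.all(np.isfinite(t)):
            raise ValueError(f"{path}: non-numeric timestamps")
        fs, jitter = _infer_fs(t)
        if jitter > jitter_tol:
            warnings.warn(
                f"{path}: timestamp jitter {jitter:.1%} exceeds "
                f"{jitter_tol:.0%}; resampling to uniform {fs:.6g} Hz"
            )
            t_uniform = t[0] + np.arange(len(t)) / fs
            data = np.column_stack(
                [np.interp(t_uniform, t, data[:, k]) for k in range(len(AXES))]
            )
        if fs_override is not None:
            fs = fs_override
    else:
        if fs_override is None:
            raise ValueError(
                f"{path}: no timestamp column and no sampling rate given"
            )
        fs = fs_override

    duration = data.shape[0] / fs
    if duration < min_duration_s:
        raise ValueError(
            f"{path}: recording is {duration:.2f} s long; "
            f"at least {min_duration_s:g} s required"
        )
    return InertialRecording(
        data, fs, subject_id or path.stem, label
    )


@dataclass
class ManifestEntry:
    path: Path
    subject_id: str
    label: Condition


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Read a CSV manifest with columns ``path,subject_id,label``.

    Paths are resolved relative to the manifest location.  Duplicate paths
    are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in ("path", "subject_id", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: manifest missing column {col!r}")
    entries: list[ManifestEntry] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        rec_path = str(row["path"]).strip()
        if rec_path in seen:
            raise ValueError(f"{path}: duplicate recording path {rec_path!r}")
        seen.add(rec_path)
        resolved = (path.parent / rec_path).resolve()
        entries.append(
            ManifestEntry(
                path=resolved,
                subject_id=str(row["subject_id"]).strip(),
                label=Condition.parse(row["label"]),
            )
        )
    return entries
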