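"""Synthetic 6-axis cardiac vibration simulator.

Each recording is built as the sum of three components per axis: a
quasi-periodic cardiac wavelet train, a slow breathing sinusoid, and white
Gaussian noise.  Condition classes differ in the statistics of the RR-interval
process (regular vs. irregular), in per-beat morphology randomisation, and in
the amplitude/width/frequency content of the systolic-diastolic complex:

* ``NORMAL`` - regular rhythm, stable morphology.
* ``AFIB``   - RR intervals drawn from a log-normal with a high coefficient of
  variation, plus per-beat amplitude/width/timing perturbation.
* ``CAD``    - regular rhythm, reduced systolic amplitude and widened complex,
  enlarged diastolic activity.
* ``STEMI``  - regular rhythm, energy shifted towards lower frequencies and
  the diastolic complex (an artifact choice; see the class defaults).

The simulator exists so the whole pipeline can be exercised and validated
without clinical data; it aims at the statistical structure the features are
sensitive to, not at physiological fidelity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import AXES, Condition, InertialRecording, write_recording

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_recording",
    "generate_cohort",
    "write_simulation",
]

#: Per-axis relative amplitude, small phase offset (rad) and frequency factor
#: used to make the six channels distinct but coherent.
_AXIS_GAINS = (1.0, 0.75, 1.2, 0.9, 1.1, 0.65)
_AXIS_PHASES = (0.0, 0.6, 1.1, 1.7, 2.3, 2.9)
_AXIS_FREQ_FACTORS = (1.0, 0.95, 1.05, 0.9, 1.1, 0.85)

_CLASS_DEFAULTS: dict[Condition, dict] = {
    Condition.NORMAL: dict(
        rr_jitter=0.02, morphology_jitter=0.02,
        systolic_amplitude_scale=1.0, systolic_width_scale=1.0,
        diastolic_amplitude_scale=1.0, systolic_freq_scale=1.0,
    ),
    Condition.AFIB: dict(
        rr_jitter=0.25, morphology_jitter=0.25,
        systolic_amplitude_scale=1.0, systolic_width_scale=1.0,
        diastolic_amplitude_scale=1.0, systolic_freq_scale=1.0,
    ),
    Condition.CAD: dict(
        rr_jitter=0.03, morphology_jitter=0.05,
        systolic_amplitude_scale=0.55, systolic_width_scale=1.5,
        diastolic_amplitude_scale=1.6, systolic_freq_scale=0.9,
    ),
    Condition.STEMI: dict(
        rr_jitter=0.04, morphology_jitter=0.08,
        systolic_amplitude_scale=0.8, systolic_width_scale=1.2,
        diastolic_amplitude_scale=1.9, systolic_freq_scale=0.7,
    ),
}


@dataclass
class SimulationConfig:
    """Parameters of one simulated recording."""

    condition: Condition
    duration_s: float
    fs: float = 200.0
    hr_mean_bpm: float = 70.0
    #: coefficient of variation of the RR-interval process
    rr_jitter: float = 0.02
    #: per-beat multiplicative template perturbation scale
    morphology_jitter: float = 0.02
    systolic_amplitude_scale: float = 1.0
    systolic_width_scale: float = 1.0
    diastolic_amplitude_scale: float = 1.0
    systolic_freq_scale: float = 1.0
    breathing_freq_hz: float = 0.25
    breathing_amplitude: float = 0.02
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.condition, str):
            self.condition = Condition.parse(self.condition)
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not (30.0 <= self.hr_mean_bpm <= 180.0):
            raise ValueError("hr_mean_bpm must lie in [30, 180]")
        if self.rr_jitter < 0:
            raise ValueError("rr_jitter must be >= 0")
        if self.noise_sd < 0 or self.breathing_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")

    @classmethod
    def for_condition(cls, condition: Condition | str, duration_s: float,
                      **overrides) -> "SimulationConfig":
        """Build a config with class-specific defaults, then apply overrides."""
        condition = (
            Condition.parse(condition) if isinstance(condition, str) else condition
        )
        params = dict(_CLASS_DEFAULTS[condition])
        params.update(overrides)
        return cls(condition=condition, duration_s=duration_s, **params)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["condition"] = self.condition.value
        return d


@dataclass
class GroundTruth:
    """True beat timing of a simulated recording."""

    beat_times: np.ndarray  # seconds of each beat onset, strictly increasing
    true_rr: np.ndarray  # true_rr[k] = beat_times[k+1] - beat_times[k]
    condition: Condition

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.true_rr = np.asarray(self.true_rr, dtype=float)
        if len(self.beat_times) >= 2 and not np.all(np.diff(self.beat_times) > 0):
            raise ValueError("beat_times must be strictly increasing")

    @property
    def mean_hr_bpm(self) -> float:
        return 60.0 / float(np.mean(self.true_rr))


def _draw_rr(rng: np.random.Generator, mean_rr: float, cv: float,
             n: int) -> np.ndarray:
    """Draw RR intervals from a log-normal with the requested mean and CV."""
    if cv == 0:
        return np.full(n, mean_rr)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean_rr) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def _gabor(t: np.ndarray, t0: float, sigma: float, freq: float,
           phase: float, amp: float) -> np.ndarray:
    x = t - t0
    return amp * np.exp(-(x * x) / (2.0 * sigma * sigma)) * np.cos(
        2.0 * np.pi * freq * x + phase
    )


def _cardiac_train(cfg: SimulationConfig, t: np.ndarray,
                   beat_times: np.ndarray, rr_all: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Render the wavelet train for all six axes; shape (n, 6)."""
    n = len(t)
    out = np.zeros((n, len(AXES)))
    sys_sigma0 = 0.035 * cfg.systolic_width_scale
    dia_sigma0 = 0.055
    sys_freq0 = 18.0 * cfg.systolic_freq_scale
    dia_freq0 = 8.0
    fs = cfg.fs

    for k, (bt, rr) in enumerate(zip(beat_times, rr_all)):
        # per-beat morphology randomisation (dominant for AFIB)
        amp_j = max(0.1, 1.0 + cfg.morphology_jitter * rng.standard_normal())
        width_j = max(0.3, 1.0 + 0.5 * cfg.morphology_jitter * rng.standard_normal())
        shift_j = 0.05 * cfg.morphology_jitter * rng.standard_normal()

        sys_t0 = bt + 0.05 + shift_j
        dia_t0 = bt + 0.35 * rr
        sys_amp = cfg.systolic_amplitude_scale * amp_j
        dia_amp = 0.35 * cfg.diastolic_amplitude_scale * amp_j
        sys_sigma = sys_sigma0 * width_j
        dia_sigma = dia_sigma0 * width_j

        # only render the window actually covered by this beat's wavelets
        lo = max(0, int((sys_t0 - 6 * sys_sigma) * fs))
        hi = min(n, int((dia_t0 + 6 * dia_sigma) * fs) + 1)
        if lo >= hi:
            continue
        tw = t[lo:hi]
        for a in range(len(AXES)):
            gain = _AXIS_GAINS[a]
            ph = _AXIS_PHASES[a]
            ff = _AXIS_FREQ_FACTORS[a]
            out[lo:hi, a] += _gabor(
                tw, sys_t0, sys_sigma, sys_freq0 * ff, ph, gain * sys_amp
            )
            out[lo:hi, a] += _gabor(
                tw, dia_t0, dia_sigma, dia_freq0 * ff, ph + 0.4, gain * dia_amp
            )
    return out


def generate_recording(
    config: SimulationConfig,
) -> tuple[InertialRecording, GroundTruth]:
    """Simulate one labelled 6-axis recording.

    Returns the recording (``round(duration_s * fs)`` samples per axis) and
    the ground-truth beat timing.  Identical configs (same seed) produce
    bitwise-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    mean_rr = 60.0 / config.hr_mean_bpm

    # beat onsets: random initial phase, then the RR process; extend one beat
    # past the end so the final partial complex is rendered
    max_beats = int(np.ceil(config.duration_s / mean_rr * 3)) + 4
    rr_all = _draw_rr(rng, mean_rr, config.rr_jitter, max_beats)
    start = rng.uniform(0.05, min(0.5, mean_rr)) if config.rr_jitter > 0 else 0.1
    beats = start + np.concatenate(([0.0], np.cumsum(rr_all[:-1])))
    keep = beats < config.duration_s + mean_rr
    beats, rr_all = beats[keep], rr_all[: keep.sum()]

    cardiac = _cardiac_train(config, t, beats, rr_all, rng)

    samples = cardiac
    if config.breathing_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        breath = np.empty((n, len(AXES)))
        for a in range(len(AXES)):
            breath[:, a] = _AXIS_GAINS[a] * np.sin(
                2 * np.pi * config.breathing_freq_hz * t + phase + _AXIS_PHASES[a]
            )
        modulation = 1.0 + 0.1 * np.sin(
            2 * np.pi * config.breathing_freq_hz * t + phase
        )
        samples = cardiac * modulation[:, None] + config.breathing_amplitude * breath
    if config.noise_sd > 0:
        samples = samples + rng.normal(0.0, config.noise_sd, size=(n, len(AXES)))

    in_range = beats <= config.duration_s
    beat_times = beats[in_range]
    truth = GroundTruth(
        beat_times=beat_times,
        true_rr=np.diff(beat_times),
        condition=config.condition,
    )
    rec = InertialRecording(
        samples, config.fs, subject_id=f"sim-{config.seed}", label=config.condition
    )
    return rec, truth


#: Per-class subject-level mean-HR sampling ranges (bpm) for cohorts.
DEFAULT_HR_RANGES: dict[Condition, tuple[float, float]] = {
    Condition.NORMAL: (55.0, 85.0),
    Condition.AFIB: (70.0, 110.0),
    Condition.CAD: (55.0, 85.0),
    Condition.STEMI: (60.0, 100.0),
}


def generate_cohort(
    n_per_class: int,
    conditions: Sequence[Condition | str] = (Condition.NORMAL, Condition.AFIB),
    duration_s: float = 60.0,
    seed: int = 0,
    hr_ranges: Optional[dict[Condition, tuple[float, float]]] = None,
    **overrides,
) -> list[tuple[InertialRecording, GroundTruth]]:
    """Simulate a labelled cohort with per-subject parameter variation.

    Each subject gets a distinct id, an independent seed derived from
    ``seed``, a mean HR drawn uniformly from the per-class range and a global
    amplitude factor in [0.8, 1.2], so leave-one-subject-out evaluation is
    meaningful.  Extra keyword arguments override :class:`SimulationConfig`
    fields for every subject.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    conditions = [
        Condition.parse(c) if isinstance(c, str) else c for c in conditions
    ]
    ranges = dict(DEFAULT_HR_RANGES)
    if hr_ranges:
        ranges.update(hr_ranges)
    master = np.random.default_rng(seed)
    out: list[tuple[InertialRecording, GroundTruth]] = []
    idx = 0
    for cond in conditions:
        lo, hi = ranges[cond]
        for _ in range(n_per_class):
            hr = master.uniform(lo, hi)
            amp = master.uniform(0.8, 1.2)
            sub_seed = int(master.integers(0, 2**31 - 1))
            params = dict(
                hr_mean_bpm=hr,
                systolic_amplitude_scale=(
                    _CLASS_DEFAULTS[cond]["systolic_amplitude_scale"] * amp
                ),
                seed=sub_seed,
            )
            params.update(overrides)
            cfg = SimulationConfig.for_condition(cond, duration_s, **params)
            rec, truth = generate_recording(cfg)
            rec.subject_id = f"S{idx:03d}-{cond.value}"
            out.append((rec, truth))
            idx += 1
    return out


def write_simulation(
    rec: InertialRecording,
    truth: GroundTruth,
    config: SimulationConfig,
    csv_path: str | Path,
) -> Path:
    """Write the recording CSV plus a JSON sidecar with truth and config.

    Returns the sidecar path (``<csv stem>.json``).
    """
    csv_path = Path(csv_path)
    write_recording(rec, csv_path)
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "config": config.to_dict(),
                "subject_id": rec.subject_id,
                "beat_times": truth.beat_times.tolist(),
                "true_rr": truth.true_rr.tolist(),
                "condition": truth.condition.value,
            },
            indent=2,
        )
    )
    return sidecar
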