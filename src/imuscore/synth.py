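"""Seeded synthetic IMU cohorts for upper-limb motor-task analysis.

Generates two-hand 9-axis inertial recordings (accelerometer, gyroscope,
magnetometer) for six clinically structured movement tasks, with per-task,
per-hand clinician-style motor scores in {0..4}.  The signal model encodes
the two motor phenomena the downstream features are designed to detect:

* tremor — a band-limited oscillation (4-6 Hz at rest, 6-9 Hz during a
  postural hold) whose acceleration amplitude grows with the motor score;
* bradykinesia — a repetitive voluntary oscillation whose amplitude decays
  over the trial and whose cycles intermittently pause (hesitation), both
  progressively with the motor score.

Controls always carry score 0.  Recordings are quantized and clipped to the
sensor's range exactly as a real 16-bit (13-bit magnetometer) IMU would, so
that downstream code sees realistic discretized samples.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaskLabel",
    "SensorSpec",
    "SeverityParams",
    "ImuRecording",
    "CohortDataset",
    "DEFAULT_SCORE_HISTOGRAM",
    "simulate_recording",
    "simulate_cohort",
    "write_recording",
    "read_recording",
]


class TaskLabel(str, enum.Enum):
    """The six upper-limb motor-examination tasks.

    Each value maps to the pair of left/right reference items of the
    standard clinical motor scale it is rated under.
    """

    AR = "AR"  # arm at rest (forearms/hands on lap)
    OA = "OA"  # outstretched arms, spread fingers (postural hold)
    FN = "FN"  # finger-to-nose
    HM = "HM"  # hand movement: opening/closing the palm
    PS = "PS"  # pronation/supination of the forearm
    FT = "FT"  # finger tapping (thumb vs index)

    @property
    def reference_items(self) -> tuple[str, str]:
        return _REFERENCE_ITEMS[self]


_REFERENCE_ITEMS = {
    TaskLabel.AR: ("3.17.1", "3.17.2"),
    TaskLabel.OA: ("3.15.1", "3.15.2"),
    TaskLabel.FN: ("3.16.1", "3.16.2"),
    TaskLabel.HM: ("3.5.1", "3.5.2"),
    TaskLabel.PS: ("3.6.1", "3.6.2"),
    TaskLabel.FT: ("3.4.1", "3.4.2"),
}

#: tasks whose signal is dominated by a repetitive voluntary oscillation
VOLUNTARY_TASKS = (TaskLabel.HM, TaskLabel.PS, TaskLabel.FT)
#: tasks that can express a tremor oscillation
TREMOR_TASKS = (TaskLabel.AR, TaskLabel.OA, TaskLabel.FN)

VALID_SCORES = (0, 1, 2, 3, 4)
HANDS = ("left", "right")


@dataclass(frozen=True)
class SensorSpec:
    """Acquisition characteristics of one 9-axis IMU.

    Ranges are symmetric (± value); the quantization step of each sensor is
    full range / 2^bits.  Simulated samples are clipped to the range and
    rounded to an integer multiple of the step.
    """

    accel_range: float = 8.0  # G
    gyro_range: float = 2000.0  # deg/s
    mag_range: float = 1200.0  # µT
    accel_bits: int = 16
    gyro_bits: int = 16
    mag_bits: int = 13
    rate: float = 200.0  # Hz

    def step(self, sensor: str) -> float:
        rng_ = {"accel": self.accel_range, "gyro": self.gyro_range, "mag": self.mag_range}[sensor]
        bits = {"accel": self.accel_bits, "gyro": self.gyro_bits, "mag": self.mag_bits}[sensor]
        return 2.0 * rng_ / 2**bits

    def quantize(self, x: np.ndarray, sensor: str) -> np.ndarray:
        rng_ = {"accel": self.accel_range, "gyro": self.gyro_range, "mag": self.mag_range}[sensor]
        step = self.step(sensor)
        return np.clip(np.round(x / step) * step, -rng_, rng_)


# Per-task voluntary movement profile: base cycle frequency (Hz),
# acceleration amplitude (G) and angular-rate amplitude (deg/s) at score 0.
_TASK_FREQ = {
    TaskLabel.OA: 0.8,  # postural sway
    TaskLabel.FN: 0.4,  # slow reach-touch-return cycle
    TaskLabel.HM: 2.0,
    TaskLabel.PS: 1.5,
    TaskLabel.FT: 3.0,
}
_TASK_ACCEL_AMP = {
    TaskLabel.OA: 0.05,
    TaskLabel.FN: 0.60,
    TaskLabel.HM: 0.35,
    TaskLabel.PS: 0.40,
    TaskLabel.FT: 0.25,
}
_TASK_GYRO_AMP = {
    TaskLabel.OA: 4.0,
    TaskLabel.FN: 30.0,
    TaskLabel.HM: 120.0,
    TaskLabel.PS: 200.0,
    TaskLabel.FT: 80.0,
}


def _geometric_amplitudes(a0: float, growth: float) -> tuple[float, ...]:
    # score 0 carries no tremor; adjacent non-zero scores differ by `growth`
    return (0.0,) + tuple(a0 * growth**s for s in range(4))


@dataclass(frozen=True)
class SeverityParams:
    """Maps a motor score in {0..4} to signal-model parameters.

    tremor_amplitude
        Acceleration amplitude (G) of the tremor oscillation per score
        level; strictly increasing, zero at score 0.  The default is
        geometric (0.08 G · 1.9^(score-1)) so adjacent scores are separable
        yet overlap under noise.
    amplitude_decrement_rate
        Exponential decay rate (fraction per second) of the voluntary
        oscillation envelope per score level; non-decreasing.
    hesitation_prob
        Per-cycle probability that one movement cycle is skipped.
    amplitude_reduction
        Fractional loss of voluntary amplitude per score point (reduced
        movement excursion), capped so amplitude never drops below 30 %.
    """

    tremor_amplitude: tuple[float, ...] = _geometric_amplitudes(0.08, 1.9)
    rest_tremor_band: tuple[float, float] = (4.0, 6.0)
    postural_tremor_band: tuple[float, float] = (6.0, 9.0)
    movement_base_freq: Mapping[TaskLabel, float] = field(default_factory=lambda: dict(_TASK_FREQ))
    amplitude_decrement_rate: tuple[float, ...] = (0.0, 0.05, 0.10, 0.15, 0.20)
    hesitation_prob: tuple[float, ...] = (0.0, 0.05, 0.10, 0.15, 0.20)
    amplitude_reduction: float = 0.12
    gyro_per_accel: float = 400.0  # deg/s of angular tremor per G of linear tremor
    accel_noise_sd: float = 0.02  # G
    gyro_noise_sd: float = 2.0  # deg/s
    mag_noise_sd: float = 1.5  # µT

    def __post_init__(self) -> None:
        amp = self.tremor_amplitude
        if len(amp) != 5 or any(a < 0 for a in amp):
            raise ValueError("tremor_amplitude must be 5 non-negative values")
        # strictly increasing required unless degenerate (all-zero, no tremor effect)
        if any(a > 0 for a in amp) and any(b <= a for a, b in zip(amp, amp[1:])):
            raise ValueError("tremor_amplitude must be strictly increasing in score")
        dec = self.amplitude_decrement_rate
        if len(dec) != 5 or any(b < a for a, b in zip(dec, dec[1:])) or any(d < 0 for d in dec):
            raise ValueError("amplitude_decrement_rate must be non-negative and non-decreasing")
        if any(not 0 <= p <= 1 for p in self.hesitation_prob):
            raise ValueError("hesitation_prob must lie in [0, 1]")

    @classmethod
    def well_separated(cls) -> "SeverityParams":
        """Default parameterization: adjacent scores statistically separable."""
        return cls()

    @classmethod
    def fully_overlapping(cls) -> "SeverityParams":
        """Degenerate parameterization: the score has no effect on the signal.

        Every score level produces statistically identical recordings, so any
        score classifier should perform at chance.
        """
        return cls(
            tremor_amplitude=(0.0,) * 5,
            amplitude_decrement_rate=(0.0,) * 5,
            hesitation_prob=(0.0,) * 5,
            amplitude_reduction=0.0,
        )

    def tremor_band(self, task: TaskLabel) -> tuple[float, float]:
        return self.postural_tremor_band if task is TaskLabel.OA else self.rest_tremor_band


@dataclass
class ImuRecording:
    """One hand-task trial: 9 channels at a fixed rate plus labels."""

    participant_id: str
    hand: str
    task: TaskLabel
    score: int
    rate: float
    samples: np.ndarray  # (n, 9): ax ay az gx gy gz mx my mz
    duration: float

    CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz")

    @property
    def accel(self) -> np.ndarray:
        return self.samples[:, 0:3]

    @property
    def gyro(self) -> np.ndarray:
        return self.samples[:, 3:6]

    @property
    def mag(self) -> np.ndarray:
        return self.samples[:, 6:9]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.samples.shape[0]) / self.rate

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.samples, columns=list(self.CHANNELS))
        df.insert(0, "t", self.t)
        return df


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _aligned_direction(rng: np.random.Generator, axis: np.ndarray, spread: float = 0.5) -> np.ndarray:
    """Random unit vector biased toward `axis` (movement roughly along the limb)."""
    v = axis + spread * _random_unit(rng)
    return v / np.linalg.norm(v)


def _gated_oscillation(
    t: np.ndarray,
    freq: float,
    hesitation: float,
    decay_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-amplitude repetitive oscillation with cycle skipping and decay.

    Cycle boundaries fall on zero crossings of sin(2πft), so zeroing whole
    cycles leaves the waveform continuous.
    """
    s = np.sin(2 * np.pi * freq * t)
    n_cycles = int(math.ceil(freq * t[-1])) + 1
    gates = (rng.uniform(size=n_cycles) >= hesitation).astype(float)
    cycle_idx = np.minimum((freq * t).astype(int), n_cycles - 1)
    return s * gates[cycle_idx] * np.exp(-decay_rate * t)


def simulate_recording(
    task: TaskLabel | str,
    score: int,
    severity: SeverityParams | None = None,
    sensor: SensorSpec | None = None,
    duration: float = 10.0,
    seed: int = 0,
    participant_id: str = "SYN00",
    hand: str = "right",
) -> ImuRecording:
    """Simulate one hand-task trial at the sensor's native rate.

    Parameters
    ----------
    task
        One of the six task codes.
    score
        Clinician-style motor score in {0..4}; drives tremor amplitude
        and/or bradykinetic decrement through `severity`.
    duration
        Trial length in seconds, at least 10 (the clinical protocol records
        each task for about 10 s).
    seed
        Seeds all randomness; identical arguments give bit-identical output.
    """
    task = TaskLabel(task)
    if score not in VALID_SCORES:
        raise ValueError(f"score must be in {VALID_SCORES}, got {score!r}")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if duration < 10.0:
        raise ValueError("duration must be at least 10 s")
    severity = severity or SeverityParams()
    sensor = sensor or SensorSpec()

    rng = np.random.default_rng(seed)
    n = int(round(sensor.rate * duration))
    t = np.arange(n) / sensor.rate

    gravity_dir = _random_unit(rng)  # per-trial hand orientation
    accel = np.outer(np.ones(n), gravity_dir)  # constant 1 G baseline
    gyro = np.zeros((n, 3))

    # slow physiological drift on the gyroscope (posture is never perfectly still)
    drift_dir = _random_unit(rng)
    drift_freq = rng.uniform(0.1, 0.3)
    gyro += np.outer(3.0 * np.sin(2 * np.pi * drift_freq * t + rng.uniform(0, 2 * np.pi)), drift_dir)

    motion_mag_amp = 0.0  # accel-scale motion fed into the magnetometer model

    if task in TREMOR_TASKS:
        lo, hi = severity.tremor_band(task)
        f_tr = rng.uniform(lo, hi)
        phase = rng.uniform(0, 2 * np.pi)
        tremor_dir = _aligned_direction(rng, gravity_dir)
        a_tr = severity.tremor_amplitude[score]
        osc = np.sin(2 * np.pi * f_tr * t + phase)
        accel += a_tr * np.outer(osc, tremor_dir)
        gyro += severity.gyro_per_accel * a_tr * np.outer(osc, _aligned_direction(rng, tremor_dir))
        motion_mag_amp += a_tr

    if task in _TASK_FREQ:  # every task except AR has a voluntary/postural component
        f_mov = _TASK_FREQ[task]
        a_mov = _TASK_ACCEL_AMP[task]
        g_mov = _TASK_GYRO_AMP[task]
        if task in VOLUNTARY_TASKS:
            # bradykinesia: reduced excursion, per-cycle hesitation, envelope decay
            factor = max(1.0 - severity.amplitude_reduction * score, 0.3)
            osc = _gated_oscillation(
                t,
                f_mov,
                severity.hesitation_prob[score],
                severity.amplitude_decrement_rate[score],
                rng,
            )
        else:
            factor = 1.0
            osc = np.sin(2 * np.pi * f_mov * t + rng.uniform(0, 2 * np.pi))
        mov_dir = _aligned_direction(rng, gravity_dir)
        accel += a_mov * factor * np.outer(osc, mov_dir)
        gyro += g_mov * factor * np.outer(osc, _aligned_direction(rng, mov_dir))
        motion_mag_amp += a_mov * factor

    # magnetometer: constant earth field + slow orientation wobble + a
    # motion-coupled component (hand rotation sweeps the field across axes)
    mag = np.outer(np.ones(n), 40.0 * _random_unit(rng))
    wobble_f = rng.uniform(0.2, 0.45)
    mag += np.outer(8.0 * np.sin(2 * np.pi * wobble_f * t + rng.uniform(0, 2 * np.pi)), _random_unit(rng))
    if motion_mag_amp > 0:
        src = accel - np.outer(np.ones(n), gravity_dir)  # motion acceleration only
        mag += 12.0 * src @ np.outer(_random_unit(rng), _random_unit(rng)).T

    accel += rng.normal(scale=severity.accel_noise_sd, size=(n, 3))
    gyro += rng.normal(scale=severity.gyro_noise_sd, size=(n, 3))
    mag += rng.normal(scale=severity.mag_noise_sd, size=(n, 3))

    samples = np.column_stack(
        [
            sensor.quantize(accel, "accel"),
            sensor.quantize(gyro, "gyro"),
            sensor.quantize(mag, "mag"),
        ]
    )
    return ImuRecording(
        participant_id=participant_id,
        hand=hand,
        task=task,
        score=int(score),
        rate=sensor.rate,
        samples=samples,
        duration=duration,
    )


#: Default per-task motor-score frequency profile over recorded hands,
#: patterned on the imbalanced distribution of a 45-participant clinical
#: cohort (counts over scores 0..4).
DEFAULT_SCORE_HISTOGRAM: dict[TaskLabel, tuple[int, ...]] = {
    TaskLabel.AR: (60, 21, 2, 1, 0),
    TaskLabel.OA: (35, 47, 2, 0, 0),
    TaskLabel.FN: (48, 31, 5, 0, 0),
    TaskLabel.HM: (14, 25, 35, 9, 1),
    TaskLabel.PS: (18, 17, 21, 23, 5),
    TaskLabel.FT: (13, 21, 38, 14, 2),
}


class InfeasibleHistogramError(ValueError):
    """The target histogram cannot be met with all controls at score 0."""


@dataclass
class CohortDataset:
    """Participants × 6 tasks × 2 hands recordings with group labels."""

    recordings: list[ImuRecording]
    groups: dict[str, str]  # participant -> "PD" | "control"
    contaminated: set[tuple[str, str, TaskLabel]]  # (participant, hand, task)

    def is_contaminated(self, rec: ImuRecording) -> bool:
        return (rec.participant_id, rec.hand, rec.task) in self.contaminated

    def filtered(self) -> list[ImuRecording]:
        """Recordings that survive the contamination filter."""
        return [r for r in self.recordings if not self.is_contaminated(r)]

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "participant": r.participant_id,
                "group": self.groups[r.participant_id],
                "hand": r.hand,
                "task": r.task.value,
                "score": r.score,
                "contaminated": self.is_contaminated(r),
            }
            for r in self.recordings
        ]
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> Path:
        """One delimited-text file per recording plus a cohort manifest."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = self.manifest()
        paths = []
        for rec in self.recordings:
            name = f"{rec.participant_id}_{rec.hand}_{rec.task.value}.csv"
            write_recording(rec, out_dir / name)
            paths.append(name)
        manifest["path"] = paths
        manifest_path = out_dir / "manifest.csv"
        manifest.to_csv(manifest_path, index=False)
        return manifest_path


def _pd_conditional(
    hist: Sequence[float], n_pd: int, n_controls: int, strict: bool
) -> np.ndarray:
    """Score distribution for PD hands given an all-hands target histogram.

    Controls contribute only zeros, so their mass is removed from the zero
    bin before renormalizing.  If the zero bin cannot absorb the control
    mass, the deficit is clipped (strict=False) or raised (strict=True).
    """
    h = np.asarray(hist, dtype=float)
    if h.ndim != 1 or h.size != 5 or h.sum() <= 0 or (h < 0).any():
        raise ValueError("histogram must be 5 non-negative counts with positive total")
    p = h / h.sum()
    total_hands = 2 * (n_pd + n_controls)
    control_mass = 2 * n_controls / total_hands
    deficit = control_mass - p[0]
    if deficit > 1e-9 and strict:
        raise InfeasibleHistogramError(
            "histogram zero-bin smaller than the control share; controls would "
            "need non-zero scores"
        )
    q = p.copy()
    q[0] = max(p[0] - control_mass, 0.0)
    if q.sum() <= 0:
        raise InfeasibleHistogramError("no probability mass left for PD hands")
    return q / q.sum()


def simulate_cohort(
    n_pd: int,
    n_controls: int,
    score_histogram: Mapping[TaskLabel, Sequence[float]] | None = None,
    dropout: int = 0,
    seed: int = 0,
    severity: SeverityParams | None = None,
    sensor: SensorSpec | None = None,
    duration: float = 10.0,
    strict_histogram: bool = False,
) -> CohortDataset:
    """Simulate a full cohort: (n_pd + n_controls) × 6 tasks × 2 hands.

    Scores for PD hands are drawn so the per-task score profile
    approximately matches `score_histogram` (a count table over scores 0-4
    for all recorded hands); controls always score 0.  A per-participant
    latent severity couples scores across tasks and hands, mimicking the
    within-patient correlation of clinical ratings.  `dropout` recordings
    are flagged contaminated (removal is a downstream filter; the dataset
    always holds the complete grid).
    """
    if n_pd < 0 or n_controls < 0 or n_pd + n_controls == 0:
        raise ValueError("cohort must contain at least one participant")
    total = (n_pd + n_controls) * 12
    if not 0 <= dropout < total:
        raise ValueError("dropout must be smaller than the total recording count")
    severity = severity or SeverityParams()
    sensor = sensor or SensorSpec()
    histogram = dict(score_histogram) if score_histogram else dict(DEFAULT_SCORE_HISTOGRAM)
    histogram = {TaskLabel(k): v for k, v in histogram.items()}

    rng = np.random.default_rng(seed)
    participants = [f"PD{i + 1:02d}" for i in range(n_pd)] + [
        f"HC{i + 1:02d}" for i in range(n_controls)
    ]
    groups = {p: ("PD" if p.startswith("PD") else "control") for p in participants}

    conditional = {
        task: _pd_conditional(histogram[task], n_pd, n_controls, strict_histogram)
        for task in TaskLabel
    }

    # Latent per-participant severity -> correlated task scores via a
    # Gaussian copula: the per-recording percentile u = Phi(rho z_p +
    # sqrt(1-rho^2) eps) is exactly Uniform(0,1), so the target histogram is
    # matched in expectation while scores stay correlated within a patient.
    rho = 0.7
    latent = {p: rng.normal() for p in participants if groups[p] == "PD"}

    recordings: list[ImuRecording] = []
    for p in participants:
        for hand in HANDS:
            for task in TaskLabel:
                if groups[p] == "control":
                    score = 0
                else:
                    z = rho * latent[p] + math.sqrt(1 - rho**2) * rng.normal()
                    u = 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))
                    score = min(int(np.searchsorted(np.cumsum(conditional[task]), u)), 4)
                rec_seed = int(rng.integers(0, 2**31 - 1))
                recordings.append(
                    simulate_recording(
                        task,
                        score,
                        severity=severity,
                        sensor=sensor,
                        duration=duration,
                        seed=rec_seed,
                        participant_id=p,
                        hand=hand,
                    )
                )

    contaminated: set[tuple[str, str, TaskLabel]] = set()
    if dropout:
        idx = rng.choice(len(recordings), size=dropout, replace=False)
        for i in idx:
            r = recordings[i]
            contaminated.add((r.participant_id, r.hand, r.task))

    return CohortDataset(recordings=recordings, groups=groups, contaminated=contaminated)


def write_recording(rec: ImuRecording, path: str | Path) -> None:
    """Write one recording as delimited text: t,ax,ay,az,gx,gy,gz,mx,my,mz."""
    rec.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_recording(
    path: str | Path,
    participant_id: str = "",
    hand: str = "",
    task: TaskLabel | str = TaskLabel.AR,
    score: int = 0,
) -> ImuRecording:
    """Read a recording written by :func:`write_recording`.

    The sampling rate is recovered from the time column; labels are supplied
    by the caller (normally from the cohort manifest).
    """
    df = pd.read_csv(path)
    t = df["t"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"recording {path} too short")
    rate = 1.0 / float(np.median(np.diff(t)))
    samples = df[list(ImuRecording.CHANNELS)].to_numpy(dtype=float)
    return ImuRecording(
        participant_id=participant_id,
        hand=hand,
        task=TaskLabel(task),
        score=int(score),
        rate=round(rate, 6),
        samples=samples,
        duration=len(t) / rate,
    )
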