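"""Signal conditioning: raw 200 Hz trials to standardized 2.5 s half-segments.

The fixed pipeline is: downsample to 50 Hz → per-sensor Euclidean magnitude
→ causal 3-pole Butterworth lowpass at 20 Hz on all 12 series (9 axes + 3
magnitudes) → centre-aligned 5 s epoch → split into two equal halves.  The
half-split exists because bradykinesia manifests as a progressive loss of
speed and amplitude toward the end of a task: comparing early vs late
features captures that decrement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .synth import ImuRecording

__all__ = [
    "ConditionedSignals",
    "SegmentPair",
    "downsample",
    "euclidean_magnitude",
    "lowpass",
    "extract_epoch",
    "split_halves",
    "condition",
    "condition_and_segment",
]

TARGET_RATE = 50.0
CUTOFF_HZ = 20.0
FILTER_ORDER = 3
EPOCH_SECONDS = 5.0

AXIS_CHANNELS = ImuRecording.CHANNELS
MAGNITUDE_CHANNELS = ("accel_mag", "gyro_mag", "mag_mag")
ALL_CHANNELS = AXIS_CHANNELS + MAGNITUDE_CHANNELS


@dataclass
class ConditionedSignals:
    """Filtered axis and magnitude series at the working rate.

    `data` columns are the 9 axes plus the 3 per-sensor magnitudes; `meta`
    carries the recording's labels (participant, hand, task, score) through
    the pipeline.
    """

    rate: float
    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def duration(self) -> float:
        return len(self.data) / self.rate

    def slice(self, start: int, stop: int) -> "ConditionedSignals":
        return ConditionedSignals(
            rate=self.rate,
            data=self.data.iloc[start:stop].reset_index(drop=True),
            meta=dict(self.meta),
        )


@dataclass
class SegmentPair:
    """The two contiguous 2.5 s halves of the analysis epoch."""

    first_half: ConditionedSignals
    second_half: ConditionedSignals
    epoch_start: float  # seconds into the recording

    @property
    def halves(self) -> tuple[ConditionedSignals, ConditionedSignals]:
        return (self.first_half, self.second_half)


def downsample(recording: ImuRecording, target_rate: float = TARGET_RATE) -> ImuRecording:
    """Decimate a recording to `target_rate`, with anti-alias protection.

    The decimation ratio must be an integer.  A zero-phase FIR anti-alias
    filter (cutoff below the new Nyquist) precedes sample selection; the
    subsequent 20 Hz conditioning filter makes the exact anti-alias choice
    observationally minor.
    """
    ratio = recording.rate / target_rate
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(
            f"rate {recording.rate} Hz is not an integer multiple of {target_rate} Hz"
        )
    if q == 1:
        return recording
    # polyphase FIR decimation: zero-phase, with linear edge extension so
    # boundaries carry no filter transient
    out = signal.resample_poly(recording.samples, 1, q, axis=0, padtype="line")
    return replace(
        recording,
        rate=target_rate,
        samples=out,
        duration=out.shape[0] / target_rate,
    )


def euclidean_magnitude(axis_triplet: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of a 3-axis series, shape (n, 3) → (n,)."""
    a = np.asarray(axis_triplet, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"expected shape (n, 3), got {a.shape}")
    return np.linalg.norm(a, axis=1)


def lowpass(
    series: np.ndarray,
    rate: float,
    cutoff: float = CUTOFF_HZ,
    poles: int = FILTER_ORDER,
) -> np.ndarray:
    """Causal Butterworth lowpass (single forward pass, unit DC gain).

    A causal single pass matches a real-time filter with group delay on the
    order of 10 ms; zero-phase filtering is deliberately not used.
    """
    if cutoff >= rate / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({rate / 2} Hz)")
    sos = signal.butter(poles, cutoff, btype="low", fs=rate, output="sos")
    return signal.sosfilt(sos, np.asarray(series, dtype=float), axis=0)


def condition(recording: ImuRecording) -> ConditionedSignals:
    """Downsample, form per-sensor magnitudes, and lowpass all 12 series.

    Magnitudes are computed from the downsampled (pre-filter) axes, so they
    are non-negative by construction; the subsequent IIR filter may
    introduce slight ripple below zero.
    """
    rec = downsample(recording)
    axes = rec.samples
    mags = np.column_stack(
        [euclidean_magnitude(rec.accel), euclidean_magnitude(rec.gyro), euclidean_magnitude(rec.mag)]
    )
    stacked = np.column_stack([axes, mags])
    filtered = lowpass(stacked, rec.rate)
    data = pd.DataFrame(filtered, columns=list(ALL_CHANNELS))
    meta = {
        "participant": rec.participant_id,
        "hand": rec.hand,
        "task": rec.task.value,
        "score": rec.score,
    }
    return ConditionedSignals(rate=rec.rate, data=data, meta=meta)


def extract_epoch(
    signals: ConditionedSignals, epoch_len: float = EPOCH_SECONDS
) -> ConditionedSignals:
    """Centre-aligned `epoch_len` window, trimming unstable task boundaries."""
    n_epoch = int(round(epoch_len * signals.rate))
    n = len(signals)
    if n < n_epoch:
        raise ValueError(
            f"recording of {n / signals.rate:.2f} s shorter than the {epoch_len} s epoch"
        )
    start = (n - n_epoch) // 2
    out = signals.slice(start, start + n_epoch)
    out.meta["epoch_start"] = start / signals.rate
    return out


def split_halves(epoch: ConditionedSignals) -> SegmentPair:
    """Split an epoch into two equal contiguous halves.

    Odd-length epochs drop their final sample (≤ 20 ms) so both halves are
    exactly equal in length.
    """
    n = len(epoch)
    if n < 2:
        raise ValueError("epoch too short to split")
    n -= n % 2
    half = n // 2
    return SegmentPair(
        first_half=epoch.slice(0, half),
        second_half=epoch.slice(half, n),
        epoch_start=float(epoch.meta.get("epoch_start", 0.0)),
    )


def condition_and_segment(recording: ImuRecording) -> SegmentPair:
    """Full conditioning pipeline: downsample → magnitude → filter → epoch → split."""
    return split_halves(extract_epoch(condition(recording)))
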