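"""Per-segment feature set: time-domain moments, Welch spectral features in
0-10 Hz, and sample entropy.

Each conditioned half-segment yields 13 features per channel.  The
magnitude variant uses the three per-sensor magnitude series (13 × 3
sensors × 2 halves = 78 features per recording); the axis variant uses all
nine axes (39 per sensor × 3 × 2 halves = 234).  Feature names follow
``{sensor}_{channel}_{half}_{feature}`` and the column order is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats
from sklearn.preprocessing import StandardScaler

from .preprocess import SegmentPair, condition_and_segment
from .synth import CohortDataset

__all__ = [
    "TIME_FEATURES",
    "FREQ_FEATURES",
    "FEATURE_NAMES",
    "LABEL_COLUMNS",
    "time_features",
    "welch_psd",
    "freq_features",
    "sample_entropy",
    "build_feature_vector",
    "feature_columns",
    "extract_cohort_features",
    "Standardizer",
    "fit_standardizer",
    "apply_standardizer",
]

TIME_FEATURES = ("rms", "range", "mean", "variance", "skew", "kurtosis")
FREQ_FEATURES = ("dom_freq", "rel_magnitude", "psd_mean", "psd_sd", "psd_skew", "psd_kurtosis")
FEATURE_NAMES = TIME_FEATURES + FREQ_FEATURES + ("sampen",)

LABEL_COLUMNS = ("participant", "group", "hand", "task", "score")

# Welch estimator settings for the 125-sample (2.5 s at 50 Hz) half-segment:
# 64-sample Hann windows with 50 % overlap give >= 2 averaged periodograms
# at ~0.78 Hz resolution, adequate for a 0-10 Hz analysis band.
WELCH_NPERSEG = 64
WELCH_OVERLAP = 0.5
PSD_BAND = (0.0, 10.0)

# Sample-entropy settings: embedding length 2, tolerance 0.2 x the segment's
# standard deviation (field-standard defaults).
SAMPEN_M = 2
SAMPEN_R_FACTOR = 0.2

_SENSOR_AXES = {"accel": ("x", "y", "z"), "gyro": ("x", "y", "z"), "mag": ("x", "y", "z")}
_AXIS_COLUMN = {
    ("accel", "x"): "ax", ("accel", "y"): "ay", ("accel", "z"): "az",
    ("gyro", "x"): "gx", ("gyro", "y"): "gy", ("gyro", "z"): "gz",
    ("mag", "x"): "mx", ("mag", "y"): "my", ("mag", "z"): "mz",
}


def time_features(segment: np.ndarray) -> dict[str, float]:
    """Six time-domain features of one series.

    Skewness and kurtosis are bias-uncorrected standardized moments with
    kurtosis reported as excess (a normal series gives 0); a constant
    series returns 0 for both by convention.
    """
    x = np.asarray(segment, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("segment must be a 1-D series of length >= 4")
    var = float(np.var(x))
    if var == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=True, bias=True))
    return {
        "rms": float(np.sqrt(np.mean(x**2))),
        "range": float(np.max(x) - np.min(x)),
        "mean": float(np.mean(x)),
        "variance": var,
        "skew": skew,
        "kurtosis": kurt,
    }


def welch_psd(
    segment: np.ndarray,
    rate: float = 50.0,
    band: tuple[float, float] | None = PSD_BAND,
    nperseg: int = WELCH_NPERSEG,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density, optionally restricted to a band.

    Returns (frequencies, densities).  Band restriction happens after
    estimation, so the estimator's resolution does not depend on the band.
    """
    x = np.asarray(segment, dtype=float)
    nperseg = min(nperseg, x.size)
    if x.size < 8:
        raise ValueError("segment shorter than one analysis window")
    f, pxx = signal.welch(
        x,
        fs=rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * WELCH_OVERLAP),
        detrend="constant",
    )
    if band is not None:
        keep = (f >= band[0]) & (f <= band[1])
        f, pxx = f[keep], pxx[keep]
    return f, pxx


def freq_features(spectrum: tuple[np.ndarray, np.ndarray]) -> dict[str, float]:
    """Six spectral features from a band-limited PSD.

    The dominant frequency is the argmax of the density.  Relative
    magnitude is the fraction of band power within ±0.5 Hz of the dominant
    frequency (a peak-concentration measure).  The PSD moments treat the
    normalized density as a probability mass over the frequency grid; the
    fourth moment is excess kurtosis, matching the time-domain convention.
    An all-zero spectrum returns zeros throughout.
    """
    f, pxx = np.asarray(spectrum[0], dtype=float), np.asarray(spectrum[1], dtype=float)
    if f.size == 0 or f.shape != pxx.shape:
        raise ValueError("spectrum must be non-empty matching (frequencies, densities)")
    total = float(pxx.sum())
    if total <= 0.0:
        return dict.fromkeys(FREQ_FEATURES, 0.0)
    i_max = int(np.argmax(pxx))
    dom = float(f[i_max])
    near = np.abs(f - dom) <= 0.5
    rel = float(pxx[near].sum() / total)
    p = pxx / total
    mean = float(np.sum(f * p))
    var = float(np.sum((f - mean) ** 2 * p))
    sd = float(np.sqrt(var))
    if sd > 0.0:
        skew = float(np.sum(((f - mean) / sd) ** 3 * p))
        kurt = float(np.sum(((f - mean) / sd) ** 4 * p) - 3.0)
    else:
        skew = kurt = 0.0
    return {
        "dom_freq": dom,
        "rel_magnitude": rel,
        "psd_mean": mean,
        "psd_sd": sd,
        "psd_skew": skew,
        "psd_kurtosis": kurt,
    }


def sample_entropy(
    segment: np.ndarray, m: int = SAMPEN_M, r: float | None = None
) -> float:
    """Sample entropy SampEn(m, r) with Chebyshev distance.

    B counts matching template pairs of length m, A of length m + 1
    (self-matches excluded); SampEn = -ln(A / B).  When no m+1 template
    pair matches (A = 0) the statistic is undefined and the conventional
    upper bound -ln(2 / ((n-m-1)(n-m))) is returned as a sentinel.  A
    constant series returns 0 (every template matches).

    `r` defaults to 0.2 x the segment's standard deviation.
    """
    x = np.asarray(segment, dtype=float)
    n = x.size
    if n <= m + 1:
        raise ValueError(f"series of length {n} too short for m={m}")
    if r is None:
        r = SAMPEN_R_FACTOR * float(np.std(x))
    if r <= 0.0:
        # constant series: all templates trivially match
        if np.ptp(x) == 0.0:
            return 0.0
        raise ValueError("tolerance r must be positive")

    def _count(mm: int) -> int:
        n_templates = n - m  # common template count for both lengths
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)[:n_templates]
        dist = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=-1)
        matches = (dist <= r).sum() - n_templates  # remove self-matches
        return int(matches // 2)

    b = _count(m)
    a = _count(m + 1)
    if b == 0:
        return 0.0
    if a == 0:
        return float(-np.log(2.0 / ((n - m - 1) * (n - m))))
    return float(-np.log(a / b))


def feature_columns(variant: str = "magnitude") -> list[str]:
    """Fixed column order of the feature vector for a variant."""
    if variant == "magnitude":
        channels = [("accel", "magnitude"), ("gyro", "magnitude"), ("mag", "magnitude")]
    elif variant == "axis":
        channels = [(s, a) for s in ("accel", "gyro", "mag") for a in _SENSOR_AXES[s]]
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return [
        f"{sensor}_{channel}_{half}_{feat}"
        for sensor, channel in channels
        for half in (1, 2)
        for feat in FEATURE_NAMES
    ]


def _channel_series(half, sensor: str, channel: str) -> np.ndarray:
    if channel == "magnitude":
        return half.data[f"{sensor}_mag"].to_numpy()
    return half.data[_AXIS_COLUMN[(sensor, channel)]].to_numpy()


def _segment_features(series: np.ndarray, rate: float) -> dict[str, float]:
    feats = dict(time_features(series))
    feats.update(freq_features(welch_psd(series, rate=rate)))
    feats["sampen"] = sample_entropy(series)
    return feats


def build_feature_vector(pair: SegmentPair, variant: str = "magnitude") -> dict[str, float]:
    """All features of one recording, keyed by the fixed column names."""
    cache: dict[tuple[str, str, str], dict[str, float]] = {}
    out: dict[str, float] = {}
    for name in feature_columns(variant):
        sensor, channel, half_s, feat = name.split("_", 3)
        key = (sensor, channel, half_s)
        if key not in cache:
            half = pair.first_half if half_s == "1" else pair.second_half
            series = _channel_series(half, sensor, channel)
            cache[key] = _segment_features(series, half.rate)
        out[name] = cache[key][feat]
    return out


def extract_cohort_features(
    dataset: CohortDataset,
    variant: str = "magnitude",
    drop_contaminated: bool = True,
) -> pd.DataFrame:
    """Feature table: one row per (non-contaminated) recording.

    Label columns (participant, group, hand, task, score) precede the
    feature columns; the feature column order is fixed per variant.
    """
    recordings = dataset.filtered() if drop_contaminated else dataset.recordings
    rows = []
    for rec in recordings:
        pair = condition_and_segment(rec)
        vec = build_feature_vector(pair, variant=variant)
        row = {
            "participant": rec.participant_id,
            "group": dataset.groups[rec.participant_id],
            "hand": rec.hand,
            "task": rec.task.value,
            "score": rec.score,
        }
        row.update(vec)
        rows.append(row)
    cols = list(LABEL_COLUMNS) + feature_columns(variant)
    return pd.DataFrame(rows, columns=cols)


@dataclass
class Standardizer:
    """Per-feature z-scoring with statistics learned from a training split.

    Degenerate features (zero variance in training) map to 0.  Backed by a
    fitted scaler so the transform is exactly (x - mean) / sd with
    population sd.
    """

    scaler: StandardScaler
    columns: list[str]

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        out[self.columns] = self.scaler.transform(table[self.columns].to_numpy())
        return out


def fit_standardizer(train: pd.DataFrame, columns: Sequence[str] | None = None) -> Standardizer:
    """Learn per-feature mean/sd on the training partition only."""
    if len(train) == 0:
        raise ValueError("cannot standardize an empty partition")
    cols = list(columns) if columns is not None else [
        c for c in train.columns if c not in LABEL_COLUMNS
    ]
    scaler = StandardScaler().fit(train[cols].to_numpy())
    return Standardizer(scaler=scaler, columns=cols)


def apply_standardizer(s: Standardizer, table: pd.DataFrame) -> pd.DataFrame:
    return s.transform(table)
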