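"""Windowed kinematic feature extraction: the 103-feature registry.

Each analysis window yields 25 features per channel (x, y, z, vector
magnitude): 15 temporal (extreme values, dispersion, jerkiness, peaks,
RMS) and 10 spectral (band powers, dominant frequency, entropy,
centroid, median frequency), plus 3 vector-magnitude extras (signal
magnitude area, 0.5 s-lag autocorrelation, 0.5 m/s^2 threshold
crossings): 4 x 25 + 3 = 103.

The four *main* features used for the group-level hour-scale statistics
are the vector-magnitude maximum, coefficient of variation, RMS and
total spectral power below 4 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from bradyflux.preprocess import ProcessedRecording

CHANNELS = ("x", "y", "z", "svm")

TEMPORAL_NAMES = (
    "mean",
    "median",
    "sd",
    "variance",
    "cov",
    "rms",
    "max",
    "min",
    "range",
    "iqr",
    "skewness",
    "kurtosis",
    "n_peaks",
    "jerk_mean_abs",
    "jerk_rms",
)

SPECTRAL_NAMES = (
    "power_total",  # total power 0.3-4 Hz ("below 4 Hz")
    "relpower_0p3_1",
    "relpower_1_2",
    "relpower_2_3",
    "relpower_3_4",
    "dom_freq",
    "dom_power",
    "spec_entropy",
    "spec_centroid",
    "median_freq",
)

SVM_EXTRA_NAMES = ("sma", "autocorr_0p5s", "crossings_0p5")

# fixed analysis parameters (the signal is band-limited to <3.5 Hz upstream)
BAND_LOW, BAND_HIGH = 0.3, 4.0
REL_BANDS = ((0.3, 1.0), (1.0, 2.0), (2.0, 3.0), (3.0, 4.0))
PEAK_PROMINENCE = 0.1  # m/s^2
PEAK_MIN_SEPARATION_S = 0.25
AUTOCORR_LAG_S = 0.5
CROSSING_THRESHOLD = 0.5  # m/s^2
MIN_WINDOW_SAMPLES = 8


def _registry() -> list[tuple[str, str, str]]:
    entries = []
    for channel in CHANNELS:
        for name in TEMPORAL_NAMES:
            entries.append((f"{channel}_{name}", channel, name))
        for name in SPECTRAL_NAMES:
            entries.append((f"{channel}_{name}", channel, name))
    for name in SVM_EXTRA_NAMES:
        entries.append((f"svm_{name}", "svm", name))
    return entries


FEATURE_REGISTRY: list[tuple[str, str, str]] = _registry()
FEATURE_NAMES: list[str] = [name for name, _, _ in FEATURE_REGISTRY]
MAIN_FEATURES = ("svm_max", "svm_cov", "svm_rms", "svm_power_total")

assert len(FEATURE_NAMES) == 103
assert all(f in FEATURE_NAMES for f in MAIN_FEATURES)


def segment_windows(n_samples: int, window_s: float, fs: float) -> list[tuple[int, int]]:
    """Non-overlapping, start-aligned, half-open sample spans; a trailing
    partial window is discarded.  A window longer than the recording gives
    an empty list."""
    w = int(round(window_s * fs))
    if w < MIN_WINDOW_SAMPLES:
        raise ValueError("window too short for feature extraction")
    return [(i * w, (i + 1) * w) for i in range(n_samples // w)]


def coefficient_of_variation(series: np.ndarray) -> float:
    """Population-sd coefficient of variation; +inf if the mean is zero
    with non-zero spread, 0 for a constant series."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    if np.all(series == series[0]):
        return 0.0
    mean = series.mean()
    sd = series.std()
    if sd == 0.0:
        return 0.0
    if mean == 0.0:
        return np.inf
    return float(sd / abs(mean))


def temporal_features(series: np.ndarray, fs: float) -> dict[str, float]:
    """Time-domain summary of one channel within one window."""
    series = np.asarray(series, dtype=float)
    if series.size < MIN_WINDOW_SAMPLES:
        raise ValueError("series too short for temporal features")
    sd = float(series.std())
    jerk = np.diff(series) * fs
    if sd > 0:
        skew = float(stats.skew(series))
        kurt = float(stats.kurtosis(series))
    else:
        skew = kurt = 0.0
    peaks, _ = signal.find_peaks(
        series,
        prominence=PEAK_PROMINENCE,
        distance=max(1, int(round(PEAK_MIN_SEPARATION_S * fs))),
    )
    # relative variability of the rectified signal: for the non-negative
    # vector-magnitude channel this is exactly the CoV of the magnitude;
    # for the zero-mean detrended axes the rectification keeps the ratio
    # well defined
    cov = coefficient_of_variation(np.abs(series))
    return {
        "mean": float(series.mean()),
        "median": float(np.median(series)),
        "sd": sd,
        "variance": sd**2,
        "cov": cov if np.isfinite(cov) else 0.0,
        "rms": float(np.sqrt(np.mean(series**2))),
        "max": float(series.max()),
        "min": float(series.min()),
        "range": float(series.max() - series.min()),
        "iqr": float(np.subtract(*np.percentile(series, [75, 25]))),
        "skewness": skew,
        "kurtosis": kurt,
        "n_peaks": float(peaks.size),
        "jerk_mean_abs": float(np.mean(np.abs(jerk))),
        "jerk_rms": float(np.sqrt(np.mean(jerk**2))),
    }


def spectral_features(series: np.ndarray, fs: float) -> dict[str, float]:
    """Welch-based band powers and spectral shape of one channel.

    Hann window, segment length min(256, n), 50% overlap.  Band powers
    and shape statistics are restricted to 0.3-4 Hz; an all-zero series
    reports zero bands and dominant frequency 0.
    """
    series = np.asarray(series, dtype=float)
    if series.size < MIN_WINDOW_SAMPLES:
        raise ValueError("series too short for spectral features")
    nperseg = min(256, series.size)
    freqs, psd = signal.welch(
        series, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    band = (freqs >= BAND_LOW) & (freqs <= BAND_HIGH)
    f_band = freqs[band]
    p_band = psd[band]
    df = freqs[1] - freqs[0] if freqs.size > 1 else 1.0
    total = float(p_band.sum() * df)

    out: dict[str, float] = {"power_total": total}
    for (lo, hi), name in zip(REL_BANDS, SPECTRAL_NAMES[1:5]):
        sub = (freqs >= lo) & (freqs < hi)
        out[name] = float(psd[sub].sum() * df / total) if total > 0 else 0.0
    if total > 0 and p_band.size:
        idx = int(np.argmax(p_band))
        out["dom_freq"] = float(f_band[idx])
        out["dom_power"] = float(p_band[idx] * df)
        p_norm = p_band / p_band.sum()
        nz = p_norm[p_norm > 0]
        out["spec_entropy"] = float(-(nz * np.log(nz)).sum())
        out["spec_centroid"] = float((f_band * p_band).sum() / p_band.sum())
        cumulative = np.cumsum(p_band)
        out["median_freq"] = float(f_band[np.searchsorted(cumulative, cumulative[-1] / 2)])
    else:
        out.update(
            dom_freq=0.0, dom_power=0.0, spec_entropy=0.0, spec_centroid=0.0, median_freq=0.0
        )
    return out


def _svm_extras(x: np.ndarray, y: np.ndarray, z: np.ndarray, svm: np.ndarray, fs: float) -> dict[str, float]:
    lag = max(1, int(round(AUTOCORR_LAG_S * fs)))
    if svm.size > lag and svm.std() > 0 and svm[:-lag].std() > 0 and svm[lag:].std() > 0:
        autocorr = float(np.corrcoef(svm[:-lag], svm[lag:])[0, 1])
    else:
        autocorr = 0.0
    crossings = int(np.count_nonzero(np.diff(np.sign(svm - CROSSING_THRESHOLD)) != 0))
    return {
        "sma": float(np.mean(np.abs(x) + np.abs(y) + np.abs(z))),
        "autocorr_0p5s": autocorr,
        "crossings_0p5": float(crossings),
    }


@dataclass(frozen=True)
class WindowSpan:
    index: int
    start: int
    stop: int


def extract_features(rec: ProcessedRecording, window_s: float = 60.0) -> pd.DataFrame:
    """One row per window with the 103 registry features.

    Columns: subject_id, state, window_index, t_start, t_end, window_s,
    the 103 feature columns in registry order, and an ``active`` flag
    (filled by the selection stage, initialised True).
    """
    spans = segment_windows(rec.n_samples, window_s, rec.fs)
    channels = {"x": rec.x, "y": rec.y, "z": rec.z, "svm": rec.svm}
    rows = []
    for index, (start, stop) in enumerate(spans):
        values: dict[str, float] = {}
        for channel in CHANNELS:
            seg = channels[channel][start:stop]
            tf = temporal_features(seg, rec.fs)
            sf = spectral_features(seg, rec.fs)
            for name in TEMPORAL_NAMES:
                values[f"{channel}_{name}"] = tf[name]
            for name in SPECTRAL_NAMES:
                values[f"{channel}_{name}"] = sf[name]
        extras = _svm_extras(
            rec.x[start:stop], rec.y[start:stop], rec.z[start:stop],
            rec.svm[start:stop], rec.fs,
        )
        for name in SVM_EXTRA_NAMES:
            values[f"svm_{name}"] = extras[name]
        row = {
            "subject_id": rec.subject_id,
            "state": rec.state,
            "window_index": index,
            "t_start": rec.t[start],
            "t_end": rec.t[start] + window_s,
            "window_s": window_s,
            **values,
            "active": True,
        }
        rows.append(row)
    columns = (
        ["subject_id", "state", "window_index", "t_start", "t_end", "window_s"]
        + FEATURE_NAMES
        + ["active"]
    )
    return pd.DataFrame(rows, columns=columns)
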