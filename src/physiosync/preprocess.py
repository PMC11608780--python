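"""Signal cleaning: skin-conductance smoothing/filtering and IBI correction.

Skin conductance is median-smoothed (1-s window) and low-pass filtered at
1 Hz (zero-phase 4th-order Butterworth). Inter-beat-interval series are
screened for artifacts against a running median with a local-MAD criterion,
repaired by cubic-spline interpolation over beat index, and resampled onto a
uniform 32 Hz grid for the concordance analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from scipy.interpolate import CubicSpline

from .errors import ConfigError, DataQualityError
from .signal_io import PhysioRecording

#: running-median window (beats) used for IBI artifact detection
_IBI_MED_WINDOW = 11
#: consistency constant making the MAD an unbiased sigma estimate for
#: Gaussian beat-to-beat variability
_MAD_SCALE = 1.4826


@dataclass
class PreprocessConfig:
    sc_median_width_s: float = 1.0
    sc_lowpass_hz: float = 1.0
    ibi_resample_hz: float = 32.0
    ibi_artifact_threshold: float = 3.0  # multiplier on local MAD

    def __post_init__(self) -> None:
        for name in ("sc_median_width_s", "sc_lowpass_hz", "ibi_resample_hz",
                     "ibi_artifact_threshold"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")


def median_smooth(rec: PhysioRecording, width_s: float = 1.0) -> PhysioRecording:
    """Centered running median; window ``round(width_s * rate)`` samples,
    forced odd by +1. Edge windows shrink to the available samples."""
    x = rec.samples
    if x.size == 0:
        raise ConfigError("empty signal")
    w = int(round(width_s * rec.rate_hz))
    if w < 1:
        raise ConfigError("median window shorter than one sample")
    if w % 2 == 0:
        w += 1
    if w == 1:
        return PhysioRecording(rec.participant_id, rec.channel, rec.rate_hz,
                               x.copy(), rec.t0)
    half = w // 2
    # interior via ndimage (edge mode irrelevant there), edges recomputed with
    # shrinking windows so the contract holds exactly
    out = ndimage.median_filter(x, size=w, mode="nearest")
    k = min(half, x.size)
    for i in range(k):
        out[i] = np.median(x[: i + half + 1])
        out[x.size - 1 - i] = np.median(x[max(0, x.size - 1 - i - half):])
    return PhysioRecording(rec.participant_id, rec.channel, rec.rate_hz, out, rec.t0)


def lowpass(rec: PhysioRecording, cutoff_hz: float = 1.0) -> PhysioRecording:
    """Zero-phase (forward-backward) 4th-order Butterworth low-pass."""
    nyq = rec.rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ConfigError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyq} Hz)")
    sos = signal.butter(4, cutoff_hz, btype="low", fs=rec.rate_hz, output="sos")
    y = signal.sosfiltfilt(sos, rec.samples)
    return PhysioRecording(rec.participant_id, rec.channel, rec.rate_hz, y, rec.t0)


def preprocess_sc(rec: PhysioRecording, cfg: PreprocessConfig | None = None) -> PhysioRecording:
    """Median smoothing followed by the 1-Hz low-pass (the SC cleaning chain)."""
    cfg = cfg or PreprocessConfig()
    return lowpass(median_smooth(rec, cfg.sc_median_width_s), cfg.sc_lowpass_hz)


def flag_ibi_artifacts(intervals_ms: np.ndarray, threshold: float = 3.0) -> np.ndarray:
    """Boolean mask of beats deviating from the running median (window 11)
    by more than ``threshold`` local robust standard deviations
    (sigma estimated as 1.4826 x the local MAD)."""
    x = np.asarray(intervals_ms, float)
    half = _IBI_MED_WINDOW // 2
    padded = np.pad(x, half, mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(padded, _IBI_MED_WINDOW)
    med = np.median(windows, axis=1)
    # canonical local MAD: spread of the window samples about the window median
    mad = np.median(np.abs(windows - med[:, None]), axis=1)
    return np.abs(x - med) > threshold * _MAD_SCALE * mad


def correct_ibi(intervals_ms: np.ndarray, cfg: PreprocessConfig | None = None,
                return_flags: bool = False):
    """Flag artifact beats and replace them by cubic-spline interpolation over
    beat index using the unflagged neighbours.

    Raises :class:`DataQualityError` when more than half the beats are flagged
    (mirrors participant exclusion for poor data quality).
    """
    cfg = cfg or PreprocessConfig()
    x = np.asarray(intervals_ms, float)
    if x.size < 4:
        raise ConfigError(f"need at least 4 intervals, got {x.size}")
    out = x.copy()
    idx = np.arange(x.size)
    total = np.zeros(x.size, dtype=bool)
    # iterate to a fixed point: replacing a beat slightly reshapes the local
    # median/MAD, which can expose a neighbouring artifact on the next pass
    for _ in range(10):
        flags = flag_ibi_artifacts(out, cfg.ibi_artifact_threshold)
        total |= flags
        if total.mean() > 0.5:
            raise DataQualityError(
                f"{total.sum()} of {total.size} beats flagged as artifacts (>50%)")
        if not flags.any():
            break
        good = idx[~flags]
        spline = CubicSpline(good, out[~flags])
        out[flags] = spline(idx[flags])
    return (out, total) if return_flags else out


def ibi_to_series(intervals_ms: np.ndarray, resample_hz: float = 32.0,
                  participant_id: str = "") -> PhysioRecording:
    """Interpolate (beat time, interval) points with a cubic spline and sample
    on a uniform grid spanning first to last beat. Beat times are cumulative
    sums of the intervals; values stay in ms."""
    x = np.asarray(intervals_ms, float)
    if x.size < 4:
        raise ConfigError(f"need at least 4 beats, got {x.size}")
    if not resample_hz > 0:
        raise ConfigError("resample_hz must be positive")
    beat_t = np.cumsum(x) / 1000.0  # seconds
    spline = CubicSpline(beat_t, x)
    n = int(np.floor((beat_t[-1] - beat_t[0]) * resample_hz)) + 1
    grid = beat_t[0] + np.arange(n) / resample_hz
    return PhysioRecording(participant_id, "HR", resample_hz, spline(grid), t0=float(beat_t[0]))
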