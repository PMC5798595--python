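"""Per-trial kinematic metrics for evoked whisker movements.

All metrics are referenced to the trial baseline, defined as the mean whisker
angle over the two frames (4 ms) immediately before stimulus onset, so adding
a constant offset to a trace changes nothing. Sign convention: protraction
positive, retraction negative.

Metrics per whisker
-------------------
mean_angle_change
    mean(stimulation window) - baseline, degrees.
binned_angle_change
    the same difference in six 20-ms bins tiling the first 120 ms.
movement_latency
    time of the first stimulation frame whose deviation from baseline exceeds
    (strictly) 4 degrees in either direction; frame ``i`` is stamped
    ``(i - onset + 1) * 2`` ms (end-of-frame). Trials that never cross are
    *censored* (returned as NaN) and excluded from latency maps.
early_peak
    signed deviation of largest magnitude within the first 100 ms
    (earliest frame wins ties).
band_amplitude
    the 5-15 Hz integral of the one-sided FFT amplitude spectrum
    (``2|X_k|/N``, degrees) of the mean-subtracted angle over the last
    400 ms of stimulation. With a 200-frame window the frequency grid is
    2.5 Hz, so the band covers the bins at 5, 7.5, 10, 12.5 and 15 Hz;
    ``bin_sum`` (default) sums the amplitudes, ``trapezoid`` integrates
    them in Hz.

Bilateral metrics
-----------------
bilateral_difference
    mean_angle_change(left) - mean_angle_change(right).
zero_lag_correlation
    zero-lag correlation of the two z-scored stimulation-window traces
    (1/N normalization throughout, so identical traces give exactly 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trials import AngleTrace, Trial

__all__ = [
    "AnalysisParams",
    "baseline_angle",
    "mean_angle_change",
    "binned_angle_change",
    "movement_latency",
    "early_peak",
    "band_amplitude",
    "bilateral_difference",
    "zero_lag_correlation",
    "compute_trial_metrics",
    "compute_metrics",
    "BILATERAL_METRICS",
]

BILATERAL_METRICS = ("lr_difference", "zero_lag_corr")


@dataclass(frozen=True)
class AnalysisParams:
    """All analysis constants, frozen for reproducibility."""

    onset_frame: int = 250
    frame_rate_hz: float = 500.0
    baseline_frames: int = 2  # the 4 ms before onset
    stim_frames: int = 250  # 500 ms of stimulation
    bin_ms: float = 20.0
    n_bins: int = 6  # 0-120 ms
    latency_threshold: float = 4.0  # degrees, strict '>'
    early_window_ms: float = 100.0
    fft_start_frame: int = 300  # 100 ms after onset
    fft_len: int = 200  # 400 ms
    fft_band_hz: tuple[float, float] = (5.0, 15.0)
    band_mode: str = "bin_sum"  # "bin_sum" | "trapezoid"

    def __post_init__(self) -> None:
        if self.band_mode not in ("bin_sum", "trapezoid"):
            raise ValueError(f"unknown band_mode {self.band_mode!r}")
        if self.latency_threshold <= 0:
            raise ValueError("latency_threshold must be positive")
        df = self.frame_rate_hz / self.fft_len
        lo, hi = self.fft_band_hz
        if not (0 < lo < hi):
            raise ValueError("fft_band_hz must be an increasing positive interval")
        for edge in (lo, hi):
            if abs(edge / df - round(edge / df)) > 1e-9:
                raise ValueError("fft_band_hz endpoints must lie on the frequency grid")
        frames_per_bin = self.bin_ms * self.frame_rate_hz / 1000.0
        if abs(frames_per_bin - round(frames_per_bin)) > 1e-9:
            raise ValueError("bin_ms must be a whole number of frames")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.frame_rate_hz

    @property
    def frames_per_bin(self) -> int:
        return int(round(self.bin_ms / self.dt_ms))

    @property
    def early_window_frames(self) -> int:
        return int(round(self.early_window_ms / self.dt_ms))


def _samples(trace) -> np.ndarray:
    if isinstance(trace, AngleTrace):
        return trace.samples
    return np.asarray(trace, dtype=float)


def baseline_angle(trace, params: AnalysisParams | None = None) -> float:
    """Mean angle over the ``baseline_frames`` frames before onset."""
    p = params or AnalysisParams()
    x = _samples(trace)
    return float(np.mean(x[p.onset_frame - p.baseline_frames : p.onset_frame]))


def _stim_window(trace, p: AnalysisParams) -> np.ndarray:
    x = _samples(trace)
    return x[p.onset_frame : p.onset_frame + p.stim_frames]


def mean_angle_change(trace, params: AnalysisParams | None = None) -> float:
    """Mean stimulation-window angle minus baseline (protraction positive)."""
    p = params or AnalysisParams()
    return float(np.mean(_stim_window(trace, p))) - baseline_angle(trace, p)


def binned_angle_change(trace, params: AnalysisParams | None = None) -> np.ndarray:
    """Baseline-referenced mean angle in ``n_bins`` consecutive 20-ms bins."""
    p = params or AnalysisParams()
    base = baseline_angle(trace, p)
    w = _stim_window(trace, p)
    k = p.frames_per_bin
    bins = w[: p.n_bins * k].reshape(p.n_bins, k)
    return bins.mean(axis=1) - base


def movement_latency(trace, params: AnalysisParams | None = None) -> float:
    """Latency (ms) to the first |change| > threshold; NaN when censored."""
    p = params or AnalysisParams()
    dev = np.abs(_stim_window(trace, p) - baseline_angle(trace, p))
    hits = np.nonzero(dev > p.latency_threshold)[0]
    if hits.size == 0:
        return float("nan")
    return float((hits[0] + 1) * p.dt_ms)


def early_peak(trace, params: AnalysisParams | None = None) -> float:
    """Signed extremal change within the first 100 ms (earliest tie wins)."""
    p = params or AnalysisParams()
    dev = _stim_window(trace, p)[: p.early_window_frames] - baseline_angle(trace, p)
    return float(dev[int(np.argmax(np.abs(dev)))])


def band_amplitude(trace, params: AnalysisParams | None = None) -> float:
    """5-15 Hz integral of the FFT amplitude spectrum over the last 400 ms."""
    p = params or AnalysisParams()
    x = _samples(trace)
    seg = x[p.fft_start_frame : p.fft_start_frame + p.fft_len]
    if seg.size != p.fft_len:
        raise ValueError(
            f"FFT window needs {p.fft_len} frames, trace provides {seg.size}"
        )
    seg = seg - seg.mean()
    spectrum = np.fft.rfft(seg)
    amp = 2.0 * np.abs(spectrum[1:]) / p.fft_len  # one-sided amplitude, degrees
    freqs = np.fft.rfftfreq(p.fft_len, d=1.0 / p.frame_rate_hz)[1:]
    lo, hi = p.fft_band_hz
    in_band = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    if p.band_mode == "bin_sum":
        return float(amp[in_band].sum())
    return float(np.trapezoid(amp[in_band], freqs[in_band]))


def bilateral_difference(trial: Trial, params: AnalysisParams | None = None) -> float:
    """Left-minus-right mean angle change, degrees."""
    p = params or AnalysisParams()
    return mean_angle_change(trial.left, p) - mean_angle_change(trial.right, p)


def zero_lag_correlation(trial: Trial, params: AnalysisParams | None = None) -> float:
    """Zero-lag correlation of the z-scored stimulation-window traces.

    Returns NaN (flagged undefined) when either window has zero variance;
    such trials are excluded from correlation maps.
    """
    p = params or AnalysisParams()
    left = _stim_window(trial.left, p)
    right = _stim_window(trial.right, p)
    sl = left.std()  # population (1/N) convention, matching the z-scoring
    sr = right.std()
    if sl == 0.0 or sr == 0.0:
        return float("nan")
    zl = (left - left.mean()) / sl
    zr = (right - right.mean()) / sr
    return float(np.mean(zl * zr))


def compute_trial_metrics(trial: Trial, params: AnalysisParams | None = None) -> dict:
    """All per-trial metrics for both whiskers plus the bilateral metrics."""
    p = params or AnalysisParams()
    if not trial.tracked:
        raise ValueError("metrics require a tracked trial")
    row, col = trial.grid_site
    out = {
        "mouse": trial.mouse_id,
        "session": trial.session_id,
        "rep": trial.rep_index,
        "row": row,
        "col": col,
        "ml_mm": trial.coord_mm[0],
        "ap_mm": trial.coord_mm[1],
        "power": trial.power,
    }
    for side in ("left", "right"):
        tr = trial.whisker(side)
        out[f"mean_change_{side}"] = mean_angle_change(tr, p)
        for k, v in enumerate(binned_angle_change(tr, p)):
            out[f"bin{k}_{side}"] = float(v)
        lat = movement_latency(tr, p)
        out[f"latency_ms_{side}"] = lat
        out[f"censored_{side}"] = bool(np.isnan(lat))
        out[f"early_peak_{side}"] = early_peak(tr, p)
        out[f"band_amp_{side}"] = band_amplitude(tr, p)
    out["lr_difference"] = bilateral_difference(trial, p)
    out["zero_lag_corr"] = zero_lag_correlation(trial, p)
    return out


def compute_metrics(
    trials: list[Trial],
    params: AnalysisParams | None = None,
    *,
    skip_untracked: bool = True,
) -> pd.DataFrame:
    """Metrics table: one row per tracked trial.

    Untracked trials are skipped with a warning (or raise when
    ``skip_untracked`` is False); normally the input is already QC-filtered.
    """
    p = params or AnalysisParams()
    rows = []
    n_untracked = 0
    for t in trials:
        if not t.tracked:
            if not skip_untracked:
                raise ValueError(f"untracked trial {t.key} in metrics input")
            n_untracked += 1
            continue
        rows.append(compute_trial_metrics(t, p))
    if n_untracked:
        warnings.warn(f"skipped {n_untracked} untracked trial(s)", stacklevel=2)
    return pd.DataFrame(rows)
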