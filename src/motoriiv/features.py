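"""Per-trial feature extraction from sampled isometric force traces.

A trial is a single rapid ("pulse") contraction recorded as a uniformly
sampled force-time series. Three features summarize it: contraction onset,
peak force, and time-to-peak force (peak time minus onset). Onset is found
with a baseline-statistics threshold — the earliest sample exceeding
baseline mean + k x baseline SD and staying above it for a minimum hold
time — falling back to a fixed absolute threshold when the baseline is
noise-free. An optional zero-lag Butterworth low-pass is available but off
by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal


class NoContractionError(ValueError):
    """The force record never crosses the onset threshold."""


@dataclass
class ForceTrace:
    """One trial's sampled force record.

    samples are force values in N at uniform spacing 1/fs, starting at t=0.
    """

    participant_id: str
    trial: int
    fs: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 0.5 * self.fs:
            raise ValueError("trace shorter than 0.5 s")
        if np.isnan(self.samples).any():
            raise ValueError("missing samples inside the record")

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.samples.size / self.fs

    def time_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) * (1000.0 / self.fs)


@dataclass(frozen=True)
class OnsetParams:
    """Onset-detection settings: baseline window, SD multiple, hold time."""

    baseline_window_ms: float = 100.0
    k_sd: float = 3.0
    min_hold_ms: float = 25.0
    absolute_fallback_N: float = 0.2


@dataclass(frozen=True)
class TrialFeatures:
    participant_id: str
    trial: int
    onset_ms: float
    peak_force_N: float
    time_to_peak_ms: float


def onset_threshold(trace: ForceTrace, params: OnsetParams) -> float:
    """Threshold in N: baseline mean + k x SD, or mean + fixed fallback when
    the baseline window has zero variance."""
    n_base = max(int(round(params.baseline_window_ms * trace.fs / 1000.0)), 1)
    base = trace.samples[:n_base]
    mu, sd = float(base.mean()), float(base.std(ddof=0))
    if sd == 0.0:
        return mu + params.absolute_fallback_N
    return mu + params.k_sd * sd


def detect_onset(trace: ForceTrace, params: OnsetParams | None = None) -> float:
    """Earliest time (ms) at which force exceeds the onset threshold and
    remains above it for ``min_hold_ms``. Raises :class:`NoContractionError`
    when no sustained crossing exists."""
    params = params or OnsetParams()
    thr = onset_threshold(trace, params)
    above = trace.samples > thr
    hold = max(int(round(params.min_hold_ms * trace.fs / 1000.0)), 1)
    if above.size < hold:
        raise NoContractionError("record shorter than the hold window")
    runs = np.convolve(above.astype(int), np.ones(hold, dtype=int), "valid")
    idx = np.nonzero(runs == hold)[0]
    if idx.size == 0:
        raise NoContractionError(
            f"no sustained crossing of {thr:.3g} N for {params.min_hold_ms} ms"
        )
    return float(idx[0]) * 1000.0 / trace.fs


def lowpass(trace: ForceTrace, cutoff_hz: float = 20.0, order: int = 4) -> ForceTrace:
    """Zero-lag (forward-backward) Butterworth low-pass filtered copy."""
    sos = signal.butter(order, cutoff_hz, btype="low", fs=trace.fs, output="sos")
    return replace(trace, samples=signal.sosfiltfilt(sos, trace.samples))


def extract_features(
    trace: ForceTrace,
    params: OnsetParams | None = None,
    filter_hz: float | None = None,
) -> TrialFeatures:
    """Onset, peak force and time-to-peak for one trial.

    Peak force is the global maximum at or after onset; exact ties go to the
    earliest sample. ``filter_hz`` optionally low-passes the trace first.
    """
    if filter_hz is not None:
        trace = lowpass(trace, cutoff_hz=filter_hz)
    onset_ms = detect_onset(trace, params)
    i0 = int(round(onset_ms * trace.fs / 1000.0))
    seg = trace.samples[i0:]
    i_peak = i0 + int(np.argmax(seg))  # argmax returns the first maximum
    peak = float(trace.samples[i_peak])
    ttp_ms = (i_peak - i0) * 1000.0 / trace.fs
    if peak <= 0 or ttp_ms <= 0:
        raise NoContractionError(
            f"degenerate peak (force {peak:.3g} N at +{ttp_ms:.0f} ms)"
        )
    return TrialFeatures(trace.participant_id, trace.trial, onset_ms, peak, ttp_ms)


def extract_features_table(
    traces: Iterable[ForceTrace],
    params: OnsetParams | None = None,
    filter_hz: float | None = None,
) -> pd.DataFrame:
    """Feature extraction over many traces, as a tidy per-trial table."""
    rows = [extract_features(tr, params, filter_hz) for tr in traces]
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in rows],
            "trial": [r.trial for r in rows],
            "onset_ms": [r.onset_ms for r in rows],
            "peak_force_N": [r.peak_force_N for r in rows],
            "time_to_peak_ms": [r.time_to_peak_ms for r in rows],
        }
    )


def read_traces_csv(path) -> list[ForceTrace]:
    """Load traces from long-format CSV (participant_id,trial,time_ms,force_N)."""
    df = pd.read_csv(path)
    required = {"participant_id", "trial", "time_ms", "force_N"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    out: list[ForceTrace] = []
    for (pid, trial), grp in df.groupby(["participant_id", "trial"], sort=True):
        grp = grp.sort_values("time_ms")
        t = grp["time_ms"].to_numpy(dtype=float)
        dt = np.diff(t)
        if t.size > 1 and not np.allclose(dt, dt[0]):
            raise ValueError(f"non-uniform sampling for {pid} trial {trial}")
        fs = 1000.0 / dt[0] if t.size > 1 else 1000.0
        out.append(ForceTrace(str(pid), int(trial), fs,
                              grp["force_N"].to_numpy(dtype=float)))
    return out


def traces_to_long_frame(traces: Iterable[ForceTrace]) -> pd.DataFrame:
    """Long-format frame (participant_id,trial,time_ms,force_N) of traces."""
    parts = []
    for tr in traces:
        parts.append(pd.DataFrame({
            "participant_id": tr.participant_id,
            "trial": tr.trial,
            "time_ms": tr.time_ms(),
            "force_N": tr.samples,
        }))
    return pd.concat(parts, ignore_index=True)
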