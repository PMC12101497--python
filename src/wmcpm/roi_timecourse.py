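"""Condition-wise percent-signal-change time courses from an ROI signal.

The ROI average signal is segmented at each trial's encoding onset, averaged
within condition, converted to percent signal change against a designated
baseline condition, psc[t] = (cond[t] - base[t]) / base[t], and summarized
over the delay-phase window (13-15 s after onset by default, endpoints
inclusive; sample times are index * TR from onset).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RoiSeries:
    """An ROI signal with trial onsets and condition labels."""

    values: np.ndarray
    tr: float
    onsets: np.ndarray  # seconds
    conditions: np.ndarray  # label per onset
    baseline_label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=object)
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.onsets.shape != self.conditions.shape:
            raise ValueError("one condition label per onset required")
        dur = len(self.values) * self.tr
        if np.any((self.onsets < 0) | (self.onsets >= dur)):
            raise ValueError("onsets must lie within the series duration")


def segment_and_average(series: RoiSeries, window_s: float) -> pd.DataFrame:
    """Mean post-onset window per condition, sampled at the series TR.

    Trials whose window runs past the end of the series are dropped with a
    warning; a condition losing every trial is an error.
    """
    n_samp = int(np.floor(window_s / series.tr)) + 1  # onset sample included
    segments: dict[str, list[np.ndarray]] = {}
    dropped = 0
    for onset, cond in zip(series.onsets, series.conditions):
        start = int(round(onset / series.tr))
        stop = start + n_samp
        if stop > len(series.values):
            dropped += 1
            continue
        segments.setdefault(cond, []).append(series.values[start:stop])
    if dropped:
        warnings.warn(f"dropped {dropped} trial(s) extending past the series end",
                      stacklevel=2)
    missing = set(series.conditions) - set(segments)
    if missing:
        raise ValueError(f"no usable trials for condition(s) {sorted(missing)}")
    times = np.arange(n_samp) * series.tr
    out = pd.DataFrame(
        {cond: np.mean(trials, axis=0) for cond, trials in segments.items()}
    ).T
    out.columns = times
    out.index.name = "condition"
    return out.sort_index()


def percent_signal_change(condition_tc, baseline_tc) -> np.ndarray:
    """psc[t] = (cond[t] - base[t]) / base[t], timepoint-wise."""
    cond = np.asarray(condition_tc, dtype=float)
    base = np.asarray(baseline_tc, dtype=float)
    if cond.shape != base.shape:
        raise ValueError("condition and baseline time courses differ in length")
    zero = np.flatnonzero(base == 0)
    if zero.size:
        raise ZeroDivisionError(
            f"baseline is zero at timepoint(s) {zero.tolist()}"
        )
    return (cond - base) / base


def psc_table(series: RoiSeries, window_s: float) -> pd.DataFrame:
    """Per-condition percent-signal-change time courses against the baseline."""
    if series.baseline_label is None:
        raise ValueError("series has no designated baseline condition")
    seg = segment_and_average(series, window_s)
    if series.baseline_label not in seg.index:
        raise ValueError(f"baseline condition {series.baseline_label!r} not found")
    base = seg.loc[series.baseline_label].to_numpy()
    rows = {
        cond: percent_signal_change(seg.loc[cond].to_numpy(), base)
        for cond in seg.index
        if cond != series.baseline_label
    }
    out = pd.DataFrame(rows).T
    out.columns = seg.columns
    out.index.name = "condition"
    return out


def delay_window_mean(
    psc, tr: float, t_start: float = 13.0, t_end: float = 15.0
) -> float:
    """Mean psc over samples with t_start <= index*tr <= t_end (inclusive)."""
    x = np.asarray(psc, dtype=float)
    if tr <= 0:
        raise ValueError("tr must be positive")
    times = np.arange(len(x)) * tr
    mask = (times >= t_start) & (times <= t_end)
    if not mask.any():
        raise ValueError(
            f"no samples in window [{t_start}, {t_end}] s at tr={tr}"
        )
    return float(x[mask].mean())
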