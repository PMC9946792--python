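"""Trial segmentation with edge exclusions and per-condition power reduction.

Trial markers in an awake-craniotomy session are placed by hand on the
acquisition system, so they carry human reaction-time error.  The
standard guard is to shave the trial edges before averaging: 2 s from
both ends of the rest period, 1 s from both ends of each task trial, and
a further 3 s from the start of every switch trial to discard the easy
initial phase of the alternation task (1, a, 2, b, ...).  The retained
windows are half-open sample intervals, so the arithmetic is exact
sample counting.

Each condition then reduces to a single scalar per electrode and band:
the time-point mean over the concatenation of its retained trials
(equivalently a duration-weighted mean over trials), and condition pairs
reduce to the percent-change ratio ``(p1/p2 - 1) * 100``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .data_model import (
    BandPowerSeries,
    ConditionPower,
    EventTable,
    Recording,
    ValidationError,
)

__all__ = [
    "ExclusionRule",
    "TrialSegment",
    "segment_trials",
    "condition_mean_power",
    "percent_change",
    "condition_power_table",
    "psd_contrast",
]


@dataclass(frozen=True)
class ExclusionRule:
    """Edge seconds removed from each trial before averaging.

    rest trials keep ``[onset + rest_edge_s, offset - rest_edge_s)``;
    count trials keep ``[onset + task_edge_s, offset - task_edge_s)``;
    switch trials additionally lose ``switch_extra_start_s`` at the start.
    """

    rest_edge_s: float = 2.0
    task_edge_s: float = 1.0
    switch_extra_start_s: float = 3.0
    # set to 0.0 for the single-ended reading of the task-trial rule
    task_edge_end_s: float | None = None

    def retained_window(self, onset_s: float, offset_s: float, condition: str) -> tuple[float, float]:
        """Retained [start, stop) in seconds for one trial."""
        end_cut = self.task_edge_s if self.task_edge_end_s is None else self.task_edge_end_s
        if condition == "rest":
            return onset_s + self.rest_edge_s, offset_s - self.rest_edge_s
        if condition == "count":
            return onset_s + self.task_edge_s, offset_s - end_cut
        if condition == "switch":
            return onset_s + self.task_edge_s + self.switch_extra_start_s, offset_s - end_cut
        raise ValidationError(f"unknown condition {condition!r}")


@dataclass(frozen=True)
class TrialSegment:
    """One retained trial window on a power series: half-open sample
    interval ``[start, start + length)`` plus its condition label."""

    start: int
    length: int
    condition: str
    trial_index: int


def segment_trials(
    power: BandPowerSeries | Recording,
    events: EventTable,
    rule: ExclusionRule = ExclusionRule(),
) -> list[TrialSegment]:
    """Map each trial to its retained half-open sample window.

    Sub-sample boundaries are rounded to the nearest sample.  Trials
    whose retained window is empty are dropped with a warning.
    """
    fs = power.fs
    n = power.power.shape[1] if isinstance(power, BandPowerSeries) else power.n_samples
    events.check_within(n / fs)
    segments: list[TrialSegment] = []
    for row in events.trials.itertuples():
        t0, t1 = rule.retained_window(row.onset_s, row.offset_s, row.condition)
        a = int(round(t0 * fs))
        b = int(round(t1 * fs))
        a, b = max(a, 0), min(b, n)
        if b <= a:
            warnings.warn(
                f"trial {row.trial_index} ({row.condition}) retains no samples after exclusions; dropped"
            )
            continue
        segments.append(TrialSegment(start=a, length=b - a, condition=row.condition,
                                     trial_index=int(row.trial_index)))
    return segments


def condition_mean_power(
    series: np.ndarray, segments: list[TrialSegment], condition: str
) -> tuple[float, int]:
    """Time-point mean over the concatenated retained trials of one
    condition for one channel; returns ``(mean, n_samples)``."""
    parts = [series[s.start:s.start + s.length] for s in segments if s.condition == condition]
    if not parts:
        raise ValidationError(f"no retained trials for condition {condition!r}")
    cat = np.concatenate(parts)
    return float(cat.mean()), int(cat.size)


def percent_change(p1: float, p2: float) -> float:
    """Percent signal change ``(p1/p2 - 1) * 100``.

    Not antisymmetric under swapping its arguments; it is exactly the
    stated ratio formula.  ``p2`` must be positive.
    """
    if not p2 > 0:
        raise ValidationError(f"percent_change undefined for reference power {p2}")
    return (p1 / p2 - 1.0) * 100.0


#: Condition pairs analyzed by default, as (numerator, denominator).
DEFAULT_CONTRASTS = (("switch", "count"), ("count", "rest"))


def condition_power_table(
    band_powers: list[BandPowerSeries],
    events: EventTable,
    rule: ExclusionRule = ExclusionRule(),
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS,
) -> ConditionPower:
    """Tidy per-(electrode, band) condition means and contrast tables."""
    mean_rows, contrast_rows = [], []
    for bp in band_powers:
        segments = segment_trials(bp, events, rule)
        present = {s.condition for s in segments}
        for ch, name in enumerate(bp.channel_names):
            means = {}
            for cond in sorted(present):
                m, nsamp = condition_mean_power(bp.power[ch], segments, cond)
                means[cond] = m
                mean_rows.append({"electrode": name, "band": bp.band.name,
                                  "condition": cond, "mean_power": m, "n_samples": nsamp})
            for c1, c2 in contrasts:
                if c1 in means and c2 in means:
                    contrast_rows.append({
                        "electrode": name, "band": bp.band.name,
                        "contrast": f"{c1}_vs_{c2}",
                        "percent_change": percent_change(means[c1], means[c2]),
                    })
    return ConditionPower(means=pd.DataFrame(mean_rows), contrasts=pd.DataFrame(contrast_rows))


def psd_contrast(
    rec: Recording,
    events: EventTable,
    conditions: tuple[str, str] = ("switch", "count"),
    rule: ExclusionRule = ExclusionRule(),
    window_s: float = 1.0,
    notch_mask_bands: list[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-frequency percent change between two conditions.

    Welch PSDs (Hann windows of ``window_s`` seconds, 50% overlap) are
    estimated per retained trial, averaged within condition, and passed
    through the percent-change formula per frequency bin.  Frequency
    bins inside ``notch_mask_bands`` can be masked for display.

    Returns a frame with columns channel, frequency_hz, percent_change,
    masked.
    """
    segments = segment_trials(rec, events, rule)
    nperseg = int(round(window_s * rec.fs))
    cond_psd: dict[str, np.ndarray] = {}
    freqs = None
    for cond in conditions:
        per_trial = []
        for s in segments:
            if s.condition != cond or s.length < nperseg:
                continue
            f, pxx = sp_signal.welch(
                rec.data[:, s.start:s.start + s.length],
                fs=rec.fs, window="hann", nperseg=nperseg,
                noverlap=nperseg // 2, axis=1,
            )
            freqs = f
            per_trial.append(pxx)
        if not per_trial:
            raise ValidationError(f"no analyzable trials for condition {cond!r}")
        cond_psd[cond] = np.mean(per_trial, axis=0)
    c1, c2 = conditions
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = (cond_psd[c1] / cond_psd[c2] - 1.0) * 100.0
    masked = np.zeros_like(freqs, dtype=bool)
    for lo, hi in notch_mask_bands or []:
        masked |= (freqs >= lo) & (freqs <= hi)
    rows = []
    for ch, name in enumerate(rec.channel_names):
        rows.append(pd.DataFrame({
            "channel": name, "frequency_hz": freqs,
            "percent_change": pct[ch], "masked": masked,
        }))
    return pd.concat(rows, ignore_index=True)
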