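"""Wearable stream cleaning and 2-hour block aggregation.

Heart rate arrives as 30-second means sampled every 10 minutes; steps and
activity states arrive as events with start/end timestamps.  Event values are
distributed across blocks by proportional temporal overlap, which conserves
totals across any partition of time into blocks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._time import dt64

HR_MIN_BPM = 30.0
HR_MAX_BPM = 220.0
#: Cadences above this are implausible even for elite runners.
MAX_STEPS_PER_MIN = 200.0
#: Heart-rate zone bounds: resting <= 60 < moderate < 100 <= vigorous.
HR_ZONE_RESTING_MAX = 60.0
HR_ZONE_VIGOROUS_MIN = 100.0

ACTIVITY_CATEGORIES = ("walking", "running", "cycling", "sleep", "rest", "active")


def clean_hr(samples: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop non-numeric values and bpm outside the physiological range.

    The bounds [30, 220] are inclusive.  Order is preserved.  Returns the
    cleaned frame and the number of removed samples.
    """
    df = samples.copy()
    bpm = pd.to_numeric(df["bpm"], errors="coerce")
    keep = bpm.notna() & (bpm >= HR_MIN_BPM) & (bpm <= HR_MAX_BPM)
    out = df.loc[keep].copy()
    out["bpm"] = bpm[keep]
    return out, int((~keep).sum())


def clean_steps(events: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop implausible step events, tallying removals by reason.

    Reasons: ``non_numeric`` (or negative counts), ``non_positive_duration``
    (end <= start), ``cadence`` (steps per minute > 200).
    """
    df = events.copy()
    steps = pd.to_numeric(df["steps"], errors="coerce")
    tally = {"non_numeric": 0, "non_positive_duration": 0, "cadence": 0}
    bad_num = steps.isna() | (steps < 0)
    tally["non_numeric"] = int(bad_num.sum())
    df = df.loc[~bad_num].copy()
    df["steps"] = steps[~bad_num]
    dur_min = (df["end"] - df["start"]).dt.total_seconds() / 60.0
    bad_dur = dur_min <= 0
    tally["non_positive_duration"] = int(bad_dur.sum())
    df = df.loc[~bad_dur]
    dur_min = dur_min[~bad_dur]
    bad_cad = df["steps"] / dur_min > MAX_STEPS_PER_MIN
    tally["cadence"] = int(bad_cad.sum())
    df = df.loc[~bad_cad]
    return df, tally


def clean_activity(events: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop events with non-boolean flags, unknown categories or end <= start."""
    df = events.copy()
    ok_flag = df["flag"].isin([True, False, 0, 1])
    ok_cat = df["category"].isin(ACTIVITY_CATEGORIES)
    ok_dur = df["end"] > df["start"]
    keep = ok_flag & ok_cat & ok_dur
    out = df.loc[keep].copy()
    out["flag"] = out["flag"].astype(bool)
    return out, int((~keep).sum())


def aggregate_hr(samples: pd.DataFrame, window: tuple, block_minutes: float = 120.0) -> dict:
    """Heart-rate features over the half-open window [start, end).

    Zone minutes are block_minutes * (samples in zone / samples in window):
    the stream is a fixed 10-minute grid, so sample counts proxy time, and
    this definition makes zone minutes sum exactly to the block length
    whenever at least one sample exists.  std uses the population formula
    (a single sample gives 0).
    """
    start, end = window
    ts = dt64(samples["timestamp"])
    m = (ts >= dt64(start)) & (ts < dt64(end))
    if not m.any():
        return {
            "hr_mean": np.nan, "hr_min": np.nan, "hr_max": np.nan, "hr_std": np.nan,
            "hr_zone_resting": np.nan, "hr_zone_moderate": np.nan,
            "hr_zone_vigorous": np.nan, "missing_hr": True,
        }
    bpm = samples.loc[m, "bpm"].to_numpy(float)
    n = bpm.size
    resting = np.sum(bpm <= HR_ZONE_RESTING_MAX)
    vigorous = np.sum(bpm >= HR_ZONE_VIGOROUS_MIN)
    moderate = n - resting - vigorous
    return {
        "hr_mean": float(bpm.mean()),
        "hr_min": float(bpm.min()),
        "hr_max": float(bpm.max()),
        "hr_std": float(bpm.std(ddof=0)),
        "hr_zone_resting": block_minutes * resting / n,
        "hr_zone_moderate": block_minutes * moderate / n,
        "hr_zone_vigorous": block_minutes * vigorous / n,
        "missing_hr": False,
    }


def aggregate_overlap(events: pd.DataFrame, window: tuple, value) -> float:
    """Sum event values weighted by the fraction of each event inside window.

    ``value`` is a column name or a callable mapping the events frame to a
    numeric series.  Contribution of an event = value * |event ∩ window| /
    |event|.  Zero-length events are rejected (cleaning must precede).
    Returns NaN when no event overlaps the window at all.
    """
    if len(events) == 0:
        return np.nan
    start = dt64(window[0])
    end = dt64(window[1])
    ev_start = dt64(events["start"])
    ev_end = dt64(events["end"])
    dur = (ev_end - ev_start) / np.timedelta64(1, "s")
    if np.any(dur <= 0):
        raise ValueError("zero- or negative-length event; clean events first")
    ov = (np.minimum(ev_end, end) - np.maximum(ev_start, start)) / np.timedelta64(1, "s")
    ov = np.clip(ov, 0.0, None)
    if not np.any(ov > 0):
        return np.nan
    vals = events[value].to_numpy(float) if isinstance(value, str) else np.asarray(value(events), float)
    return float(np.sum(vals * ov / dur))


def activity_minutes(events: pd.DataFrame, window: tuple) -> dict:
    """Overlap-weighted minutes per activity category; NaN when no events."""
    out = {}
    for cat in ACTIVITY_CATEGORIES:
        sub = events[(events["category"] == cat) & events["flag"]] if len(events) else events
        val = aggregate_overlap(
            sub, window, lambda df: (df["end"] - df["start"]).dt.total_seconds() / 60.0
        ) if len(sub) else np.nan
        out[f"activity_{cat}"] = val
    return out


def wearable_block_features(
    hr: pd.DataFrame,
    steps: pd.DataFrame,
    activity: pd.DataFrame,
    window: tuple,
    block_minutes: float = 120.0,
) -> dict:
    """All wearable features for one block, with per-stream missing flags.

    ``watch_off`` is true iff heart rate, steps and activity are all absent
    in the window — the signature of the watch not being worn.
    """
    feats = aggregate_hr(hr, window, block_minutes)
    step_sum = aggregate_overlap(steps, window, "steps") if len(steps) else np.nan
    feats["steps"] = step_sum
    feats["missing_steps"] = bool(np.isnan(step_sum)) if isinstance(step_sum, float) else False
    act = activity_minutes(activity, window)
    feats.update(act)
    feats["missing_activity"] = all(np.isnan(v) for v in act.values())
    feats["watch_off"] = bool(
        feats["missing_hr"] and feats["missing_steps"] and feats["missing_activity"]
    )
    return feats
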