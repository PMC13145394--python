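"""Outcome construction, context features, missingness policy, assembly.

A *block* is the half-open 2-hour window [t-2h, t) preceding an answered EMA
beep at time t; the beep's negative-affect score (mean of eight 1-7 items)
is the label and the window's aggregated sensor features are the predictors.

Missing sensor values are split into two disjoint mechanisms:

* structural absence of an event (no location change, no detected walking)
  -> fixed fills: 0 for distance, GPS point count, transition minutes, steps
  and all activity minutes; 120 for minutes at home and minutes stationary;
* absence despite an expected signal (watch not worn; GPS dropout while the
  participant reported travelling) -> cells marked MCAR for in-fold k-NN
  imputation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import gps as gpsmod
from . import wearables as wear

GPS_FEATURES = ["distance_km", "n_gps_points", "minutes_home",
                "minutes_transition", "minutes_stationary"]
HR_FEATURES = ["hr_mean", "hr_min", "hr_max", "hr_std",
               "hr_zone_resting", "hr_zone_moderate", "hr_zone_vigorous"]
ACTIVITY_FEATURES = [f"activity_{c}" for c in wear.ACTIVITY_CATEGORIES]
STEP_FEATURES = ["steps"]
WEARABLE_FEATURES = HR_FEATURES + STEP_FEATURES + ACTIVITY_FEATURES
PASSIVE_FEATURES = GPS_FEATURES + WEARABLE_FEATURES
CONTEXT_FEATURES = ["assessment_hour", "time_of_day", "weekday", "weekend",
                    "season", "month", "temp_avg", "sunshine_h", "precipitation_h"]
#: The 28 time-varying model features.
TIME_VARYING_FEATURES = PASSIVE_FEATURES + CONTEXT_FEATURES
#: The six person-stable model features.
PS_FEATURES = ["age", "employable", "smartphone_type", "somatic_problems",
               "psychotropic_medication", "prior_treatment"]

ITEM_COLUMNS = ["item_downcast", "item_sad", "item_anxious", "item_nervous",
                "item_irritable", "item_angry", "item_ashamed", "item_dissatisfied"]

#: Structural fill values for event-based features absent without an event.
STRUCTURAL_FILLS = {
    "distance_km": 0.0, "n_gps_points": 0.0, "minutes_transition": 0.0,
    "minutes_home": 120.0, "minutes_stationary": 120.0,
    "steps": 0.0, **{c: 0.0 for c in ACTIVITY_FEATURES},
}

BLOCK_HOURS = 2.0


def compute_na(items) -> float:
    """Negative-affect score: arithmetic mean of the eight 1-7 items.

    A beep missing any item is unanswered; there is no partial scoring.
    """
    arr = np.asarray(items, float)
    if arr.shape != (8,) or np.any(~np.isfinite(arr)):
        raise ValueError("need exactly 8 answered items")
    if np.any(arr < 1) or np.any(arr > 7) or np.any(arr != np.round(arr)):
        raise ValueError("items must be integers in [1, 7]")
    return float(arr.mean())


_SEASONS = {12: "winter", 1: "winter", 2: "winter", 3: "spring", 4: "spring",
            5: "spring", 6: "summer", 7: "summer", 8: "summer",
            9: "fall", 10: "fall", 11: "fall"}
_WEEKDAYS = ["monday", "tuesday", "wednesday", "thursday", "friday", "saturday", "sunday"]


def time_of_day(hour: int) -> str:
    if 5 <= hour < 9:
        return "early_morning"
    if 9 <= hour < 12:
        return "morning"
    if 12 <= hour < 18:
        return "afternoon"
    if 18 <= hour < 23:
        return "evening"
    return "night"


def context_features(timestamp_utc, weather: pd.DataFrame, utc_offset_h: int = 1) -> dict:
    """Time-of-assessment and weather covariates for one beep.

    Weather is a single-site daily table joined on the beep's local calendar
    date; time bins follow the local clock (fixed UTC offset).
    """
    local = pd.Timestamp(timestamp_utc) + pd.Timedelta(hours=utc_offset_h)
    date = local.strftime("%Y-%m-%d")
    w = weather[weather["date"] == date]
    row = w.iloc[0] if len(w) else None
    return {
        "assessment_hour": int(local.hour),
        "time_of_day": time_of_day(local.hour),
        "weekday": _WEEKDAYS[local.dayofweek],
        "weekend": bool(local.dayofweek >= 5),
        "season": _SEASONS[local.month],
        "month": int(local.month),
        "temp_avg": float(row["temp_avg"]) if row is not None else np.nan,
        "sunshine_h": float(row["sunshine_h"]) if row is not None else np.nan,
        "precipitation_h": float(row["precipitation_h"]) if row is not None else np.nan,
    }


def _overlap_sum(ev_start, ev_end, ev_val, w0, w1):
    """Vectorized proportional-overlap sum; NaN when nothing overlaps."""
    if len(ev_start) == 0:
        return np.nan
    dur = (ev_end - ev_start) / np.timedelta64(1, "s")
    ov = np.minimum(ev_end, w1) - np.maximum(ev_start, w0)
    ov = np.clip(ov / np.timedelta64(1, "s"), 0.0, None)
    if not np.any(ov > 0):
        return np.nan
    return float(np.sum(ev_val * ov / dur))


def build_blocks_for_participant(pid, streams, beeps, weather, utc_offset_h=1) -> pd.DataFrame:
    """Compute features for every answered beep of one participant.

    Semantically identical to composing :func:`wearables.aggregate_hr`,
    :func:`wearables.aggregate_overlap` and :func:`gps.mobility_features`
    per window, but with per-participant precomputed arrays so a 14-day
    burst stays cheap.
    """
    from ._time import dt64

    hr, _ = wear.clean_hr(streams["hr"])
    steps, _ = wear.clean_steps(streams["steps"])
    activity, _ = wear.clean_activity(streams["activity"])
    gpsres = gpsmod.process_trace(streams["gps"], utc_offset_h)
    block_minutes = BLOCK_HOURS * 60

    hr_ts = dt64(hr["timestamp"]) if len(hr) else np.empty(0, "datetime64[ns]")
    hr_bpm = hr["bpm"].to_numpy(float) if len(hr) else np.empty(0)
    st_start = dt64(steps["start"]) if len(steps) else np.empty(0, "datetime64[ns]")
    st_end = dt64(steps["end"]) if len(steps) else np.empty(0, "datetime64[ns]")
    st_val = steps["steps"].to_numpy(float) if len(steps) else np.empty(0)
    act_arrays = {}
    for cat in wear.ACTIVITY_CATEGORIES:
        sub = activity[(activity["category"] == cat) & activity["flag"]] if len(activity) else activity
        if len(sub):
            a0, a1 = dt64(sub["start"]), dt64(sub["end"])
            act_arrays[cat] = (a0, a1, (a1 - a0) / np.timedelta64(1, "m"))
        else:
            act_arrays[cat] = None
    ann = gpsres.annotated
    g_ts = dt64(ann["timestamp"]) if len(ann) else np.empty(0, "datetime64[ns]")
    g_lat = ann["lat"].to_numpy(float) if len(ann) else np.empty(0)
    g_lon = ann["lon"].to_numpy(float) if len(ann) else np.empty(0)
    g_dwell = ann["dwell_min"].to_numpy(float) if len(ann) else np.empty(0)
    g_stat = ann["stationary"].to_numpy(bool) if len(ann) else np.empty(0, bool)
    g_lab = gpsres.labels_full
    home_id = gpsres.cluster_set.home_id
    weather_by_date = {r["date"]: r for _, r in weather.iterrows()}

    rows = []
    for b in beeps.itertuples():
        if not b.answered:
            continue
        items = [getattr(b, c) for c in ITEM_COLUMNS]
        if any(pd.isna(items)):
            continue
        t = b.timestamp
        w0 = dt64(t - pd.Timedelta(hours=BLOCK_HOURS))
        w1 = dt64(t)
        row = {"participant": pid, "timestamp": t, "beep_idx": int(b.beep_idx),
               "na": compute_na(items), "travelling_flag": bool(b.travelling_flag)}
        # heart rate
        lo, hi = np.searchsorted(hr_ts, w0), np.searchsorted(hr_ts, w1)
        bpm = hr_bpm[lo:hi]
        if bpm.size:
            n = bpm.size
            resting = int(np.sum(bpm <= wear.HR_ZONE_RESTING_MAX))
            vigorous = int(np.sum(bpm >= wear.HR_ZONE_VIGOROUS_MIN))
            row.update(hr_mean=float(bpm.mean()), hr_min=float(bpm.min()),
                       hr_max=float(bpm.max()), hr_std=float(bpm.std(ddof=0)),
                       hr_zone_resting=block_minutes * resting / n,
                       hr_zone_moderate=block_minutes * (n - resting - vigorous) / n,
                       hr_zone_vigorous=block_minutes * vigorous / n,
                       missing_hr=False)
        else:
            row.update(hr_mean=np.nan, hr_min=np.nan, hr_max=np.nan, hr_std=np.nan,
                       hr_zone_resting=np.nan, hr_zone_moderate=np.nan,
                       hr_zone_vigorous=np.nan, missing_hr=True)
        # steps
        s = _overlap_sum(st_start, st_end, st_val, w0, w1)
        row["steps"] = s
        row["missing_steps"] = bool(np.isnan(s))
        # activity categories
        any_act = False
        for cat in wear.ACTIVITY_CATEGORIES:
            arrs = act_arrays[cat]
            v = _overlap_sum(*arrs, w0, w1) if arrs is not None else np.nan
            row[f"activity_{cat}"] = v
            any_act = any_act or not np.isnan(v)
        row["missing_activity"] = not any_act
        row["watch_off"] = bool(row["missing_hr"] and row["missing_steps"]
                                and row["missing_activity"])
        # GPS mobility
        lo, hi = np.searchsorted(g_ts, w0), np.searchsorted(g_ts, w1)
        if hi > lo:
            lat, lon = g_lat[lo:hi], g_lon[lo:hi]
            dist_m = float(np.sum(gpsmod.haversine_m((lat[:-1], lon[:-1]),
                                                     (lat[1:], lon[1:])))) if hi - lo > 1 else 0.0
            dw = g_dwell[lo:hi]
            st = g_stat[lo:hi]
            lb = g_lab[lo:hi]
            row.update(
                distance_km=dist_m / 1000.0, n_gps_points=float(hi - lo),
                minutes_home=(float(dw[st & (lb == home_id)].sum())
                              if home_id is not None else np.nan),
                minutes_transition=float(dw[~st].sum()),
                minutes_stationary=float(dw[st].sum()),
                missing_gps=False)
        else:
            row.update(distance_km=np.nan, n_gps_points=np.nan, minutes_home=np.nan,
                       minutes_transition=np.nan, minutes_stationary=np.nan,
                       missing_gps=True)
        # context
        local = pd.Timestamp(t) + pd.Timedelta(hours=utc_offset_h)
        wrow = weather_by_date.get(local.strftime("%Y-%m-%d"))
        row.update(
            assessment_hour=int(local.hour), time_of_day=time_of_day(local.hour),
            weekday=_WEEKDAYS[local.dayofweek], weekend=bool(local.dayofweek >= 5),
            season=_SEASONS[local.month], month=int(local.month),
            temp_avg=float(wrow["temp_avg"]) if wrow is not None else np.nan,
            sunshine_h=float(wrow["sunshine_h"]) if wrow is not None else np.nan,
            precipitation_h=float(wrow["precipitation_h"]) if wrow is not None else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def apply_missingness_policy(blocks: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resolve missing feature cells into structural fills or MCAR marks.

    Returns (blocks with fills applied, boolean MCAR mask aligned on the
    passive feature columns).  Structural fills and MCAR marks are disjoint
    by construction.
    """
    df = blocks.copy()
    mask = pd.DataFrame(False, index=df.index, columns=PASSIVE_FEATURES)
    watch_off = df["watch_off"].astype(bool).to_numpy()
    missing_hr = df["missing_hr"].astype(bool).to_numpy()
    missing_gps = df["missing_gps"].astype(bool).to_numpy()
    travelling = df["travelling_flag"].astype(bool).to_numpy()

    mask.loc[watch_off, WEARABLE_FEATURES] = True
    df.loc[watch_off, WEARABLE_FEATURES] = np.nan
    hr_only = ~watch_off & missing_hr
    mask.loc[hr_only, HR_FEATURES] = True
    df.loc[hr_only, HR_FEATURES] = np.nan
    worn = ~watch_off
    # structural zeros: no event of that kind while the watch was worn
    for c in STEP_FEATURES + ACTIVITY_FEATURES:
        fill = worn & df[c].isna().to_numpy()
        df.loc[fill, c] = 0.0

    gps_mcar = missing_gps & travelling
    mask.loc[gps_mcar, GPS_FEATURES] = True
    df.loc[gps_mcar, GPS_FEATURES] = np.nan
    gps_structural = missing_gps & ~travelling
    for c in GPS_FEATURES:
        df.loc[gps_structural, c] = STRUCTURAL_FILLS[c]
    # GPS present but no home cluster could be found
    no_home = ~missing_gps & df["minutes_home"].isna().to_numpy()
    mask.loc[no_home, "minutes_home"] = True
    return df, mask


def apply_inclusion_filters(
    blocks_by_pid: dict, beeps_by_pid: dict, gps_counts: dict,
    min_days: int = 7, min_beeps_per_day: int = 4, min_gps_points: int = 50,
    max_travel_missing_frac: float = 0.5,
) -> tuple[dict, list]:
    """Apply the ordered participant-level inclusion rules.

    1. fewer than ``min_days`` calendar days with >= ``min_beeps_per_day``
       answered beeps -> excluded (reason ``ema_days``);
    2. fewer than ``min_gps_points`` GPS points in total -> ``gps_count``;
    3. GPS missing while travelling in more than half of available blocks ->
       ``gps_mcar_rate``;
    4. after dropping rows whose passive features are all missing, rule 1 is
       re-checked -> ``ema_days_after_row_removal``.

    Returns (surviving blocks with all-missing rows dropped, exclusion log).
    """
    log = []

    def days_ok(beeps_df):
        answered = beeps_df[beeps_df["answered"].astype(bool)]
        if not len(answered):
            return False
        per_day = answered.groupby("day").size()
        return int((per_day >= min_beeps_per_day).sum()) >= min_days

    survivors = {}
    for pid in blocks_by_pid:
        if not days_ok(beeps_by_pid[pid]):
            log.append({"participant": pid, "rule": 1, "reason": "ema_days"})
        else:
            survivors[pid] = blocks_by_pid[pid]
    out = {}
    for pid, bl in survivors.items():
        if gps_counts.get(pid, 0) < min_gps_points:
            log.append({"participant": pid, "rule": 2, "reason": "gps_count"})
        else:
            out[pid] = bl
    survivors, out = out, {}
    for pid, bl in survivors.items():
        n = len(bl)
        bad = int((bl["missing_gps"].astype(bool) & bl["travelling_flag"].astype(bool)).sum())
        if n > 0 and bad / n > max_travel_missing_frac:
            log.append({"participant": pid, "rule": 3, "reason": "gps_mcar_rate"})
        else:
            out[pid] = bl
    survivors, out = out, {}
    for pid, bl in survivors.items():
        all_missing = (
            bl["watch_off"].astype(bool)
            & bl["missing_gps"].astype(bool)
            & bl["travelling_flag"].astype(bool)
        )
        kept = bl.loc[~all_missing]
        beeps_df = beeps_by_pid[pid]
        answered_kept = beeps_df[beeps_df["beep_idx"].isin(kept["beep_idx"])]
        per_day = answered_kept.groupby("day").size() if len(answered_kept) else pd.Series(dtype=int)
        if int((per_day >= min_beeps_per_day).sum()) < min_days:
            log.append({"participant": pid, "rule": 4, "reason": "ema_days_after_row_removal"})
        else:
            out[pid] = kept
    return out, log


@dataclass
class AssembledDataset:
    """Model-ready matrix: features X, labels y, participant groups, mask."""

    X: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray
    timestamps: np.ndarray
    missing_mask: pd.DataFrame
    variant: str

    def __len__(self):
        return len(self.X)

    def feature_columns(self):
        return list(self.X.columns)


def assemble(
    blocks_by_pid: dict,
    masks_by_pid: dict,
    participants: pd.DataFrame,
    variant: str = "passive_only",
) -> AssembledDataset:
    """Stack per-participant blocks into one canonical dataset.

    One row per answered beep with a complete label, sorted by
    (participant, timestamp); ``variant`` = ``with_PS`` appends the six
    person-stable columns.  Duplicate (participant, timestamp) rows are
    rejected.
    """
    if variant not in ("passive_only", "with_PS"):
        raise ValueError("variant must be 'passive_only' or 'with_PS'")
    frames, masks = [], []
    for pid in sorted(blocks_by_pid):
        bl = blocks_by_pid[pid]
        if not len(bl):
            continue
        frames.append(bl)
        masks.append(masks_by_pid[pid].loc[bl.index])
    if not frames:
        return AssembledDataset(pd.DataFrame(columns=TIME_VARYING_FEATURES), np.empty(0),
                                np.empty(0, object), np.empty(0), pd.DataFrame(), variant)
    all_bl = pd.concat(frames, ignore_index=False)
    all_mask = pd.concat(masks, ignore_index=False)
    order = np.lexsort((all_bl["timestamp"].to_numpy(), all_bl["participant"].to_numpy()))
    all_bl = all_bl.iloc[order].reset_index(drop=True)
    all_mask = all_mask.iloc[order].reset_index(drop=True)
    if all_bl.duplicated(subset=["participant", "timestamp"]).any():
        raise ValueError("duplicate (participant, timestamp) rows")
    cols = list(TIME_VARYING_FEATURES)
    if variant == "with_PS":
        ps = participants.set_index("participant")[PS_FEATURES]
        for c in PS_FEATURES:
            all_bl[c] = ps[c].reindex(all_bl["participant"]).to_numpy()
        cols = cols + PS_FEATURES
    X = all_bl[cols].copy()
    mask = pd.DataFrame(False, index=X.index, columns=cols)
    for c in all_mask.columns:
        mask[c] = all_mask[c].to_numpy()
    from ._time import dt64
    return AssembledDataset(
        X=X, y=all_bl["na"].to_numpy(float),
        groups=all_bl["participant"].to_numpy(object),
        timestamps=dt64(all_bl["timestamp"]),
        missing_mask=mask, variant=variant,
    )


def build_dataset(bundle, variant: str = "passive_only"):
    """Full path from a cohort bundle to an assembled dataset.

    Returns (dataset, exclusion_log).
    """
    cfg = bundle.config
    blocks_by_pid, masks_by_pid, gps_counts = {}, {}, {}
    for pid in bundle.streams:
        bl = build_blocks_for_participant(
            pid, bundle.streams[pid], bundle.beeps[pid], bundle.weather, cfg.utc_offset_h)
        if len(bl):
            bl, mask = apply_missingness_policy(bl)
        else:
            mask = pd.DataFrame(columns=PASSIVE_FEATURES)
        blocks_by_pid[pid] = bl
        masks_by_pid[pid] = mask
        gps_counts[pid] = len(bundle.streams[pid]["gps"])
    included, log = apply_inclusion_filters(blocks_by_pid, bundle.beeps, gps_counts)
    ds = assemble(included, masks_by_pid, bundle.participants, variant)
    return ds, log
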