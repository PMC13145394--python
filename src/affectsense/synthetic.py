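"""Synthetic EMA + passive-sensing cohort with a known generative model.

Each participant gets a home location, a few "away" anchor places, a daily
excursion plan, and sensor streams derived from that plan: an event-based GPS
trace (points only while moving, sparse check-ins at stays, night check-ins
at home), heart rate on a 10-minute grid, event-based step counts and
activity events.  Momentary negative affect (NA) for each EMA beep is

    NA_it = grid(mu + b_i + sum_f beta_f * z_f(window) + circadian(t) + eps_it)

with person intercepts b_i ~ N(0, sigma_b^2), AR(1) residuals eps with
stationary SD sigma_eps, z_f the cohort-standardized true feature value in
the 2-h window preceding the beep, and grid(.) the projection onto the
achievable score grid (means of eight 1-7 Likert items, i.e. multiples of
1/8 in [1, 7]; latent item values are rounded and averaged, which reproduces
the discreteness and mild skew of real EMA scores).

Missingness is injected per 2-h block: skipped beeps, watch-off sessions
(all wearable streams absent), and GPS dropouts during movement.  Ground
truth (intercepts, latent labels, true features) survives injection so
parameter recovery can be scored downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._time import dt64
from .gps import haversine_m

#: Feature names the generative coupling ``beta`` may reference.
COUPLABLE_FEATURES = ("hr_mean", "steps", "minutes_home", "distance_km")

_M_PER_DEG_LAT = 111_320.0


@dataclass
class SyntheticConfig:
    """Generative settings for a synthetic cohort.

    Defaults emulate a clinical EMA burst: 14 days of 8 beeps/day at ~2-h
    intervals (jitter ±0.5 h); latent grand mean ``mu`` with between-person
    SD ``sigma_b`` and within-person SD ``sigma_eps`` chosen so the
    *observed* scores, after projection onto the 1-7 item grid (which
    floor-clips the left tail), have mean ~2.89 and SD ~1.09 with a mild
    right skew; lag-1 residual autocorrelation ``rho``; and block-level
    missingness rates for skipped beeps, watch-off sessions and GPS
    dropouts.
    """

    n_participants: int = 30
    n_days: int = 14
    beeps_per_day: int = 8
    beep_interval_h: float = 2.0
    beep_jitter_h: float = 0.5
    mu: float = 2.87
    sigma_b: float = 0.95
    sigma_eps: float = 0.64
    rho: float = 0.3
    beta: dict = field(default_factory=lambda: {"steps": -0.10, "minutes_home": 0.10, "hr_mean": 0.10})
    circadian_amp: float = 0.0
    p_skip_beep: float = 0.2
    p_watch_off: float = 0.035
    p_gps_drop: float = 0.08
    seed: int = 0
    start_date: str = "2023-05-01"
    utc_offset_h: int = 1

    def __post_init__(self):
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.n_days * self.beeps_per_day < 1:
            raise ValueError("need at least one beep")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if self.sigma_b < 0 or self.sigma_eps < 0:
            raise ValueError("variance components must be non-negative")
        for name in ("p_skip_beep", "p_watch_off", "p_gps_drop"):
            p = getattr(self, name)
            if not (0 <= p <= 1):
                raise ValueError(f"{name} must be a probability")
        for k in self.beta:
            if k not in COUPLABLE_FEATURES:
                raise ValueError(f"unknown coupling feature {k!r}")


@dataclass
class GroundTruth:
    person_intercepts: dict
    beta: dict
    latent_labels: pd.DataFrame  # participant, beep_idx, timestamp, latent, label
    true_features: pd.DataFrame


@dataclass
class CohortBundle:
    participants: pd.DataFrame
    streams: dict  # pid -> {"hr": df, "steps": df, "activity": df, "gps": df}
    beeps: dict  # pid -> df
    weather: pd.DataFrame
    truth: GroundTruth
    config: SyntheticConfig
    missingness_log: pd.DataFrame | None = None


def _offset_latlon(lat, lon, north_m, east_m):
    return lat + north_m / _M_PER_DEG_LAT, lon + east_m / (_M_PER_DEG_LAT * np.cos(np.radians(lat)))


def na_grid(latent: float) -> tuple[float, np.ndarray]:
    """Project a latent NA value onto the 8-item mean grid.

    Clips to [1, 7], rounds latent * 8 to the nearest achievable item total,
    and returns (score, item vector of eight integers whose mean is the
    score).
    """
    v = float(np.clip(latent, 1.0, 7.0))
    total = int(round(v * 8))
    total = min(max(total, 8), 56)
    lo = total // 8
    k = total % 8
    if lo >= 7:
        lo, k = 7, 0
    items = np.array([lo + 1] * k + [lo] * (8 - k), int)
    return total / 8.0, items


def _day_plan(rng, home, anchors, day_start_local):
    """Excursion legs for one local day: [(t0, t1, p0, p1, speed_mps), ...]."""
    legs = []
    n_exc = min(int(rng.poisson(1.0)), 2)
    starts = np.sort(rng.uniform(8.5, 18.0, size=n_exc))
    t_busy_until = 0.0
    for s in starts:
        if s < t_busy_until:
            continue
        anchor = anchors[rng.integers(len(anchors))]
        dist = haversine_m(home, anchor)
        speed = float(rng.uniform(1.25, 2.4)) if rng.random() < 0.5 else float(rng.uniform(3.0, 8.0))
        travel_h = dist / speed / 3600.0
        stay_h = float(rng.uniform(0.5, 2.0))
        t0 = day_start_local + pd.Timedelta(hours=s)
        legs.append((t0, t0 + pd.Timedelta(hours=travel_h), home, anchor, speed))
        t1 = t0 + pd.Timedelta(hours=travel_h + stay_h)
        legs.append((t1, t1 + pd.Timedelta(hours=travel_h), anchor, home, speed))
        t_busy_until = s + 2 * travel_h + stay_h + 0.25
    return legs


def generate_gps_trace(rng, day_start_local, day_end_local, home, legs, utc_offset_h=1):
    """Event-based GPS points for one day: movement points plus check-ins.

    Points are emitted every ~45 s while moving (positions interpolated along
    the leg), every 20-60 min at daytime stays, and every ~45 min near home
    during the night hours (20:00-06:00), with ~8 m positional jitter.
    Timestamps returned in UTC.
    """
    tz = pd.Timedelta(hours=utc_offset_h)
    rows = []

    def emit(t_local, lat, lon, jitter_m=8.0):
        jlat, jlon = _offset_latlon(lat, lon, rng.normal(0, jitter_m), rng.normal(0, jitter_m))
        rows.append((t_local - tz, jlat, jlon))

    # stay timeline: start at home; legs partition movement
    cursor = day_start_local
    loc = home
    for (t0, t1, p0, p1, speed) in legs:
        # check-ins at current stay until leg start
        t = cursor
        while t < t0:
            hour = (t - day_start_local).total_seconds() / 3600.0
            at_night = hour < 6.0 or hour >= 20.0
            if at_night:
                if tuple(loc) == tuple(home):
                    emit(t, *loc)
                step = rng.uniform(35, 55)
            else:
                emit(t, *loc)
                step = rng.uniform(20, 60)
            t = t + pd.Timedelta(minutes=step)
        # movement points
        dur_s = (t1 - t0).total_seconds()
        n_pts = max(2, int(dur_s / 45.0))
        for i in range(n_pts + 1):
            f = i / n_pts
            lat = p0[0] + f * (p1[0] - p0[0])
            lon = p0[1] + f * (p1[1] - p0[1])
            emit(t0 + pd.Timedelta(seconds=f * dur_s), lat, lon, jitter_m=3.0)
        cursor = t1
        loc = p1
    # trailing stay until midnight
    t = cursor
    while t < day_end_local:
        hour = (t - day_start_local).total_seconds() / 3600.0
        at_night = hour < 6.0 or hour >= 20.0
        if not at_night or tuple(loc) == tuple(home):
            emit(t, *loc)
        t = t + pd.Timedelta(minutes=rng.uniform(35, 55) if at_night else rng.uniform(20, 60))
    df = pd.DataFrame(rows, columns=["timestamp", "lat", "lon"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df.sort_values("timestamp", kind="stable").reset_index(drop=True)


def _home_minutes_in_window(legs_all, away_stays, win_start, win_end):
    """Minutes of [win_start, win_end) spent at home per the day plan."""
    total = (win_end - win_start).total_seconds() / 60.0
    away = 0.0
    for (a, b) in away_stays:
        lo, hi = max(a, win_start), min(b, win_end)
        if hi > lo:
            away += (hi - lo).total_seconds() / 60.0
    for (t0, t1, *_rest) in legs_all:
        lo, hi = max(t0, win_start), min(t1, win_end)
        if hi > lo:
            away += (hi - lo).total_seconds() / 60.0
    return max(total - away, 0.0)


def generate_cohort(config: SyntheticConfig) -> CohortBundle:
    """Generate a full cohort (streams, beeps, weather, ground truth).

    Deterministic for a fixed config.seed (numpy PCG64 generator).  Labels
    are computed after the streams so that the configured feature coupling
    uses the true (pre-missingness) window features.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tz = pd.Timedelta(hours=cfg.utc_offset_h)
    study_start_local = pd.Timestamp(cfg.start_date, tz="UTC") + tz

    pids = [f"p{i:03d}" for i in range(cfg.n_participants)]
    intercepts = {pid: float(rng.normal(0.0, cfg.sigma_b)) for pid in pids}

    # person-stable covariates
    ps_rows = []
    for pid in pids:
        ps_rows.append({
            "participant": pid,
            "age": float(np.clip(rng.normal(33.0, 10.8), 18, 70)),
            "employable": bool(rng.random() < 0.8),
            "smartphone_type": "iPhone" if rng.random() < 0.56 else "Android",
            "somatic_problems": bool(rng.random() < 0.45),
            "psychotropic_medication": bool(rng.random() < 0.35),
            "prior_treatment": ["none", "outpatient", "inpatient"][rng.choice(3, p=[0.37, 0.35, 0.28])],
        })
    participants = pd.DataFrame(ps_rows)

    # weather: one table for all participants (single-site convention)
    dates = pd.date_range(cfg.start_date, periods=cfg.n_days + 1, freq="D")
    doy = dates.dayofyear.to_numpy()
    weather = pd.DataFrame({
        "date": dates.strftime("%Y-%m-%d"),
        "temp_avg": 10.0 + 10.0 * np.sin(2 * np.pi * (doy - 105) / 365.0) + rng.normal(0, 2, len(dates)),
        "sunshine_h": np.clip(6.0 + 4.0 * np.sin(2 * np.pi * (doy - 105) / 365.0) + rng.normal(0, 2, len(dates)), 0, 16),
        "precipitation_h": np.where(rng.random(len(dates)) < 0.4, rng.exponential(2.0, len(dates)), 0.0).round(2),
    })

    streams: dict = {}
    beeps: dict = {}
    truth_rows = []
    feat_rows = []

    for pid in pids:
        home = (52.52 + rng.normal(0, 0.03), 13.41 + rng.normal(0, 0.05))
        anchors = []
        for _ in range(3):
            d = rng.uniform(500, 4000)
            brg = rng.uniform(0, 2 * np.pi)
            anchors.append(_offset_latlon(home[0], home[1], d * np.cos(brg), d * np.sin(brg)))
        base_hr = float(rng.normal(70, 6))

        legs_all = []
        away_stays = []
        gps_parts = []
        for day in range(cfg.n_days):
            d0 = study_start_local + pd.Timedelta(days=day)
            d1 = d0 + pd.Timedelta(days=1)
            legs = _day_plan(rng, home, anchors, d0)
            legs_all.extend(legs)
            for i in range(0, len(legs), 2):
                away_stays.append((legs[i][1], legs[i + 1][0]))
            gps_parts.append(generate_gps_trace(rng, d0, d1, home, legs, cfg.utc_offset_h))
        gps = pd.concat(gps_parts, ignore_index=True).sort_values("timestamp", kind="stable").reset_index(drop=True)

        # heart rate on a 10-minute grid, elevated while moving, lower at night
        hr_times_local = pd.date_range(
            study_start_local, study_start_local + pd.Timedelta(days=cfg.n_days),
            freq="10min", inclusive="left",
        )
        bpm = base_hr + rng.normal(0, 5, len(hr_times_local))
        hours = ((hr_times_local - study_start_local).total_seconds() / 3600.0) % 24
        bpm = np.where((hours >= 23) | (hours < 7), bpm - 8.0, bpm)
        moving = np.zeros(len(hr_times_local), bool)
        for (t0, t1, _p0, _p1, _s) in legs_all:
            moving |= (hr_times_local >= t0) & (hr_times_local < t1)
        bpm = np.where(moving, bpm + 25.0, bpm)
        hr = pd.DataFrame({
            "timestamp": (hr_times_local - tz).tz_localize(None).tz_localize("UTC")
            if hr_times_local.tz is None else hr_times_local - tz,
            "bpm": np.clip(bpm, 35, 210).round(1),
        })

        # step + activity events
        step_rows = []
        act_rows = []
        for (t0, t1, _p0, _p1, speed) in legs_all:
            if speed < 2.5:  # walking leg
                cursor = t0
                while cursor < t1:
                    seg_end = min(cursor + pd.Timedelta(minutes=5), t1)
                    mins = (seg_end - cursor).total_seconds() / 60.0
                    cad = float(np.clip(rng.normal(105, 10), 60, 180))
                    step_rows.append((cursor - tz, seg_end - tz, round(cad * mins)))
                    cursor = seg_end
                act_rows.append((t0 - tz, t1 - tz, "walking", True))
            else:
                act_rows.append((t0 - tz, t1 - tz, "cycling", True))
        for day in range(cfg.n_days):
            d0 = study_start_local + pd.Timedelta(days=day)
            # short ambulation bouts at home
            for _ in range(rng.poisson(3)):
                s = d0 + pd.Timedelta(hours=float(rng.uniform(7, 22)))
                e = s + pd.Timedelta(minutes=float(rng.uniform(1, 6)))
                mins = (e - s).total_seconds() / 60.0
                step_rows.append((s - tz, e - tz, round(float(np.clip(rng.normal(60, 15), 20, 190)) * mins)))
            act_rows.append((d0 + pd.Timedelta(hours=23) - tz,
                             d0 + pd.Timedelta(hours=31) - tz, "sleep", True))
            # non-overlapping evening rest bouts (one per 2-h slot)
            for slot in (17.0, 19.0, 21.0):
                if rng.random() < 0.5:
                    s = d0 + pd.Timedelta(hours=slot + float(rng.uniform(0, 0.5)))
                    e = s + pd.Timedelta(minutes=float(rng.uniform(30, 85)))
                    act_rows.append((s - tz, e - tz, "rest", True))
        steps_df = pd.DataFrame(step_rows, columns=["start", "end", "steps"])
        for c in ("start", "end"):
            steps_df[c] = pd.to_datetime(steps_df[c], utc=True)
        steps_df = steps_df.sort_values("start", kind="stable").reset_index(drop=True)
        act_df = pd.DataFrame(act_rows, columns=["start", "end", "category", "flag"])
        for c in ("start", "end"):
            act_df[c] = pd.to_datetime(act_df[c], utc=True)
        act_df = act_df.sort_values("start", kind="stable").reset_index(drop=True)

        streams[pid] = {"hr": hr, "steps": steps_df, "activity": act_df, "gps": gps}

        # beep schedule + true window features
        hr_ts = dt64(hr["timestamp"])
        step_start = dt64(steps_df["start"])
        step_end = dt64(steps_df["end"])
        step_cnt = steps_df["steps"].to_numpy(float)
        beep_rows = []
        for day in range(cfg.n_days):
            d0 = study_start_local + pd.Timedelta(days=day)
            for k in range(cfg.beeps_per_day):
                t_local = d0 + pd.Timedelta(
                    hours=8.0 + k * cfg.beep_interval_h + float(rng.uniform(-cfg.beep_jitter_h, cfg.beep_jitter_h))
                )
                t = t_local - tz
                w0, w1 = t - pd.Timedelta(hours=2), t
                w0l, w1l = t_local - pd.Timedelta(hours=2), t_local
                in_w = (hr_ts >= dt64(w0)) & (hr_ts < dt64(w1))
                hr_mean = float(hr["bpm"].to_numpy()[in_w].mean()) if in_w.any() else base_hr
                dur = (step_end - step_start) / np.timedelta64(1, "s")
                ov = np.clip(
                    (np.minimum(step_end, dt64(w1)) - np.maximum(step_start, dt64(w0)))
                    / np.timedelta64(1, "s"), 0, None)
                steps_true = float(np.sum(step_cnt * ov / dur)) if len(dur) else 0.0
                minutes_home = _home_minutes_in_window(legs_all, away_stays, w0l, w1l)
                dist_km = 0.0
                travelling = False
                for (t0, t1, _p0, _p1, speed) in legs_all:
                    lo, hi = max(t0, w0l), min(t1, w1l)
                    if hi > lo:
                        dist_km += speed * (hi - lo).total_seconds() / 1000.0
                        travelling = True
                beep_rows.append({
                    "timestamp": t, "day": day, "beep_idx": day * cfg.beeps_per_day + k,
                    "travelling_flag": travelling, "answered": True,
                })
                feat_rows.append({
                    "participant": pid, "beep_idx": day * cfg.beeps_per_day + k,
                    "hr_mean": hr_mean, "steps": steps_true,
                    "minutes_home": minutes_home, "distance_km": dist_km,
                })
        beeps[pid] = pd.DataFrame(beep_rows)

    true_features = pd.DataFrame(feat_rows)
    z = true_features.copy()
    for f in COUPLABLE_FEATURES:
        col = z[f].to_numpy(float)
        sd = col.std()
        z[f] = (col - col.mean()) / sd if sd > 0 else 0.0

    # labels: AR(1) residuals per participant, then grid projection
    item_names = ["downcast", "sad", "anxious", "nervous", "irritable", "angry",
                  "ashamed", "dissatisfied"]
    for pid in pids:
        bdf = beeps[pid]
        nb = len(bdf)
        eps = np.zeros(nb)
        if nb:
            eps[0] = rng.normal(0, cfg.sigma_eps)
            innov_sd = cfg.sigma_eps * np.sqrt(1 - cfg.rho ** 2)
            for j in range(1, nb):
                eps[j] = cfg.rho * eps[j - 1] + rng.normal(0, innov_sd)
        zi = z[z["participant"] == pid].set_index("beep_idx")
        items_mat = np.zeros((nb, 8), int)
        labels = np.zeros(nb)
        latents = np.zeros(nb)
        for j, row in enumerate(bdf.itertuples()):
            coupling = sum(cfg.beta.get(f, 0.0) * zi.at[row.beep_idx, f] for f in cfg.beta)
            hour_local = (row.timestamp + tz).hour + (row.timestamp + tz).minute / 60.0
            circ = cfg.circadian_amp * np.sin(2 * np.pi * hour_local / 24.0)
            latent = cfg.mu + intercepts[pid] + coupling + circ + eps[j]
            label, items = na_grid(latent)
            latents[j], labels[j] = latent, label
            items_mat[j] = items
        for c, name in enumerate(item_names):
            beeps[pid][f"item_{name}"] = items_mat[:, c]
        for j, row in enumerate(bdf.itertuples()):
            truth_rows.append({
                "participant": pid, "beep_idx": int(row.beep_idx),
                "timestamp": row.timestamp, "latent": latents[j], "label": labels[j],
            })

    truth = GroundTruth(
        person_intercepts=intercepts,
        beta=dict(cfg.beta),
        latent_labels=pd.DataFrame(truth_rows),
        true_features=true_features,
    )
    return CohortBundle(
        participants=participants, streams=streams, beeps=beeps,
        weather=weather, truth=truth, config=cfg,
    )


def inject_missingness(bundle: CohortBundle, config: SyntheticConfig | None = None) -> CohortBundle:
    """Apply block-level missingness mechanisms; ground truth is untouched.

    Per 2-h block: with p_watch_off all HR samples and step/activity events
    overlapping the window are removed; with p_gps_drop all GPS points in
    the window are removed (the beep's travelling flag already reflects
    whether movement was simulated); with p_skip_beep the beep's items are
    blanked and it is marked unanswered.  Removals are logged.
    """
    cfg = config or bundle.config
    rng = np.random.default_rng((cfg.seed + 1) & 0x7FFFFFFF)
    log_rows = []
    streams = {}
    beeps = {}
    item_cols = None
    for pid in bundle.beeps:
        s = {k: v.copy() for k, v in bundle.streams[pid].items()}
        b = bundle.beeps[pid].copy()
        if item_cols is None:
            item_cols = [c for c in b.columns if c.startswith("item_")]
        drop_hr = np.zeros(len(s["hr"]), bool)
        drop_steps = np.zeros(len(s["steps"]), bool)
        drop_act = np.zeros(len(s["activity"]), bool)
        drop_gps = np.zeros(len(s["gps"]), bool)
        for row in b.itertuples():
            w0 = row.timestamp - pd.Timedelta(hours=2)
            w1 = row.timestamp
            if rng.random() < cfg.p_watch_off:
                drop_hr |= (s["hr"]["timestamp"] >= w0) & (s["hr"]["timestamp"] < w1)
                drop_steps |= (s["steps"]["end"] > w0) & (s["steps"]["start"] < w1)
                drop_act |= (s["activity"]["end"] > w0) & (s["activity"]["start"] < w1)
                log_rows.append({"participant": pid, "beep_idx": row.beep_idx, "kind": "watch_off"})
            if rng.random() < cfg.p_gps_drop:
                drop_gps |= (s["gps"]["timestamp"] >= w0) & (s["gps"]["timestamp"] < w1)
                log_rows.append({"participant": pid, "beep_idx": row.beep_idx, "kind": "gps_drop"})
            if rng.random() < cfg.p_skip_beep:
                b.loc[b["beep_idx"] == row.beep_idx, "answered"] = False
                b.loc[b["beep_idx"] == row.beep_idx, item_cols] = np.nan
                log_rows.append({"participant": pid, "beep_idx": row.beep_idx, "kind": "skip_beep"})
        s["hr"] = s["hr"].loc[~drop_hr].reset_index(drop=True)
        s["steps"] = s["steps"].loc[~drop_steps].reset_index(drop=True)
        s["activity"] = s["activity"].loc[~drop_act].reset_index(drop=True)
        s["gps"] = s["gps"].loc[~drop_gps].reset_index(drop=True)
        streams[pid] = s
        beeps[pid] = b
    return CohortBundle(
        participants=bundle.participants, streams=streams, beeps=beeps,
        weather=bundle.weather, truth=bundle.truth, config=cfg,
        missingness_log=pd.DataFrame(log_rows, columns=["participant", "beep_idx", "kind"]),
    )
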