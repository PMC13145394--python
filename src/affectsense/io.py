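"""Plain-text persistence for cohorts, blocks and datasets.

Layout of a cohort directory::

    cohort/
      weather.csv          # date, temp_avg, sunshine_h, precipitation_h
      person_stable.csv
      truth.json           # person intercepts, beta, latent labels
      beeps/<pid>.csv
      streams/<pid>/{hr,steps,activity,gps}.csv

All timestamps are ISO-8601 UTC (column ``timestamp_utc`` or
``start_utc``/``end_utc``); every feature window downstream is the
half-open interval [beep - 2h, beep).  Each CSV starts with ``#`` comment
lines stating its conventions.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .synthetic import CohortBundle, GroundTruth, SyntheticConfig

_HEADER = "# timestamps ISO-8601 UTC; feature windows are half-open [beep-2h, beep)\n"


def _write_csv(df: pd.DataFrame, path: Path):
    with open(path, "w") as f:
        f.write(_HEADER)
        df.to_csv(f, index=False)


def _read_csv(path: Path, parse_dates=(), **kw) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", **kw)
    for c in parse_dates:  # force tz-aware UTC regardless of csv offset style
        df[c] = pd.to_datetime(df[c], utc=True, format="ISO8601")
    return df


def write_cohort(bundle: CohortBundle, outdir) -> Path:
    out = Path(outdir)
    (out / "streams").mkdir(parents=True, exist_ok=True)
    (out / "beeps").mkdir(exist_ok=True)
    _write_csv(bundle.weather, out / "weather.csv")
    _write_csv(bundle.participants, out / "person_stable.csv")
    for pid, s in bundle.streams.items():
        d = out / "streams" / pid
        d.mkdir(exist_ok=True)
        hr = s["hr"].rename(columns={"timestamp": "timestamp_utc"})
        _write_csv(hr, d / "hr.csv")
        st = s["steps"].rename(columns={"start": "start_utc", "end": "end_utc"})
        _write_csv(st, d / "steps.csv")
        ac = s["activity"].rename(columns={"start": "start_utc", "end": "end_utc"})
        _write_csv(ac, d / "activity.csv")
        gp = s["gps"].rename(columns={"timestamp": "timestamp_utc"})
        _write_csv(gp, d / "gps.csv")
    for pid, b in bundle.beeps.items():
        _write_csv(b.rename(columns={"timestamp": "timestamp_utc"}), out / "beeps" / f"{pid}.csv")
    truth = {
        "person_intercepts": bundle.truth.person_intercepts,
        "beta": bundle.truth.beta,
        "latent_labels": bundle.truth.latent_labels.assign(
            timestamp=bundle.truth.latent_labels["timestamp"].astype(str)
        ).to_dict(orient="list"),
        "config": {k: v for k, v in vars(bundle.config).items() if not isinstance(v, dict)},
        "config_beta": bundle.config.beta,
    }
    with open(out / "truth.json", "w") as f:
        json.dump(truth, f, indent=1)
    if bundle.missingness_log is not None:
        _write_csv(bundle.missingness_log, out / "missingness_log.csv")
    return out


def read_cohort(indir) -> CohortBundle:
    src = Path(indir)
    weather = _read_csv(src / "weather.csv")
    participants = _read_csv(src / "person_stable.csv")
    streams, beeps = {}, {}
    for d in sorted((src / "streams").iterdir()):
        pid = d.name
        hr = _read_csv(d / "hr.csv", parse_dates=["timestamp_utc"]).rename(
            columns={"timestamp_utc": "timestamp"})
        st = _read_csv(d / "steps.csv", parse_dates=["start_utc", "end_utc"]).rename(
            columns={"start_utc": "start", "end_utc": "end"})
        ac = _read_csv(d / "activity.csv", parse_dates=["start_utc", "end_utc"]).rename(
            columns={"start_utc": "start", "end_utc": "end"})
        gp = _read_csv(d / "gps.csv", parse_dates=["timestamp_utc"]).rename(
            columns={"timestamp_utc": "timestamp"})
        streams[pid] = {"hr": hr, "steps": st, "activity": ac, "gps": gp}
    for p in sorted((src / "beeps").iterdir()):
        beeps[p.stem] = _read_csv(p, parse_dates=["timestamp_utc"]).rename(
            columns={"timestamp_utc": "timestamp"})
    with open(src / "truth.json") as f:
        tr = json.load(f)
    lat = pd.DataFrame(tr["latent_labels"])
    if len(lat):
        lat["timestamp"] = pd.to_datetime(lat["timestamp"], utc=True)
    cfg_kw = {k: v for k, v in tr["config"].items()}
    cfg_kw["beta"] = tr.get("config_beta", {})
    cfg = SyntheticConfig(**cfg_kw)
    truth = GroundTruth(person_intercepts=tr["person_intercepts"], beta=tr["beta"],
                        latent_labels=lat, true_features=pd.DataFrame())
    log = None
    if (src / "missingness_log.csv").exists():
        log = _read_csv(src / "missingness_log.csv")
    return CohortBundle(participants=participants, streams=streams, beeps=beeps,
                        weather=weather, truth=truth, config=cfg, missingness_log=log)


def write_dataset(ds, path_prefix) -> None:
    """Assembled dataset as CSV plus a JSON sidecar with the schema."""
    prefix = Path(path_prefix)
    df = ds.X.copy()
    df.insert(0, "participant", ds.groups)
    df.insert(1, "timestamp_utc", pd.to_datetime(ds.timestamps, utc=True))
    df["na"] = ds.y
    _write_csv(df, prefix.with_suffix(".csv"))
    mask = ds.missing_mask.copy()
    _write_csv(mask.astype(int), prefix.parent / (prefix.name + "_mask.csv"))
    sidecar = {"variant": ds.variant, "n_rows": len(ds),
               "feature_columns": ds.feature_columns()}
    with open(prefix.with_suffix(".json"), "w") as f:
        json.dump(sidecar, f, indent=1)


def read_dataset(path_prefix):
    from .blocks import AssembledDataset
    prefix = Path(path_prefix)
    df = _read_csv(prefix.with_suffix(".csv"), parse_dates=["timestamp_utc"])
    with open(prefix.with_suffix(".json")) as f:
        sidecar = json.load(f)
    mask = _read_csv(prefix.parent / (prefix.name + "_mask.csv")).astype(bool)
    cols = sidecar["feature_columns"]
    X = df[cols].copy()
    # restore NaN at masked cells (CSV round-trip keeps them NaN already)
    return AssembledDataset(
        X=X, y=df["na"].to_numpy(float), groups=df["participant"].to_numpy(object),
        timestamps=df["timestamp_utc"].to_numpy(),
        missing_mask=mask, variant=sidecar["variant"])
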