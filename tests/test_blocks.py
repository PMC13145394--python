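"""Outcome scoring, missingness policy, inclusion filters and assembly."""

import numpy as np
import pandas as pd
import pytest

from affectsense import blocks
from affectsense.blocks import (
    ACTIVITY_FEATURES, GPS_FEATURES, HR_FEATURES, PASSIVE_FEATURES,
    PS_FEATURES, TIME_VARYING_FEATURES, WEARABLE_FEATURES,
)

T0 = pd.Timestamp("2023-05-01 10:00", tz="UTC")


class TestComputeNa:
    @pytest.mark.parametrize("items,expected", [
        ([1] * 8, 1.0),
        ([2, 2, 2, 2, 4, 4, 4, 4], 3.0),
        ([7] * 8, 7.0),
        ([1, 2, 3, 4, 5, 6, 7, 1], 3.625),
    ])
    def test_mean_of_items(self, items, expected):
        assert blocks.compute_na(items) == expected

    def test_score_on_eighth_grid(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            v = blocks.compute_na(rng.integers(1, 8, 8))
            assert 1 <= v <= 7 and (v * 8) == int(v * 8)

    @pytest.mark.parametrize("bad", [
        [1] * 7,                      # too few
        [1, 2, 3, 4, 5, 6, 7, None],  # missing item
        [0, 1, 1, 1, 1, 1, 1, 1],     # below scale
        [1, 1, 1, 1, 1, 1, 1, 8],     # above scale
        [1.5] + [1] * 7,              # non-integer
    ])
    def test_invalid_items_rejected(self, bad):
        with pytest.raises(ValueError):
            blocks.compute_na(bad)


def make_block_row(missing_hr=False, missing_steps=False, missing_activity=False,
                   missing_gps=False, travelling=False, beep_idx=0):
    row = {"participant": "pX", "timestamp": T0 + pd.Timedelta(hours=2 * beep_idx),
           "beep_idx": beep_idx, "na": 3.0, "travelling_flag": travelling,
           "missing_hr": missing_hr, "missing_steps": missing_steps,
           "missing_activity": missing_activity,
           "watch_off": missing_hr and missing_steps and missing_activity,
           "missing_gps": missing_gps}
    for c in HR_FEATURES:
        row[c] = np.nan if missing_hr else 70.0
    row["steps"] = np.nan if missing_steps else 500.0
    for c in ACTIVITY_FEATURES:
        row[c] = np.nan if missing_activity else 10.0
    for c in GPS_FEATURES:
        row[c] = np.nan if missing_gps else 30.0
    return row


class TestMissingnessPolicy:
    def test_gps_structural_fills(self):
        df = pd.DataFrame([make_block_row(missing_gps=True, travelling=False)])
        out, mask = blocks.apply_missingness_policy(df)
        assert out.at[0, "distance_km"] == 0
        assert out.at[0, "n_gps_points"] == 0
        assert out.at[0, "minutes_transition"] == 0
        assert out.at[0, "minutes_home"] == 120
        assert out.at[0, "minutes_stationary"] == 120
        assert not mask.loc[0, GPS_FEATURES].any()

    def test_gps_travelling_marks_mcar(self):
        df = pd.DataFrame([make_block_row(missing_gps=True, travelling=True)])
        out, mask = blocks.apply_missingness_policy(df)
        assert mask.loc[0, GPS_FEATURES].all()
        assert out.loc[0, GPS_FEATURES].isna().all()

    def test_watch_off_marks_all_wearables_mcar(self):
        df = pd.DataFrame([make_block_row(True, True, True)])
        out, mask = blocks.apply_missingness_policy(df)
        assert mask.loc[0, WEARABLE_FEATURES].all()

    def test_hr_missing_alone_is_mcar_steps_structural(self):
        # HR absent but steps prove the watch was worn
        df = pd.DataFrame([make_block_row(missing_hr=True, missing_activity=True)])
        out, mask = blocks.apply_missingness_policy(df)
        assert mask.loc[0, HR_FEATURES].all()
        assert not mask.loc[0, ACTIVITY_FEATURES].any()
        assert (out.loc[0, ACTIVITY_FEATURES] == 0).all()

    def test_truth_table_all_presence_patterns(self):
        """2^3 wearable patterns x 3 GPS states against a hand-built ledger."""
        rows, expected = [], []
        idx = 0
        for mh in (False, True):
            for ms in (False, True):
                for ma in (False, True):
                    for gps_state in ("present", "structural", "mcar"):
                        rows.append(make_block_row(
                            mh, ms, ma, missing_gps=gps_state != "present",
                            travelling=gps_state == "mcar", beep_idx=idx))
                        watch_off = mh and ms and ma
                        expected.append({
                            "hr_mcar": mh,  # MCAR whether alone or watch-off
                            "steps_mcar": watch_off,
                            "act_mcar": watch_off,
                            "steps_zero": ms and not watch_off,
                            "act_zero": ma and not watch_off,
                            "gps_mcar": gps_state == "mcar",
                            "gps_filled": gps_state == "structural",
                        })
                        idx += 1
        out, mask = blocks.apply_missingness_policy(pd.DataFrame(rows))
        for i, exp in enumerate(expected):
            assert mask.loc[i, HR_FEATURES].all() == exp["hr_mcar"]
            assert mask.at[i, "steps"] == exp["steps_mcar"]
            assert mask.loc[i, ACTIVITY_FEATURES].all().item() == exp["act_mcar"]
            if exp["steps_zero"]:
                assert out.at[i, "steps"] == 0
            if exp["act_zero"]:
                assert (out.loc[i, ACTIVITY_FEATURES] == 0).all()
            assert mask.loc[i, GPS_FEATURES].all() == exp["gps_mcar"]
            if exp["gps_filled"]:
                assert out.at[i, "minutes_home"] == 120
                assert out.at[i, "distance_km"] == 0

    def test_structural_and_mcar_disjoint(self):
        rows = [make_block_row(mh, ms, ma, mg, tv, beep_idx=i)
                for i, (mh, ms, ma, mg, tv) in enumerate(
                    [(a, b, c, d, e) for a in (0, 1) for b in (0, 1) for c in (0, 1)
                     for d in (0, 1) for e in (0, 1)])]
        out, mask = blocks.apply_missingness_policy(pd.DataFrame(rows))
        for c in PASSIVE_FEATURES:
            marked = mask[c].to_numpy()
            vals = out[c].to_numpy(float)
            assert np.isnan(vals[marked]).all()       # MCAR cells stay NaN
            assert np.isfinite(vals[~marked]).all()   # everything else filled


def make_participant(pid, n_days=14, answered_per_day=8, gps_bad_frac=0.0,
                     all_missing_rows=0):
    """Beeps + block frames for the filter tests."""
    beep_rows, block_rows = [], []
    idx = 0
    for day in range(n_days):
        for k in range(8):
            answered = k < answered_per_day
            t = T0 + pd.Timedelta(days=day, hours=2 * k)
            beep_rows.append({"timestamp": t, "day": day, "beep_idx": idx,
                              "answered": answered, "travelling_flag": False})
            if answered:
                r = make_block_row(beep_idx=idx)
                r["participant"] = pid
                r["timestamp"] = t
                block_rows.append(r)
            idx += 1
    bl = pd.DataFrame(block_rows)
    n_bad = int(gps_bad_frac * len(bl))
    bl.iloc[:n_bad, bl.columns.get_loc("missing_gps")] = True
    bl.iloc[:n_bad, bl.columns.get_loc("travelling_flag")] = True
    for j in range(all_missing_rows):
        i = len(bl) - 1 - j
        for c in ("watch_off", "missing_gps", "travelling_flag",
                  "missing_hr", "missing_steps", "missing_activity"):
            bl.iloc[i, bl.columns.get_loc(c)] = True
    return pd.DataFrame(beep_rows), bl


class TestInclusionFilters:
    def test_boundary_participant_included(self):
        beeps, bl = make_participant("ok", n_days=7, answered_per_day=4)
        surv, log = blocks.apply_inclusion_filters({"ok": bl}, {"ok": beeps}, {"ok": 100})
        assert "ok" in surv and log == []

    def test_too_few_ema_days_excluded(self):
        beeps, bl = make_participant("a", n_days=6)
        surv, log = blocks.apply_inclusion_filters({"a": bl}, {"a": beeps}, {"a": 100})
        assert surv == {} and log[0]["reason"] == "ema_days"

    def test_49_gps_points_excluded(self):
        beeps, bl = make_participant("b")
        surv, log = blocks.apply_inclusion_filters({"b": bl}, {"b": beeps}, {"b": 49})
        assert surv == {} and log[0]["reason"] == "gps_count"

    def test_travelling_gps_missing_majority_excluded(self):
        beeps, bl = make_participant("c", gps_bad_frac=0.6)
        surv, log = blocks.apply_inclusion_filters({"c": bl}, {"c": beeps}, {"c": 100})
        assert surv == {} and log[0]["reason"] == "gps_mcar_rate"

    def test_row_removal_can_break_rule_one(self):
        # exactly 7 days x 4 beeps; dropping one all-missing row leaves 6 days
        beeps, bl = make_participant("d", n_days=7, answered_per_day=4,
                                     all_missing_rows=1)
        surv, log = blocks.apply_inclusion_filters({"d": bl}, {"d": beeps}, {"d": 100})
        assert surv == {} and log[0]["reason"] == "ema_days_after_row_removal"

    def test_planted_violations_logged_in_order(self):
        cohort, beeps, gps_counts = {}, {}, {}
        specs = {
            "p_rule1": dict(n_days=5),
            "p_rule2": dict(),
            "p_rule3": dict(gps_bad_frac=0.7),
            "p_ok": dict(),
        }
        for pid, kw in specs.items():
            b, bl = make_participant(pid, **kw)
            beeps[pid] = b
            cohort[pid] = bl
            gps_counts[pid] = 10 if pid == "p_rule2" else 500
        surv, log = blocks.apply_inclusion_filters(cohort, beeps, gps_counts)
        assert list(surv) == ["p_ok"]
        assert [(r["participant"], r["reason"]) for r in log] == [
            ("p_rule1", "ema_days"), ("p_rule2", "gps_count"),
            ("p_rule3", "gps_mcar_rate")]
        assert len(surv) + len(log) == 4  # log reconciles with input count


class TestAssemble:
    def _cohort(self, n_pids=2, n_blocks=3):
        participants = pd.DataFrame([
            {"participant": f"p{i}", "age": 30.0 + i, "employable": True,
             "smartphone_type": "iPhone", "somatic_problems": False,
             "psychotropic_medication": False, "prior_treatment": "none"}
            for i in range(n_pids)])
        blocks_by, masks_by = {}, {}
        for i in range(n_pids):
            rows = [make_block_row(beep_idx=j) for j in range(n_blocks)]
            bl = pd.DataFrame(rows)
            bl["participant"] = f"p{i}"
            for c in ("assessment_hour", "month"):
                bl[c] = 10
            bl["time_of_day"] = "morning"
            bl["weekday"] = "monday"
            bl["weekend"] = False
            bl["season"] = "spring"
            bl["temp_avg"] = 15.0
            bl["sunshine_h"] = 5.0
            bl["precipitation_h"] = 0.0
            blocks_by[f"p{i}"] = bl
            masks_by[f"p{i}"] = pd.DataFrame(False, index=bl.index,
                                             columns=PASSIVE_FEATURES)
        return blocks_by, masks_by, participants

    def test_row_count(self):
        bl, mk, ps = self._cohort(2, 3)
        ds = blocks.assemble(bl, mk, ps)
        assert len(ds) == 6 and list(ds.X.columns) == TIME_VARYING_FEATURES

    def test_with_ps_adds_six_columns(self):
        bl, mk, ps = self._cohort()
        d0 = blocks.assemble(bl, mk, ps, "passive_only")
        d1 = blocks.assemble(bl, mk, ps, "with_PS")
        assert len(d1.X.columns) - len(d0.X.columns) == 6
        assert list(d1.X.columns[-6:]) == PS_FEATURES

    def test_shuffled_blocks_same_dataset(self):
        bl, mk, ps = self._cohort(3, 4)
        d0 = blocks.assemble(bl, mk, ps)
        bl2 = {p: df.sample(frac=1, random_state=5) for p, df in bl.items()}
        mk2 = {p: mk[p].loc[bl2[p].index] for p in bl2}
        d1 = blocks.assemble(bl2, mk2, ps)
        pd.testing.assert_frame_equal(d0.X, d1.X)
        assert (d0.y == d1.y).all() and (d0.groups == d1.groups).all()

    def test_duplicate_rows_rejected(self):
        bl, mk, ps = self._cohort(1, 2)
        bl["p0"].iloc[1] = bl["p0"].iloc[0]
        with pytest.raises(ValueError, match="duplicate"):
            blocks.assemble(bl, mk, ps)

    def test_canonical_order_and_mask_alignment(self, small_datasets):
        ds = small_datasets["passive_only"]
        df = pd.DataFrame({"g": ds.groups, "t": ds.timestamps})
        for _, sub in df.groupby("g"):
            assert sub["t"].is_monotonic_increasing
        assert len(ds) > 0 and ds.missing_mask.shape[0] == len(ds)
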