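"""AOI geometry, velocity-threshold fixation parsing, QC and exclusions."""

import numpy as np
import pandas as pd
import pytest

from matgaze.aoi import AOILayout, default_layout
from matgaze.preprocess import (
    Fixation,
    compute_qc,
    detect_fixations,
    detect_fixations_table,
    exclude_trials_participants,
    read_fixations,
    read_samples,
    truncate_at_response,
    velocity_threshold,
)


class TestAOILayout:
    def test_containment_center(self):
        lay = default_layout()
        for cell in range(1, 11):
            x0, y0, x1, y1 = lay.rects[cell]
            assert lay.assign((x0 + x1) / 2, (y0 + y1) / 2) == cell

    def test_outside_everything(self):
        lay = default_layout()
        assert lay.assign(5.0, 5.0) == 0

    def test_margin_single_candidate(self):
        lay = default_layout(margin=10.0)
        x0, y0, _, _ = lay.rects[3]
        assert lay.assign(x0 - 5, y0 - 5) == 3

    def test_margin_tie_breaks_to_nearest_center(self):
        lay = default_layout(margin=15.0)
        # point in the gap between cells 1 and 2, slightly nearer cell 2
        x1_right = lay.rects[1][2]
        y_mid = (lay.rects[1][1] + lay.rects[1][3]) / 2
        assert lay.assign(x1_right + 12, y_mid) == 2
        assert lay.assign(x1_right + 3, y_mid) == 1

    def test_overlapping_matrix_cells_rejected(self):
        rects = default_layout().rects.copy()
        rects[2] = rects[1]
        with pytest.raises(ValueError, match="overlap"):
            AOILayout(rects=rects)

    def test_yaml_round_trip(self, tmp_path):
        lay = default_layout(margin=4.0)
        p = tmp_path / "layout.yaml"
        lay.to_yaml(p)
        back = AOILayout.from_yaml(p)
        assert back.rects == lay.rects and back.margin == lay.margin

    def test_assign_array_matches_scalar(self, rng):
        lay = default_layout(margin=5.0)
        x = rng.uniform(0, 1280, 300)
        y = rng.uniform(0, 1024, 300)
        vec = lay.assign_array(x, y)
        assert all(vec[i] == lay.assign(x[i], y[i]) for i in range(300))


def _stationary(n, x=700.0, y=170.0, t0=0.0, rate=50.0):
    t = t0 + np.arange(n) / rate
    return t, np.full(n, x), np.full(n, y)


class TestDetectFixations:
    def test_six_stationary_samples_make_one_fixation(self):
        # 6 samples at 50 Hz = 120 ms >= the 100 ms minimum
        t, x, y = _stationary(6)
        fixes = detect_fixations(t, x, y, threshold=1000.0)
        assert len(fixes) == 1
        assert fixes[0].duration >= 0.100

    def test_four_samples_too_short(self):
        # 80 ms run flanked by saccades -> rejected by the duration floor
        t = np.arange(8) / 50.0
        x = np.array([0, 2000, 700, 700, 700, 700, 3000, 0.0])
        y = np.full(8, 170.0)
        fixes = detect_fixations(t, x, y, threshold=1000.0)
        assert fixes == []

    def test_long_stationary_stream_is_single_fixation(self):
        t, x, y = _stationary(500)  # 10 s of zero velocity
        fixes = detect_fixations(t, x, y, threshold=1000.0)
        assert len(fixes) == 1
        assert fixes[0].duration == pytest.approx(10.0)

    def test_saccade_splits_runs(self):
        t = np.arange(14) / 50.0
        x = np.r_[np.full(6, 700.0), 2000.0, np.full(7, 300.0)]
        y = np.full(14, 170.0)
        fixes = detect_fixations(t, x, y, threshold=1000.0)
        assert len(fixes) == 2
        assert fixes[0].x == pytest.approx(700.0)
        assert fixes[1].x == pytest.approx(300.0)

    def test_lower_min_duration_never_fewer_fixations(self, rng):
        t = np.arange(200) / 50.0
        x = np.cumsum(rng.choice([0.0, 0.0, 0.0, 400.0], size=200))
        y = rng.normal(0, 2, 200)
        lo = detect_fixations(t, x, y, min_duration=0.06, threshold=1000.0)
        hi = detect_fixations(t, x, y, min_duration=0.14, threshold=1000.0)
        assert len(lo) >= len(hi)

    def test_bridges_short_invalid_gap(self):
        t = np.arange(12) / 50.0
        x = np.full(12, 700.0)
        y = np.full(12, 170.0)
        valid = np.ones(12, bool)
        valid[5] = False  # single dropped sample (20 ms < 75 ms)
        fixes = detect_fixations(t, x, y, valid, threshold=1000.0)
        assert len(fixes) == 1
        assert fixes[0].duration == pytest.approx(12 / 50.0)

    def test_long_invalid_gap_splits(self):
        t = np.arange(30) / 50.0
        x = np.full(30, 700.0)
        y = np.full(30, 170.0)
        valid = np.ones(30, bool)
        valid[10:20] = False  # 200 ms gap > bridge limit
        fixes = detect_fixations(t, x, y, valid, threshold=1000.0)
        assert len(fixes) == 2

    def test_non_monotone_timestamps_error(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            detect_fixations([0.0, 0.02, 0.02], [0, 0, 0], [0, 0, 0])

    def test_all_invalid_warns_and_returns_empty(self):
        t, x, y = _stationary(10)
        with pytest.warns(UserWarning):
            assert detect_fixations(t, x, y, np.zeros(10, bool)) == []

    def test_adaptive_threshold_floor(self):
        t, x, y = _stationary(50)
        assert velocity_threshold(t, x, y) == pytest.approx(30.0 * 40.0)

    def test_idempotent_on_own_output(self):
        t, x, y = _stationary(20)
        fixes = detect_fixations(t, x, y, threshold=1000.0)
        # re-sample the detected fixation as stationary points
        t2 = np.arange(int(fixes[0].duration * 50)) / 50.0
        again = detect_fixations(
            t2, np.full_like(t2, fixes[0].x), np.full_like(t2, fixes[0].y),
            threshold=1000.0,
        )
        assert len(again) == 1
        assert again[0].duration == pytest.approx(fixes[0].duration)


class TestTruncateAtResponse:
    def test_all_before_boundary_unchanged(self):
        f = [Fixation(0.0, 0.5, 1, 1), Fixation(1.0, 0.5, 1, 1)]
        assert truncate_at_response(f, 10.0) == f

    def test_straddling_fixation_truncated(self):
        f = [Fixation(9.9, 0.4, 1, 1)]
        out = truncate_at_response(f, 10.0)
        assert len(out) == 1
        assert out[0].duration == pytest.approx(0.1)

    def test_zero_boundary_empties(self):
        assert truncate_at_response([Fixation(0.0, 0.5, 1, 1)], 0.0) == []

    def test_dataframe_variant(self):
        df = pd.DataFrame({"onset": [0.0, 9.9, 11.0], "duration": [1.0, 0.4, 1.0]})
        out = truncate_at_response(df, 10.0)
        assert len(out) == 2
        assert out["duration"].tolist() == pytest.approx([1.0, 0.1])


class TestQC:
    def test_valid_fraction_arithmetic(self):
        fixes = [Fixation(0, 4.0, 0, 0, aoi=5), Fixation(5, 2.0, 0, 0, aoi=10)]
        assert compute_qc(fixes, 10.0).valid_fraction == pytest.approx(0.6)

    def test_no_aoi_fixations(self):
        assert compute_qc([Fixation(0, 2.0, 0, 0, aoi=0)], 8.0).valid_fraction == 0.0

    def test_bad_trial_duration(self):
        with pytest.raises(ValueError):
            compute_qc([], 0.0)

    def test_exclusions(self):
        qc = pd.DataFrame(
            {
                "participant": ["a", "a", "b", "b"],
                "trial": [0, 1, 0, 1],
                "valid_fraction": [0.9, 0.8, 0.05, 0.0],
            }
        )
        out = exclude_trials_participants(qc, min_valid_fraction=0.2)
        assert out["excluded"].tolist() == [False, False, True, True]
        assert set(out.loc[out["excluded"], "reason"]) >= {"low_valid_fraction"}

    def test_no_exclusions_above_threshold(self):
        qc = pd.DataFrame(
            {"participant": ["a"] * 3, "trial": range(3), "valid_fraction": [0.5] * 3}
        )
        assert not exclude_trials_participants(qc).excluded.any()

    def test_planted_low_quality_participants_recovered(self, six_group_config):
        import dataclasses

        import matgaze as mg

        grp = six_group_config.groups[0]
        bad_params = dataclasses.replace(grp.params, missing_frac=0.92)
        bad = dataclasses.replace(grp, label="bad", n=3, params=bad_params)
        cfg = dataclasses.replace(six_group_config, groups=(grp, bad))
        coh = mg.simulate_cohort(cfg, seed=5, light=True)
        qc = coh.trial_indices[["participant", "trial", "valid_fraction"]]
        out = exclude_trials_participants(qc, min_valid_fraction=0.2)
        per_p = out.groupby("participant")["excluded"].mean()
        flagged = set(per_p[per_p > 0.5].index)
        assert flagged == {p for p in per_p.index if p.startswith("bad")}


class TestRawSampleRoundTrip:
    def test_fixations_recovered_from_rasterised_samples(self, small_cohort):
        import matgaze as mg

        fix = small_cohort.fixations
        one = fix[fix["participant"] == fix["participant"].iloc[0]]
        one = one[one["trial"].isin(one["trial"].unique()[:4])]
        resp = small_cohort.responses
        samples = mg.samples_from_fixations(one, resp, seed=3)
        lay = default_layout()
        det = detect_fixations_table(samples, lay)
        for tr, g in one.groupby("trial"):
            got = det[det["trial"] == tr]
            # counts may differ by merged/short fixations; time must agree
            t_in = g["duration"].sum()
            t_out = got["duration"].sum()
            assert t_out == pytest.approx(t_in, rel=0.15)
            # time budget per AOI is preserved (fixations may merge/split
            # at rasterisation boundaries, so sequences need not be equal)
            in_by_aoi = g.groupby("aoi")["duration"].sum()
            out_by_aoi = got.groupby("aoi")["duration"].sum()
            for aoi, t in in_by_aoi.items():
                if t >= 0.4:
                    assert out_by_aoi.get(aoi, 0.0) == pytest.approx(t, rel=0.3)

    def test_io_round_trip(self, tmp_path, small_cohort):
        p = tmp_path / "fix.csv"
        small_cohort.fixations.to_csv(p, index=False)
        back = read_fixations(p, layout=default_layout())
        assert (back["aoi"] == small_cohort.fixations["aoi"]).all()
        sp = tmp_path / "samples.csv"
        import matgaze as mg

        fix = small_cohort.fixations
        one = fix[
            (fix["participant"] == fix["participant"].iloc[0]) & (fix["trial"] == 0)
        ]
        mg.samples_from_fixations(one, small_cohort.responses, seed=1).to_csv(
            sp, index=False
        )
        assert {"t", "x", "y", "valid"} <= set(read_samples(sp).columns)
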