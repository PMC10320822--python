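"""Synthetic cohort generator: item bank structure, determinism, degenerate
parameter limits, and calibration of the observables it promises."""

import dataclasses

import numpy as np
import pytest

import matgaze as mg
from matgaze.aoi import default_layout
from matgaze.indices import compute_trial_indices
from matgaze.synthetic import (
    AccuracyModel,
    SimConfig,
    StrategyParams,
    StrategySpread,
    accuracy_model,
    generate_item_bank,
    simulate_trial,
)


def _plain_params(**kw):
    base = dict(
        p_scan=0.2, toggle_intensity=0.4, first_toggle_mean=2.0,
        trial_time_mean=8.0, missing_frac=0.0,
    )
    base.update(kw)
    return StrategyParams(**base)


class TestItemBank:
    def test_structure(self, six_group_config):
        items = generate_item_bank(six_group_config)
        assert len(items) == 24
        rels = [it.n_relations for it in items]
        assert rels.count(1) == 9 and rels.count(2) == 9 and rels.count(3) == 6
        for it in items:
            assert it.n_options == 8
            assert sum(o == it.correct_option for o in range(8)) == 1
            assert it.n_relations_matched[it.correct_option] == it.n_relations
            assert sum(it.is_duplicate) == 1 and sum(it.has_novel_feature) == 1

    def test_difficulty_nondecreasing_across_sets(self, six_group_config):
        items = generate_item_bank(six_group_config)
        set_means = [
            np.mean([it.difficulty for it in items[8 * s : 8 * s + 8]])
            for s in range(3)
        ]
        assert set_means[0] < set_means[1] < set_means[2]

    def test_deterministic(self, six_group_config):
        a = generate_item_bank(six_group_config)
        b = generate_item_bank(six_group_config)
        assert a == b

    def test_invalid_option_count_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(groups=mg.default_config().groups, n_options=3)


class TestSimulateTrial:
    def test_same_seed_identical(self, six_group_config):
        item = generate_item_bank(six_group_config)[5]
        p = _plain_params()
        a = simulate_trial(p, item, seed=42, accuracy=AccuracyModel())
        b = simulate_trial(p, item, seed=42, accuracy=AccuracyModel())
        assert np.array_equal(a["aoi"], b["aoi"])
        assert np.allclose(a["duration"], b["duration"])
        assert np.allclose(a["onset"], b["onset"])
        assert a["chosen"] == b["chosen"]

    def test_forced_sweeps_always_encode(self, six_group_config):
        item = generate_item_bank(six_group_config)[0]
        p = _plain_params(p_scan=1.0, toggle_intensity=1e-9)
        for seed in range(30):
            out = simulate_trial(p, item, seed=seed)
            ti = out["indices"]
            assert ti.encoding and ti.integration
            assert ti.n_toggles == 1  # one forced final toggle

    def test_no_sweeps_without_scanning_or_accident(self, six_group_config):
        item = generate_item_bank(six_group_config)[0]
        p = _plain_params(p_scan=0.0)
        flagged = accidental = 0
        for seed in range(150):
            out = simulate_trial(p, item, seed=seed)
            assert not out["latent"]["do_row"] and not out["latent"]["do_col"]
            flagged += out["indices"].encoding
            accidental += 1
        # only chance sweeps from wandering remain, and they are uncommon
        assert flagged / accidental < 0.35

    def test_renewal_toggle_count(self, six_group_config):
        # lambda = 1/s over ~10 s trials: mean measured rate ~ 1.0
        item = dataclasses.replace(
            generate_item_bank(six_group_config)[8], difficulty=45.0
        )
        p = _plain_params(
            p_scan=0.0, toggle_intensity=1.0, trial_time_mean=10.0,
            trial_time_sd=0.05, first_toggle_mean=1.0,
        )
        rng = np.random.default_rng(0)
        rates, counts = [], []
        for _ in range(1000):
            out = simulate_trial(p, item, rng=rng)
            ti = out["indices"]
            counts.append(ti.n_toggles)
            rates.append(ti.toggle_rate)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert np.mean(counts) == pytest.approx(10.0, abs=max(4 * se, 0.35))
        assert np.mean(rates) == pytest.approx(1.0, abs=0.05)

    def test_first_toggle_time_matches_parameter(self, six_group_config):
        item = dataclasses.replace(
            generate_item_bank(six_group_config)[8], difficulty=45.0
        )
        p = _plain_params(first_toggle_mean=2.5, trial_time_mean=12.0)
        rng = np.random.default_rng(1)
        vals = [
            simulate_trial(p, item, rng=rng)["indices"].time_to_first_toggle
            for _ in range(1000)
        ]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(2.5, abs=3.5 * se)

    def test_missing_fraction_exact_per_trial(self, six_group_config):
        item = generate_item_bank(six_group_config)[3]
        p = _plain_params(missing_frac=0.4)
        out = simulate_trial(p, item, seed=11)
        ti = compute_trial_indices(
            out["aoi"], out["duration"], trial_duration=out["trial_duration"]
        )
        latent = out["latent"]
        assert ti.valid_fraction == pytest.approx(1.0 - latent["missing"], abs=1e-9)

    def test_zero_missing_gives_full_valid_fraction(self, six_group_config):
        item = generate_item_bank(six_group_config)[3]
        out = simulate_trial(_plain_params(), item, seed=2)
        assert out["trial_duration"] == pytest.approx(out["duration"].sum())

    def test_fixation_durations_respect_floor(self, six_group_config):
        item = generate_item_bank(six_group_config)[7]
        for seed in range(20):
            out = simulate_trial(_plain_params(), item, seed=seed)
            assert (out["duration"] >= 0.1 - 1e-12).all()
            # fixations are time-ordered and non-overlapping
            ends = out["onset"] + out["duration"]
            assert (out["onset"][1:] >= ends[:-1] - 1e-9).all()

    def test_time_partition(self, six_group_config):
        # AOI fixation time + off-AOI gap time = trial duration
        item = generate_item_bank(six_group_config)[0]
        out = simulate_trial(_plain_params(missing_frac=0.3), item, seed=4)
        aoi_time = out["duration"].sum()
        assert aoi_time / out["trial_duration"] == pytest.approx(
            1.0 - out["latent"]["missing"]
        )


class TestAccuracyModel:
    def _indices(self):
        return compute_trial_indices([1, 2, 3, 10], [0.5, 0.5, 0.5, 0.5])

    def test_uniform_guess_limit(self, six_group_config, rng):
        item = generate_item_bank(six_group_config)[0]
        acc = AccuracyModel(uniform_guess=True)
        picks = [
            accuracy_model(acc, item, self._indices(), rng=rng) for _ in range(4000)
        ]
        assert np.mean(np.array(picks) == item.correct_option) == pytest.approx(
            1 / 8, abs=0.02
        )

    def test_saturating_intercept_always_correct(self, six_group_config, rng):
        item = generate_item_bank(six_group_config)[0]
        acc = AccuracyModel()
        for _ in range(200):
            ch = accuracy_model(
                acc, item, self._indices(), rng=rng, intercept=50.0, d_ref=45.0
            )
            assert ch == item.correct_option

    def test_zero_weights_rejected(self, six_group_config, rng):
        item = generate_item_bank(six_group_config)[0]
        acc = AccuracyModel(w_duplicate=0, w_novel=0, w_partial=0, w_other=0)
        with pytest.raises(ValueError, match="weights"):
            for _ in range(50):
                accuracy_model(acc, item, self._indices(), rng=rng, intercept=-50.0)

    def test_encoding_coefficient_drives_correlation(self):
        # cohort-level sign check of the constructive-matching ground truth
        cfg = mg.default_config(n_per_group=40, seed=23)
        cfg = dataclasses.replace(cfg, groups=(cfg.groups[0],))
        rs = []
        for s in range(8):
            coh = mg.simulate_cohort(cfg, seed=600 + s, light=True)
            parts = mg.aggregate_participants(coh.trial_indices, coh.responses)
            rs.append(np.corrcoef(parts["pct_encoding"], parts["percent_correct"])[0, 1])
        assert np.mean(rs) > 0.2 and sum(r > 0 for r in rs) >= 7


class TestCohort:
    def test_deterministic_output(self, six_group_config):
        a = mg.simulate_cohort(six_group_config, seed=3)
        b = mg.simulate_cohort(six_group_config, seed=3)
        assert a.fixations.equals(b.fixations)
        assert a.responses.equals(b.responses)
        assert a.truth_participants.equals(b.truth_participants)

    def test_light_and_full_agree(self, six_group_config):
        full = mg.simulate_cohort(six_group_config, seed=3)
        light = mg.simulate_cohort(six_group_config, seed=3, light=True)
        assert light.responses.equals(full.responses)
        # indices computed from the full fixation table match the light table
        trials = mg.trial_table(full.fixations)
        merged = trials.merge(
            light.trial_indices, on=["participant", "trial"], suffixes=("_f", "_l")
        )
        assert np.allclose(merged["toggle_rate_f"], merged["toggle_rate_l"])
        assert (merged["encoding_f"] == merged["encoding_l"]).all()

    def test_aoi_round_trip_through_layout(self, small_cohort):
        lay = default_layout()
        fix = small_cohort.fixations
        assigned = lay.assign_array(fix["x"].to_numpy(), fix["y"].to_numpy())
        assert (assigned == fix["aoi"].to_numpy()).all()

    def test_pipeline_loadable_end_to_end(self, small_cohort):
        res = mg.run_pipeline(
            small_cohort.fixations, small_cohort.responses, fit_trial_models=False
        )
        assert len(res.participants) == 12
        assert set(res.item_difficulty["item"]) == set(range(24))

    def test_cohort_valid_fraction_tracks_missing(self, six_group_config):
        grp = six_group_config.groups[0]
        g43 = dataclasses.replace(
            grp, n=40, params=dataclasses.replace(grp.params, missing_frac=0.43)
        )
        cfg = dataclasses.replace(six_group_config, groups=(g43,))
        coh = mg.simulate_cohort(cfg, seed=9, light=True)
        vf = coh.trial_indices.groupby("participant")["valid_fraction"].mean().mean()
        assert vf == pytest.approx(0.57, abs=0.03)

    def test_to_dir_writes_tables(self, tmp_path, small_cohort):
        small_cohort.to_dir(tmp_path / "out")
        names = {p.name for p in (tmp_path / "out").iterdir()}
        assert {"fixations.csv", "responses.csv", "items.csv", "options.csv",
                "truth_participants.csv", "truth_trials.csv"} <= names


class TestValidation:
    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            _plain_params(p_scan=1.4)
        with pytest.raises(ValueError):
            _plain_params(toggle_intensity=0.0)
        with pytest.raises(ValueError):
            _plain_params(missing_frac=1.0)

    def test_spread_fields_exist(self):
        sp = StrategySpread()
        assert 0 <= sp.scan_adapt_cor <= 1
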