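"""Synthetic-data generators: invariants, determinism, planted directions."""

import numpy as np
import pandas as pd
import pytest

from aa_phenoscreen.features import feature_table, normalize_to_controls
from aa_phenoscreen.phospho import KO_COLS, WT_COLS, merge_entries
from aa_phenoscreen.simulate import (
    ARCHETYPES,
    BASE_STARTLE_GAIN,
    BehaviourArchetype,
    simulate_network,
    simulate_phosphoproteome,
    simulate_plate,
    simulate_track,
)
from aa_phenoscreen.tracking import AnalysisWindow, StimulusSchedule, battery_windows


class TestArchetypes:
    def test_control_is_identity(self):
        c = ARCHETYPES["control"]
        assert (c.speed, c.pause, c.turning, c.spurt, c.thigmo) == (1,) * 5

    def test_dose_zero_neutralises_any_archetype(self):
        a = ARCHETYPES["AA"].at_dose(0)
        assert (a.speed, a.pause, a.turning, a.spurt, a.thigmo) == (1,) * 5

    def test_dose_scaling_is_linear(self):
        a = ARCHETYPES["AA"]
        assert a.at_dose(3).speed == pytest.approx(a.speed)
        assert a.at_dose(1).speed == pytest.approx(1 + (a.speed - 1) / 3)

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(ValueError):
            BehaviourArchetype("bad", speed=0.0)


class TestSimulateTrack:
    def test_track_satisfies_invariants(self, short_schedule, well):
        tr = simulate_track("AA", 2, short_schedule, well, seed=3, frame_rate=10)
        assert np.all(np.diff(tr.t) > 0)
        assert np.all(tr.step_dist >= 0) and tr.step_dist[0] == 0
        assert np.all((tr.heading >= 0) & (tr.heading < 360))
        assert np.all((tr.x >= well.x_min) & (tr.x <= well.x_max))
        assert np.all((tr.y >= well.y_min) & (tr.y <= well.y_max))

    def test_identical_seeds_identical_tracks(self, short_schedule, well):
        a = simulate_track("other", 1, short_schedule, well, seed=9, frame_rate=10)
        b = simulate_track("other", 1, short_schedule, well, seed=9, frame_rate=10)
        np.testing.assert_array_equal(a.step_dist, b.step_dist)
        np.testing.assert_array_equal(a.x, b.x)

    def test_certain_pausing_freezes_the_fish(self, short_schedule, well):
        glued = BehaviourArchetype("glued", pause=10.0)  # prob clips to 1
        tr = simulate_track(glued, 3, short_schedule, well, seed=0, frame_rate=10)
        assert tr.step_dist.sum() == 0.0

    def test_extreme_wall_bias_pins_fish_to_border(self, well):
        sched = StimulusSchedule(acclimation_s=0, n_cycles=1, intermission_s=120)
        wally = BehaviourArchetype("wally", thigmo=20.0)
        tr = simulate_track(wally, 3, sched, well, seed=1, frame_rate=10)
        from aa_phenoscreen.features import thigmotaxis

        t_ratio, _ = thigmotaxis(tr, AnalysisWindow("custom", 1, 30.0, 180.0), well)
        assert t_ratio > 0.97

    def test_neutralised_startle_gain_equalises_srb_and_psrb_rates(self, well):
        flat = BehaviourArchetype("flat",
                                  startle_gain=tuple(1 / g for g in BASE_STARTLE_GAIN))
        sched = StimulusSchedule(acclimation_s=0, n_cycles=1, intermission_s=600)
        rates = []
        for seed in range(8):
            tr = simulate_track(flat, 3, sched, well, seed=seed, frame_rate=10)
            srb = tr.step_dist[tr.window_slice(0, 60)].sum() / 60
            psrb = tr.step_dist[tr.window_slice(60, 660)].sum() / 600
            rates.append(srb / psrb)
        assert np.mean(rates) == pytest.approx(1.0, abs=0.15)

    def test_startle_gain_boosts_motility_during_startle(self, well):
        sched = StimulusSchedule(acclimation_s=0, n_cycles=1, intermission_s=600)
        ratios = []
        for seed in range(5):
            tr = simulate_track("control", 0, sched, well, seed=seed, frame_rate=10)
            srb = tr.step_dist[tr.window_slice(0, 60)].sum() / 60
            psrb = tr.step_dist[tr.window_slice(60, 660)].sum() / 600
            ratios.append(srb / psrb)
        assert np.mean(ratios) > 1.5


class TestSimulatePlate:
    def test_no_control_arm_errors(self, short_schedule, well):
        with pytest.raises(ValueError, match="control"):
            simulate_plate({"d": ("AA", [1, 2])}, 3, short_schedule, well)

    def test_zero_fish_arm_omitted_with_warning(self, short_schedule, well):
        panel = {"control": ("control", [0]), "ghost": ("AA", [1])}
        with pytest.warns(UserWarning, match="ghost"):
            tracks, meta, _ = simulate_plate(panel, {"control": 3, "ghost": 0},
                                             short_schedule, well, seed=0,
                                             frame_rate=5)
        assert set(meta["treatment"]) == {"control"}

    def test_truth_records_every_fish(self, short_schedule, well):
        panel = {"control": ("control", [0]), "d": ("AA", [1, 3])}
        tracks, meta, truth = simulate_plate(panel, 2, short_schedule, well,
                                             seed=1, frame_rate=5)
        assert len(truth.fish) == len(tracks) == len(meta) == 6
        assert set(truth.fish["archetype"]) == {"control", "AA"}

    def test_aa_archetype_shifts_follow_the_screen_direction_pattern(self, well):
        # distance/thigmotaxis/spurt down, turning up vs same-plate controls
        sched = StimulusSchedule(acclimation_s=0, n_cycles=1, intermission_s=0,
                                 psrb_s=0)
        signs = []
        for seed in range(6):
            tracks, meta, _ = simulate_plate(
                {"control": ("control", [0]), "aa": ("AA", [3])},
                8, sched, well, seed=seed, frame_rate=10)
            wins = battery_windows(sched)
            norm = normalize_to_controls(feature_table(tracks, wins, well))
            treated = norm[norm["treatment"] == "aa"]
            signs.append([
                treated["distance_mm_pct"].mean() < 0,
                treated["thigmo_time_ratio_pct"].mean() < 0,
                treated["thigmo_dist_ratio_pct"].mean() < 0,
                treated["spurt_velocity_pct"].mean() < 0,
                treated["turning_rel_pct"].mean() > 0,
            ])
        assert np.array(signs).all(axis=0).all()


class TestSimulatePhospho:
    def test_truth_and_shapes(self):
        table, truth = simulate_phosphoproteome(n_entries=100, n_true=10, seed=0)
        assert truth["is_true"].sum() == 10
        assert set(truth.loc[truth["is_true"], "direction"]) <= {"up", "down"}
        merged = merge_entries(table)
        assert len(merged) == 100  # duplicates collapse back to unique entries

    def test_missingness_rate_matches_request(self):
        table, _ = simulate_phosphoproteome(n_entries=400, n_true=0.0 or 1,
                                            missing_rate=0.3, seed=1)
        frac = table[WT_COLS + KO_COLS].isna().to_numpy().mean()
        assert frac == pytest.approx(0.3, abs=0.03)

    def test_planted_fold_change_visible_in_ko(self):
        table, truth = simulate_phosphoproteome(n_entries=50, n_true=25,
                                                effect_fold=4.0, missing_rate=0.0,
                                                frac_up=1.0, seed=2)
        merged = merge_entries(table).merge(truth, on=["sequence", "protein"])
        ratio = merged[KO_COLS].mean(axis=1) / merged[WT_COLS].mean(axis=1)
        assert ratio[merged["is_true"]].median() == pytest.approx(4.0, rel=0.3)
        assert ratio[~merged["is_true"]].median() == pytest.approx(1.0, rel=0.2)

    def test_deterministic_given_seed(self):
        a, _ = simulate_phosphoproteome(n_entries=30, n_true=3, seed=5)
        b, _ = simulate_phosphoproteome(n_entries=30, n_true=3, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateNetwork:
    def test_planted_hubs_are_boosted_into_diff_set(self):
        net, universe, diff, truth = simulate_network(
            n_nodes=200, mean_degree=20, n_hubs=3, density_boost=3.0,
            diff_size=50, seed=0)
        p = truth["p_edge"]
        target = round(3.0 * p * 49)
        diff_set = set(diff)
        for hub in truth["hubs"]:
            count = sum(1 for nbr in net[hub] if nbr in diff_set and nbr != hub)
            assert count >= target

    def test_boost_one_leaves_no_signal(self):
        net, universe, diff, truth = simulate_network(
            n_nodes=200, mean_degree=20, n_hubs=3, density_boost=1.0,
            diff_size=50, seed=1)
        p = truth["p_edge"]
        diff_set = set(diff)
        for hub in truth["hubs"]:
            count = sum(1 for nbr in net[hub] if nbr in diff_set and nbr != hub)
            assert count <= 3 * p * 49  # nothing beyond the background rate zone

    def test_weights_in_range_and_no_self_loops(self):
        net, *_ = simulate_network(n_nodes=100, mean_degree=10, seed=2)
        assert all(a != b for a, b in net.edges)
        ws = [d["weight"] for _, _, d in net.edges(data=True)]
        assert all(0 < w <= 0.1 for w in ws)

    def test_deterministic_given_seed(self):
        n1, _, d1, t1 = simulate_network(n_nodes=80, mean_degree=8, diff_size=30, seed=7)
        n2, _, d2, t2 = simulate_network(n_nodes=80, mean_degree=8, diff_size=30, seed=7)
        assert set(n1.edges) == set(n2.edges)
        assert d1 == d2 and t1["hubs"] == t2["hubs"]
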