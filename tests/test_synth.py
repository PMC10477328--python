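import numpy as np
import pytest

from dbsrecruit import synth
from dbsrecruit.network import mean_nearest_neighbor_distance
from dbsrecruit.synth import BehaviorParams, SynthConfig, generate_behavior, generate_session, generate_spatial_layout


def _one_neuron_config(**kw):
    base = dict(
        n_neurons=1,
        n_blocks=1,
        trials_per_block=2,
        class_fractions={"sustained_excited": (1.0,)},
        noise_sd=0.0,
        baseline_event_rate_hz=0.0,
        behavior_params=BehaviorParams(tuned_fractions={}),
        seed=0,
    )
    base.update(kw)
    return SynthConfig(**base)


class TestTraceConstruction:
    def test_noiseless_sustained_excited_is_exact_box(self):
        cfg = _one_neuron_config()
        session, gt = generate_session(cfg)
        assert gt.neuron_class[0, 0] == "sustained_excited"
        trace = session.traces[0]
        for _, row in session.trial_table.iterrows():
            on, off = int(row["dbs_on_frame"]), int(row["dbs_off_frame"])
            np.testing.assert_array_equal(trace[on:off], cfg.effect_amplitude)
            np.testing.assert_array_equal(trace[on - 150 : on], 0.0)
            np.testing.assert_array_equal(trace[off : off + 150], 0.0)

    def test_noiseless_transient_confined_to_first_20s(self):
        cfg = _one_neuron_config(class_fractions={"transient_inhibited": (1.0,)})
        session, gt = generate_session(cfg)
        trace = session.traces[0]
        row = session.trial_table.iloc[0]
        on, off = int(row["dbs_on_frame"]), int(row["dbs_off_frame"])
        n_tr = int(20 * cfg.frame_rate_hz)
        assert trace[on] == -cfg.effect_amplitude  # inhibited: negative deflection
        assert np.all(trace[on : on + n_tr] < 0)
        np.testing.assert_array_equal(trace[on + n_tr : off], 0.0)

    def test_seed_reproducibility_bit_for_bit(self):
        cfg = SynthConfig(n_neurons=10, n_blocks=1, trials_per_block=2,
                          class_fractions={"sustained_excited": (0.3,)}, seed=9)
        s1, g1 = generate_session(cfg)
        s2, g2 = generate_session(cfg)
        np.testing.assert_array_equal(s1.traces, s2.traces)
        np.testing.assert_array_equal(s1.events, s2.events)
        np.testing.assert_array_equal(g1.neuron_class, g2.neuron_class)

    def test_planted_fractions_recovered_by_counting(self):
        cfg = SynthConfig(n_neurons=200, n_blocks=2, trials_per_block=2,
                          class_fractions={"sustained_excited": (0.1, 0.25),
                                           "transient_excited": (0.0, 0.10)},
                          seed=3)
        _, gt = generate_session(cfg)
        counts = {
            b: dict(zip(*np.unique(gt.neuron_class[:, b], return_counts=True)))
            for b in range(2)
        }
        assert counts[0].get("sustained_excited") == 20
        assert counts[1].get("sustained_excited") == 50
        assert counts[1].get("transient_excited") == 20

    def test_anesthetized_suppresses_sustained_and_transient_inhibited(self):
        cfg = SynthConfig(n_neurons=100, n_blocks=2, trials_per_block=2,
                          class_fractions={"sustained_excited": (0.0, 0.2),
                                           "sustained_inhibited": (0.0, 0.1),
                                           "transient_excited": (0.0, 0.1),
                                           "transient_inhibited": (0.0, 0.1)},
                          anesthetized=True, seed=4)
        _, gt = generate_session(cfg)
        classes = set(np.unique(gt.neuron_class))
        assert "sustained_excited" not in classes
        assert "sustained_inhibited" not in classes
        assert "transient_inhibited" not in classes

    def test_events_nonnegative_and_positive_fraction_plants_neuron(self):
        cfg = SynthConfig(n_neurons=30, n_blocks=1, trials_per_block=2,
                          class_fractions={"transient_excited": (0.01,)}, seed=5)
        session, gt = generate_session(cfg)
        assert np.all(session.events >= 0)
        # fraction 0.01 of 30 rounds to 0 but must still plant >= 1 neuron
        assert (gt.neuron_class[:, 0] == "transient_excited").sum() >= 1

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(class_fractions={"sustained_excited": (0.7, 0.7, 0.7, 0.7),
                                         "transient_excited": (0.4, 0.4, 0.4, 0.4)}).validate()
        with pytest.raises(ValueError):
            SynthConfig(trial_len_s=-1).validate()
        with pytest.raises(ValueError):
            SynthConfig(dbs_len_s=100.0).validate()


class TestSpatialLayouts:
    def test_single_cluster_tighter_than_random(self):
        c_rand, r_rand = generate_spatial_layout("random", 20, 200, 400.0, seed=1)
        c_clu, r_clu = generate_spatial_layout("single_cluster", 20, 200, 400.0, seed=1)
        assert mean_nearest_neighbor_distance(c_clu[r_clu]) < mean_nearest_neighbor_distance(
            c_rand[r_rand]
        )

    def test_dispersed_has_maximal_nn_distance(self):
        stats = {}
        for pattern in ("random", "single_cluster", "ring", "dispersed"):
            c, r = generate_spatial_layout(pattern, 4, 100, 400.0, seed=2)
            stats[pattern] = mean_nearest_neighbor_distance(c[r])
        assert stats["dispersed"] == max(stats.values())
        # four dispersed points in a square field sit near the corners
        c, r = generate_spatial_layout("dispersed", 4, 100, 400.0, seed=2)
        corners = np.array([[0, 0], [0, 400], [400, 0], [400, 400]])
        for p in c[r]:
            assert np.min(np.linalg.norm(corners - p, axis=1)) < 120

    def test_zero_recruited_is_valid(self):
        c, r = generate_spatial_layout("single_cluster", 0, 50, 400.0, seed=3)
        assert c.shape == (50, 2)
        assert r.size == 0

    def test_within_fov_and_unknown_pattern_errors(self):
        for pattern in synth.SPATIAL_PATTERNS:
            c, _ = generate_spatial_layout(pattern, 10, 60, 300.0, seed=4)
            assert np.all(c >= 0) and np.all(c < 300.0)
        with pytest.raises(ValueError):
            generate_spatial_layout("hexagon", 5, 10, 100.0)
        with pytest.raises(ValueError):
            generate_spatial_layout("random", 11, 10, 100.0)


class TestBehaviorStreams:
    def test_no_suppression_leaves_dbs_grooming_at_baseline(self):
        cfg = SynthConfig(n_neurons=1, behavior_params=BehaviorParams(dbs_groom_suppression=1.0),
                          seed=6)
        table, n_frames = synth.build_trial_table(cfg)
        mask = synth.stim_mask(cfg, table, n_frames)
        groom, _ = generate_behavior(cfg)
        frac_on = groom[mask].mean()
        frac_off = groom[~mask].mean()
        assert abs(frac_on - frac_off) < 0.05

    def test_full_suppression_zeroes_dbs_grooming(self):
        cfg = SynthConfig(n_neurons=1, behavior_params=BehaviorParams(dbs_groom_suppression=0.0),
                          seed=7)
        table, n_frames = synth.build_trial_table(cfg)
        mask = synth.stim_mask(cfg, table, n_frames)
        groom, _ = generate_behavior(cfg)
        assert groom[mask].sum() == 0
        assert groom[~mask].sum() > 0

    def test_baseline_grooming_fraction_near_20_percent(self):
        # 3-s bouts / 12-s gaps target ~20% grooming outside stimulation
        cfg = SynthConfig(n_neurons=1, behavior_params=BehaviorParams(dbs_groom_suppression=1.0),
                          seed=8)
        table, n_frames = synth.build_trial_table(cfg)
        mask = synth.dbs_mask_from_trials(table, n_frames)
        fracs = []
        for seed in range(5):
            cfg2 = SynthConfig(n_neurons=1, seed=seed,
                               behavior_params=BehaviorParams(dbs_groom_suppression=1.0))
            groom, _ = generate_behavior(cfg2)
            fracs.append(groom[~mask].mean())
        assert 0.14 < np.mean(fracs) < 0.27

    def test_grooming_and_locomotion_never_cooccur(self):
        cfg = SynthConfig(n_neurons=1, seed=9)
        groom, loco = generate_behavior(cfg)
        assert np.all(loco[groom > 0] == 0)
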