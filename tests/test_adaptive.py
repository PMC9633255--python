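"""Adaptive high-pass tracking and the full-experiment runner."""

import numpy as np
import pytest

import dsirlab as d


def always_correct(label, stimulus, rng):
    return label


def never_correct(label, stimulus, rng):
    return "none"


def step_observer(threshold):
    """Deterministic observer: correct iff the HPF cutoff is at or below threshold."""
    def responder(label, stimulus, rng):
        return label if stimulus.hpf_cutoff <= threshold else "none"
    return responder


class TestRunTrack:
    def test_always_correct_converges_at_start_in_three_trials(self):
        res = d.run_track("ka", "unprocessed", 250, always_correct, np.random.default_rng(0))
        assert res.dsir_low == 7000
        assert res.n_trials == 3
        assert not res.floored

    def test_step_threshold_4000_recovered_in_33_trials(self):
        res = d.run_track("ka", "unprocessed", 250, step_observer(4000), np.random.default_rng(0))
        assert res.dsir_low == 4000
        assert res.n_trials == 33  # 30 decrements + 3 consecutive correct

    def test_never_correct_floors_with_flag(self):
        res = d.run_track("ka", "unprocessed", 250, never_correct, np.random.default_rng(0))
        assert res.floored
        assert res.dsir_low == 100

    def test_exhaustive_step_threshold_recovery_on_grid(self):
        """Every grid threshold in [100, 7000] is recovered exactly."""
        rng = np.random.default_rng(0)
        for c_star in range(100, 7100, 100):
            res = d.run_track("ka", "unprocessed", 250, step_observer(c_star), rng)
            assert res.dsir_low == c_star, c_star
            assert not res.floored

    def test_result_on_grid_and_pct_consistent(self):
        res = d.run_track("ka", "unprocessed", 250, step_observer(3200), np.random.default_rng(0))
        assert res.dsir_low % 100 == 0
        assert res.pct_of_band == pytest.approx((8000 - res.dsir_low) / 8000 * 100)

    def test_non_grid_floor_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            d.run_track("ka", "unprocessed", 250, always_correct,
                        np.random.default_rng(0), floor=150)

    def test_track_length_bound_holds_for_adversarial_observer(self):
        """n_trials <= 3 + 3 * (start - floor) / step for any response pattern."""
        def adversary(label, stimulus, rng):
            # two corrects then an error, maximising trials per level
            adversary.count += 1
            return label if adversary.count % 3 != 0 else "none"
        adversary.count = 0
        track = d.AdaptiveTrack(label="ka", condition="unprocessed", lpf_cutoff=250)
        res = d.run_track("ka", "unprocessed", 250, adversary,
                          np.random.default_rng(0), track_out=track)
        assert res.n_trials <= 3 + 3 * (7000 - 100) // 100


class TestFirstDecrement:
    def test_error_moves_cutoff_to_6900(self):
        track = d.AdaptiveTrack(label="ka", condition="unprocessed", lpf_cutoff=250)
        track.observe("none", False)
        assert d.first_decrement_check(track) == 6900

    def test_correct_leaves_cutoff_unchanged(self):
        track = d.AdaptiveTrack(label="ka", condition="unprocessed", lpf_cutoff=250)
        track.observe("ka", True)
        assert d.first_decrement_check(track) == 7000

    def test_two_errors_give_6800(self):
        track = d.AdaptiveTrack(label="ka", condition="unprocessed", lpf_cutoff=250)
        track.observe("none", False)
        track.observe("none", False)
        assert d.first_decrement_check(track) == 6800

    def test_before_any_response_raises(self):
        track = d.AdaptiveTrack(label="ka", condition="unprocessed", lpf_cutoff=250)
        with pytest.raises(ValueError, match="no responses"):
            d.first_decrement_check(track)


class TestStochasticRecovery:
    def test_logistic_observer_recovers_threshold_within_200_hz(self):
        """k=50 logistic listener: MAE of recovered DSIR vs true crossing <= 200 Hz.

        For /ka/ (target band 1400-2000 Hz) at LPF 250 Hz the coverage
        crosses theta at hpf = 2000 - 600 * theta, a grid value for the
        thetas chosen here.
        """
        for theta, c_star in [(0.25, 1850), (0.5, 1700), (0.75, 1550)]:
            model = d.ListenerModel(slope=50.0, thresholds=theta)
            errs = [
                abs(
                    d.run_track("ka", "unprocessed", 250, model,
                                np.random.default_rng(seed)).dsir_low - c_star
                )
                for seed in range(100)
            ]
            assert np.mean(errs) <= 200, (theta, np.mean(errs))


class TestExperiment:
    def test_default_design_row_count(self):
        cfg = d.ExperimentConfig(n_subjects=2, seed=3)
        df = d.run_experiment(cfg)
        assert len(df) == 2 * 3 * 4 * 14

    def test_single_cell_config(self):
        cfg = d.ExperimentConfig(
            n_subjects=1, conditions=("unprocessed",), lpf_cutoffs=(250,),
            consonants=("ka",), seed=3,
        )
        df = d.run_experiment(cfg)
        assert len(df) == 1

    def test_same_seed_reproduces_table(self):
        cfg = d.ExperimentConfig(n_subjects=1, conditions=("unprocessed",), seed=9)
        assert d.run_experiment(cfg).equals(d.run_experiment(cfg))

    def test_different_seeds_differ(self):
        base = dict(n_subjects=1, conditions=("unprocessed",), lpf_cutoffs=(250,))
        a = d.run_experiment(d.ExperimentConfig(seed=1, **base))
        b = d.run_experiment(d.ExperimentConfig(seed=2, **base))
        assert not a["dsir_low"].equals(b["dsir_low"])

    def test_block_order_randomised(self):
        cfg = d.ExperimentConfig(
            n_subjects=1, conditions=("unprocessed",), lpf_cutoffs=(250, 500), seed=5
        )
        df = d.run_experiment(cfg)
        orders = df.groupby("lpf_cutoff").apply(
            lambda g: tuple(g.sort_values("block_position")["consonant"]),
            include_groups=False,
        )
        assert orders.iloc[0] != orders.iloc[1]

    def test_invalid_config_keys_rejected(self):
        with pytest.raises(ValueError, match="invalid config keys"):
            d.ExperimentConfig.from_dict({"n_subjects": 2, "subjects": 5})

    def test_config_from_dict_with_listener_block(self):
        cfg = d.ExperimentConfig.from_dict({
            "n_subjects": 1,
            "seed": 11,
            "listener": {"slope": 25.0, "thresholds": 0.4},
        })
        assert cfg.listener.slope == 25.0

    def test_mean_dsir_narrows_with_more_low_frequency_information(self):
        """Mean DSIR lower bound is non-decreasing in the LPF cutoff.

        A sharp, low-guessing coverage listener isolates the spectral
        mechanism: consonants whose target bands extend below 1 kHz gain
        coverage from the LF ear, so less high-frequency range is needed
        (the lower bound rises) as the LPF cutoff increases.
        """
        cfg = d.ExperimentConfig(
            n_subjects=10,
            conditions=("unprocessed",),
            seed=20,
            listener=d.ListenerModel(slope=50.0, guess_rate=1e-3, thresholds=0.5),
        )
        df = d.run_experiment(cfg)
        means = df.groupby("lpf_cutoff")["dsir_low"].mean().sort_index()
        assert np.all(np.diff(means.values) >= 0), means
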