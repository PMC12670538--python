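"""Behavioral metrics, speed, judgment point, stage clustering, skewness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from striosync import behavior


def make_trials(n, rt=2.0, iti=5.0, zone_frac=0.8):
    rows = []
    clock = iti
    for i in range(n):
        rows.append({
            "stimulus": "Stim1" if i % 2 == 0 else "Stim2",
            "choice": "left" if i % 2 == 0 else "right",
            "correct": True,
            "t_entry": clock,
            "t_exit": clock + rt * zone_frac,
            "t_choice": clock + rt,
        })
        clock += rt + iti
    return pd.DataFrame(rows)


def make_tracking(trials, zone_length=100.0, fs=50.0, lateral=None,
                  bifurcation=0.5, offset=15.0, noise=0.0, rng=None):
    """Constant-speed traversals with an optional linear divergence."""
    frames = []
    for row in trials.itertuples():
        t = np.arange(row.t_entry, row.t_exit, 1.0 / fs)
        d = (t - row.t_entry) / (row.t_exit - row.t_entry)
        x = d * zone_length
        sign = 1.0 if row.choice == "right" else -1.0
        slope = offset / (1.0 - bifurcation)
        y = sign * slope * np.maximum(0.0, d - bifurcation)
        if lateral is not None:
            y = np.full_like(t, lateral)
        if noise > 0:
            y = y + rng.normal(0, noise, t.size)
        frames.append(pd.DataFrame({"t": t, "x": x, "y": y}))
    return pd.concat(frames, ignore_index=True)


class TestTrialMetrics:
    def test_reaction_time_is_latency_to_reward_port(self):
        trials = make_trials(3, rt=2.5)
        out = behavior.trial_metrics(trials)
        assert np.allclose(out["reaction_time"], 2.5)

    def test_all_correct_success_rate_one(self):
        assert behavior.success_rate(make_trials(10)) == 1.0

    def test_missing_timestamps_excluded_with_warning(self):
        trials = make_trials(4)
        trials.loc[2, "t_choice"] = np.nan
        with pytest.warns(UserWarning, match="excluding 1"):
            out = behavior.trial_metrics(trials)
        assert len(out) == 3

    def test_programmed_success_probability_recovered(self):
        # binomial oracle: 0.8 +/- 3 SE at n=300
        rng = np.random.default_rng(0)
        n = 300
        correct = rng.random(n) < 0.8
        trials = make_trials(n)
        trials["correct"] = correct
        se = np.sqrt(0.8 * 0.2 / n)
        assert abs(behavior.success_rate(trials) - 0.8) < 3 * se


class TestRunningSpeed:
    def test_constant_advance_constant_speed(self):
        t = np.arange(0, 10, 0.1)
        x = np.arange(t.size) * 1.0
        _, v = behavior.running_speed(t, x, np.zeros_like(t), sigma=2)
        assert np.allclose(v, 10.0)

    def test_sigma_zero_returns_raw_finite_difference(self):
        t = np.array([0.0, 0.1, 0.2, 0.3])
        x = np.array([0.0, 1.0, 3.0, 6.0])
        _, v = behavior.running_speed(t, x, np.zeros_like(t), sigma=0)
        assert np.allclose(v, [10.0, 20.0, 30.0])

    def test_step_change_crosses_midpoint_at_change(self):
        # discrete-convolution oracle: symmetric kernel halves the step
        t = np.arange(0, 8, 0.1)
        dx = np.where(np.arange(t.size - 1) < 40, 1.0, 2.0)
        x = np.concatenate([[0.0], np.cumsum(dx)])[: t.size]
        _, v = behavior.running_speed(t, x, np.zeros_like(t), sigma=2)
        sigma, radius = 2, 8  # kernel truncated at 4 sigma
        kernel = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
        kernel /= kernel.sum()
        raw = np.where(np.arange(t.size - 1) < 40, 10.0, 20.0)
        expected = np.convolve(np.pad(raw, radius, mode="edge"), kernel,
                               mode="valid")
        np.testing.assert_allclose(v, expected, rtol=1e-6)
        assert v[39] < 15.0 < v[40]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            behavior.running_speed([0, 1], [0, 1], [0, 0])


class TestJudgment:
    def test_identical_trajectories_no_divergence(self):
        trials = make_trials(8)
        tracking = make_tracking(trials, lateral=3.0)
        d, t, _ = behavior.judgment_metrics(trials, tracking, 100.0,
                                            n_perm=500, seed=0)
        assert d is None and t is None

    def test_bifurcation_recovered_and_kinematics(self):
        """Programmed divergence at 0.5; constant speed v = L / T_zone, so
        judgment_time = d* . L / v."""
        rng = np.random.default_rng(1)
        trials = make_trials(40, rt=2.5)
        tracking = make_tracking(trials, noise=0.5, rng=rng)
        d, t, _ = behavior.judgment_metrics(trials, tracking, 100.0,
                                            n_perm=5000, seed=2)
        assert d == pytest.approx(0.5, abs=0.05)
        v = 100.0 / 2.0  # zone crossed in rt * 0.8 = 2 s
        assert t == pytest.approx(d * 100.0 / v, abs=0.05)


class TestStages:
    @staticmethod
    def staged_features(rng, sep=10.0, spread=1.0, n_per=6):
        rows = []
        centers = {"early": (0.55, 4.0), "middle": (0.75, 2.5),
                   "late": (0.95, 1.2)}
        scale = 0.01 * spread / sep
        for stage, (sr, rt) in centers.items():
            for _ in range(n_per):
                rows.append({
                    "success_rate": sr + rng.normal(0, 10 * scale),
                    "reaction_time": rt + rng.normal(0, 100 * scale),
                    "true_stage": stage,
                })
        return pd.DataFrame(rows)

    def test_well_separated_clusters_recovered_exactly(self):
        feats = self.staged_features(np.random.default_rng(0))
        out = behavior.cluster_stages(feats)
        assert (out["stage"] == out["true_stage"]).all()

    def test_hand_computed_ward_merge_order(self):
        # 1-D points {0, 1, 10}, k=2: Ward merges {0,1} first
        feats = pd.DataFrame({"success_rate": [0.0, 1.0, 10.0],
                              "reaction_time": [0.0, 1.0, 10.0]})
        out = behavior.cluster_stages(feats, k=2, standardize=False)
        assert out["cluster"].iloc[0] == out["cluster"].iloc[1]
        assert out["cluster"].iloc[2] != out["cluster"].iloc[0]

    def test_duplication_leaves_partition_unchanged(self):
        feats = self.staged_features(np.random.default_rng(3))
        out1 = behavior.cluster_stages(feats)
        doubled = pd.concat([feats, feats], ignore_index=True)
        out2 = behavior.cluster_stages(doubled)
        n = len(feats)
        assert (out2["stage"].iloc[:n].to_numpy()
                == out1["stage"].to_numpy()).all()
        assert (out2["stage"].iloc[n:].to_numpy()
                == out1["stage"].to_numpy()).all()

    def test_stage_order_is_behavioral(self):
        """late = fastest (lowest reaction time), regardless of leaf order."""
        feats = self.staged_features(np.random.default_rng(4))
        out = behavior.cluster_stages(feats)
        means = out.groupby("stage")["reaction_time"].mean()
        assert means["early"] > means["middle"] > means["late"]

    def test_too_few_sets_rejected(self):
        feats = pd.DataFrame({"success_rate": [0.5, 0.6],
                              "reaction_time": [2.0, 1.0]})
        with pytest.raises(ValueError, match="session sets"):
            behavior.cluster_stages(feats, k=3)

    def test_session_sets_tiling_and_sliding(self):
        metrics = pd.DataFrame({
            "success_rate": np.linspace(0.5, 1.0, 10),
            "reaction_time_median": np.linspace(4, 1, 10),
        })
        assert len(behavior.session_sets(metrics, size=3)) == 3
        assert len(behavior.session_sets(metrics, size=3, sliding=True)) == 8


class TestSkewness:
    def test_symmetric_sample_zero(self):
        assert behavior.sample_skewness([-1.0, 0.0, 1.0]) == pytest.approx(0.0)

    def test_hand_computed_moments(self):
        # m2 = 10, m3 = 36 -> g1 = 36 / 10^1.5
        assert behavior.sample_skewness([1, 2, 3, 4, 10]) == pytest.approx(
            36 / 10**1.5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=30))
    def test_mirroring_flips_sign(self, values):
        values = np.asarray(values)
        if np.var(values) < 1e-12:
            return
        g = behavior.sample_skewness(values)
        assert behavior.sample_skewness(-values) == pytest.approx(-g, abs=1e-9)

    def test_zero_variance_signalled(self):
        with pytest.raises(ValueError, match="zero-variance"):
            behavior.sample_skewness([2.0, 2.0, 2.0])

    def test_dagostino_test_detects_asymmetry(self):
        rng = np.random.default_rng(0)
        skewed = rng.exponential(1.0, 500)
        _, p = behavior.skewness_test(skewed)
        assert p < 1e-6
        _, p_sym = behavior.skewness_test(rng.normal(size=500))
        assert p_sym > 0.01
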