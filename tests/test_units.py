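"""Unit characterization: width, ISI, classification, maps, information."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from striosync import units
from tests.test_behavior import make_trials, make_tracking


def triangular_waveform(depth=60.0, duration_ms=0.6, fs=40000.0,
                        peak=0.0, n_pre=30):
    """Symmetric triangular trough, optional after-peak at `peak` µV."""
    dt = 1000.0 / fs
    half = duration_ms / 2.0
    t = np.arange(-n_pre * dt, duration_ms + 20 * dt, dt)
    v = np.zeros(t.size)
    tri = 1.0 - np.abs(t - half) / half
    v -= depth * np.clip(tri, 0.0, None)
    if peak > 0:
        bump = 1.0 - np.abs(t - (duration_ms + 5 * dt)) / (5 * dt)
        v += peak * np.clip(bump, 0.0, None)
    return v


class TestSpikeWidth:
    def test_triangular_trough_similar_triangles(self):
        """Depth-60 triangle over 0.6 ms, no after-peak: time below -20 µV
        is two thirds of the trough duration = 0.4 ms."""
        v = triangular_waveform()
        assert units.spike_width(v, 40000.0) == pytest.approx(0.4, abs=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 100.0))
    def test_amplitude_scale_invariance(self, scale):
        v = triangular_waveform(peak=20.0)
        w1 = units.spike_width(v, 40000.0)
        w2 = units.spike_width(v * scale, 40000.0)
        assert w2 == pytest.approx(w1, rel=1e-12)

    def test_resampling_invariance(self):
        v = triangular_waveform()
        w1 = units.spike_width(v, 40000.0)
        w2 = units.spike_width(np.repeat(v, 2), 80000.0)
        assert w2 == pytest.approx(w1, abs=1000.0 / 40000.0)

    def test_flat_waveform_rejected(self):
        with pytest.raises(ValueError):
            units.spike_width(np.zeros(50), 40000.0)


class TestPropLongISI:
    def test_regular_one_hz_zero(self):
        assert units.prop_long_isi(np.arange(100.0), 100.0) == 0.0

    def test_hand_enumerated(self):
        # ISIs (5, 1, 1): only the 5 s gap counts -> 5/10
        assert units.prop_long_isi([0.0, 5.0, 6.0, 7.0], 10.0) == 0.5

    def test_infinite_threshold_zero(self):
        st_ = np.array([0.0, 5.0, 6.0])
        assert units.prop_long_isi(st_, 10.0, threshold=np.inf) == 0.0

    def test_lt_two_spikes_is_one_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            assert units.prop_long_isi([1.0], 10.0) == 1.0


class TestClassify:
    def test_deep_rs_and_fs(self):
        assert units.classify_unit(1.0, 0.5) == "RS"
        assert units.classify_unit(0.2, 15.0) == "FS"

    def test_tan_merge_flag(self):
        assert units.classify_unit(0.9, 5.0, prop_isi=0.01) == "FS"
        assert units.classify_unit(0.9, 5.0, prop_isi=0.01,
                                   merge_tan=False) == "TAN"

    def test_generator_labels_recovered(self, tiny_session):
        session, truth, _ = tiny_session
        hits = 0
        for (uid, unit), spec in zip(session.units.items(), truth.units):
            feats = units.unit_features(unit, session.meta["duration"])
            hits += feats.label == spec.unit_class
        assert hits >= 0.8 * len(session.units)  # small-n spot check


class TestRateMap:
    def test_two_bin_division_oracle(self):
        # occupancy (1 s, 2 s), spikes (3, 4) -> rates (3, 2)
        trials = make_trials(1, rt=3.75, zone_frac=0.8)  # 3 s in zone
        t0 = trials["t_entry"].iloc[0]
        t = t0 + np.array([0.0, 0.5, 1.0, 2.0, 2.99])
        # 1 s in first half, 2 s in second half of a 2-bin zone
        x = np.array([0.0, 20.0, 50.0, 70.0, 99.0])
        tracking = pd.DataFrame({"t": t, "x": x, "y": np.zeros(5)})
        spikes = t0 + np.array([0.1, 0.2, 0.3, 1.2, 1.5, 2.0, 2.5])
        rmap = units.rate_map(spikes, trials, tracking, 100.0, n_bins=2,
                              split=None)
        np.testing.assert_allclose(rmap.occupancy["pooled"], [1.0, 2.0])
        np.testing.assert_allclose(rmap.count["pooled"], [3.0, 4.0])
        np.testing.assert_allclose(rmap.rate["pooled"], [3.0, 2.0])

    def test_conservation_invariant(self, tiny_session):
        session, _, _ = tiny_session
        unit = next(iter(session.units.values()))
        rmap = units.rate_map(unit.spike_times, session.trials,
                              session.tracking, session.zone_length)
        in_zone = 0
        for row in session.trials.itertuples():
            in_zone += np.sum((unit.spike_times >= row.t_entry)
                              & (unit.spike_times < row.t_exit))
        assert rmap.count["pooled"].sum() == in_zone
        assert (rmap.count["Stim1"] + rmap.count["Stim2"]
                == rmap.count["pooled"]).all()
        ok = rmap.valid()
        np.testing.assert_allclose(
            rmap.rate["pooled"][ok] * rmap.occupancy["pooled"][ok],
            rmap.count["pooled"][ok])

    def test_homogeneous_unit_flat_map(self):
        """Constant-speed traversals + Poisson spiking: chi-square GOF
        against a flat map does not reject."""
        rng = np.random.default_rng(7)
        trials = make_trials(25, rt=6.25, iti=1.0)  # 5 s per traversal
        tracking = make_tracking(trials, lateral=0.0)
        spikes = []
        for row in trials.itertuples():
            n = rng.poisson(80.0 * (row.t_exit - row.t_entry))
            spikes.append(rng.uniform(row.t_entry, row.t_exit, n))
        spikes = np.sort(np.concatenate(spikes))
        rmap = units.rate_map(spikes, trials, tracking, 100.0, split=None)
        counts = rmap.count["pooled"]
        expected = rmap.occupancy["pooled"] / rmap.occupancy["pooled"].sum()
        chi2, p = stats.chisquare(counts, expected * counts.sum())
        assert p > 0.01

    def test_zero_spikes_all_zero(self, tiny_session):
        session, _, _ = tiny_session
        rmap = units.rate_map(np.array([]), session.trials, session.tracking,
                              session.zone_length, split=None)
        assert np.nansum(rmap.rate["pooled"]) == 0.0


class TestSpatialInformation:
    def test_uniform_map_zero_bits(self):
        si = units.spatial_information(np.full(10, 3.0), np.full(10, 1.0))
        assert si.information == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("p,rates,expected", [
        ((0.5, 0.5), (2.0, 0.0), 1.0),
        ((0.25, 0.75), (4.0, 0.0), 2.0),
    ])
    def test_two_bin_closed_forms(self, p, rates, expected):
        si = units.spatial_information(np.array(rates), np.array(p))
        assert si.information == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 50.0))
    def test_rate_rescaling_invariance(self, scale):
        rng = np.random.default_rng(0)
        rates = rng.uniform(0, 5, 20)
        occ = rng.uniform(0.5, 2, 20)
        i1 = units.spatial_information(rates, occ).information
        i2 = units.spatial_information(rates * scale, occ).information
        assert i2 == pytest.approx(i1, rel=1e-9)

    def test_zero_mean_rate_signalled(self):
        with pytest.raises(ValueError, match="mean rate"):
            units.spatial_information(np.zeros(5), np.ones(5))


class TestSelectivity:
    def test_identical_curves_not_selective(self):
        trials = make_trials(12, rt=2.5)
        tracking = make_tracking(trials, lateral=0.0)
        _, selective = units.stimulus_selectivity(
            np.array([]), trials, tracking, 100.0, n_perm=300, seed=0)
        assert not selective

    def test_strong_gain_detected(self):
        """Stim1 rate 3x Stim2 over the whole zone."""
        rng = np.random.default_rng(3)
        trials = make_trials(40, rt=2.5, iti=1.0)
        tracking = make_tracking(trials, lateral=0.0)
        spikes = []
        for row in trials.itertuples():
            rate = 30.0 if row.stimulus == "Stim1" else 10.0
            n = rng.poisson(rate * (row.t_exit - row.t_entry))
            spikes.append(rng.uniform(row.t_entry, row.t_exit, n))
        spikes = np.sort(np.concatenate(spikes))
        _, selective = units.stimulus_selectivity(
            spikes, trials, tracking, 100.0, n_perm=5000, seed=1)
        assert selective


class TestPopulationAverage:
    def test_identical_populations_nothing_significant(self):
        rng = np.random.default_rng(2)
        pop = rng.uniform(1, 5, size=(10, 50))
        summary, res = units.population_stage_average(
            {"early": pop, "late": pop}, n_perm=500, seed=0)
        assert not res.global_sig.any()
        assert summary["early"]["n"] == 10

    def test_localized_rate_increase_detected_locally(self):
        rng = np.random.default_rng(4)
        base = 3.0 + rng.normal(0, 0.3, size=(15, 50))
        late = 3.0 + rng.normal(0, 0.3, size=(15, 50))
        late[:, :10] *= 2.0  # doubled on bins [0, 0.2)
        _, res = units.population_stage_average(
            {"early": base, "late": late}, n_perm=5000, seed=1)
        sig = np.flatnonzero(res.global_sig)
        assert sig.size > 0
        assert sig.max() < 13  # confined to a neighborhood of [0, 0.2)

    def test_sem_shrinks_with_sqrt_n(self):
        rng = np.random.default_rng(5)
        pop = rng.normal(0, 1.0, size=(200, 20))
        s1, _ = units.population_stage_average(
            {"early": pop[:50], "late": pop[:50]}, n_perm=1, seed=0)
        s2, _ = units.population_stage_average(
            {"early": pop, "late": pop}, n_perm=1, seed=0)
        ratio = s1["early"]["sem"].mean() / s2["early"]["sem"].mean()
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_empty_stage_rejected(self):
        with pytest.raises(ValueError, match=">= 2 units"):
            units.population_stage_average({"early": np.ones((1, 5)),
                                            "late": np.ones((3, 5))})
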