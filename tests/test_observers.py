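import collections

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from serialdep.observers import (
    ObserverParams,
    balanced_noise_sequence,
    simulate_adjustment_session,
    simulate_binary_experiment,
    simulate_binary_session,
    simulate_experiment,
)
from serialdep.serial import condition_on_previous, dog_value


def _transition_counts(seq):
    lab = np.where(np.asarray(seq) == "low", "L", "H")
    return collections.Counter(a + b for a, b in zip(lab[:-1], lab[1:]))


class TestBalancedSequence:
    def test_five_trials_one_of_each(self):
        counts = _transition_counts(balanced_noise_sequence(5, 0))
        assert sorted(counts.values()) == [1, 1, 1, 1]

    def test_paper_scale_exactly_balanced(self):
        counts = _transition_counts(balanced_noise_sequence(821, 3))
        assert all(counts[t] == 205 for t in ("LL", "LH", "HL", "HH"))

    def test_deterministic_per_seed(self):
        assert np.array_equal(balanced_noise_sequence(101, 9), balanced_noise_sequence(101, 9))

    @given(st.integers(5, 400), st.integers(0, 2**31 - 1))
    def test_counts_within_one(self, n, seed):
        counts = _transition_counts(balanced_noise_sequence(n, seed))
        vals = [counts.get(t, 0) for t in ("LL", "LH", "HL", "HH")]
        assert sum(vals) == n - 1
        assert max(vals) - min(vals) <= 1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            balanced_noise_sequence(4, 0)


class TestObserverParams:
    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            ObserverParams(sigma_low_deg=8, sigma_high_deg=4)
        with pytest.raises(ValueError):
            ObserverParams(lapse_rate=1.0)
        with pytest.raises(ValueError):
            ObserverParams(dog_width=0.5)
        with pytest.raises(ValueError):
            ObserverParams(dog_amplitude_deg={"LL": 1.0})

    def test_per_transition_amplitudes(self):
        p = ObserverParams(dog_amplitude_deg={"LL": 1.0, "LH": 2.0, "HL": 3.0, "HH": 4.0})
        assert p.amplitude("LH") == 2.0
        assert p.max_amplitude == 4.0


class TestAdjustmentSession:
    def test_identity_observer(self):
        p = ObserverParams(
            dog_amplitude_deg=0, sigma_low_deg=0, sigma_high_deg=0,
            global_bias_deg=0, lapse_rate=0,
        )
        t = simulate_adjustment_session(p, 60)
        assert np.allclose(t["response_deg"], t["orientation_deg"])
        assert np.allclose(t["error_deg"], 0)

    def test_schema_and_trial_index(self):
        t = simulate_adjustment_session(ObserverParams(seed=1), 100, "pX")
        assert list(t["trial_index"]) == list(range(1, 101))
        assert set(t["noise_level"]) == {"low", "high"}
        assert t["position_index"].between(0, 7).all()
        # position steps 45 degrees counterclockwise: index decrements mod 8
        diffs = np.diff(t["position_index"].to_numpy()) % 8
        assert np.all(diffs == 7)
        assert (t["orientation_deg"] >= 0).all() and (t["orientation_deg"] < 180).all()

    def test_noise_free_attractive_observer_traces_dog(self):
        """With zero response noise the generated error at each inter-trial
        difference is exactly the DoG pull; at the peak x* = 1/(w sqrt 2)
        ~ 14.1 deg the error equals the amplitude."""
        p = ObserverParams(
            dog_amplitude_deg=3.0, dog_width=0.05, sigma_low_deg=0, sigma_high_deg=0,
            global_bias_deg=0, lapse_rate=0, conditioning="previous_percept",
        )
        t = simulate_adjustment_session(p, 3000)
        s = condition_on_previous(t, "stimulus_contingent")
        pred = dog_value(s.data["delta_deg"].to_numpy(), 3.0, 0.05, 0.0)
        assert np.allclose(s.data["error_deg"], pred, atol=1e-9)
        near_peak = np.abs(s.data["delta_deg"] - 1 / (0.05 * np.sqrt(2))) < 0.2
        assert s.data.loc[near_peak, "error_deg"].to_numpy() == pytest.approx(3.0, abs=0.01)

    def test_null_observer_flat_error_vs_delta(self):
        p = ObserverParams(
            dog_amplitude_deg=0, sigma_low_deg=4, sigma_high_deg=4,
            global_bias_deg=0, lapse_rate=0, seed=2,
        )
        t = simulate_adjustment_session(p, 10000)
        s = condition_on_previous(t, "stimulus_contingent")
        slope = stats.linregress(s.data["delta_deg"], s.data["error_deg"]).slope
        assert abs(slope) < 0.02

    def test_high_noise_increases_error_spread(self):
        t = simulate_adjustment_session(ObserverParams(seed=3), 2000)
        by = t.groupby("noise_level")["error_deg"].apply(lambda e: e.abs().mean())
        assert by["high"] > by["low"]

    def test_first_trial_has_no_pull(self):
        p = ObserverParams(
            dog_amplitude_deg=4.0, sigma_low_deg=0, sigma_high_deg=0,
            global_bias_deg=0, lapse_rate=0, conditioning="previous_response",
        )
        t = simulate_adjustment_session(p, 30)
        assert t["error_deg"].iloc[0] == pytest.approx(0.0)

    def test_experiment_reproducible(self):
        p = ObserverParams(seed=4)
        a = simulate_experiment(p, 3, 50)
        b = simulate_experiment(p, 3, 50)
        assert a.equals(b)
        assert a["participant_id"].nunique() == 3


class TestBinarySession:
    def test_step_limit(self):
        # sample well outside the (vanishing) transition zone
        t = simulate_binary_session(0.01, 0.01, 500, seed=0, design_range_factor=500)
        x = t["signed_orientation_deg"].to_numpy()
        expect = np.where(x > 0, "right", "left")
        agree = np.mean(t["choice"].to_numpy() == expect)
        assert agree > 0.99

    def test_probability_matches_cumulative_gaussian(self):
        t = simulate_binary_session(5.0, 5.0, 30000, seed=1, design_range_factor=2.0)
        low = t[t["noise_level"] == "low"]
        sel = low["signed_orientation_deg"].between(4, 6)
        p_right = (low.loc[sel, "choice"] == "right").mean()
        assert p_right == pytest.approx(stats.norm.cdf(1.0), abs=0.04)
        near0 = low["signed_orientation_deg"].abs() < 1
        assert (low.loc[near0, "choice"] == "right").mean() == pytest.approx(0.5, abs=0.05)

    def test_invalid_spread_rejected(self):
        with pytest.raises(ValueError):
            simulate_binary_session(0.0, 5.0, 100)

    def test_experiment_structure(self):
        t = simulate_binary_experiment(4, n_trials=50, seed=2)
        assert t["participant_id"].nunique() == 4
        assert set(t["noise_level"]) == {"low", "high"}
        assert set(t["choice"]) <= {"left", "right"}
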