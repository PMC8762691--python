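import numpy as np
import pandas as pd
import pytest
from scipy.optimize import curve_fit

from serialdep.circstats import axial_delta
from serialdep.serial import (
    DOG_CONSTANT,
    GRID_DEG,
    ConditionedSeries,
    alternate_flip,
    condition_on_previous,
    dog_peak_location,
    dog_value,
    fit_dog,
    moving_average,
    permutation_test_amplitude,
    permutation_test_difference,
)


def _two_trial_table(stims, responses=None, noise=("low", "low"), pid="p1"):
    n = len(stims)
    responses = stims if responses is None else responses
    return pd.DataFrame(
        {
            "participant_id": pid,
            "trial_index": np.arange(1, n + 1),
            "orientation_deg": stims,
            "noise_level": list(noise),
            "response_deg": responses,
            "error_deg": axial_delta(np.asarray(responses, float), np.asarray(stims, float)),
        }
    )


def _series_from(deltas, errors, pid="p1", mode="stimulus_contingent"):
    return ConditionedSeries(
        pd.DataFrame(
            {"participant_id": pid, "delta_deg": deltas, "error_deg": errors,
             "transition": "LL"}
        ),
        mode,
    )


class TestConditioning:
    def test_two_trial_delta(self):
        t = _two_trial_table([10.0, 30.0])
        s = condition_on_previous(t, "stimulus_contingent")
        assert len(s.data) == 1
        assert s.data["delta_deg"].iloc[0] == pytest.approx(-20.0)

    def test_identical_stimuli_zero_delta(self):
        s = condition_on_previous(_two_trial_table([42.0, 42.0]), "stimulus_contingent")
        assert s.data["delta_deg"].iloc[0] == pytest.approx(0.0)

    def test_response_contingent_uses_previous_response(self):
        t = _two_trial_table([10.0, 30.0], responses=[20.0, 30.0])
        s = condition_on_previous(t, "response_contingent")
        assert s.data["delta_deg"].iloc[0] == pytest.approx(-10.0)

    def test_offset_plus_one_uses_next_trial(self):
        t = _two_trial_table([10.0, 30.0])
        s = condition_on_previous(t, "stimulus_contingent", offset=+1)
        # trial 1's error is paired with trial 2's orientation as reference
        assert s.data["delta_deg"].iloc[0] == pytest.approx(20.0)

    def test_transition_labels_previous_to_current(self):
        t = _two_trial_table([10.0, 30.0, 50.0], noise=("low", "high", "low"))
        s = condition_on_previous(t, "stimulus_contingent")
        assert s.data["transition"].tolist() == ["LH", "HL"]

    def test_pairs_never_span_participants(self):
        t = pd.concat(
            [_two_trial_table([10.0, 30.0], pid="a"), _two_trial_table([50.0, 90.0], pid="b")],
            ignore_index=True,
        )
        s = condition_on_previous(t, "stimulus_contingent")
        assert len(s.data) == 2  # one pair per participant, none across

    def test_offset_zero_rejected(self):
        with pytest.raises(ValueError):
            condition_on_previous(_two_trial_table([1.0, 2.0]), "stimulus_contingent",
                                  offset=0)


class TestMovingAverage:
    def test_constant_errors(self):
        rng = np.random.default_rng(0)
        s = _series_from(rng.uniform(-89.9, 89.9, 5000), np.full(5000, 2.5))
        curve = moving_average(s)
        assert np.allclose(curve["mean_error_deg"].dropna(), 2.5)

    def test_antisymmetric_input_gives_antisymmetric_curve(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(0.5, 89.5, 4000)
        deltas = np.concatenate([d, -d])
        errors = np.concatenate([np.sin(np.deg2rad(d * 4)), -np.sin(np.deg2rad(d * 4))])
        curve = moving_average(_series_from(deltas, errors))
        m = curve.set_index("delta_deg")["mean_error_deg"]
        for x in range(1, 89):
            if np.isfinite(m[x]) and np.isfinite(m[-x]):
                assert m[x] == pytest.approx(-m[-x], abs=1e-9)

    def test_matches_bruteforce_windowing(self):
        """The binned/convolved implementation must agree exactly with a
        direct per-grid-point masked mean, including wrap at +/-90."""
        rng = np.random.default_rng(2)
        deltas = rng.uniform(-90, 90, 3000)
        deltas = deltas[deltas < 90]
        errors = rng.normal(0, 5, deltas.size)
        curve = moving_average(_series_from(deltas, errors), window_deg=20)
        for d in (-89, -80, -45, -1, 0, 33, 89):
            dist = np.mod(deltas - d + 90, 180) - 90
            mask = (dist >= -10) & (dist < 10)
            row = curve[curve["delta_deg"] == d].iloc[0]
            assert row["n"] == mask.sum()
            assert row["mean_error_deg"] == pytest.approx(errors[mask].mean())

    def test_dog_input_matches_convolution_oracle(self):
        """Dense noiseless DoG data smooth to the boxcar-convolved DoG."""
        deltas = np.arange(-89.995, 90, 0.01)
        errors = dog_value(deltas, 2.0, 0.05, 0.0)
        curve = moving_average(_series_from(deltas, errors))
        fine = np.arange(-90, 90, 0.01)
        vals = dog_value(fine, 2.0, 0.05, 0.0)
        for d in (-60, -14, 0, 14, 40):
            dist = np.mod(fine - d + 90, 180) - 90
            expected = vals[(dist >= -10) & (dist < 10)].mean()
            got = curve.loc[curve["delta_deg"] == d, "mean_error_deg"].iloc[0]
            assert got == pytest.approx(expected, abs=0.1)

    def test_odd_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average(_series_from([0.0], [0.0]), window_deg=15)


class TestDogModel:
    def test_constant_value(self):
        assert DOG_CONSTANT == pytest.approx(np.sqrt(2) * np.exp(0.5))

    def test_zero_crossing_at_origin(self):
        assert dog_value(0.0, 3.0, 0.05, 1.25) == pytest.approx(1.25)

    @pytest.mark.parametrize("a,w", [(3.0, 0.05), (-2.0, 0.1), (1.0, 0.02)])
    def test_peak_height_equals_amplitude(self, a, w):
        xs = np.linspace(0, 90, 100001)  # positive lobe carries the sign of a
        ys = dog_value(xs, a, w, 0.0)
        assert ys[np.argmax(np.abs(ys))] == pytest.approx(a, abs=1e-5)
        assert xs[np.argmax(np.sign(a) * ys)] == pytest.approx(
            dog_peak_location(w), abs=0.01
        )
        assert dog_value(dog_peak_location(w), a, w, 0.0) == pytest.approx(a)

    def test_odd_symmetry(self):
        x = np.linspace(0.1, 89, 50)
        assert np.allclose(dog_value(-x, 2.0, 0.07, 0.5) - 0.5,
                           -(dog_value(x, 2.0, 0.07, 0.5) - 0.5))


class TestFitDog:
    def _curve(self, a, w, b, noise=0.0, rng=None):
        y = dog_value(GRID_DEG, a, w, b)
        if noise:
            y = y + rng.normal(0, noise, y.size)
        return pd.DataFrame({"delta_deg": GRID_DEG, "mean_error_deg": y})

    def test_noiseless_recovery(self):
        fit = fit_dog(self._curve(2.0, 0.05, 0.0))
        assert fit.a == pytest.approx(2.0, abs=1e-3)
        assert fit.w == pytest.approx(0.05, abs=1e-4)
        assert fit.converged and not fit.w_at_bound

    def test_flat_curve_zero_amplitude(self):
        fit = fit_dog(pd.DataFrame({"delta_deg": GRID_DEG,
                                    "mean_error_deg": np.zeros_like(GRID_DEG)}))
        assert abs(fit.a) < 1e-9

    def test_boundary_width_flagged(self):
        fit = fit_dog(self._curve(2.0, 0.25, 0.0))  # true w above the ceiling
        assert fit.w_at_bound

    def test_matches_independent_optimizer_on_noisy_curves(self):
        """Cross-check the grid+refine fit against multi-start scipy
        curve_fit (an independent optimisation route)."""
        rng = np.random.default_rng(3)
        for a, w, b in [(2.5, 0.04, 0.2), (-1.5, 0.12, -0.3), (3.5, 0.07, 0.0)]:
            curve = self._curve(a, w, b, noise=0.3, rng=rng)
            fit = fit_dog(curve)
            best = None
            for w0 in (0.03, 0.06, 0.1, 0.15):
                try:
                    popt, _ = curve_fit(
                        dog_value, curve["delta_deg"], curve["mean_error_deg"],
                        p0=[1.0, w0, 0.0],
                        bounds=([-np.inf, 0.02, -np.inf], [np.inf, 0.2, np.inf]),
                        maxfev=5000,
                    )
                except RuntimeError:
                    continue
                rss = np.sum(
                    (dog_value(curve["delta_deg"], *popt) - curve["mean_error_deg"]) ** 2
                )
                if best is None or rss < best[1]:
                    best = (popt, rss)
            assert best is not None
            assert fit.a == pytest.approx(best[0][0], abs=0.02)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_dog(pd.DataFrame({"delta_deg": GRID_DEG[:10],
                                  "mean_error_deg": np.zeros(10)}))


class TestPermutationTests:
    def _cohort_series(self, amp, n_participants=6, n_trials=300, seed=0):
        from serialdep.observers import ObserverParams, simulate_experiment
        from serialdep.preprocess import preprocess

        p = ObserverParams(dog_amplitude_deg=amp, lapse_rate=0.0, seed=seed,
                           conditioning="previous_percept")
        t = simulate_experiment(p, n_participants, n_trials)
        clean, _ = preprocess(t, apply_exclusions=False)
        return condition_on_previous(clean, "stimulus_contingent")

    def test_seed_reproducible(self):
        s = self._cohort_series(2.0)
        r1 = permutation_test_amplitude(s, n_perm=300, seed=5)
        r2 = permutation_test_amplitude(s, n_perm=300, seed=5)
        assert r1.p == r2.p and r1.observed_stat == r2.observed_stat

    def test_negating_all_errors_negates_amplitude(self):
        s = self._cohort_series(2.0)
        r = permutation_test_amplitude(s, n_perm=200, seed=0)
        flipped = ConditionedSeries(
            s.data.assign(error_deg=-s.data["error_deg"]), s.mode
        )
        rf = permutation_test_amplitude(flipped, n_perm=200, seed=0)
        assert rf.observed_stat == pytest.approx(-r.observed_stat, abs=1e-9)

    def test_strong_effect_detected(self):
        s = self._cohort_series(3.0, n_participants=8, n_trials=400)
        r = permutation_test_amplitude(s, n_perm=500, seed=1)
        assert r.observed_stat > 1.0
        assert r.p < 0.01

    def test_p_display_bound_when_zero(self):
        s = self._cohort_series(3.0, n_participants=8, n_trials=400)
        r = permutation_test_amplitude(s, n_perm=500, seed=1)
        if r.p == 0:
            assert r.p_display == "< 0.002"

    def test_difference_same_data_is_zero(self):
        s = self._cohort_series(2.0)
        r = permutation_test_difference(s, s, n_perm=100, seed=0)
        assert r.observed_stat == pytest.approx(0.0, abs=1e-12)

    def test_difference_mismatched_participants_rejected(self):
        s = self._cohort_series(2.0)
        other = ConditionedSeries(
            s.data[s.data["participant_id"] != "p01"].copy(), s.mode
        )
        with pytest.raises(ValueError, match="missing"):
            permutation_test_difference(s, other, n_perm=100, seed=0)

    def test_low_nperm_warns(self):
        s = self._cohort_series(2.0)
        with pytest.warns(UserWarning):
            permutation_test_amplitude(s, n_perm=50, seed=0)


class TestAlternateFlip:
    def _table(self, n, pid="p1"):
        return pd.DataFrame(
            {
                "participant_id": pid,
                "trial_index": np.arange(1, n + 1),
                "orientation_deg": np.arange(n, dtype=float),
                "noise_level": ["low", "high"] * (n // 2) + ["low"] * (n % 2),
                "response_deg": np.arange(n, dtype=float) + 100,
                "error_deg": np.zeros(n),
            }
        )

    def test_six_trial_hand_example(self):
        out = alternate_flip(self._table(6)).sort_values("trial_index")
        # even positions 2,4,6 receive the contents of 6,4,2
        assert out["orientation_deg"].tolist() == [0.0, 5.0, 2.0, 3.0, 4.0, 1.0]
        assert out["response_deg"].tolist() == [100.0, 105.0, 102.0, 103.0, 104.0, 101.0]

    def test_odd_count_reverses_interior_evens(self):
        out = alternate_flip(self._table(7)).sort_values("trial_index")
        # evens are 2,4,6; they receive the contents of 6,4,2
        assert out["orientation_deg"].tolist() == [0.0, 5.0, 2.0, 3.0, 4.0, 1.0, 6.0]

    def test_involution(self, small_cohort):
        t = small_cohort
        twice = alternate_flip(alternate_flip(t))
        pd.testing.assert_frame_equal(
            twice.sort_values(["participant_id", "trial_index"]).reset_index(drop=True),
            t.sort_values(["participant_id", "trial_index"]).reset_index(drop=True),
            check_like=True,
        )

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            alternate_flip(self._table(3))
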