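"""Neural analyses: warping, CPD, permutation nulls, projections, PCA, decoding."""

import numpy as np
import pytest

from twostep.neural import (NeuralSession, benjamini_hochberg, cpd_regression,
                            circular_shift_permutation, decode_locations,
                            neural_design, representation_projection,
                            time_warp_align, trial_type_pca)
from twostep.synth import (CohortSpec, NeuralSpec, generate_behavior_cohort,
                           generate_neural_cohort)
from twostep.task import Session


def make_behavior(n, rng, **arrays):
    return Session(
        choice=arrays.get("choice", rng.integers(2, size=n).astype(np.int8)),
        second_step=arrays.get("second_step", rng.integers(2, size=n).astype(np.int8)),
        outcome=arrays.get("outcome", rng.integers(2, size=n).astype(np.int8)),
        transition_state=np.zeros(n, np.int8),
        reward_state=np.zeros(n, np.int8),
        block_index=np.zeros(n, np.int16))


def make_neural(activity, choice_times, outcome_times, rng=None, behavior=None):
    n = len(choice_times)
    if behavior is None:
        behavior = make_behavior(n, rng or np.random.default_rng(0))
    return NeuralSession(activity=np.asarray(activity, float),
                         choice_times=np.asarray(choice_times, float),
                         outcome_times=np.asarray(outcome_times, float),
                         behavior=behavior)


class TestTimeWarp:
    def test_impulse_at_outcome_lands_on_outcome_index(self):
        """Activity peaks locked to the outcome align on the same grid column
        regardless of trial duration."""
        rng = np.random.default_rng(0)
        durations = [0.4, 0.7, 1.0, 1.3]
        choice_times = 2.0 + 5.0 * np.arange(4)
        outcome_times = choice_times + durations
        n_frames = int((outcome_times[-1] + 2) * 10)
        activity = np.zeros((1, n_frames))
        for ot in outcome_times:
            activity[0, int(round(ot * 10))] = 1.0
        ns = make_neural(activity, choice_times, outcome_times, rng)
        tensor = time_warp_align(ns, smooth_sd=0.0)
        peaks = tensor.values[:, 0, :].argmax(axis=1)
        assert (np.abs(peaks - tensor.outcome_index) <= 1).all()

    def test_all_zero_activity_stays_zero(self):
        rng = np.random.default_rng(1)
        ns = make_neural(np.zeros((3, 200)), [2.0, 8.0], [2.7, 8.7], rng)
        tensor = time_warp_align(ns, log2=False)
        assert not tensor.values.any()

    def test_median_duration_trial_is_plain_resampling(self):
        rng = np.random.default_rng(2)
        n_frames = 300
        activity = rng.random((1, n_frames))
        choice_times = np.array([3.0, 10.0, 17.0])
        outcome_times = choice_times + 0.8          # all at the median
        ns = make_neural(activity, choice_times, outcome_times, rng)
        tensor = time_warp_align(ns, smooth_sd=0.0)
        frame_t = np.arange(n_frames) / 10.0
        k = tensor.choice_index
        t_grid = choice_times[1] + (np.arange(tensor.n_timepoints) - k) / tensor.fs
        expected = np.interp(t_grid, frame_t, activity[0])
        assert tensor.values[1, 0] == pytest.approx(expected, abs=1e-12)

    def test_mass_conserved_up_to_warp_factor(self):
        """For smooth signals the warped-segment integral equals the original
        segment integral rescaled by (median / duration), within 2%."""
        rng = np.random.default_rng(3)
        n_frames = 400
        frame_t = np.arange(n_frames) / 10.0
        activity = (1.2 + np.sin(frame_t * 1.7))[None, :]
        choice_times = np.array([5.0, 15.0, 25.0])
        durations = np.array([0.6, 0.8, 1.2])
        outcome_times = choice_times + durations
        ns = make_neural(activity, choice_times, outcome_times, rng)
        tensor = time_warp_align(ns, smooth_sd=0.0)
        med = tensor.median_interval
        for i in range(3):
            seg = tensor.values[i, 0, tensor.choice_index:tensor.outcome_index + 1]
            grid_mass = np.trapezoid(seg, dx=1.0 / tensor.fs)
            a, b = choice_times[i], outcome_times[i]
            tt = np.linspace(a, b, 400)
            true_mass = np.trapezoid(np.interp(tt, frame_t, activity[0]), tt)
            assert grid_mass == pytest.approx(true_mass * med / durations[i], rel=0.02)

    def test_outcome_before_choice_rejected(self):
        with pytest.raises(ValueError):
            make_neural(np.zeros((1, 100)), [2.0], [1.5])


class TestCPD:
    @staticmethod
    def _tensor_from_Y(Y, behavior):
        """Wrap a (trials, neurons) matrix as a 1-timepoint tensor."""
        from twostep.neural import TrialTensor
        return TrialTensor(values=Y[:, :, None], fs=20.0, choice_index=0,
                           outcome_index=0, median_interval=0.5, behavior=behavior)

    def test_exact_predictor_gives_cpd_one(self):
        rng = np.random.default_rng(4)
        n = 80
        x1 = rng.choice([-0.5, 0.5], n)
        x2 = rng.choice([-0.5, 0.5], n)
        X = np.column_stack([np.ones(n), x1, x2])
        Y = x1[:, None] * np.ones((1, 3))
        tensor = self._tensor_from_Y(Y, make_behavior(n, rng))
        res = cpd_regression(tensor, X, ("intercept", "x1", "x2"))
        assert res.cpd[0, 0] == pytest.approx(1.0)
        assert res.cpd[1, 0] == pytest.approx(0.0, abs=1e-10)

    def test_noise_gives_small_cpd(self):
        rng = np.random.default_rng(5)
        n = 500
        X = np.column_stack([np.ones(n), rng.choice([-0.5, 0.5], n)])
        Y = rng.standard_normal((n, 4))
        tensor = self._tensor_from_Y(Y, make_behavior(n, rng))
        res = cpd_regression(tensor, X, ("intercept", "x"))
        assert res.cpd[0, 0] < 0.02

    def test_cpd_bounded_unit_interval(self):
        rng = np.random.default_rng(6)
        beh = make_behavior(60, rng)
        X, names = neural_design(beh)
        from twostep.neural import TrialTensor
        V = rng.random((60, 5, 8))
        tensor = TrialTensor(values=V, fs=20.0, choice_index=2, outcome_index=5,
                             median_interval=0.3, behavior=beh)
        res = cpd_regression(tensor, X, names)
        assert (res.cpd >= 0).all() and (res.cpd <= 1).all()
        assert (res.neuron_cpd >= 0).all() and (res.neuron_cpd <= 1).all()

    def test_rank_deficient_design_names_collinear_predictors(self):
        rng = np.random.default_rng(7)
        n = 50
        x = rng.choice([-0.5, 0.5], n)
        X = np.column_stack([np.ones(n), x, x])
        Y = rng.standard_normal((n, 2))
        tensor = self._tensor_from_Y(Y, make_behavior(n, rng))
        with pytest.raises(ValueError, match="collinear"):
            cpd_regression(tensor, X, ("intercept", "a", "b"))


class TestPermutationNull:
    def test_bh_step_up_rule(self):
        sig = benjamini_hochberg(np.array([0.01, 0.02, 0.04]), alpha=0.05)
        assert sig.all()
        sig = benjamini_hochberg(np.array([0.01, 0.5, 0.9]), alpha=0.05)
        assert sig.tolist() == [True, False, False]

    def test_zero_shift_reproduces_true_cpd(self):
        from twostep.neural import _pooled_cpd
        rng = np.random.default_rng(8)
        beh = make_behavior(60, rng)
        X, names = neural_design(beh)
        from twostep.neural import TrialTensor
        tensor = TrialTensor(values=rng.random((60, 4, 6)), fs=20.0,
                             choice_index=1, outcome_index=4,
                             median_interval=0.3, behavior=beh)
        data = [(tensor, X, names)]
        preds = ("choice", "outcome")
        assert _pooled_cpd(data, preds, shifts=[0]) == pytest.approx(
            _pooled_cpd(data, preds))

    def test_cross_session_pooling_needs_a_shared_grid(self):
        """Sessions warped to different medians cannot be pooled; a shared
        median interval puts them on one grid."""
        rng = np.random.default_rng(30)
        beh = generate_behavior_cohort(
            CohortSpec(n_subjects=2, trials_per_session=60), rng)
        spec = NeuralSpec(n_neurons=6, mean_rate=0.5,
                          interval_range=(0.3, 0.9))
        cohort = generate_neural_cohort(beh, spec, rng)
        meds = [float(np.median(ns.outcome_times - ns.choice_times))
                for ns in cohort]
        own = [time_warp_align(ns) for ns in cohort]
        data_own = [(t, *neural_design(t.behavior)) for t in own]
        if own[0].n_timepoints != own[1].n_timepoints:
            with pytest.raises(ValueError, match="shared median_interval"):
                circular_shift_permutation(data_own, predictors=("choice",),
                                           n_perm=2)
        shared = [time_warp_align(ns, median_interval=np.median(meds))
                  for ns in cohort]
        data = [(t, *neural_design(t.behavior)) for t in shared]
        res = circular_shift_permutation(data, predictors=("choice",), n_perm=5,
                                         rng=np.random.default_rng(31))
        assert res.cpd.shape[1] == shared[0].n_timepoints

    def test_planted_tuning_beats_circular_null(self):
        """Second-step tuning planted in a third of neurons produces a CPD
        peak between choice and outcome that clears the permutation null."""
        rng = np.random.default_rng(9)
        beh = generate_behavior_cohort(
            CohortSpec(n_subjects=1, trials_per_session=200), rng)[0]
        spec = NeuralSpec(n_neurons=30, amplitude=1.0, mean_rate=0.5,
                          tuned_fractions={"second_step_pre": 0.33})
        ns = generate_neural_cohort([beh], spec, rng)[0]
        tensor = time_warp_align(ns, log2=True)
        X, names = neural_design(beh)
        res = circular_shift_permutation(
            [(tensor, X, names)], predictors=("second_step", "outcome"),
            n_perm=100, rng=np.random.default_rng(10))
        mid = slice(tensor.choice_index, tensor.outcome_index + 1)
        assert res.significant[0, mid].any()
        peak_t = res.cpd[0].argmax()
        assert tensor.choice_index <= peak_t <= tensor.outcome_index + 3


class TestProjections:
    @staticmethod
    def _tensor_with_weights(w_pre, w_post, rng, n_trials=120, T=20):
        """Neurons encode second step with time-varying population vectors."""
        from twostep.neural import TrialTensor
        beh = make_behavior(n_trials, rng)
        ss = beh.second_step - 0.5
        n_nrn = w_pre.size
        profile_pre = np.exp(-0.5 * ((np.arange(T) - 6) / 2.0) ** 2)
        profile_post = np.exp(-0.5 * ((np.arange(T) - 14) / 2.0) ** 2)
        V = (ss[:, None, None]
             * (w_pre[None, :, None] * profile_pre[None, None, :]
                + w_post[None, :, None] * profile_post[None, None, :])
             + 0.05 * rng.standard_normal((n_trials, n_nrn, T)))
        return TrialTensor(values=V, fs=20.0, choice_index=4, outcome_index=10,
                           median_interval=0.3, behavior=beh), beh

    def test_constant_representation_has_aligned_axes(self):
        rng = np.random.default_rng(11)
        w = rng.standard_normal(25)
        tensor, beh = self._tensor_with_weights(w, w, rng)
        X, names = neural_design(beh)
        res = representation_projection(tensor, X, names, "second_step",
                                        t_ref1=6, t_ref2=14)
        assert abs(res.ref_cosine) > 0.95

    def test_orthogonal_populations_peak_in_sequence(self):
        rng = np.random.default_rng(12)
        w_pre = np.zeros(30)
        w_post = np.zeros(30)
        w_pre[:15] = rng.uniform(0.5, 1.0, 15)
        w_post[15:] = rng.uniform(0.5, 1.0, 15)
        tensor, beh = self._tensor_with_weights(w_pre, w_post, rng)
        X, names = neural_design(beh)
        res = representation_projection(tensor, X, names, "second_step",
                                        t_ref1=6, t_ref2=14)
        assert abs(res.ref_cosine) < 0.2
        assert res.projection_ref1.argmax() < res.projection_ref2.argmax()

    def test_pure_noise_projections_fluctuate_near_zero(self):
        from twostep.neural import TrialTensor
        rng = np.random.default_rng(13)
        beh = make_behavior(150, rng)
        tensor = TrialTensor(values=rng.standard_normal((150, 20, 16)), fs=20.0,
                             choice_index=4, outcome_index=10,
                             median_interval=0.3, behavior=beh)
        X, names = neural_design(beh)
        res = representation_projection(tensor, X, names, "second_step",
                                        t_ref1=6, t_ref2=14)
        assert np.abs(res.projection_ref1).mean() < 0.2


class TestTrialTypePCA:
    def test_identical_types_collapse_to_origin(self):
        from twostep.neural import TrialTensor
        rng = np.random.default_rng(14)
        beh = make_behavior(400, rng)
        V = np.ones((400, 10, 8))
        tensor = TrialTensor(values=V, fs=20.0, choice_index=2, outcome_index=5,
                             median_interval=0.3, behavior=beh)
        res = trial_type_pca(tensor)
        assert np.abs(res.trajectories).max() < 1e-10

    def test_planted_choice_code_loads_on_first_axis(self):
        from twostep.neural import TrialTensor
        rng = np.random.default_rng(15)
        beh = make_behavior(400, rng)
        w = rng.standard_normal(12)
        V = ((beh.choice - 0.5)[:, None, None] * w[None, :, None]
             * np.ones((1, 1, 8)))
        tensor = TrialTensor(values=V, fs=20.0, choice_index=2, outcome_index=5,
                             median_interval=0.3, behavior=beh)
        res = trial_type_pca(tensor)
        assert res.explained_variance_ratio[0] > 0.99
        # trajectories separate by choice along PC1 only
        pc1 = res.trajectories[:, 0, 0]
        types = np.array(res.type_labels)
        assert np.sign(pc1[types[:, 0] == 1]).size == 4

    def test_variance_ratios_sum_to_one(self):
        from twostep.neural import TrialTensor
        rng = np.random.default_rng(16)
        beh = make_behavior(300, rng)
        tensor = TrialTensor(values=rng.standard_normal((300, 6, 5)), fs=20.0,
                             choice_index=1, outcome_index=3,
                             median_interval=0.3, behavior=beh)
        res = trial_type_pca(tensor, n_pc=48)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-8)

    def test_missing_type_rejected(self):
        from twostep.neural import TrialTensor
        rng = np.random.default_rng(17)
        beh = make_behavior(50, rng, outcome=np.ones(50, dtype=np.int8))
        tensor = TrialTensor(values=np.zeros((50, 3, 4)), fs=20.0,
                             choice_index=1, outcome_index=2,
                             median_interval=0.3, behavior=beh)
        with pytest.raises(ValueError, match="not present"):
            trial_type_pca(tensor)


@pytest.fixture(scope="module")
def tuned_tensors():
    """Three sessions of strongly tuned synthetic activity."""
    rng = np.random.default_rng(18)
    beh = generate_behavior_cohort(
        CohortSpec(n_subjects=3, trials_per_session=250,
                   means={"G_mf": 0.01, "G_mb": 0.01, "G_mo": 0.01,
                          "P_c": 0.0, "P_m": 0.0, "B_c": 0.0, "B_r": 0.0}), rng)
    spec = NeuralSpec(n_neurons=45, amplitude=4.0, mean_rate=1.0,
                      tuned_fractions={"choice": 0.2, "second_step_pre": 0.2,
                                       "second_step_post": 0.2,
                                       "outcome_left": 0.2, "outcome_right": 0.2})
    cohort = generate_neural_cohort(beh, spec, rng)
    return [time_warp_align(ns) for ns in cohort]


class TestDecoding:
    def test_tuned_population_decodes_accurately(self, tuned_tensors):
        res = decode_locations(tuned_tensors, rng=np.random.default_rng(19),
                               n_repeats=3)
        assert res.accuracy > 0.9
        assert np.trace(res.confusion) / 10 > 0.85

    def test_confusion_rows_normalised(self, tuned_tensors):
        res = decode_locations(tuned_tensors, rng=np.random.default_rng(20),
                               n_repeats=2)
        assert res.confusion.sum(axis=1) == pytest.approx(np.ones(10))

    def test_shuffled_labels_fall_to_chance(self, tuned_tensors):
        res = decode_locations(tuned_tensors, rng=np.random.default_rng(21),
                               n_repeats=5, shuffle_labels=True)
        assert abs(res.accuracy - 0.1) < 0.08

    def test_sessions_without_coverage_are_dropped(self, tuned_tensors):
        with pytest.raises(ValueError, match="enough visits"):
            decode_locations(tuned_tensors, rng=np.random.default_rng(22),
                             n_repeats=1, n_visits=10_000)
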