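"""Trial selection, class weights, balanced accuracy, nested-CV decoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import balanced_accuracy_score

from icpop import decoding, signals
from icpop.decoding import ConfusionCounts, DecoderConfig

FAST = DecoderConfig(n_search=4, dummy_repeats=30)


def _outcomes_with_level_dprimes(hit_rates, n_per_level=60, n_catch=60, fa=6):
    """Outcome table whose per-level d' rises with the supplied hit rates."""
    rows = []
    for i, hr in enumerate(hit_rates):
        lv = 41.0 + 3 * i
        n_hit = int(round(hr * n_per_level))
        rows += [{"label": "hit", "level_db": lv, "onset_s": 0.0}] * n_hit
        rows += [{"label": "miss", "level_db": lv, "onset_s": 0.0}] * (n_per_level - n_hit)
    rows += [{"label": "false_alarm", "level_db": np.nan, "onset_s": 0.0}] * fa
    rows += [{"label": "correct_rejection", "level_db": np.nan, "onset_s": 0.0}] * (n_catch - fa)
    return pd.DataFrame(rows)


class TestSelectTrials:
    def test_interior_anchor_selects_five_levels(self):
        # d' rises through 1.5 mid-range -> anchor rank 3 of 9, window ranks 1-5
        out = _outcomes_with_level_dprimes([0.3, 0.45, 0.6, 0.8, 0.9, 0.95, 0.97, 0.98, 0.99])
        mask, levels = decoding.select_trials(out)
        assert levels.size == 5
        from icpop.behavior import psychometric

        per = psychometric(out).per_level.set_index("level_db")
        anchor = per[per["dprime"] > 1.5].index.min()
        rank = list(per.index).index(anchor)
        np.testing.assert_allclose(levels, per.index[rank - 2 : rank + 3])
        assert mask.sum() == out["level_db"].isin(levels).sum()

    def test_edge_anchor_truncates_window(self):
        # already above threshold at the lowest level -> only 3 levels exist
        out = _outcomes_with_level_dprimes([0.95, 0.97, 0.99][:3])
        _, levels = decoding.select_trials(out)
        assert levels.size == 3

    def test_no_level_above_threshold_excludes_session(self):
        out = _outcomes_with_level_dprimes([0.2, 0.25, 0.3])
        with pytest.raises(ValueError, match="excluded"):
            decoding.select_trials(out)


class TestSessionGate:
    @pytest.mark.parametrize(
        "n_hit,n_miss,expected",
        [(15, 15, True), (40, 14, False), (14, 40, False), (100, 15, True)],
    )
    def test_fifteen_each_rule(self, n_hit, n_miss, expected):
        assert decoding.session_gate(n_hit, n_miss) is expected


class TestClassWeights:
    def test_balanced_labels_give_unit_weights(self):
        w = decoding.class_weights(np.array([0] * 50 + [1] * 50))
        assert w.weights == {0: 1.0, 1: 1.0}

    def test_printed_formula_80_20(self):
        w = decoding.class_weights(np.array([1] * 80 + [0] * 20))
        assert w.weights[1] == pytest.approx(0.625)
        assert w.weights[0] == pytest.approx(2.5)

    @given(n1=st.integers(1, 200), n0=st.integers(1, 200))
    @settings(max_examples=50, deadline=None)
    def test_conservation_identity(self, n1, n0):
        """Sum of W_i * N_i equals the total trial count."""
        labels = np.array([1] * n1 + [0] * n0)
        w = decoding.class_weights(labels)
        total = sum(w.weights[c] * w.counts[c] for c in w.weights)
        assert total == pytest.approx(w.n_total)

    def test_matches_sklearn_balanced_heuristic(self):
        from sklearn.utils.class_weight import compute_class_weight

        labels = np.array([0] * 30 + [1] * 70)
        w = decoding.class_weights(labels)
        ref = compute_class_weight("balanced", classes=np.array([0, 1]), y=labels)
        np.testing.assert_allclose([w.weights[0], w.weights[1]], ref)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            decoding.class_weights(np.ones(10))


class TestBalancedAccuracy:
    def test_perfect_predictions(self):
        assert decoding.balanced_accuracy(ConfusionCounts(10, 0, 5, 0)) == 1.0

    def test_majority_only_predictor_scores_chance(self):
        # predict hit always on 90/10 data: TPR 1, TNR 0
        assert decoding.balanced_accuracy(ConfusionCounts(90, 0, 0, 10)) == 0.5

    def test_formula_arithmetic(self):
        assert decoding.balanced_accuracy(ConfusionCounts(8, 2, 3, 1)) == pytest.approx(0.775)

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError):
            decoding.balanced_accuracy(ConfusionCounts(5, 5, 0, 0))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_equals_mean_recall_fuzz(self, seed):
        """Identity with the mean of per-class recalls (library oracle)."""
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=40)
        pred = rng.integers(0, 2, size=40)
        if y.all() or not y.any():
            return
        ours = decoding.balanced_accuracy(decoding.confusion_counts(y, pred))
        assert ours == pytest.approx(balanced_accuracy_score(y, pred))


class TestDummyDecoder:
    def test_mean_converges_to_half_on_imbalanced_labels(self):
        labels = np.array([1] * 70 + [0] * 30)
        mean, scores = decoding.dummy_decoder(labels, seed=0, n_repeats=2000)
        assert mean == pytest.approx(0.5, abs=0.02)
        assert scores.size == 2000

    def test_deterministic_given_seed(self):
        labels = np.array([1] * 20 + [0] * 20)
        a, _ = decoding.dummy_decoder(labels, seed=3, n_repeats=50)
        b, _ = decoding.dummy_decoder(labels, seed=3, n_repeats=50)
        assert a == b

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            decoding.dummy_decoder(np.ones(10), seed=0)


class TestFitFrameDecoder:
    def test_separable_signal_scores_high(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 20)
        X = y[:, None] * 2.0 + 0.05 * rng.standard_normal((40, 10))
        scores = decoding.fit_frame_decoder(X, y, cv_seed=0, config=FAST)
        assert scores.mean() >= 0.95

    def test_null_activity_scores_near_chance(self):
        rng = np.random.default_rng(1)
        accs = []
        for r in range(40):
            y = np.array([0, 1] * 20)
            X = rng.standard_normal((40, 30))
            accs.append(decoding.fit_frame_decoder(X, y, cv_seed=r, config=FAST).mean())
        assert 0.45 <= np.mean(accs) <= 0.55

    def test_determinism(self):
        rng = np.random.default_rng(2)
        y = np.array([0, 1] * 15)
        X = rng.standard_normal((30, 8))
        a = decoding.fit_frame_decoder(X, y, cv_seed=5, config=FAST)
        b = decoding.fit_frame_decoder(X, y, cv_seed=5, config=FAST)
        np.testing.assert_array_equal(a, b)

    def test_monotone_in_effect_size(self):
        rng = np.random.default_rng(3)
        means = []
        for effect in (0.0, 0.5, 2.0):
            accs = []
            for r in range(10):
                y = np.array([0, 1] * 20)
                X = effect * y[:, None] + rng.standard_normal((40, 10))
                accs.append(decoding.fit_frame_decoder(X, y, cv_seed=r, config=FAST).mean())
            means.append(np.mean(accs))
        assert means[0] <= means[1] + 0.05 <= means[2] + 0.10
        assert means[2] > means[0]


def _planted_tensor(n_trials=40, n_neurons=12, n_frames=28, fs=28.0, onset=8,
                    pre_amp=0.0, post_amp=1.0, noise=0.3, seed=0):
    """Tiny tensor with outcome information planted pre and/or post onset."""
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n_trials // 2))
    vals = noise * rng.standard_normal((n_trials, n_neurons, n_frames))
    sign = 2 * y - 1
    vals[:, :, :onset] += pre_amp * sign[:, None, None]
    vals[:, :, onset:] += post_amp * sign[:, None, None]
    tensor = signals.TrialTensor(
        values=vals, frame_rate=fs, onset_frame_index=onset,
        trial_indices=np.arange(n_trials),
    )
    return tensor, y


class TestDecodeSession:
    def test_post_only_coding_rises_after_onset(self):
        tensor, y = _planted_tensor(pre_amp=0.0, post_amp=1.0, seed=4)
        res = decoding.decode_session(tensor, y, seed=0, config=FAST)
        pre = res.trained[res.frame_times < 0]
        post = res.trained[res.frame_times >= 0.25]
        assert pre.mean() < 0.65
        assert post.mean() > 0.9

    def test_pre_stimulus_state_decodable_before_onset(self):
        """A planted pre-stimulus state signal yields above-chance decoding
        before the sound arrives."""
        tensor, y = _planted_tensor(pre_amp=1.0, post_amp=1.0, seed=5)
        res = decoding.decode_session(tensor, y, seed=0, config=FAST)
        pre = res.trained[res.frame_times < 0]
        assert pre.mean() > 0.8
        assert np.all(res.dummy > 0.3) and np.all(res.dummy < 0.7)

    def test_zero_variance_activity_stays_at_chance(self):
        tensor, y = _planted_tensor(pre_amp=0.0, post_amp=0.0, noise=0.0, seed=6)
        tensor.values[:] = 1.0
        res = decoding.decode_session(tensor, y, seed=0, config=FAST)
        assert np.all(np.abs(res.trained - 0.5) < 0.2)

    def test_gate_enforced(self):
        tensor, y = _planted_tensor(n_trials=20, seed=7)
        with pytest.raises(ValueError, match="gate"):
            decoding.decode_session(tensor, y, seed=0, config=FAST)


class TestInterpolateTimecourse:
    def test_identity_at_same_length(self):
        x = np.random.default_rng(0).random(50)
        np.testing.assert_array_equal(decoding.interpolate_timecourse(x, 50), x)

    def test_constant_series_unchanged_197_to_193(self):
        y = decoding.interpolate_timecourse(np.full(197, 0.7), 193)
        np.testing.assert_allclose(y, 0.7)

    def test_linear_ramp_stays_linear(self):
        x = np.linspace(0, 1, 197)
        y = decoding.interpolate_timecourse(x, 193)
        np.testing.assert_allclose(y, np.linspace(0, 1, 193), atol=1e-12)

    def test_short_target_rejected(self):
        with pytest.raises(ValueError):
            decoding.interpolate_timecourse(np.ones(10), 1)


def _fake_result(n_rois, acc, n_frames=14):
    return decoding.DecodingResult(
        frame_times=np.linspace(-2, 5, n_frames),
        trained=np.full(n_frames, acc),
        trained_folds=np.full((n_frames, 5), acc),
        dummy=np.full(n_frames, 0.5),
        n_rois=n_rois,
        n_hit=20,
        n_miss=20,
    )


class TestRoiCountCorrelation:
    def test_constant_accuracy_flagged(self):
        results = [_fake_result(n, 0.7) for n in (10, 20, 30, 40)]
        tab = decoding.roi_count_correlation(results)
        assert tab["constant"].all()
        assert tab["rho"].isna().all()

    def test_monotone_accuracy_gives_rho_one(self):
        results = [_fake_result(n, 0.5 + n / 200) for n in (10, 20, 30, 40)]
        tab = decoding.roi_count_correlation(results)
        assert not tab["constant"].any()
        np.testing.assert_allclose(tab["rho"], 1.0)

    def test_random_pairing_centred_at_zero(self):
        rng = np.random.default_rng(8)
        rhos = []
        for _ in range(200):
            results = [_fake_result(int(n), float(a)) for n, a in
                       zip(rng.integers(5, 100, 8), rng.random(8))]
            tab = decoding.roi_count_correlation(results)
            rhos.append(tab["rho"].iloc[0])
        assert abs(np.mean(rhos)) < 0.1

    def test_too_few_sessions_rejected(self):
        with pytest.raises(ValueError):
            decoding.roi_count_correlation([_fake_result(5, 0.5)] * 3)


class TestControls:
    def test_subsample_all_neurons_equals_full_decode(self):
        tensor, y = _planted_tensor(n_frames=8, onset=4, seed=9)
        full = decoding.decode_session(tensor, y, seed=11, config=FAST)
        sub = decoding.subsample_neurons_control(
            tensor, y, target_n=tensor.n_neurons, n_draws=2, seed=11, config=FAST
        )
        np.testing.assert_allclose(sub, full.trained)

    def test_subsample_determinism_and_bounds(self):
        tensor, y = _planted_tensor(n_frames=8, onset=4, seed=10)
        a = decoding.subsample_neurons_control(tensor, y, 4, n_draws=2, seed=3, config=FAST)
        b = decoding.subsample_neurons_control(tensor, y, 4, n_draws=2, seed=3, config=FAST)
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            decoding.subsample_neurons_control(tensor, y, 1, seed=0)
        with pytest.raises(ValueError):
            decoding.subsample_neurons_control(tensor, y, 99, seed=0)

    def test_level_matched_control_identity_when_balanced(self):
        tensor, y = _planted_tensor(n_frames=8, onset=4, seed=12)
        outcomes = pd.DataFrame(
            {
                "label": np.where(y == 1, "hit", "miss"),
                "level_db": np.tile([50.0, 50.0, 56.0, 56.0], len(y) // 4),
            }
        )
        res = decoding.level_matched_control(tensor, outcomes, y, seed=0, config=FAST)
        assert res is not None
        assert res.n_hit == res.n_miss == y.sum()

    def test_level_confounded_signal_removed(self):
        """A neuron coding sound level only: once levels are fully confounded
        with outcome, matching removes those trials and the control skips
        (gate fails) rather than reporting spurious accuracy."""
        tensor, y = _planted_tensor(seed=13)
        outcomes = pd.DataFrame(
            {
                "label": np.where(y == 1, "hit", "miss"),
                "level_db": np.where(y == 1, 62.0, 44.0),  # fully confounded
            }
        )
        with pytest.raises(ValueError):
            # no level carries both outcomes -> balanced subsample impossible
            decoding.level_matched_control(tensor, outcomes, y, seed=0, config=FAST)
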