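"""Cascade structure, period arithmetic, causality, and training harness."""

import numpy as np
import pytest

from sonostage.features import N_FEATURES
from sonostage.simulator import SimConfig, simulate_hypnogram
from sonostage.staging import (
    OFFLINE_CASCADE_SPEC,
    REALTIME_CASCADE_SPEC,
    CascadeTrainingError,
    StagingTrainConfig,
    build_offline_input,
    build_realtime_input,
    scores_to_label,
    select_period_offline,
    select_period_realtime,
    stages_to_ints,
    train_cascades,
)

STAGE_SHIFT = {"W": 0.0, "R": 1.5, "N": 3.0}


def fake_night(seed, T=230, hyp=None):
    """Synthetic feature matrix with a stage-dependent mean shift: cheap,
    linearly separable stand-in for pipeline features in harness tests."""
    rng = np.random.default_rng(seed)
    if hyp is None:
        hyp = simulate_hypnogram(SimConfig(seed=seed, night_epochs=T))
    X = rng.normal(size=(len(hyp), N_FEATURES))
    X += np.array([[STAGE_SHIFT[s]] for s in hyp])
    return X, np.asarray(hyp, dtype="<U1")


FAST = StagingTrainConfig(seed=0, hidden_scale=0.05, min_hidden=4,
                          max_iter=40, batch_size=256, lr=1e-2, patience=8)


@pytest.fixture(scope="module")
def trained():
    nights = [fake_night(s) for s in range(6)]
    rt, off, rep = train_cascades(nights, FAST)
    return nights, rt, off, rep


class TestStructure:
    def test_realtime_period_boundaries(self):
        assert select_period_realtime(5) == 1
        assert select_period_realtime(6) == 2
        assert select_period_realtime(20) == 2
        assert select_period_realtime(21) == 3
        assert select_period_realtime(50) == 3
        assert select_period_realtime(51) == 4
        assert select_period_realtime(100) == 4
        assert select_period_realtime(101) == 5
        assert select_period_realtime(200) == 5
        assert select_period_realtime(201) == 6
        with pytest.raises(ValueError):
            select_period_realtime(0)

    def test_cascade_constants_match_design(self):
        """Configuration self-test: lookback/lookahead windows and hidden
        unit counts of all six periods in both cascades."""
        assert [(s.window, s.hidden) for s in REALTIME_CASCADE_SPEC] == [
            (0, 0), (5, 100), (20, 400), (50, 1000), (100, 1000), (200, 1000)]
        assert [(s.window, s.hidden) for s in OFFLINE_CASCADE_SPEC] == [
            (0, 0), (5, 20), (20, 50), (50, 100), (100, 200), (200, 200)]

    def test_offline_period_boundaries(self):
        T = 100
        assert select_period_offline(98, T) == 1      # T-5 <= t
        assert select_period_offline(95, T) == 1
        assert select_period_offline(80, T) == 2      # lookahead 5
        assert select_period_offline(40, T) == 4      # lookahead 50
        T = 300
        assert select_period_offline(299, T) == 1
        assert select_period_offline(294, T) == 2
        assert select_period_offline(99, T) == 6
        with pytest.raises(ValueError):
            select_period_offline(0, 10)

    def test_offline_window_always_fits(self):
        """First-match period selection guarantees t + lookahead <= T."""
        for T in (6, 10, 30, 55, 120, 201, 500):
            for t in range(1, T + 1):
                p = select_period_offline(t, T)
                assert t + OFFLINE_CASCADE_SPEC[p - 1].window <= T
        for t in range(1, 500):
            p = select_period_realtime(t)
            assert t - REALTIME_CASCADE_SPEC[p - 1].window >= 1 or p == 1


class TestInputs:
    def test_lookback_lengths(self):
        X = np.arange(300 * N_FEATURES, dtype=float).reshape(300, N_FEATURES)
        assert build_realtime_input(X, 6, 5).shape == (67 * 6,)
        assert build_realtime_input(X, 201, 200).shape == (13_467,)
        with pytest.raises(ValueError):
            build_realtime_input(X, 5, 5)

    def test_lookback_ignores_future(self):
        X = np.random.default_rng(0).normal(size=(50, N_FEATURES))
        v1 = build_realtime_input(X, 21, 20)
        X2 = X.copy()
        X2[21:] = 999.0
        np.testing.assert_array_equal(v1, build_realtime_input(X2, 21, 20))

    def test_offline_input_includes_t(self):
        rt = np.random.default_rng(1).dirichlet([1, 1, 1], size=100)
        v = build_offline_input(rt, 40, 50)
        assert v.shape == (3 * 51 + 1,)
        assert v[-1] == 40.0


class TestScoresToLabel:
    @pytest.mark.parametrize("scores,label", [
        ((1.0, 0.0, 0.0), "W"),
        ((0.2, 0.3, 0.5), "N"),
        ((0.4, 0.4, 0.2), "R"),      # tie broken by N > R > W priority
        ((0.4, 0.2, 0.4), "N"),
    ])
    def test_argmax_and_ties(self, scores, label):
        assert scores_to_label(np.array(scores)) == label


class TestTrainedCascades:
    def test_first_five_epochs_are_wake(self, trained):
        nights, rt, off, _ = trained
        scores = rt.scores_for_night(nights[0][0])
        np.testing.assert_array_equal(scores[:5],
                                      np.tile([1.0, 0.0, 0.0], (5, 1)))

    def test_scores_normalized(self, trained):
        nights, rt, off, _ = trained
        scores = rt.scores_for_night(nights[0][0])
        assert np.allclose(scores.sum(axis=1), 1.0, atol=1e-6)

    def test_realtime_causality_under_future_mutation(self, trained):
        nights, rt, _, _ = trained
        X = nights[0][0]
        rng = np.random.default_rng(7)
        for t in (3, 8, 30, 120, 210):
            base = rt.classify_epoch(X, t)
            X_mut = X.copy()
            X_mut[t:] = rng.normal(size=X_mut[t:].shape)
            np.testing.assert_array_equal(base, rt.classify_epoch(X_mut, t))

    def test_offline_last_five_passthrough(self, trained):
        nights, rt, off, _ = trained
        rt_scores = rt.scores_for_night(nights[0][0])
        off_scores = off.scores_for_night(rt_scores)
        np.testing.assert_array_equal(off_scores[-5:], rt_scores[-5:])

    def test_offline_short_night_is_identity(self, trained):
        _, _, off, _ = trained
        rt_scores = np.random.default_rng(3).dirichlet([1, 1, 1], size=5)
        np.testing.assert_array_equal(off.scores_for_night(rt_scores), rt_scores)

    def test_learns_separable_stages(self, trained):
        nights, rt, off, rep = trained
        assert rep.dev_accuracy_realtime >= 0.75
        assert rep.dev_accuracy_offline >= 0.75

    def test_determinism(self):
        nights = [fake_night(s) for s in range(6)]
        rt1, _, _ = train_cascades(nights, FAST)
        rt2, _, _ = train_cascades(nights, FAST)
        for p in rt1.subs:
            np.testing.assert_array_equal(rt1.subs[p].net.W1, rt2.subs[p].net.W1)
            np.testing.assert_array_equal(rt1.subs[p].net.W2, rt2.subs[p].net.W2)


class TestTrainingErrors:
    def test_too_few_nights(self):
        with pytest.raises(ValueError, match="5"):
            train_cascades([fake_night(0)] * 3, FAST)

    def test_missing_class(self):
        nights = []
        for s in range(6):
            X, hyp = fake_night(s)
            hyp = np.where(hyp == "R", "N", hyp)     # remove REM everywhere
            nights.append((X, hyp))
        with pytest.raises(ValueError, match="R"):
            train_cascades(nights, FAST)

    def test_short_nights_name_untrainable_period(self):
        hyp = ["W"] * 10 + ["N"] * 100 + ["R"] * 30 + ["W"] * 10   # 150 epochs
        nights = [fake_night(s, hyp=hyp) for s in range(6)]
        with pytest.raises(CascadeTrainingError, match="period 6"):
            train_cascades(nights, FAST)


def test_stage_int_roundtrip():
    assert stages_to_ints(["W", "R", "N"]).tolist() == [0, 1, 2]
    with pytest.raises(ValueError):
        stages_to_ints(["W", "X"])
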