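"""PC-NMF: folding, training, prediction, reconstruction, evaluation."""

import numpy as np
import pytest
from scipy.optimize import nnls

from soundscapeir import pcnmf
from soundscapeir.pcnmf import (
    FoldedLTSA,
    evaluate_detection,
    fold,
    periodicity_matrix,
    training_days,
    unfold,
)


class TestFolding:
    def test_unit_patch_is_identity(self, rng):
        X = rng.random((5, 9))
        folded = fold(X, 1)
        np.testing.assert_array_equal(folded.V, X)
        np.testing.assert_array_equal(unfold(folded), X)

    def test_hand_checked_indices_with_padding(self):
        # F=4 bins, T=7 frames, B=3 -> 3 columns of length 12, last patch
        # carries two zero frames
        X = np.arange(28, dtype=float).reshape(4, 7)
        folded = fold(X, 3)
        assert folded.V.shape == (12, 3)
        # first patch: frames 0,1,2 frequency-major
        np.testing.assert_array_equal(folded.V[:, 0], X[:, :3].reshape(-1, order="F"))
        # last patch: frame 6 then zero padding
        np.testing.assert_array_equal(folded.V[:4, 2], X[:, 6])
        assert np.all(folded.V[4:, 2] == 0)

    def test_round_trip_discards_padding(self, rng):
        X = rng.random((6, 17))
        np.testing.assert_array_equal(unfold(fold(X, 5)), X)

    def test_invalid_patch_length_rejected(self, rng):
        with pytest.raises(ValueError):
            fold(rng.random((3, 6)), 0)


class TestTraining:
    def test_objective_monotone_nonincreasing(self, separation):
        trace = separation["model"].objective_trace
        assert np.all(np.diff(trace) <= 1e-9 * trace[0])

    def test_same_seed_reproduces_model(self, scene):
        _, grid, _ = scene
        folded = fold(grid, 30)
        kw = dict(n_features=6, n_sources=3, iterations=30, seed=5)
        m1 = pcnmf.train(folded, **kw)
        m2 = pcnmf.train(folded, **kw)
        np.testing.assert_array_equal(m1.W, m2.W)
        np.testing.assert_array_equal(m1.Hs, m2.Hs)
        np.testing.assert_array_equal(m1.assignment, m2.assignment)

    def test_dictionary_columns_unit_norm_sparse(self, separation):
        W = separation["model"].W
        np.testing.assert_allclose(np.linalg.norm(W, axis=0), 1.0, atol=1e-9)
        for col in W.T:
            assert pcnmf.sparseness(col) == pytest.approx(0.5, abs=1e-6)

    def test_features_with_distinct_periods_get_distinct_sources(self):
        """Two planted features with 24 h vs 12 h activation periods are
        grouped into different sources by the periodicity layer."""
        rng = np.random.default_rng(0)
        T = 480  # patches of 15 min over 5 days
        t = np.arange(T) / 96.0  # days
        h1 = 1.0 + np.sin(2 * np.pi * t)  # 24 h
        h2 = 1.0 + np.sin(2 * np.pi * 2 * t)  # 12 h
        W_true = np.zeros((40, 2))
        W_true[5:15, 0] = 1.0
        W_true[25:35, 1] = 1.0
        V = W_true @ np.stack([h1, h2]) + 0.01 * rng.random((40, T))
        folded = FoldedLTSA(V=V, n_freq=40, frames_per_patch=1, n_frames=T)
        model = pcnmf.train(folded, n_features=2, n_sources=2, iterations=150, seed=1)
        assert model.assignment[0] != model.assignment[1]

    def test_all_zero_input_rejected(self):
        folded = FoldedLTSA(V=np.zeros((8, 10)), n_freq=8, frames_per_patch=1, n_frames=10)
        with pytest.raises(ValueError, match="all-zero"):
            pcnmf.train(folded, n_features=2, n_sources=2, iterations=5)

    def test_overcomplete_factorization_warns(self, rng):
        folded = FoldedLTSA(
            V=rng.random((6, 8)), n_freq=6, frames_per_patch=1, n_frames=8
        )
        with pytest.warns(UserWarning, match="overcomplete"):
            pcnmf.train(folded, n_features=10, n_sources=2, iterations=5, seed=0)


class TestPeriodicity:
    def test_columns_are_unit_sum_without_dc(self, rng):
        H = rng.random((4, 64))
        Q = periodicity_matrix(H)
        assert Q.shape == (32, 4)
        np.testing.assert_allclose(Q.sum(axis=0), 1.0)

    def test_scale_invariant(self, rng):
        H = rng.random((3, 50))
        np.testing.assert_allclose(
            periodicity_matrix(H), periodicity_matrix(7.3 * H), atol=1e-12
        )


class TestIndicatorAdjustment:
    def test_empty_overrides_keep_assignment(self, separation):
        model = separation["model"]
        adjusted = pcnmf.adjust_indicators(model, {})
        np.testing.assert_array_equal(
            adjusted.effective_assignment(), model.effective_assignment()
        )

    def test_override_moves_feature_channel(self, separation):
        model, folded, H = separation["model"], separation["folded"], separation["H"]
        feat = 0
        target = (model.assignment[feat] + 1) % model.n_sources
        adjusted = pcnmf.adjust_indicators(model, {feat: int(target)})
        assert adjusted.effective_assignment()[feat] == target
        assert model.assignment[feat] == adjusted.assignment[feat]  # audit retained

    def test_all_features_to_one_source_reconstructs_everything(self, separation):
        model, folded, H = separation["model"], separation["folded"], separation["H"]
        merged = pcnmf.adjust_indicators(
            model, {a: 1 for a in range(model.n_features)}
        )
        with pytest.warns(UserWarning, match="no assigned features"):
            sep = pcnmf.reconstruct(merged, folded, H)
        V = unfold(folded)
        WH = unfold(folded, model.W @ H)
        support = WH > 1e-12 * WH.max()
        np.testing.assert_allclose(sep.grids[1][support], V[support], rtol=1e-9)
        assert np.all(sep.grids[0] == 0)
        assert np.all(sep.grids[2] == 0)

    def test_unknown_ids_rejected(self, separation):
        with pytest.raises(ValueError, match="feature"):
            pcnmf.adjust_indicators(separation["model"], {999: 0})
        with pytest.raises(ValueError, match="source"):
            pcnmf.adjust_indicators(separation["model"], {0: 99})


class TestPrediction:
    def test_dictionary_column_input_activates_its_feature(self, separation):
        """Presenting one dictionary atom as the input concentrates the
        activation on that feature, matching a nonnegative-least-squares
        oracle on the same column."""
        model = separation["model"]
        j = 3
        V = model.W[:, [j]] * 5.0
        folded = FoldedLTSA(
            V=V, n_freq=model.n_freq, frames_per_patch=model.frames_per_patch,
            n_frames=model.frames_per_patch,
        )
        H = pcnmf.predict_activations(model, folded, iterations=500, seed=0)
        assert np.argmax(H[:, 0]) == j
        h_oracle, _ = nnls(model.W, V[:, 0])
        assert np.argmax(h_oracle) == j
        np.testing.assert_allclose(H[:, 0], h_oracle, atol=1e-3 * h_oracle.max())

    def test_zero_column_gives_zero_activations(self, separation):
        model = separation["model"]
        V = np.zeros((model.W.shape[0], 3))
        V[:, 1] = model.W[:, 0]
        folded = FoldedLTSA(
            V=V, n_freq=model.n_freq, frames_per_patch=model.frames_per_patch,
            n_frames=3 * model.frames_per_patch,
        )
        H = pcnmf.predict_activations(model, folded, iterations=100, seed=0)
        assert np.all(H[:, 0] == 0)
        assert np.all(H[:, 2] == 0)

    def test_repeated_columns_get_identical_activations(self, separation):
        model = separation["model"]
        col = separation["folded"].V[:, [5]]
        V = np.repeat(col, 4, axis=1)
        folded = FoldedLTSA(
            V=V, n_freq=model.n_freq, frames_per_patch=model.frames_per_patch,
            n_frames=4 * model.frames_per_patch,
        )
        H = pcnmf.predict_activations(model, folded, iterations=400, seed=1)
        spread = np.abs(H - H[:, [0]]).max()
        assert spread <= 1e-6 * max(H.max(), 1e-30)

    def test_objective_monotone(self, separation):
        model, folded = separation["model"], separation["folded"]
        _, trace = pcnmf.predict_activations(
            model, folded, iterations=80, seed=2, return_trace=True
        )
        assert np.all(np.diff(trace) <= 1e-9 * trace[0])

    def test_dimension_mismatch_names_both_shapes(self, separation):
        model = separation["model"]
        folded = FoldedLTSA(V=np.ones((4, 2)), n_freq=4, frames_per_patch=1, n_frames=2)
        with pytest.raises(ValueError, match=r"\(4, 2\)"):
            pcnmf.predict_activations(model, folded)


class TestReconstruction:
    def test_mask_conservation(self, separation):
        model, folded, H, sep = (
            separation["model"], separation["folded"], separation["H"], separation["sep"],
        )
        V = unfold(folded)
        WH = unfold(folded, model.W @ H)
        support = WH > 1e-12 * WH.max()
        total = np.sum(sep.grids, axis=0)
        np.testing.assert_allclose(total[support], V[support], rtol=1e-6)

    def test_zero_input_cells_stay_zero(self, separation):
        V = unfold(separation["folded"])
        total = np.sum(separation["sep"].grids, axis=0)
        assert np.all(total[V == 0] == 0)

    def test_channels_nonnegative(self, separation):
        for g in separation["sep"].grids:
            assert np.all(g >= 0)

    def test_scale_invariance(self, scene):
        """Scaling the grid by c scales every reconstructed channel by c."""
        _, grid, _ = scene
        c = 37.0
        folded = fold(grid.Pw, 30)
        scaled = fold(grid.Pw * c, 30)
        kw = dict(n_features=6, n_sources=3, iterations=40, seed=11)
        m1 = pcnmf.train(folded, **kw)
        m2 = pcnmf.train(scaled, **kw)
        H1 = pcnmf.predict_activations(m1, folded, iterations=40, seed=12)
        H2 = pcnmf.predict_activations(m2, scaled, iterations=40, seed=12)
        s1 = pcnmf.reconstruct(m1, folded, H1)
        s2 = pcnmf.reconstruct(m2, scaled, H2)
        for g1, g2 in zip(s1.grids, s2.grids):
            np.testing.assert_allclose(g2, c * g1, rtol=1e-6, atol=1e-8 * c)

    def test_source_separation_recovers_band_energy(self, separation):
        """On a scene with partially disjoint bands each channel's energy
        lands mostly in frames where its matched source is active."""
        truth, sep = separation["truth"], separation["sep"]
        match = pcnmf.match_channels(sep, truth.intensities)
        for i, name in enumerate(truth.source_names):
            purity = pcnmf.channel_purity(sep.grids[match[i]], truth.labels[:, i])
            assert purity > 0.5, f"{name} channel purity {purity:.2f}"


class TestDetectionEvaluation:
    def test_perfect_separation_reaches_full_tpr(self):
        truth = np.array([0, 0, 0, 1, 1, 1, 0, 1], dtype=bool)
        score = truth.astype(float)
        tpr, thr = evaluate_detection(score, truth, fpr=0.01)
        assert tpr == 1.0
        assert thr > 0

    def test_random_score_sits_at_chance_level(self):
        rng = np.random.default_rng(0)
        truth = rng.random(20000) < 0.5
        score = rng.random(20000)
        tpr, _ = evaluate_detection(score, truth, fpr=0.05)
        assert tpr == pytest.approx(0.05, abs=0.02)

    def test_matches_exhaustive_threshold_enumeration(self):
        score = np.array([0.1, 0.8, 0.35, 0.7, 0.2, 0.9, 0.55, 0.4, 0.65, 0.05])
        truth = np.array([0, 1, 0, 1, 0, 1, 1, 0, 0, 0], dtype=bool)
        fpr_cap = 0.2
        best_tpr = 0.0
        for thr in np.unique(score):
            pred = score >= thr
            fp = (pred & ~truth).sum() / (~truth).sum()
            tp = (pred & truth).sum() / truth.sum()
            if fp <= fpr_cap:
                best_tpr = max(best_tpr, tp)
        tpr, _ = evaluate_detection(score, truth, fpr=fpr_cap)
        assert tpr == pytest.approx(best_tpr)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            evaluate_detection(np.arange(5.0), np.ones(5, dtype=bool))


class TestHelpers:
    def test_first_day_of_month_selector(self):
        days = training_days("2011-11", 12)
        assert len(days) == 12
        assert days[0] == np.datetime64("2011-11-01")
        assert days[-1] == np.datetime64("2012-10-01")

    def test_model_archive_round_trip(self, separation, tmp_path):
        model = pcnmf.adjust_indicators(separation["model"], {2: 0})
        path = tmp_path / "model.npz"
        pcnmf.save_model(path, model)
        loaded = pcnmf.load_model(path)
        np.testing.assert_array_equal(loaded.W, model.W)
        np.testing.assert_array_equal(loaded.assignment, model.assignment)
        assert loaded.overrides == model.overrides
        assert loaded.frames_per_patch == model.frames_per_patch
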