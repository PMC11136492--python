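"""Diagonal-Gaussian decoding, cross-validation, permutation inference."""

import numpy as np
import pytest

from driftdecode.design import ConditionLabel
from driftdecode.glm import BetaMatrix
from driftdecode.decode import (
    fit_diag_gaussian,
    illusion_decoding,
    loro_cv,
    path_decoding,
    permutation_null,
    permute_labels_within_runs,
    select_top_r2,
    zscore_features,
)

C = ConditionLabel


def make_betas(betas, condition, run_id, r2=None):
    """BetaMatrix with uniform per-run R² bookkeeping unless given."""
    betas = np.asarray(betas, float)
    run_id = np.asarray(run_id)
    runs = np.unique(run_id)
    m = betas.shape[0]
    if r2 is None:
        ss_res = np.ones((m, runs.size))
        ss_tot = 2 * np.ones((m, runs.size))
    else:
        r2 = np.asarray(r2, float)
        ss_tot = np.ones((m, runs.size))
        ss_res = np.tile((1 - r2)[:, None], (1, runs.size))
    return BetaMatrix(
        betas=betas,
        condition=np.array(condition, dtype=object),
        run_id=run_id,
        ss_res=ss_res,
        ss_tot=ss_tot,
        run_ids=runs,
    )


def synthetic_pair_betas(
    n_runs=6, per_class=4, n_vox=20, sep=0.0, noise_sd=1.0, seed=0,
    pair=(C.LEFT_ILLUSION, C.RIGHT_ILLUSION),
):
    """Gaussian two-class beta matrix; `sep` scales a fixed pattern."""
    rng = np.random.default_rng(seed)
    pattern = rng.normal(0, 1, n_vox)
    cols, labels, runs = [], [], []
    for r in range(n_runs):
        for c, cond in enumerate(pair):
            for _ in range(per_class):
                sign = 1 if c == 0 else -1
                cols.append(sign * sep * pattern + rng.normal(0, noise_sd, n_vox))
                labels.append(cond)
                runs.append(r)
    return make_betas(np.array(cols).T, labels, np.array(runs))


class TestVoxelSelection:
    def test_percentile_with_ties_to_higher(self):
        bm = make_betas(
            np.zeros((4, 8)),
            [C.LEFT_ILLUSION, C.RIGHT_ILLUSION] * 4,
            np.repeat([0, 1], 4),
            r2=[0.1, 0.2, 0.3, 0.4],
        )
        np.testing.assert_array_equal(select_top_r2(bm), [2, 3])

    def test_all_equal_r2_keeps_everything(self):
        bm = make_betas(
            np.zeros((5, 8)),
            [C.LEFT_ILLUSION, C.RIGHT_ILLUSION] * 4,
            np.repeat([0, 1], 4),
            r2=[0.3] * 5,
        )
        assert select_top_r2(bm).size == 5

    def test_training_fold_selection_differs_from_whole_session(self):
        """Fold-restricted R² avoids using the held-out run, so on noisy
        data the selected voxel sets differ."""
        rng = np.random.default_rng(3)
        m, runs = 30, np.repeat(np.arange(4), 8)
        ss_res = rng.uniform(0.2, 1.0, size=(m, 4))
        ss_tot = np.ones((m, 4))
        bm = BetaMatrix(
            betas=np.zeros((m, 32)),
            condition=np.array([C.LEFT_ILLUSION, C.RIGHT_ILLUSION] * 16, dtype=object),
            run_id=runs,
            ss_res=ss_res,
            ss_tot=ss_tot,
            run_ids=np.arange(4),
        )
        whole = set(select_top_r2(bm))
        fold = set(select_top_r2(bm, fit_runs=[0, 1, 2]))
        assert whole != fold

    def test_invalid_percentile(self):
        bm = synthetic_pair_betas()
        with pytest.raises(ValueError):
            select_top_r2(bm, percentile=0)


class TestZscore:
    def test_two_point_column(self):
        train = np.array([[1.0], [3.0]])
        tr, te = zscore_features(train, np.array([[2.0]]))
        np.testing.assert_allclose(tr.ravel(), [-0.70710678, 0.70710678])
        np.testing.assert_allclose(te.ravel(), [0.0])

    def test_test_set_uses_train_statistics(self):
        train = np.array([[0.0], [2.0]])
        _, te = zscore_features(train, np.array([[4.0]]))
        # (4 - 1) / sqrt(2), not z-scored by its own stats
        np.testing.assert_allclose(te.ravel(), [3 / np.sqrt(2)])

    def test_train_columns_standardized(self):
        rng = np.random.default_rng(0)
        train = rng.normal(2, 5, size=(20, 7))
        tr, _ = zscore_features(train, train[:2])
        np.testing.assert_allclose(tr.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(tr.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_zero_sd_feature_dropped_with_warning(self):
        train = np.column_stack([np.ones(4), np.arange(4.0)])
        with pytest.warns(UserWarning, match="zero training SD"):
            tr, te = zscore_features(train, train[:1])
        assert tr.shape[1] == 1 and te.shape[1] == 1


class TestDiagGaussian:
    def test_symmetric_boundary_at_zero(self):
        train = np.array([[-1.0], [-1.2], [1.0], [1.2]])
        labels = [C.LEFT_ILLUSION] * 2 + [C.RIGHT_ILLUSION] * 2
        model = fit_diag_gaussian(train, labels)
        assert model.predict(np.array([[-0.1]]))[0] == C.LEFT_ILLUSION
        assert model.predict(np.array([[0.1]]))[0] == C.RIGHT_ILLUSION

    def test_log_ratio_matches_density_oracle(self):
        """The linear discriminant score equals the difference of diagonal
        Gaussian log-densities evaluated directly."""
        from scipy.stats import norm

        rng = np.random.default_rng(1)
        train = rng.normal(size=(40, 6))
        labels = [C.LEFT_ILLUSION, C.NO_ILLUSION] * 20
        model = fit_diag_gaussian(train, labels)
        X = rng.normal(size=(10, 6))
        sd = np.sqrt(model.pooled_var)
        direct = norm.logpdf(X, model.class_means[0], sd).sum(axis=1) - norm.logpdf(
            X, model.class_means[1], sd
        ).sum(axis=1)
        np.testing.assert_allclose(model.log_ratio(X), direct, atol=1e-10)

    def test_duplicated_features_leave_predictions_unchanged(self):
        rng = np.random.default_rng(2)
        train = rng.normal(size=(30, 5)) + np.repeat([[0.5], [-0.5]], 15, axis=0)
        labels = [C.LEFT_ILLUSION] * 15 + [C.RIGHT_ILLUSION] * 15
        X = rng.normal(size=(20, 5))
        base = fit_diag_gaussian(train, labels).predict(X)
        dup = fit_diag_gaussian(np.hstack([train, train]), labels).predict(
            np.hstack([X, X])
        )
        np.testing.assert_array_equal(base, dup)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            fit_diag_gaussian(np.zeros((4, 2)), [C.LEFT_ILLUSION] * 4)


class TestLoroCv:
    def test_perfectly_separable_gives_one(self):
        bm = synthetic_pair_betas(sep=50.0, noise_sd=0.1, seed=4)
        assert loro_cv(bm, (C.LEFT_ILLUSION, C.RIGHT_ILLUSION)) == 1.0

    def test_null_centered_at_chance(self):
        accs = [
            loro_cv(
                synthetic_pair_betas(sep=0.0, seed=s),
                (C.LEFT_ILLUSION, C.RIGHT_ILLUSION),
            )
            for s in range(40)
        ]
        assert np.mean(accs) == pytest.approx(0.5, abs=0.03)

    def test_label_swap_symmetry(self):
        bm = synthetic_pair_betas(sep=1.0, seed=5)
        acc = loro_cv(bm, (C.LEFT_ILLUSION, C.RIGHT_ILLUSION))
        swapped = BetaMatrix(
            betas=bm.betas,
            condition=np.array(
                [
                    C.RIGHT_ILLUSION if c is C.LEFT_ILLUSION else C.LEFT_ILLUSION
                    for c in bm.condition
                ],
                dtype=object,
            ),
            run_id=bm.run_id,
            ss_res=bm.ss_res,
            ss_tot=bm.ss_tot,
            run_ids=bm.run_ids,
        )
        assert loro_cv(swapped, (C.LEFT_ILLUSION, C.RIGHT_ILLUSION)) == acc

    def test_affine_feature_rescaling_invariance(self):
        """Per-feature affine transforms are absorbed by train-fold
        z-scoring, leaving accuracy unchanged."""
        bm = synthetic_pair_betas(sep=0.8, seed=6)
        acc = loro_cv(bm, (C.LEFT_ILLUSION, C.RIGHT_ILLUSION))
        scales = np.linspace(0.1, 30, bm.n_voxels)[:, None]
        offsets = np.linspace(-5, 7, bm.n_voxels)[:, None]
        rescaled = BetaMatrix(
            betas=bm.betas * scales + offsets,
            condition=bm.condition,
            run_id=bm.run_id,
            ss_res=bm.ss_res,
            ss_tot=bm.ss_tot,
            run_ids=bm.run_ids,
        )
        assert loro_cv(rescaled, (C.LEFT_ILLUSION, C.RIGHT_ILLUSION)) == acc

    def test_no_information_flows_from_test_fold(self, monkeypatch):
        """Every fold's training set excludes exactly the held-out run's
        blocks, and fold-wise voxel selection never sees the held-out
        run's fit statistics."""
        import driftdecode.decode as dec

        bm = synthetic_pair_betas(n_runs=4, sep=0.5, seed=7)
        pair = (C.LEFT_ILLUSION, C.RIGHT_ILLUSION)
        fit_calls, select_calls = [], []

        real_fit = dec.fit_diag_gaussian
        real_select = dec.select_top_r2

        def spy_fit(train, labels):
            fit_calls.append(train.shape[0])
            return real_fit(train, labels)

        def spy_select(betas, percentile=50.0, fit_runs=None):
            select_calls.append(tuple(fit_runs))
            return real_select(betas, percentile, fit_runs)

        monkeypatch.setattr(dec, "fit_diag_gaussian", spy_fit)
        monkeypatch.setattr(dec, "select_top_r2", spy_select)
        loro_cv(bm, pair)
        # 4 folds; each trains on the other 3 runs' 8 pair blocks each
        assert fit_calls == [24, 24, 24, 24]
        # fold-wise selection always excludes the held-out run
        held_out = [set(bm.run_ids) - set(fr) for fr in select_calls]
        assert held_out == [{0}, {1}, {2}, {3}]

    def test_single_run_rejected(self):
        bm = synthetic_pair_betas(n_runs=1)
        with pytest.raises(ValueError, match="at least 2 runs"):
            loro_cv(bm, (C.LEFT_ILLUSION, C.RIGHT_ILLUSION))


class TestCompositeDecoders:
    def test_illusion_decoding_is_mean_of_pairwise(self, monkeypatch):
        import driftdecode.decode as dec

        calls = {}

        def fake_loro(betas, pair, **kw):
            calls[pair] = True
            return {C.LEFT_ILLUSION: 0.75, C.RIGHT_ILLUSION: 0.65}[pair[0]]

        monkeypatch.setattr(dec, "loro_cv", fake_loro)
        bm = synthetic_pair_betas(pair=(C.LEFT_ILLUSION, C.NO_ILLUSION))
        assert dec.illusion_decoding(bm) == pytest.approx(0.70)
        assert len(calls) == 2

    def test_path_decoding_null_near_chance(self):
        accs = [
            path_decoding(synthetic_pair_betas(sep=0.0, seed=100 + s))
            for s in range(30)
        ]
        assert np.mean(accs) == pytest.approx(0.5, abs=0.04)

    def test_missing_control_condition_rejected(self):
        bm = synthetic_pair_betas(pair=(C.LEFT_ILLUSION, C.RIGHT_ILLUSION))
        with pytest.raises(ValueError, match="control"):
            illusion_decoding(bm)


class TestPermutationInference:
    def test_permutation_preserves_per_run_class_counts(self):
        bm = synthetic_pair_betas(n_runs=3, seed=8)
        rng = np.random.default_rng(0)
        pair = (C.LEFT_ILLUSION, C.RIGHT_ILLUSION)
        perm = permute_labels_within_runs(bm.condition, bm.run_id, pair, rng)
        for r in bm.run_ids:
            orig = sorted(str(c) for c in bm.condition[bm.run_id == r])
            new = sorted(str(c) for c in perm[bm.run_id == r])
            assert orig == new

    def test_p_value_matches_rank(self):
        bm = synthetic_pair_betas(sep=50.0, noise_sd=0.1, seed=9)
        res = permutation_null(
            bm, (C.LEFT_ILLUSION, C.RIGHT_ILLUSION), n_perm=200, seed=0
        )
        rank = int(np.sum(res.null_accuracies >= res.accuracy))
        assert res.p_value == pytest.approx((1 + rank) / 201)
        assert res.significant

    def test_null_of_separable_data_centered_at_chance(self):
        bm = synthetic_pair_betas(sep=50.0, noise_sd=0.1, seed=10)
        res = permutation_null(
            bm, (C.LEFT_ILLUSION, C.RIGHT_ILLUSION), n_perm=300, seed=1
        )
        assert np.mean(res.null_accuracies) == pytest.approx(0.5, abs=0.03)

    def test_small_n_perm_warns(self):
        bm = synthetic_pair_betas(sep=1.0, seed=11)
        with pytest.warns(UserWarning, match="unstable"):
            permutation_null(bm, (C.LEFT_ILLUSION, C.RIGHT_ILLUSION), n_perm=50, seed=0)
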