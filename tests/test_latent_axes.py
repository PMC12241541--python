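import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wm_dynamics.latent_axes import (
    BetaStack,
    balanced_accuracy,
    condition_trajectories,
    fisher_lda,
    fit_pca,
    lda_sweep,
    orthogonalize_axes,
    region_loadings,
    select_operating_point,
    stack_betas,
    subject_folds,
    train_final_lda,
    zscore_timepoints,
)


def _random_stack(rng, P=6, C=2, T=4, R=20):
    return BetaStack(
        data=rng.normal(0, 1, (P, C, T, R)),
        participants=[f"s{i}" for i in range(P)],
        conditions=["a", "b", "c", "d"][:C],
    )


class TestZscore:
    def test_slice_means_and_sds(self, rng):
        z = zscore_timepoints(_random_stack(rng))
        means = z.data.mean(axis=-1)
        sds = z.data.std(axis=-1)
        assert np.abs(means).max() < 1e-10
        np.testing.assert_allclose(sds, 1.0, atol=1e-10)

    def test_idempotent(self, rng):
        z1 = zscore_timepoints(_random_stack(rng))
        z2 = zscore_timepoints(z1)
        np.testing.assert_allclose(z1.data, z2.data, atol=1e-12)

    def test_affine_invariance(self, rng):
        stack = _random_stack(rng)
        a = rng.uniform(0.5, 2.0, stack.data.shape[:3])[..., None]
        b = rng.normal(0, 3, stack.data.shape[:3])[..., None]
        transformed = BetaStack(
            data=a * stack.data + b,
            participants=stack.participants,
            conditions=stack.conditions,
        )
        np.testing.assert_allclose(
            zscore_timepoints(stack).data,
            zscore_timepoints(transformed).data,
            atol=1e-10,
        )

    def test_zero_spread_slice_raises(self, rng):
        stack = _random_stack(rng)
        stack.data[0, 0, 0, :] = 3.14
        with pytest.raises(ValueError, match="zero spread"):
            zscore_timepoints(stack)


class TestPca:
    def test_rank_one_data(self, rng):
        u = rng.normal(0, 1, 24)
        v = rng.normal(0, 1, 10)
        data = (u[:, None] * v[None, :]).reshape(6, 2, 2, 10)
        stack = BetaStack(
            data=data, participants=[f"s{i}" for i in range(6)], conditions=["a", "b"]
        )
        with pytest.warns(UserWarning, match="truncating"):
            latent = fit_pca(stack, n_max=5)
        assert latent.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_variance_ratio_matches_eigendecomposition(self, rng):
        stack = _random_stack(rng, P=8, R=12)
        latent = fit_pca(stack, n_max=12)
        X = stack.data.reshape(-1, 12)
        evals = np.linalg.eigvalsh(np.cov(X - X.mean(0), rowvar=False))[::-1]
        np.testing.assert_allclose(
            latent.explained_variance_ratio, evals[:12] / evals.sum(), atol=1e-10
        )
        assert (np.diff(latent.explained_variance_ratio) <= 1e-12).all()

    def test_full_reconstruction(self, rng):
        stack = _random_stack(rng, P=8, R=10)
        latent = fit_pca(stack, n_max=10)
        X = stack.data.reshape(-1, 10)
        recon = latent.scores.reshape(-1, latent.n_pcs) @ latent.components
        np.testing.assert_allclose(recon, X - X.mean(0), atol=1e-8)

    def test_components_orthonormal(self, rng):
        latent = fit_pca(_random_stack(rng, P=8, R=15), n_max=10)
        gram = latent.components @ latent.components.T
        np.testing.assert_allclose(gram, np.eye(latent.n_pcs), atol=1e-10)

    def test_too_few_observations_raise(self):
        stack = BetaStack(
            data=np.zeros((1, 1, 1, 5)), participants=["s0"], conditions=["a"]
        )
        with pytest.raises(ValueError):
            fit_pca(stack)


class TestBalancedAccuracy:
    def test_perfect(self):
        y = np.array([0, 0, 1, 1], bool)
        assert balanced_accuracy(y, y) == 1.0

    def test_one_class_prediction_is_chance(self):
        truth = np.array([0, 0, 1, 1], bool)
        assert balanced_accuracy(truth, np.ones(4, bool)) == 0.5

    def test_confusion_matrix_arithmetic(self):
        # TP=3, FN=1, TN=2, FP=2 -> (0.75 + 0.5) / 2
        truth = np.array([1, 1, 1, 1, 0, 0, 0, 0], bool)
        pred = np.array([1, 1, 1, 0, 1, 1, 0, 0], bool)
        assert balanced_accuracy(truth, pred) == pytest.approx(0.625)

    def test_single_class_truth_raises(self):
        with pytest.raises(ValueError):
            balanced_accuracy(np.ones(4, bool), np.ones(4, bool))


class TestSubjectFolds:
    def test_purity_and_coverage(self):
        subjects = np.repeat([f"s{i}" for i in range(11)], 3)
        folds = subject_folds(subjects, n_folds=5, seed=3)
        seen = np.concatenate(folds)
        assert sorted(seen) == list(range(len(subjects)))
        for fold in folds:
            inside = set(subjects[fold])
            outside = set(subjects) - inside
            assert not inside & outside
            # no subject is split across the boundary
            for s in inside:
                assert set(np.flatnonzero(subjects == s)) <= set(fold)

    def test_too_few_subjects_raise(self):
        with pytest.raises(ValueError):
            subject_folds(["a", "b"], n_folds=5)


class TestFisherLda:
    def test_matches_closed_form_on_spherical_gaussians(self, rng):
        n = 4000
        mu0, mu1 = np.array([0.0, 0.0, 0.0]), np.array([2.0, 1.0, -1.0])
        X = np.vstack([rng.normal(mu0, 1, (n, 3)), rng.normal(mu1, 1, (n, 3))])
        y = np.r_[np.zeros(n), np.ones(n)].astype(bool)
        w = fisher_lda(X, y)
        expected = mu1 - mu0  # sigma = identity
        cos = w @ expected / np.linalg.norm(expected)
        assert cos > 0.99

    def test_equal_means_yield_overlap(self, rng):
        X = rng.normal(0, 1, (200, 4))
        y = np.arange(200) % 2 == 0
        w = fisher_lda(X, y)
        proj0, proj1 = X[~y] @ w, X[y] @ w
        # projections overlap: gap between class means is small vs spread
        assert abs(proj1.mean() - proj0.mean()) < proj0.std()

    def test_sign_convention(self, rng):
        X = np.vstack([rng.normal(0, 1, (50, 2)), rng.normal(5, 1, (50, 2))])
        y = np.r_[np.zeros(50), np.ones(50)].astype(bool)
        w = fisher_lda(X, y)
        assert X[y].mean(0) @ w > X[~y].mean(0) @ w


class TestLdaSweep:
    def test_grid_has_600_cells(self, small_latent):
        grid = lda_sweep(small_latent, ("easy-correct", "hard-correct"), seed=0)
        assert grid.scores.shape == (15, 40)
        valid = grid.scores[~np.isnan(grid.scores)]
        assert ((valid >= 0) & (valid <= 1)).all()

    def test_separable_data_reaches_one(self, small_latent):
        grid = lda_sweep(small_latent, ("easy-correct", "hard-correct"), seed=0)
        assert np.nanmax(grid.scores) == 1.0

    def test_cv_subject_purity(self, small_latent):
        grid = lda_sweep(small_latent, ("easy-correct", "hard-correct"), seed=0)
        subjects = np.repeat(small_latent.participants, 2)
        for fold in grid.meta["folds"]:
            inside = set(subjects[fold])
            rest = set(np.delete(subjects, fold))
            assert not inside & rest

    def test_permutation_null_centers_at_chance(self, rng):
        # labels carry no signal: mean cell accuracy ~ 0.5
        P, T, R = 20, 3, 10
        from wm_dynamics.latent_axes import LatentSpace

        scores = rng.normal(0, 1, (P, 2, T, R))
        latent = LatentSpace(
            components=np.eye(R),
            explained_variance_ratio=np.full(R, 1 / R),
            scores=scores,
            mean=np.zeros(R),
            participants=[f"s{i}" for i in range(P)],
            conditions=["a", "b"],
        )
        grid = lda_sweep(
            latent, ("a", "b"), t_range=range(1, T + 1), pc_range=range(1, 9), seed=1
        )
        assert abs(np.nanmean(grid.scores) - 0.5) < 0.06


class TestSelectOperatingPoint:
    def test_singleton_grid(self):
        from wm_dynamics.latent_axes import SweepGrid

        grid = SweepGrid(
            scores=np.array([[0.8]]),
            timepoints=np.array([3]),
            pc_counts=np.array([7]),
            n_folds=5,
            seed=0,
        )
        assert select_operating_point(grid) == (3, 7)

    def test_tie_prefers_fewer_pcs(self):
        from wm_dynamics.latent_axes import SweepGrid

        scores = np.array([[0.6, 0.9, 0.9], [0.7, 0.8, 0.85]])
        grid = SweepGrid(
            scores=scores,
            timepoints=np.array([1, 2]),
            pc_counts=np.array([1, 2, 3]),
            n_folds=5,
            seed=0,
        )
        assert select_operating_point(grid) == (1, 2)

    def test_tie_prefers_earlier_timepoint(self):
        from wm_dynamics.latent_axes import SweepGrid

        scores = np.array([[0.5, 0.9], [0.9, 0.5]])
        grid = SweepGrid(
            scores=scores,
            timepoints=np.array([4, 9]),
            pc_counts=np.array([1, 2]),
            n_folds=5,
            seed=0,
        )
        assert select_operating_point(grid) == (4, 2)

    def test_all_invalid_raises(self):
        from wm_dynamics.latent_axes import SweepGrid

        grid = SweepGrid(
            scores=np.full((2, 2), np.nan),
            timepoints=np.array([1, 2]),
            pc_counts=np.array([1, 2]),
            n_folds=5,
            seed=0,
        )
        with pytest.raises(ValueError):
            select_operating_point(grid)


class TestOrthogonalize:
    def test_orthonormal_inputs_are_fixed_point(self):
        axes = orthogonalize_axes(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        np.testing.assert_allclose(axes.axis1_orth, [1, 0])
        np.testing.assert_allclose(axes.axis2_orth, [0, 1])

    def test_hand_gram_schmidt_2d(self):
        axes = orthogonalize_axes(np.array([1.0, 0.0]), np.array([1.0, 1.0]))
        np.testing.assert_allclose(axes.axis2_orth, [0, 1], atol=1e-12)
        # |pearson r| of (1,1) with (0,1) is undefined: (1,1) has no variance
        assert np.isnan(axes.corr_with_raw[1])

    def test_collinear_raises(self):
        with pytest.raises(ValueError, match="collinear"):
            orthogonalize_axes(np.array([1.0, 2.0]), np.array([2.0, 4.0]))

    def test_zero_axis_raises(self):
        with pytest.raises(ValueError):
            orthogonalize_axes(np.zeros(3), np.ones(3))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_orthonormal_property(self, seed):
        r = np.random.default_rng(seed)
        a1, a2 = r.normal(0, 1, (2, 8))
        axes = orthogonalize_axes(a1, a2)
        assert abs(axes.axis1_orth @ axes.axis2_orth) <= 1e-10
        assert np.linalg.norm(axes.axis1_orth) == pytest.approx(1.0, abs=1e-10)
        assert np.linalg.norm(axes.axis2_orth) == pytest.approx(1.0, abs=1e-10)


@pytest.fixture(scope="module")
def fitted_axes(small_latent):
    a1 = train_final_lda(
        small_latent, ("easy-correct", "hard-correct"), timepoint=6, n_pcs=13
    )
    a2 = train_final_lda(
        small_latent, ("hard-incorrect", "hard-correct"), timepoint=6, n_pcs=13
    )
    return orthogonalize_axes(a1, a2)


class TestProjection:
    def test_axis_self_projection_is_unit(self, fitted_axes):
        assert fitted_axes.axis1_orth @ fitted_axes.axis1_orth == pytest.approx(1.0)

    def test_axis_cross_projection_is_zero(self, fitted_axes):
        assert fitted_axes.axis1_orth @ fitted_axes.axis2_orth == pytest.approx(
            0.0, abs=1e-10
        )

    def test_loadings_shape(self, small_latent, fitted_axes):
        loadings = region_loadings(small_latent, fitted_axes)
        assert loadings.shape == (482, 2)

    def test_projection_linearity(self, small_latent, fitted_axes):
        import copy

        scaled = copy.copy(small_latent)
        scaled.scores = 2.0 * small_latent.scores
        np.testing.assert_allclose(
            condition_trajectories(scaled, fitted_axes),
            2.0 * condition_trajectories(small_latent, fitted_axes),
            atol=1e-10,
        )

    def test_medium_lies_between_easy_and_hard(self, small_latent, fitted_axes):
        traj = condition_trajectories(small_latent, fitted_axes)
        conds = small_latent.conditions
        e, m, h = (
            conds.index("easy-correct"),
            conds.index("medium-correct"),
            conds.index("hard-correct"),
        )
        peak = np.argmax(traj[h, :, 0])
        assert traj[e, peak, 0] < traj[m, peak, 0] < traj[h, peak, 0]

    def test_dimension_mismatch_raises(self, small_latent):
        bad = orthogonalize_axes(np.array([1.0, 0.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            region_loadings(small_latent, bad)

    def test_final_lda_n_pcs_bound(self, small_latent):
        with pytest.raises(ValueError):
            train_final_lda(
                small_latent, ("easy-correct", "hard-correct"), 6, n_pcs=1000
            )


class TestStackBetas:
    def test_missing_condition_drops_participant(self, small_betas):
        import copy

        betas = [copy.deepcopy(fb) for fb in small_betas]
        del betas[0].betas["hard-incorrect"]
        stack = stack_betas(betas, ["hard-correct", "hard-incorrect"])
        assert len(stack.participants) == len(small_betas) - 1

    def test_no_participant_raises(self, small_betas):
        with pytest.raises(ValueError):
            stack_betas(small_betas, ["nonexistent"])
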