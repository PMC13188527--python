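"""Trajectory fPCA: PCA reduction, missing-data path, component selection,
lasso-logistic prediction."""

import numpy as np
import pandas as pd
import pytest

from longisal import (
    TrajectoryFPCA,
    build_trajectories,
    clr_transform,
    lasso_logistic_cv,
    select_components,
)
from longisal.fpca import _select_k, fit_fpca, group_average_scores, shape_match_report

WEEKS = (0, 4, 8, 12, 16, 22)


@pytest.fixture(scope="module")
def traj(balanced_cohort):
    table, _ = balanced_cohort
    clr = clr_transform(table, 0.05)
    return build_trajectories(clr, table.sample_meta)


class TestBuildTrajectories:
    def test_centered_per_trajectory(self, traj):
        X = traj.data
        obs_mean = np.nanmean(X, axis=2)
        assert np.nanmax(np.abs(obs_mean)) < 1e-9

    def test_constant_trajectory_becomes_zero(self):
        x = np.full(6, 3.7)
        assert np.allclose(x - x.mean(), 0.0)

    def test_shift_invariance(self, traj):
        """Adding a constant to a trajectory leaves the centered version
        unchanged — scores are level-free."""
        X = traj.trajectories(traj.otus[0])
        shifted = X + 5.0
        c1 = X - np.nanmean(X, axis=1, keepdims=True)
        c2 = shifted - np.nanmean(shifted, axis=1, keepdims=True)
        np.testing.assert_allclose(c1, c2)

    def test_missing_weeks_marked(self, default_cohort):
        table, truth = default_cohort
        clr = clr_transform(table, 0.05)
        t = build_trajectories(clr, table.sample_meta)
        mask = truth.visit_mask.loc[t.mice].to_numpy()
        observed = ~np.isnan(t.data[:, 0, :])
        np.testing.assert_array_equal(observed, mask)


class TestFpcaFit:
    def test_complete_data_equals_classical_pca(self, traj):
        X = traj.trajectories(traj.otus[0])
        res = TrajectoryFPCA(X, weeks=WEEKS).fit()
        Xc = X - X.mean(axis=0)
        cov = np.cov(Xc.T, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evecs = evecs[:, order]
        for k in range(5):
            pca_scores = Xc @ evecs[:, k]
            diff = min(
                np.abs(res.scores[:, k] - pca_scores).max(),
                np.abs(res.scores[:, k] + pca_scores).max(),
            )
            assert diff < 1e-8

    def test_orthonormal_eigenfunctions(self, traj):
        res = TrajectoryFPCA(traj.trajectories(traj.otus[1]), weeks=WEEKS).fit()
        gram = res.eigenfunctions @ res.eigenfunctions.T
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-6)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert (res.eigenvalues >= 0).all()

    def test_full_reconstruction(self, traj):
        X = traj.trajectories(traj.otus[2])
        res = TrajectoryFPCA(X, weeks=WEEKS).fit()
        Xc = X - X.mean(axis=0)
        recon = res.reconstruct() - res.mean[None, :]
        np.testing.assert_allclose(recon, Xc, atol=1e-8)

    def test_single_shape_recovered(self):
        """Data generated from one temporal shape: one component explains
        99% variance and the eigenfunction matches up to sign."""
        rng = np.random.default_rng(0)
        shape = np.array([-1.0, -0.8, 0.0, 0.8, 1.0, 1.2])
        shape = (shape - shape.mean()) / np.linalg.norm(shape - shape.mean())
        scores = rng.normal(0, 3.0, 120)
        X = scores[:, None] * shape[None, :] + rng.normal(0, 0.03, (120, 6))
        res = TrajectoryFPCA(X, weeks=WEEKS).fit()
        assert res.n_components == 1
        assert abs(np.dot(res.eigenfunctions[0], shape)) > 0.99

    def test_missingness_agrees_with_complete_path_when_none_missing(self, traj):
        X = traj.trajectories(traj.otus[0])
        res1 = TrajectoryFPCA(X, weeks=WEEKS).fit()
        res2 = TrajectoryFPCA(X.copy(), weeks=WEEKS).fit()
        np.testing.assert_array_equal(res1.scores, res2.scores)

    def test_missing_entries_scored_by_blp(self):
        rng = np.random.default_rng(1)
        shape = np.array([-1, -0.5, 0, 0.5, 1.0, 1.5])
        shape = (shape - shape.mean()) / np.linalg.norm(shape - shape.mean())
        scores = rng.normal(0, 2.0, 200)
        X = scores[:, None] * shape[None, :] + rng.normal(0, 0.1, (200, 6))
        Xm = X.copy()
        Xm[::5, 2] = np.nan  # knock out one week for a fifth of the mice
        res = TrajectoryFPCA(Xm, weeks=WEEKS).fit()
        sign = np.sign(np.dot(res.eigenfunctions[0], shape))
        corr = np.corrcoef(res.scores[:, 0] * sign, scores)[0, 1]
        assert corr > 0.99

    def test_sparse_week_pair_error(self):
        X = np.full((12, 6), np.nan)
        X[:, :3] = np.random.default_rng(0).normal(size=(12, 3))
        X[0, 4] = 0.0
        with pytest.raises(ValueError, match="week pair"):
            TrajectoryFPCA(X, weeks=WEEKS).fit()

    def test_too_few_trajectories(self):
        with pytest.raises(ValueError, match=">= 10"):
            TrajectoryFPCA(np.zeros((5, 6)))


class TestSelectComponents:
    def test_worked_example(self):
        """Eigenvalues (98, 1.5, 0.5): 98% < 99% <= 99.5% -> k = 2."""
        assert _select_k(np.array([98.0, 1.5, 0.5]), 0.99) == 2

    def test_single_component(self):
        assert _select_k(np.array([5.0, 0.0, 0.0]), 0.99) == 1

    def test_threshold_one_keeps_all_nonzero(self):
        assert _select_k(np.array([3.0, 2.0, 0.0]), 1.0) == 2

    def test_degenerate_error(self):
        with pytest.raises(ValueError):
            _select_k(np.zeros(3), 0.99)


class TestLassoLogistic:
    def test_huge_penalty_selects_nothing(self):
        rng = np.random.default_rng(2)
        feats = pd.DataFrame(
            rng.normal(size=(40, 6)),
            index=[f"m{i}" for i in range(40)],
            columns=[f"Otu{j}|fPC1" for j in range(6)],
        )
        labels = pd.Series(
            ["OSCC"] * 20 + ["ED/CIS"] * 20, index=feats.index
        )
        fit = lasso_logistic_cv(feats, labels, "KO", seed=0, Cs=[1e-6])
        assert fit.predictive_otus == []

    def test_single_class_skipped(self):
        feats = pd.DataFrame(
            np.zeros((10, 2)), index=[f"m{i}" for i in range(10)],
            columns=["A|fPC1", "B|fPC1"],
        )
        labels = pd.Series(["OSCC"] * 10, index=feats.index)
        with pytest.warns(UserWarning, match="single diagnosis class"):
            assert lasso_logistic_cv(feats, labels, "KO") is None

    def test_separating_feature_selected(self):
        rng = np.random.default_rng(3)
        n = 60
        y = np.repeat([0, 1], n // 2)
        signal = y * 3.0 + rng.normal(0, 1.0, n)
        feats = pd.DataFrame(
            np.column_stack([signal] + [rng.normal(size=n) for _ in range(5)]),
            index=[f"m{i}" for i in range(n)],
            columns=["Hit|fPC2"] + [f"Noise{j}|fPC1" for j in range(5)],
        )
        labels = pd.Series(np.where(y == 1, "OSCC", "ED/CIS"), index=feats.index)
        fit = lasso_logistic_cv(feats, labels, "KO", seed=0)
        assert "Hit" in fit.predictive_otus


class TestGroupScores:
    def test_table_structure_and_balance(self, traj):
        models = fit_fpca(traj)
        table = group_average_scores(models, traj)
        cells = traj.mouse_meta.groupby(["genotype", "diagnosis"]).size()
        expected = sum(models[o].n_components for o in traj.otus) * len(cells)
        assert len(table) == expected
        assert set(table.columns) == {
            "otu", "component", "genotype", "diagnosis", "mean_score"
        }

    def test_shape_report_flags_matching_trends(self):
        rng = np.random.default_rng(4)
        w = np.array(WEEKS, dtype=float)
        rise = np.tanh((w - 12) / 3)
        rise = (rise - rise.mean()) / np.linalg.norm(rise - rise.mean())
        X = rng.normal(0, 2, 100)[:, None] * rise[None, :] + rng.normal(
            0, 0.05, (100, 6)
        )
        res = TrajectoryFPCA(X, weeks=WEEKS).fit()
        report = shape_match_report({"OtuX": res}, WEEKS)
        assert report["OtuX"]["fPC1"]["matches"]
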