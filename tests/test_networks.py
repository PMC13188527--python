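"""Copula latent correlation, neighborhood selection, StARS, and the
genotype/period network comparison."""

import numpy as np
import pytest
from scipy import stats

from longisal import (
    build_period_networks,
    compare_networks,
    latent_correlation,
    mclr_transform,
    stars_select,
)
from longisal.networks import (
    NetworkEstimate,
    _bridge_tt_mvncdf,
    bridge_inverse,
    bridge_tt,
    default_lambda_seq,
    graph_path,
    kendall_tau_a,
    latent_correlation_matrix,
    psd_project,
)


class TestMclr:
    def test_zeros_preserved_exactly(self):
        out = mclr_transform([0, 5, 0, 10, 3])
        assert out[0] == 0.0 and out[2] == 0.0

    def test_nonzero_entries_strictly_positive(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            row = rng.integers(0, 20, 12)
            if row.sum() == 0:
                continue
            out = mclr_transform(row)
            assert (out[row > 0] > 0).all()

    def test_no_zeros_is_shifted_clr(self):
        row = np.array([2.0, 3.0, 10.0])
        out = mclr_transform(row)
        clr = np.log(row / row.sum())
        clr = clr - clr.mean()
        diffs = out - clr
        np.testing.assert_allclose(diffs, diffs[0])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            mclr_transform([0, 0, 0])


class TestBridge:
    def test_quadrature_matches_mvn_cdf_reference(self):
        """Two independent implementations of the same bridge agree."""
        for rho in (-0.8, -0.2, 0.4, 0.9):
            for d in (-1.5, -0.5, 0.5):
                assert bridge_tt(rho, d, d) == pytest.approx(
                    _bridge_tt_mvncdf(rho, d, d), abs=5e-5
                )

    def test_forward_inverse_round_trip(self):
        """Recovers rho to 1e-4 over the rho x zero-proportion grid."""
        for rho in np.arange(-0.9, 0.91, 0.2):
            for pz in (0.0, 0.3, 0.6):
                d = stats.norm.ppf(max(pz, 1e-3))
                tau = bridge_tt(rho, d, d)
                assert abs(bridge_inverse(tau, d, d, tol=1e-8) - rho) < 1e-4

    def test_no_zero_limit_is_arcsine(self):
        assert bridge_tt(0.6, -5.5, -5.5) == pytest.approx(
            2 / np.pi * np.arcsin(0.6), abs=1e-4
        )

    def test_kendall_tau_a_counts_ties(self):
        x = np.array([0, 0, 1, 2])
        y = np.array([0, 1, 2, 3])
        # concordant pairs among non-tied: (1,3),(1,4),(2,3)->tie in x for (1,2)
        tau = kendall_tau_a(x, y)
        assert tau == pytest.approx(5 / 6)
        with pytest.raises(ValueError):
            kendall_tau_a([1, 1, 1], [1, 2, 3])


class TestLatentCorrelation:
    def test_identical_vectors_give_one(self):
        x = np.abs(np.random.default_rng(0).normal(size=50)) + 0.1
        assert latent_correlation(x, x) == pytest.approx(0.999)

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(1)
        ests = []
        for _ in range(30):
            z = rng.standard_normal((500, 2))
            x = np.where(z[:, 0] > stats.norm.ppf(0.3), z[:, 0], 0.0)
            y = np.where(z[:, 1] > stats.norm.ppf(0.3), z[:, 1], 0.0)
            ests.append(latent_correlation(x, y))
        assert abs(np.median(ests)) < 0.1

    def test_known_rho_recovered(self):
        rng = np.random.default_rng(2)
        rho = 0.6
        L = np.linalg.cholesky([[1, rho], [rho, 1]])
        ests = []
        for _ in range(30):
            z = rng.standard_normal((500, 2)) @ L.T
            d = stats.norm.ppf(0.3)
            x = np.where(z[:, 0] > d, z[:, 0] - d, 0.0)
            y = np.where(z[:, 1] > d, z[:, 1] - d, 0.0)
            ests.append(latent_correlation(x, y))
        assert abs(np.median(ests) - rho) < 0.1

    def test_min_nonzero_precondition(self):
        with pytest.raises(ValueError):
            latent_correlation([0, 0, 0, 1, 0, 0], np.arange(6.0))

    def test_matrix_is_psd_unit_diagonal(self):
        rng = np.random.default_rng(3)
        X = np.where(rng.random((60, 8)) < 0.3, 0.0, np.abs(rng.standard_normal((60, 8))))
        R = latent_correlation_matrix(X)
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)
        assert np.linalg.eigvalsh(R).min() >= -1e-10


class TestGraphPath:
    @pytest.fixture(scope="class")
    def corr(self):
        rng = np.random.default_rng(4)
        A = rng.standard_normal((8, 30))
        R = np.corrcoef(A)
        return psd_project(R)

    def test_huge_lambda_empty_graph(self, corr):
        off = np.abs(corr - np.eye(len(corr))).max()
        adj = graph_path(corr, [off * 1.01])[0]
        assert (adj == 0).all()

    def test_tiny_lambda_dense_graph(self, corr):
        adj = graph_path(corr, [1e-6])[0]
        iu = np.triu_indices(len(corr), 1)
        assert (adj[iu] != 0).mean() > 0.9

    def test_no_self_edges_and_symmetry(self, corr):
        for adj in graph_path(corr, [0.5, 0.2, 0.05]):
            assert (np.diag(adj) == 0).all()
            np.testing.assert_array_equal(adj != 0, (adj != 0).T)


class TestStars:
    def test_instability_bounded(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((100, 8))
        est = stars_select(X, lambda_seq=default_lambda_seq(8, 0.8), n_subsamples=10, seed=0)
        assert (est.instability_path >= 0).all()
        assert (est.instability_path <= 0.5).all()

    def test_monotonized_instability_nondecreasing_with_density(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((100, 8))
        est = stars_select(X, lambda_seq=default_lambda_seq(10, 0.8), n_subsamples=10, seed=1)
        mono = np.maximum.accumulate(est.instability_path)
        assert (np.diff(mono) >= -1e-12).all()

    def test_subsample_floor(self):
        with pytest.raises(ValueError):
            stars_select(np.random.default_rng(0).normal(size=(50, 4)), n_subsamples=5)

    def test_chain_recovery_single_run(self):
        """One chain-graph replicate recovers most true edges (the
        100-replicate median check lives in the acceptance suite)."""
        p, n = 12, 400
        P = np.eye(p)
        for i in range(p - 1):
            P[i, i + 1] = P[i + 1, i] = 0.45
        C = np.linalg.inv(P)
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        X = np.random.default_rng(7).multivariate_normal(np.zeros(p), C, size=n)
        est = stars_select(X, lambda_seq=default_lambda_seq(15, 0.8), n_subsamples=15, seed=0)
        true_edges = {frozenset((i, i + 1)) for i in range(p - 1)}
        found = est.edge_set
        fn = len(true_edges - found) / len(true_edges)
        assert fn <= 0.2


class TestPeriodNetworks:
    def test_planted_family_association(self, default_cohort):
        """A strong latent co-variation between two families survives the
        pipeline into the selected networks."""
        import longisal as ls

        design = ls.StudyDesign(
            seed=31, n_otus=40, dropout_rate=0.0,
            n_mice={("WT", "M"): 30, ("WT", "F"): 30},
        )
        table, truth = ls.generate_cohort(
            design, ls.TruthConfig(zero_inflation=0.0, sigma_b=0.3, sigma_e=0.4)
        )
        # plant the association by replacing two OTUs' counts with strongly
        # coupled values on the latent scale
        rng = np.random.default_rng(0)
        shared = rng.normal(0, 1.5, table.n_samples)
        fam = table.taxonomy.map(lambda t: t[4])
        o1 = fam.index[fam == "Sphingomonadaceae"]
        o2 = fam.index[fam == "Pasteurellaceae"]
        if len(o1) == 0 or len(o2) == 0:
            pytest.skip("family pool draw lacks the planted families")
        base = table.counts.to_numpy().astype(float)
        scale = np.exp(shared)
        base[:, table.counts.columns.get_loc(o1[0])] = 3000 * scale
        base[:, table.counts.columns.get_loc(o2[0])] = 5000 * scale
        table.counts.iloc[:, :] = base.astype(np.int64)
        nets = build_period_networks(
            table, "family", "WT", n_subsamples=10,
            lambda_seq=default_lambda_seq(10, 0.8), seed=0,
        )
        assert len(nets) == 3
        planted = frozenset(("Sphingomonadaceae", "Pasteurellaceae"))
        for est in nets:
            assert planted in est.edge_set

    def test_missing_genotype_warns_empty(self, small_table):
        table = small_table.copy()
        table.sample_meta["genotype"] = "WT"
        with pytest.warns(UserWarning):
            assert build_period_networks(table, "family", "KO") == []


class TestCompare:
    @staticmethod
    def _net(edges, geno, period):
        return NetworkEstimate(
            nodes=list("abcd"),
            edges=[(a, b, 1) for a, b in edges],
            genotype=geno,
            period=period,
            lambda_selected=0.1,
            instability_path=np.zeros(3),
            lambda_seq=np.ones(3),
        )

    def test_identical_networks_all_core(self):
        nets = {
            (g, p): self._net([("a", "b"), ("c", "d")], g, p)
            for g in ("WT", "KO")
            for p in ("0-4", "8-12", "16-22")
        }
        rep = compare_networks(nets)
        assert rep.class_counts() == {
            "core": 2, "genotype-stable": 0, "period-specific": 0,
        }

    def test_genotype_stable_edge(self):
        nets = {}
        for p in ("0-4", "8-12", "16-22"):
            nets[("KO", p)] = self._net([("a", "b")], "KO", p)
            nets[("WT", p)] = self._net([], "WT", p)
        rep = compare_networks(nets)
        assert rep.classes["genotype-stable"] == ["a -- b"]

    def test_classes_partition_edges(self):
        rng = np.random.default_rng(8)
        nodes = list("abcde")
        all_pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
        nets = {}
        for g in ("WT", "KO"):
            for p in ("0-4", "8-12", "16-22"):
                sel = [e for e in all_pairs if rng.random() < 0.4]
                nets[(g, p)] = self._net(sel, g, p)
        rep = compare_networks(nets)
        assert sum(rep.class_counts().values()) == len(rep.presence)
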