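"""Correlation screening, consensus clustering, k selection, covariate tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from _oracles import (
    calinski_harabasz_brute,
    davies_bouldin_brute,
    silhouette_brute,
    spearman_brute,
)
from ecosig.ecosigclust import (
    associate_exposure_covariate,
    choose_k,
    cluster_mean_correlation,
    consensus_kmeans,
    correlate_expression_signatures,
    cut_consensus,
    select_significant_genes,
    spearman,
    validation_indices,
)


class TestSpearman:
    @pytest.mark.parametrize(
        ("x", "y", "expected"),
        [
            ([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], 1.0),
            ([1, 2, 3, 4, 5], [2, 1, 4, 3, 5], 0.8),
            ([1, 2, 3, 4, 5], [5, 4, 3, 2, 1], -1.0),
        ],
    )
    def test_textbook_values(self, x, y, expected):
        rho, _ = spearman(np.array(x), np.array(y))
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_constant_input_flagged(self):
        rho, p = spearman(np.ones(6), np.arange(6.0))
        assert np.isnan(rho)
        assert p == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            spearman(np.arange(5.0), np.arange(6.0))

    def test_agrees_with_scipy_t_approximation(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.normal(size=25)
            y = rng.normal(size=25)
            rho, p = spearman(x, y)
            ref_rho, ref_p = spearmanr(x, y)
            assert rho == pytest.approx(ref_rho, abs=1e-12)
            assert p == pytest.approx(ref_p, rel=1e-9)

    def test_exact_permutation_p_matches_enumeration(self):
        import itertools

        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.0, 3.0, 5.0, 4.0])
        rho, p = spearman(x, y, exact=True)
        assert rho == pytest.approx(0.9)
        # independent enumeration over all 120 pairings with the brute rho
        count = sum(
            abs(spearman_brute(x, np.array(perm))) >= 0.9 - 1e-12
            for perm in itertools.permutations(y)
        )
        assert p == pytest.approx(count / 120)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.integers(min_value=-50, max_value=50), min_size=5, max_size=20
        ),
        st.randoms(use_true_random=False),
    )
    def test_matches_brute_force_ranks_with_ties(self, values, rnd):
        x = np.array(values, dtype=float)
        y = np.array(sorted(values, key=lambda _: rnd.random()), dtype=float)
        if np.ptp(x) == 0:
            return
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(spearman_brute(x, y), abs=1e-12)
        assert -1.0 - 1e-12 <= rho <= 1.0 + 1e-12


class TestCorrelateExpressionSignatures:
    def test_planted_noise_free_gene_hits_rho_one(self):
        # one-hot effects: each planted cluster tracks exactly one signature
        from ecosig.synthetic_data import SimConfig, simulate_exposures, simulate_expression

        eff = np.array([[1.0, 0.0, 0.0], [0.0, -1.0, 0.0]])
        config = SimConfig(
            n_samples=30, n_genes=20, n_signatures=3, n_clusters=2,
            genes_per_cluster=5, noise_sd=0.0, seed=15, effect_matrix=eff,
        )
        exposures = simulate_exposures(config)
        expression, planted = simulate_expression(exposures, config)
        profile = correlate_expression_signatures(expression, exposures)
        for gene in planted[planted == 1].index:
            assert profile.rho.loc[gene].iloc[0] == pytest.approx(1.0, abs=1e-12)
        for gene in planted[planted == 2].index:
            assert profile.rho.loc[gene].iloc[1] == pytest.approx(-1.0, abs=1e-12)

    def test_constant_gene_flagged_with_unit_p(self, small_sim):
        expr = small_sim.expression.copy()
        expr.iloc[0] = 7
        profile = correlate_expression_signatures(
            expr, small_sim.truth.true_exposures
        )
        gene = expr.index[0]
        assert profile.constant[gene]
        assert np.isnan(profile.rho.loc[gene]).all()
        assert (profile.pval.loc[gene] == 1.0).all()

    def test_invariant_to_monotone_gene_transform(self, small_sim):
        expr = small_sim.expression.astype(float)
        transformed = expr.copy()
        transformed.iloc[5] = np.exp(transformed.iloc[5] / 1000.0)
        a = correlate_expression_signatures(expr, small_sim.truth.true_exposures)
        b = correlate_expression_signatures(
            transformed, small_sim.truth.true_exposures
        )
        pd.testing.assert_frame_equal(a.rho, b.rho)

    def test_matches_entrywise_scipy(self, small_sim):
        profile = correlate_expression_signatures(
            small_sim.expression, small_sim.truth.true_exposures
        )
        rng = np.random.default_rng(0)
        genes = rng.choice(small_sim.expression.index, 5, replace=False)
        for g in genes:
            for s in small_sim.truth.true_exposures.columns:
                ref_rho, ref_p = spearmanr(
                    small_sim.expression.loc[g].to_numpy(),
                    small_sim.truth.true_exposures[s].to_numpy(),
                )
                assert profile.rho.loc[g, s] == pytest.approx(ref_rho, abs=1e-12)
                assert profile.pval.loc[g, s] == pytest.approx(ref_p, rel=1e-9)

    def test_too_few_samples_rejected(self, small_sim):
        with pytest.raises(ValueError):
            correlate_expression_signatures(
                small_sim.expression.iloc[:, :3],
                small_sim.truth.true_exposures.iloc[:3],
            )


class TestSelectSignificantGenes:
    def _profile(self, pvals):
        pvals = np.asarray(pvals, dtype=float)
        from ecosig.ecosigclust import CorrelationProfile

        genes = [f"g{i}" for i in range(pvals.shape[0])]
        sigs = [f"S{j}" for j in range(pvals.shape[1])]
        return CorrelationProfile(
            rho=pd.DataFrame(np.zeros_like(pvals), index=genes, columns=sigs),
            pval=pd.DataFrame(pvals, index=genes, columns=sigs),
            constant=pd.Series(False, index=genes),
        )

    def test_single_marginal_hit_is_selected(self):
        profile = self._profile([[0.049, 0.8], [0.6, 0.7]])
        assert select_significant_genes(profile) == ["g0"]

    def test_empty_selection_raises(self):
        profile = self._profile([[0.5, 0.5]])
        with pytest.raises(ValueError):
            select_significant_genes(profile, alpha=1e-6)

    def test_null_selection_rate_near_independence_value(self):
        rng = np.random.default_rng(12)
        n, genes, S = 60, 2000, 4
        E = pd.DataFrame(
            rng.normal(size=(n, S)),
            index=[f"s{i}" for i in range(n)],
            columns=[f"S{j}" for j in range(S)],
        )
        X = pd.DataFrame(
            rng.normal(size=(genes, n)),
            index=[f"g{i}" for i in range(genes)],
            columns=E.index,
        )
        profile = correlate_expression_signatures(X, E)
        frac = len(select_significant_genes(profile)) / genes
        expected = 1 - 0.95**S
        se = np.sqrt(expected * (1 - expected) / genes)
        assert abs(frac - expected) < 3 * se


@pytest.fixture(scope="module")
def blobs():
    rng = np.random.default_rng(3)
    a = rng.normal(0.0, 0.05, size=(15, 4)) + np.array([1.0, 0, 0, 0])
    b = rng.normal(0.0, 0.05, size=(15, 4)) + np.array([-1.0, 0, 0, 0])
    X = pd.DataFrame(np.vstack([a, b]), index=[f"g{i}" for i in range(30)])
    truth = np.array([0] * 15 + [1] * 15)
    return X, truth


class TestConsensusAndCut:

    def test_separated_blobs_give_exact_block_consensus(self, blobs):
        X, truth = blobs
        M = consensus_kmeans(X, k=2, n_runs=30, seed=0)
        same = truth[:, None] == truth[None, :]
        np.testing.assert_array_equal(M.to_numpy(), same.astype(float))

    def test_single_run_entries_are_binary(self, blobs):
        X, _ = blobs
        M = consensus_kmeans(X, k=2, n_runs=1, seed=5).to_numpy()
        assert set(np.unique(M)) <= {0.0, 1.0}

    def test_symmetric_with_unit_diagonal(self, blobs):
        X, _ = blobs
        M = consensus_kmeans(X, k=3, n_runs=10, seed=1).to_numpy()
        np.testing.assert_allclose(M, M.T)
        np.testing.assert_allclose(np.diag(M), 1.0)
        assert (M >= 0).all() and (M <= 1).all()

    def test_degenerate_duplicate_rows_rejected(self):
        X = pd.DataFrame(np.ones((10, 3)), index=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError):
            consensus_kmeans(X, k=2, n_runs=5, seed=0)

    def test_cut_recovers_perfect_blocks(self, blobs):
        X, truth = blobs
        M = consensus_kmeans(X, k=2, n_runs=30, seed=0)
        labels = cut_consensus(M, 2)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_cut_k_equals_n_gives_singletons(self, blobs):
        X, _ = blobs
        M = consensus_kmeans(X, k=2, n_runs=5, seed=0)
        labels = cut_consensus(M, len(M))
        assert labels.nunique() == len(M)

    def test_cut_is_deterministic(self, blobs):
        X, _ = blobs
        M = consensus_kmeans(X, k=2, n_runs=10, seed=2)
        pd.testing.assert_series_equal(cut_consensus(M, 2), cut_consensus(M, 2))

    def test_adding_runs_changes_consensus_boundedly(self, blobs):
        X, _ = blobs
        m1 = consensus_kmeans(X, k=3, n_runs=10, seed=7).to_numpy()
        m2 = consensus_kmeans(X, k=3, n_runs=11, seed=7).to_numpy()
        # first 10 runs are shared, so entries shift by at most 1/11 + 10*(1/10-1/11)
        assert np.abs(m2 - m1).max() <= 1.0 / 11 + 10 * (1 / 10 - 1 / 11) + 1e-12


class TestValidationIndices:
    def test_matches_brute_force_oracles_on_fixture(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 3))
        labels = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3, 3])
        features = pd.DataFrame(X, index=[f"g{i}" for i in range(10)])
        assignment = pd.Series(labels, index=features.index)
        out = validation_indices(features, assignment)
        assert out["silhouette"] == pytest.approx(
            silhouette_brute(X, labels), abs=1e-10
        )
        assert out["calinski_harabasz"] == pytest.approx(
            calinski_harabasz_brute(X, labels), abs=1e-10
        )
        assert out["davies_bouldin"] == pytest.approx(
            davies_bouldin_brute(X, labels), abs=1e-10
        )

    def test_two_point_masses_have_unit_silhouette(self):
        X = pd.DataFrame(
            np.array([[0.0, 0], [0, 0], [5, 5], [5, 5]]),
            index=list("abcd"),
        )
        labels = pd.Series([1, 1, 2, 2], index=X.index)
        out = validation_indices(X, labels)
        assert out["silhouette"] == pytest.approx(1.0)
        assert out["davies_bouldin"] >= 0.0

    def test_single_cluster_rejected(self):
        X = pd.DataFrame(np.eye(4), index=list("abcd"))
        with pytest.raises(ValueError):
            validation_indices(X, pd.Series([1, 1, 1, 1], index=X.index))


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(6)
    centers = np.array(
        [[1, 0, 0, 0], [-1, 0, 0, 0], [0, 1, 0, 0], [0, -1, 0, 0]],
        dtype=float,
    )
    rows, truth = [], []
    for c, center in enumerate(centers):
        rows.append(rng.normal(0.0, 0.08, size=(20, 4)) + center)
        truth += [c] * 20
    X = pd.DataFrame(np.vstack(rows), index=[f"g{i}" for i in range(80)])
    return X, np.array(truth)


class TestChooseK:

    def test_recovers_planted_cluster_count_and_membership(self, planted):
        X, truth = planted
        result = choose_k(X, k_range=range(2, 8), n_runs=30, seed=4)
        assert result.k == 4
        assert adjusted_rand_score(truth, result.assignment) >= 0.9

    def test_singleton_range_returns_that_k(self, planted):
        X, _ = planted
        result = choose_k(X, k_range=[3], n_runs=10, seed=0)
        assert result.k == 3

    def test_override_honored_and_reported(self, planted):
        X, _ = planted
        result = choose_k(X, k_range=range(2, 7), n_runs=10, seed=0, k_override=6)
        assert result.k == 6
        assert set(result.validation.index) == set(range(2, 7))

    def test_deterministic_given_seed(self, planted):
        X, _ = planted
        a = choose_k(X, k_range=range(2, 6), n_runs=15, seed=11)
        b = choose_k(X, k_range=range(2, 6), n_runs=15, seed=11)
        assert a.k == b.k
        pd.testing.assert_series_equal(a.assignment, b.assignment)
        pd.testing.assert_frame_equal(a.validation, b.validation)

    def test_empty_range_rejected(self, planted):
        X, _ = planted
        with pytest.raises(ValueError):
            choose_k(X, k_range=[], n_runs=5, seed=0)


class TestClusterMeanCorrelation:
    def test_single_gene_cluster_is_its_own_row(self):
        rho = pd.DataFrame(
            [[0.9, -0.2], [0.1, 0.3], [0.2, 0.4]],
            index=["a", "b", "c"],
            columns=["S1", "S2"],
        )
        assignment = pd.Series([1, 2, 2], index=rho.index)
        means = cluster_mean_correlation(rho, assignment)
        np.testing.assert_allclose(means.loc[1], [0.9, -0.2])

    def test_size_weighted_grand_mean_equals_overall_mean(self):
        rng = np.random.default_rng(2)
        rho = pd.DataFrame(
            rng.uniform(-1, 1, size=(12, 3)),
            index=[f"g{i}" for i in range(12)],
        )
        assignment = pd.Series(
            rng.integers(1, 4, size=12), index=rho.index
        )
        means = cluster_mean_correlation(rho, assignment)
        sizes = assignment.value_counts().sort_index()
        grand = (means.mul(sizes, axis=0)).sum() / sizes.sum()
        np.testing.assert_allclose(grand, rho.mean(), atol=1e-12)

    def test_incomplete_assignment_rejected(self):
        rho = pd.DataFrame(np.zeros((3, 2)), index=["a", "b", "c"])
        with pytest.raises(ValueError):
            cluster_mean_correlation(rho, pd.Series([1, 2], index=["a", "b"]))


class TestCovariateAssociation:
    def _exposures(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.gamma(2.0, 100.0, size=(n, 3)),
            index=[f"s{i}" for i in range(n)],
            columns=["SBS1", "SBS4", "SBS40"],
        )

    def test_covariate_equal_to_exposure_has_unit_rho(self):
        exposures = self._exposures()
        out = associate_exposure_covariate(
            exposures, exposures["SBS1"], kind="continuous"
        )
        assert out.loc["SBS1", "statistic"] == pytest.approx(1.0)
        assert out.loc["SBS1", "pvalue"] < 1e-10

    def test_constant_covariate_flagged(self):
        exposures = self._exposures()
        out = associate_exposure_covariate(
            exposures, pd.Series(3.0, index=exposures.index), kind="continuous"
        )
        assert out["statistic"].isna().all()
        assert (out["pvalue"] == 1.0).all()

    def test_missing_values_dropped_pairwise(self):
        exposures = self._exposures()
        cov = exposures["SBS4"].copy()
        cov.iloc[:5] = np.nan
        out = associate_exposure_covariate(exposures, cov, kind="continuous")
        assert out.loc["SBS4", "statistic"] == pytest.approx(1.0)

    def test_binary_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(8)
        n, sims = 40, 2000
        labels = pd.Series(
            np.repeat([0, 1], n // 2), index=[f"s{i}" for i in range(n)]
        )
        rejections = 0
        for _ in range(sims):
            exposures = pd.DataFrame(
                rng.gamma(2.0, 100.0, size=(n, 1)),
                index=labels.index,
                columns=["SBS1"],
            )
            out = associate_exposure_covariate(exposures, labels, kind="binary")
            rejections += out.loc["SBS1", "pvalue"] < 0.05
        assert rejections / sims == pytest.approx(0.05, abs=0.02)

    def test_all_missing_rejected(self):
        exposures = self._exposures()
        with pytest.raises(ValueError):
            associate_exposure_covariate(
                exposures, pd.Series(np.nan, index=exposures.index)
            )
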