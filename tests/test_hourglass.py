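import numpy as np
import pandas as pd
import pytest
from scipy.special import rel_entr

from hourglass_kit.expression import ScaledMatrix
from hourglass_kit.hourglass import (
    METRICS,
    cluster_genes,
    concat_vectors,
    min_distance_summary,
    pca_stages,
    shannon_distance,
    stage_associated_counts,
    stage_distance,
    tissue_associated_counts,
    tissue_entropy,
)

from conftest import make_matrix


def sm(values, stages, genes, species="sp", method="max1"):
    return ScaledMatrix(
        method=method,
        values=pd.DataFrame(values, index=genes, columns=stages),
        species=species,
    )


def jsd_oracle(u, v):
    """Independently coded generalized Jensen-Shannon divergence."""
    m = (u + v) / 2.0
    return 0.5 * (rel_entr(u, m).sum() + rel_entr(v, m).sum())


def one_stage_pair(u, v):
    genes = [f"g{i}" for i in range(len(u))]
    sa = sm(np.asarray(u, float)[:, None], ["sA"], genes, "A")
    sb = sm(np.asarray(v, float)[:, None], ["sB"], genes, "B")
    return sa, sb, [(g, g) for g in genes]


class TestStageDistance:
    def test_identical_profiles_have_zero_distance_under_all_metrics(self):
        vals = np.array([[1.0, 2.0], [3.0, 1.0], [0.5, 4.0]])
        genes = ["g1", "g2", "g3"]
        sa = sm(vals, ["s1", "s2"], genes, "A")
        sb = sm(vals, ["t1", "t2"], genes, "B")
        pairs = [(g, g) for g in genes]
        for metric in METRICS:
            d = stage_distance(sa, sb, pairs, metric).values
            assert np.allclose(np.diag(d), 0.0, atol=1e-12), metric
            assert (d.to_numpy() >= -1e-12).all()

    def test_unit_vector_closed_forms(self):
        sa, sb, pairs = one_stage_pair([1.0, 0.0], [0.0, 1.0])
        d_euc = stage_distance(sa, sb, pairs, "euclidean").values.iloc[0, 0]
        d_sha = stage_distance(sa, sb, pairs, "shannon").values.iloc[0, 0]
        d_cor = stage_distance(sa, sb, pairs, "correlation").values.iloc[0, 0]
        assert d_euc == pytest.approx(np.sqrt(2.0))
        assert d_sha == pytest.approx(np.log(2.0))
        assert d_cor == pytest.approx(2.0)  # anti-correlated

    def test_correlation_zero_variance_rejected(self):
        sa, sb, pairs = one_stage_pair([1.0, 1.0], [0.0, 1.0])
        with pytest.raises(ValueError):
            stage_distance(sa, sb, pairs, "correlation")

    def test_shannon_negative_values_rejected(self):
        with pytest.raises(ValueError):
            shannon_distance(np.array([1.0, -0.1]), np.array([0.5, 0.5]))

    def test_shannon_equals_independent_jsd(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            u = rng.uniform(0, 5, size=50)
            v = rng.uniform(0, 5, size=50)
            u[rng.uniform(size=50) < 0.1] = 0.0
            v[rng.uniform(size=50) < 0.1] = 0.0
            assert abs(shannon_distance(u, v) - jsd_oracle(u, v)) < 1e-12

    def test_shannon_bounded_by_log2_on_probability_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            u = rng.dirichlet(np.ones(20))
            v = rng.dirichlet(np.ones(20))
            assert 0.0 <= shannon_distance(u, v) <= np.log(2.0) + 1e-12

    def test_metric_symmetry(self):
        rng = np.random.default_rng(3)
        vals_a = rng.uniform(0.1, 1, size=(30, 3))
        vals_b = rng.uniform(0.1, 1, size=(30, 2))
        genes = [f"g{i}" for i in range(30)]
        sa = sm(vals_a, ["a1", "a2", "a3"], genes, "A")
        sb = sm(vals_b, ["b1", "b2"], genes, "B")
        pairs = [(g, g) for g in genes]
        for metric in METRICS:
            d_ab = stage_distance(sa, sb, pairs, metric).values.to_numpy()
            d_ba = stage_distance(sb, sa, pairs, metric).values.to_numpy()
            assert np.allclose(d_ab, d_ba.T), metric

    def test_std_euclidean_reduces_to_euclidean_at_unit_variance(self):
        # two genes whose values over all 4 stage profiles have variance 1
        vals_a = np.array([[0.0, 2.0], [2.0, 0.0]])
        vals_b = np.array([[1.0, 3.0], [3.0, 1.0]])
        genes = ["g1", "g2"]
        sa = sm(vals_a, ["a1", "a2"], genes, "A")
        sb = sm(vals_b, ["b1", "b2"], genes, "B")
        pairs = [(g, g) for g in genes]
        var = np.vstack([vals_a.T, vals_b.T]).var(axis=0)
        assert np.allclose(var, 1.25)
        d_std = stage_distance(sa, sb, pairs, "std_euclidean").values.to_numpy()
        d_euc = stage_distance(sa, sb, pairs, "euclidean").values.to_numpy()
        assert np.allclose(d_std, d_euc / np.sqrt(1.25))


class TestMinDistanceSummary:
    def test_global_argmin(self):
        from hourglass_kit.hourglass import DistanceMatrix

        m = DistanceMatrix(
            values=pd.DataFrame([[1.0, 2.0], [0.5, 3.0]], index=["a1", "a2"], columns=["b1", "b2"]),
            metric="euclidean",
            n_genes=2,
        )
        s = min_distance_summary(m)
        assert s.global_pair == ("a2", "b1")
        assert s.global_value == 0.5
        assert s.per_b_stage.set_index("b_stage").loc["b2", "best_a_stage"] == "a1"

    def test_constant_matrix_reports_all_ties(self):
        from hourglass_kit.hourglass import DistanceMatrix

        m = DistanceMatrix(
            values=pd.DataFrame(np.ones((2, 2)), index=["a1", "a2"], columns=["b1", "b2"]),
            metric="euclidean",
            n_genes=1,
        )
        s = min_distance_summary(m)
        assert len(s.global_ties) == 4


class TestConcatVectors:
    def test_dimension_and_round_trip(self):
        genes = ["g1", "g2"]
        sa = sm(np.arange(12.0).reshape(2, 6), [f"a{i}" for i in range(6)], genes, "A")
        sb = sm(np.arange(8.0).reshape(2, 4), [f"b{i}" for i in range(4)], genes, "B")
        vec = concat_vectors(sa, sb, [(g, g) for g in genes])
        assert vec.shape == (2, 10)
        # slicing recovers the original per-species profiles
        assert np.allclose(vec.iloc[0, :6], sa.values.iloc[0])
        assert np.allclose(vec.iloc[0, 6:], sb.values.iloc[0])

    def test_zero_fill_for_genes_missing_in_one_species(self):
        sa = sm([[1.0, 2.0]], ["a1", "a2"], ["g1"], "A")
        sb = sm([[3.0]], ["b1"], ["g9"], "B")
        vec = concat_vectors(sa, sb, [("g1", "gX")], missing="zero")
        assert np.allclose(vec.loc["g1"], [1.0, 2.0, 0.0])
        assert np.allclose(vec.loc["g9"], [0.0, 0.0, 3.0])


class TestClusterGenes:
    def test_separated_blobs_perfectly_split(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 0.1, (20, 4)), rng.normal(5, 0.1, (20, 4))])
        vec = pd.DataFrame(x, index=[f"g{i}" for i in range(40)])
        labels = cluster_genes(vec, k=2)
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert set(labels) == {1, 2}

    def test_identical_vectors_collapse_at_any_positive_cut(self):
        vec = pd.DataFrame(np.ones((10, 3)))
        labels = cluster_genes(vec, height=0.5)
        assert labels.nunique() == 1

    def test_embedder_is_injected(self):
        vec = pd.DataFrame(np.eye(4))
        calls = []

        def embedder(x):
            calls.append(x.shape)
            return x[:, :2]

        cluster_genes(vec, k=2, embedder=embedder)
        assert calls == [(4, 4)]

    def test_fewer_vectors_than_clusters_rejected(self):
        with pytest.raises(ValueError):
            cluster_genes(pd.DataFrame(np.ones((2, 3))), k=5)

    def test_planted_gene_classes_recovered_at_low_noise(self):
        """Seven planted expression classes separate cleanly at k=7."""
        from sklearn.metrics import adjusted_rand_score

        from hourglass_kit.expression import filter_expressed, scale
        from hourglass_kit.synthetic import ExpressionSimConfig, simulate_expression

        cfg = ExpressionSimConfig(seed=3, noise_cv=0.02, hourglass_strength=0.0)
        ma, mb, truth = simulate_expression(cfg)
        sa = scale(ma.subset(filter_expressed(ma)), "max1")
        sb = scale(mb.subset(filter_expressed(mb)), "max1")
        vec = concat_vectors(sa, sb, sorted(truth.ortholog_truth), missing="zero")
        labels = cluster_genes(vec, k=7)
        truth_labels = [truth.gene_class[g] for g in vec.index]
        assert adjusted_rand_score(truth_labels, labels.to_numpy()) >= 0.9


class TestStagePCA:
    def test_rank_one_matrix_explained_by_pc1(self):
        # all stage profiles proportional to one gene pattern -> PC1 takes 100%
        genes = [f"g{i}" for i in range(5)]
        pattern = np.arange(1, 6.0)
        sa = sm(np.column_stack([pattern, 2 * pattern]), ["a1", "a2"], genes, "A")
        sb = sm(np.column_stack([3 * pattern, 4 * pattern]), ["b1", "b2"], genes, "B")
        pca = pca_stages(sa, sb, [(g, g) for g in genes])
        assert pca.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_reconstruction_and_variance_ratios(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(30)]
        sa = sm(rng.uniform(0, 1, (30, 3)), ["a1", "a2", "a3"], genes, "A")
        sb = sm(rng.uniform(0, 1, (30, 2)), ["b1", "b2"], genes, "B")
        pairs = [(g, g) for g in genes]
        pca = pca_stages(sa, sb, pairs)
        assert pca.explained_variance_ratio.sum() == pytest.approx(1.0)
        x = np.vstack([sa.values.to_numpy().T, sb.values.to_numpy().T])
        recon = pca.scores.to_numpy() @ pca.loadings.to_numpy().T + x.mean(axis=0)
        assert np.allclose(recon, x, atol=1e-10)
        # orthogonal score columns
        gram = pca.scores.to_numpy().T @ pca.scores.to_numpy()
        assert np.allclose(gram, np.diag(np.diag(gram)), atol=1e-8)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(10)]
        sa = sm(rng.uniform(0, 1, (10, 2)), ["a1", "a2"], genes, "A")
        sb = sm(rng.uniform(0, 1, (10, 2)), ["b1", "b2"], genes, "B")
        pca = pca_stages(sa, sb, [(g, g) for g in genes])
        for col in pca.loadings.columns:
            v = pca.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] >= 0


class TestStageAssociation:
    def test_single_peak_gene_counted_once(self):
        m = make_matrix("sp", ["g"], list("abcd"), [[10.0, 0.0, 0.0, 0.0]])
        tab = stage_associated_counts(m)
        # z1 = 7.5 / sqrt(18.75) ~ 1.732 and TPM >= 1 at stage a only
        assert tab.zscores.loc["g", "a"] == pytest.approx(7.5 / np.sqrt(18.75))
        assert tab.counts.tolist() == [1, 0, 0, 0]

    def test_flat_gene_never_counted_and_zscores_sum_to_zero(self):
        m = make_matrix("sp", ["g1", "g2"], list("abc"), [[5.0, 5.0, 5.0], [1.0, 2.0, 9.0]])
        tab = stage_associated_counts(m)
        assert np.isnan(tab.zscores.loc["g1"]).all()
        assert tab.zscores.loc["g2"].sum() == pytest.approx(0.0, abs=1e-12)

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(6)
        means = rng.uniform(0, 5, size=(1000, 4))
        m = make_matrix("sp", [f"g{i}" for i in range(1000)], list("abcd"), means)
        counts = stage_associated_counts(m).counts.to_numpy()
        brute = np.zeros(4, dtype=int)
        for row in means:
            sd = row.std()
            if sd == 0:
                continue
            z = (row - row.mean()) / sd
            brute += (row >= 1.0) & (np.abs(z) >= 1.0)
        assert (counts == brute).all()


class TestTissueEntropy:
    def test_closed_forms(self):
        ref = pd.DataFrame(
            {
                "single": [1.0, 0.0, 0.0, 0.0],
                "uniform": [2.0, 2.0, 2.0, 2.0],
                "mixed": [0.5, 0.25, 0.25, 0.0],
                "silent": [0.0, 0.0, 0.0, 0.0],
            },
            index=[f"t{i}" for i in range(4)],
        )
        e = tissue_entropy(ref)
        assert e.entropy["single"] == pytest.approx(0.0)
        assert e.entropy["uniform"] == pytest.approx(np.log(4.0))
        assert e.entropy["mixed"] == pytest.approx(1.0397207708399179)
        assert np.isnan(e.entropy["silent"])
        assert e.probabilities["mixed"].sum() == pytest.approx(1.0)

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValueError):
            tissue_entropy(pd.DataFrame({"g": [-1.0, 2.0]}))

    def test_entropy_bounded_by_log_k(self):
        rng = np.random.default_rng(7)
        ref = pd.DataFrame(rng.uniform(0, 10, size=(12, 50)))
        e = tissue_entropy(ref)
        assert ((e.entropy >= 0) & (e.entropy <= np.log(12) + 1e-12)).all()


class TestTissueAssociatedCounts:
    def test_zero_entropy_genes_never_counted_in_ge_direction(self):
        m = make_matrix("sp", ["g"], ["a", "b"], [[5.0, 5.0]])
        ref = pd.DataFrame({"g": [1.0, 0.0]}, index=["t1", "t2"])
        counts = tissue_associated_counts(m, tissue_entropy(ref))
        assert counts.tolist() == [0, 0]

    def test_threshold_is_inclusive(self):
        m = make_matrix("sp", ["g"], ["a", "b"], [[5.0, 0.5]])
        # entropy exactly 0.65: p solves -p ln p - (1-p) ln(1-p) = 0.65
        from scipy.optimize import brentq

        p = brentq(lambda q: -(q * np.log(q) + (1 - q) * np.log(1 - q)) - 0.65, 1e-9, 0.5)
        ref = pd.DataFrame({"g": [p, 1 - p]}, index=["t1", "t2"])
        e = tissue_entropy(ref)
        assert e.entropy["g"] == pytest.approx(0.65)
        counts = tissue_associated_counts(m, e, tpm_min=1.0, h_thr=e.entropy["g"])
        assert counts.tolist() == [1, 0]  # stage b fails the TPM floor

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(8)
        n = 1000
        genes = [f"g{i}" for i in range(n)]
        means = rng.uniform(0, 5, size=(n, 3))
        m = make_matrix("sp", genes, list("abc"), means)
        ref = pd.DataFrame(rng.uniform(0, 4, size=(10, n)) ** 3, columns=genes)
        e = tissue_entropy(ref)
        counts = tissue_associated_counts(m, e).to_numpy()
        h = e.entropy.to_numpy()
        brute = ((means >= 1.0) & (h >= 0.65)[:, None]).sum(axis=0)
        assert (counts == brute).all()
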