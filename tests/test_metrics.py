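import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr

from gexgan import (
    DistanceMatrix,
    ExpressionMatrix,
    RegulatoryNetwork,
    cluster_match,
    cosine_similarity,
    dendrogram_distance_matrix,
    gamma,
    pearson_dissimilarity_matrix,
    realism_report,
    s_dend,
    s_dist,
    s_tf_tg,
    s_tg_tg,
    tf_tg_vector,
    tstr_classification,
)
from gexgan.metrics import RealismReport, gamma_values


def _expr(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        values, genes, [f"s{i}" for i in range(values.shape[0])]
    )


def _sym(n, seed):
    rng = np.random.default_rng(seed)
    A = rng.random((n, n))
    A = 0.5 * (A + A.T)
    np.fill_diagonal(A, 0.0)
    return A


class TestPearsonDissimilarity:
    def test_copied_gene_distance_zero(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=30)
        X = _expr(np.column_stack([col, 2.0 * col + 1.0]))
        D = pearson_dissimilarity_matrix(X)
        assert D.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_gene_distance_two(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=30)
        X = _expr(np.column_stack([col, -col]))
        D = pearson_dissimilarity_matrix(X)
        assert D.values[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_independent_genes_near_one(self):
        rng = np.random.default_rng(2)
        X = _expr(rng.normal(size=(10000, 5)))
        D = pearson_dissimilarity_matrix(X)
        off = D.values[np.triu_indices(5, k=1)]
        assert np.abs(off - 1.0).max() < 0.05

    def test_zero_variance_gene_gets_unit_distance_and_warns(self):
        X = _expr(np.column_stack([np.arange(10.0), np.full(10, 2.0)]))
        with pytest.warns(UserWarning, match="zero-variance"):
            D = pearson_dissimilarity_matrix(X)
        assert D.values[0, 1] == 1.0
        assert D.values[1, 1] == 0.0


class TestGamma:
    def test_self_correlation_is_one(self):
        A = DistanceMatrix(_sym(6, 0), [f"g{j}" for j in range(6)])
        assert gamma(A, A) == pytest.approx(1.0, abs=1e-12)

    def test_positive_affine_invariance(self):
        vals = _sym(6, 1)
        ids = [f"g{j}" for j in range(6)]
        A = DistanceMatrix(vals, ids)
        B = DistanceMatrix(3.0 * vals + 0.7, ids)
        assert gamma(A, B) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_three_gene_value(self):
        # upper triangles (1,2,3) and (1,3,2): Pearson r = 0.5
        def mat(u12, u13, u23):
            M = np.zeros((3, 3))
            M[0, 1] = M[1, 0] = u12
            M[0, 2] = M[2, 0] = u13
            M[1, 2] = M[2, 1] = u23
            return M

        ids = ["a", "b", "c"]
        A = DistanceMatrix(mat(1, 2, 3), ids)
        B = DistanceMatrix(mat(1, 3, 2), ids)
        assert gamma(A, B) == pytest.approx(0.5, abs=1e-12)
        assert gamma(B, A) == pytest.approx(0.5, abs=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_pearson_oracle_on_random_matrices(self, seed):
        A, B = _sym(10, seed), _sym(10, seed + 1)
        iu = np.triu_indices(10, k=1)
        expected = pearsonr(A[iu], B[iu]).statistic  # independent oracle
        assert gamma_values(A, B) == pytest.approx(expected, abs=1e-12)

    def test_constant_triangle_rejected(self):
        ids = ["a", "b", "c"]
        A = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids)
        B = DistanceMatrix(_sym(3, 2), ids)
        with pytest.raises(ValueError, match="first"):
            gamma(A, B)


class TestSDist:
    def test_identity_scores_one(self, small_expression):
        assert s_dist(small_expression, small_expression) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_sample_order_invariance(self, small_expression):
        rng = np.random.default_rng(3)
        perm = rng.permutation(small_expression.n_samples)
        Z = ExpressionMatrix(
            small_expression.values[perm],
            list(small_expression.gene_ids),
            [small_expression.sample_ids[i] for i in perm],
        )
        assert s_dist(small_expression, Z) == pytest.approx(1.0, abs=1e-12)

    def test_alignment_by_gene_id_not_position(self, small_expression):
        Z = small_expression.reorder_genes(
            list(reversed(small_expression.gene_ids))
        )
        assert s_dist(small_expression, Z) == pytest.approx(1.0, abs=1e-12)

    def test_gene_set_mismatch_lists_difference(self, small_expression):
        Z = ExpressionMatrix(
            small_expression.values,
            ["other" + g for g in small_expression.gene_ids],
            list(small_expression.sample_ids),
        )
        with pytest.raises(ValueError, match="otherg0"):
            s_dist(small_expression, Z)


class TestDendrogram:
    def test_two_genes_single_merge(self):
        D = DistanceMatrix(np.array([[0.0, 0.4], [0.4, 0.0]]), ["a", "b"])
        C = dendrogram_distance_matrix(D)
        assert C.values[0, 1] == pytest.approx(0.4)

    def test_hand_traced_complete_linkage(self):
        # merge {1,2} at 1; then {1,2} joins 3 at max(4,5) = 5
        vals = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        D = DistanceMatrix(vals, ["a", "b", "c"])
        C = dendrogram_distance_matrix(D, "complete")
        assert C.values[0, 1] == pytest.approx(1.0)
        assert C.values[0, 2] == pytest.approx(5.0)
        assert C.values[1, 2] == pytest.approx(5.0)

    @pytest.mark.parametrize("linkage", ["complete", "average", "single"])
    def test_ultrametric_inequality(self, linkage):
        D = DistanceMatrix(_sym(8, 4), [f"g{j}" for j in range(8)])
        C = dendrogram_distance_matrix(D, linkage).values
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert C[i, j] <= max(C[i, k], C[k, j]) + 1e-10

    def test_matches_brute_force_agglomeration(self):
        # independent complete-linkage oracle on small matrices
        def brute_cophenetic(D):
            n = D.shape[0]
            clusters = [{i} for i in range(n)]
            C = np.zeros_like(D)
            while len(clusters) > 1:
                best = None
                for a in range(len(clusters)):
                    for b in range(a + 1, len(clusters)):
                        d = max(
                            D[i, j]
                            for i in clusters[a]
                            for j in clusters[b]
                        )
                        if best is None or d < best[0]:
                            best = (d, a, b)
                d, a, b = best
                for i in clusters[a]:
                    for j in clusters[b]:
                        C[i, j] = C[j, i] = d
                clusters[a] = clusters[a] | clusters[b]
                del clusters[b]
            return C

        for seed in range(5):
            vals = _sym(6, 100 + seed)
            D = DistanceMatrix(vals, [f"g{j}" for j in range(6)])
            C = dendrogram_distance_matrix(D, "complete")
            assert np.allclose(C.values, brute_cophenetic(vals), atol=1e-10)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="2"):
            dendrogram_distance_matrix(DistanceMatrix(np.zeros((1, 1)), ["a"]))

    def test_unknown_linkage_rejected(self):
        D = DistanceMatrix(_sym(3, 0), ["a", "b", "c"])
        with pytest.raises(ValueError, match="linkage"):
            dendrogram_distance_matrix(D, "ward")


class TestSDend:
    def test_identity_scores_one(self, small_expression):
        assert s_dend(small_expression, small_expression) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_need_not_track_distance_agreement(self):
        # two distance structures whose raw upper triangles correlate highly
        # while their dendrogram (cophenetic) structures diverge
        rng = np.random.default_rng(0)
        found = False
        for _ in range(500):
            A, B = _sym(4, rng.integers(2**31)), None
            B = A + rng.normal(0.0, 0.12, size=A.shape)
            B = 0.5 * (B + B.T)
            np.fill_diagonal(B, 0.0)
            B = np.abs(B)
            try:
                g_raw = gamma_values(A, B)
                CA = dendrogram_distance_matrix(
                    DistanceMatrix(A, list("abcd"))
                ).values
                CB = dendrogram_distance_matrix(
                    DistanceMatrix(B, list("abcd"))
                ).values
                g_dend = gamma_values(CA, CB)
            except ValueError:
                continue
            if g_raw > 0.85 and g_dend < g_raw - 0.3:
                found = True
                break
        assert found


class TestCosine:
    def test_self_similarity(self):
        assert cosine_similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_positive_scale_invariance(self):
        a = np.array([0.3, 0.7, 0.1])
        assert cosine_similarity(a, 3.0 * a) == pytest.approx(1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cosine_similarity([0, 0], [1, 2])


def _star_data(seed=0, n_targets=3, m=60):
    """Expression for a star GRN TF -> {T1..Tk} with known geometry."""
    rng = np.random.default_rng(seed)
    tf = rng.normal(size=m)
    cols = {"TF1": tf}
    for i in range(n_targets):
        cols[f"T{i + 1}"] = 0.8 * tf + rng.normal(0, 0.6, size=m)
    genes = sorted(cols)
    X = ExpressionMatrix(
        np.column_stack([cols[g] for g in genes]), genes,
        [f"s{i}" for i in range(m)],
    )
    net = RegulatoryNetwork({("TF1", f"T{i + 1}") for i in range(n_targets)})
    return X, net


class TestTfTgVector:
    def test_length_and_lexicographic_order(self):
        X, net = _star_data()
        D = pearson_dissimilarity_matrix(X)
        v = tf_tg_vector(D, "TF1", net)
        assert v.shape == (3,)
        assert np.array_equal(
            v, [D.entry("TF1", "T1"), D.entry("TF1", "T2"), D.entry("TF1", "T3")]
        )

    def test_target_identical_to_tf_has_zero_entry(self):
        rng = np.random.default_rng(1)
        tf = rng.normal(size=40)
        X = ExpressionMatrix(
            np.column_stack([tf, tf, rng.normal(size=40)]),
            ["TF1", "T1", "T2"],
            [f"s{i}" for i in range(40)],
        )
        net = RegulatoryNetwork({("TF1", "T1"), ("TF1", "T2")})
        v = tf_tg_vector(pearson_dissimilarity_matrix(X), "TF1", net)
        assert v[0] == pytest.approx(0.0, abs=1e-12)

    def test_missing_gene_named(self):
        X, net = _star_data()
        D = pearson_dissimilarity_matrix(X)
        bigger = RegulatoryNetwork(net.edges | {("TF1", "absent")})
        with pytest.raises(KeyError, match="absent"):
            tf_tg_vector(D, "TF1", bigger)


class TestGrnScores:
    def test_identity_scores_one(self):
        X, net = _star_data()
        assert s_tf_tg(X, X, net) == pytest.approx(1.0, abs=1e-12)
        assert s_tg_tg(X, X, net) == pytest.approx(1.0, abs=1e-12)

    def test_single_tf_reduces_to_plain_cosine(self):
        X, net = _star_data(seed=2)
        Z, _ = _star_data(seed=3)
        from gexgan.metrics import pearson_dissimilarity_values

        dx = pearson_dissimilarity_values(X.values)
        dz = pearson_dissimilarity_values(Z.values)
        genes = X.gene_ids
        f = genes.index("TF1")
        cols = [genes.index(t) for t in ["T1", "T2", "T3"]]
        expected = cosine_similarity(dx[f, cols], dz[f, cols])
        assert s_tf_tg(X, Z, net) == pytest.approx(expected, abs=1e-12)

    def test_weighted_mean_matches_brute_force(self):
        # TFs with regulon sizes 1 and 3: score = (1*c1 + 3*c2) / 4
        rng = np.random.default_rng(4)
        m = 50
        vals_x = rng.normal(size=(m, 6))
        vals_z = rng.normal(size=(m, 6))
        genes = ["A", "B", "u", "v", "w", "y"]
        X = _expr(vals_x, genes)
        Z = _expr(vals_z, genes)
        net = RegulatoryNetwork(
            {("A", "y"), ("B", "u"), ("B", "v"), ("B", "w")}
        )
        from gexgan.metrics import pearson_dissimilarity_values

        dx = pearson_dissimilarity_values(vals_x)
        dz = pearson_dissimilarity_values(vals_z)
        gi = {g: i for i, g in enumerate(genes)}
        c1 = cosine_similarity(
            [dx[gi["A"], gi["y"]]], [dz[gi["A"], gi["y"]]]
        )
        cols = [gi["u"], gi["v"], gi["w"]]
        c2 = cosine_similarity(dx[gi["B"], cols], dz[gi["B"], cols])
        assert s_tf_tg(X, Z, net) == pytest.approx(
            (1 * c1 + 3 * c2) / 4, abs=1e-12
        )

    def test_tg_tg_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(5)
        X, net = _star_data(seed=6)
        Z = _expr(rng.normal(size=(60, 4)), list(X.gene_ids))
        from gexgan.metrics import pearson_dissimilarity_values

        dx = pearson_dissimilarity_values(X.values)
        dz = pearson_dissimilarity_values(Z.values)
        gi = {g: i for i, g in enumerate(X.gene_ids)}
        targets = ["T1", "T2", "T3"]
        sims = []
        for g in targets:
            others = [gi[t] for t in targets if t != g]
            sims.append(
                cosine_similarity(dx[gi[g], others], dz[gi[g], others])
            )
        assert s_tg_tg(X, Z, net) == pytest.approx(np.mean(sims), abs=1e-12)

    def test_two_target_regulon_uses_scalar_cosine(self):
        rng = np.random.default_rng(7)
        genes = ["TF1", "T1", "T2"]
        X = _expr(rng.normal(size=(50, 3)), genes)
        Z = _expr(rng.normal(size=(50, 3)), genes)
        net = RegulatoryNetwork({("TF1", "T1"), ("TF1", "T2")})
        # both scalar distances are positive => each cosine is exactly 1
        assert s_tg_tg(X, Z, net) == pytest.approx(1.0, abs=1e-12)

    def test_no_eligible_tf_rejected(self):
        X, _ = _star_data()
        lonely = RegulatoryNetwork({("nope", "nothere")})
        with pytest.raises(ValueError):
            s_tf_tg(X, X, lonely)
        single = RegulatoryNetwork({("TF1", "T1")})
        with pytest.raises(ValueError, match="2"):
            s_tg_tg(X, X, single)

    def test_consistent_gene_permutation_invariance(self):
        X, net = _star_data(seed=8)
        rng = np.random.default_rng(9)
        Z = _expr(rng.normal(size=(60, 4)), list(X.gene_ids))
        perm = ["T2", "TF1", "T3", "T1"]
        Xp, Zp = X.reorder_genes(perm), Z.reorder_genes(perm)
        for fn in (s_dist, s_dend):
            assert fn(Xp, Zp) == pytest.approx(fn(X, Z), abs=1e-10)
        for fn in (s_tf_tg, s_tg_tg):
            assert fn(Xp, Zp, net) == pytest.approx(fn(X, Z, net), abs=1e-10)


class TestRealismReport:
    def test_identity_report_all_ones(self):
        X, net = _star_data(n_targets=4)
        rep = realism_report(X, X, net=net)
        for name in RealismReport.COLUMNS:
            assert getattr(rep, name) == pytest.approx(1.0, abs=1e-10)

    def test_grn_scores_absent_without_network(self, small_expression):
        rep = realism_report(small_expression, small_expression)
        assert rep.s_tf_tg is None and rep.s_tg_tg is None

    def test_json_round_trip_and_tsv_shape(self, small_expression):
        rep = realism_report(small_expression, small_expression)
        back = RealismReport.from_json(rep.to_json())
        assert back.to_dict() == rep.to_dict()
        lines = rep.to_tsv().strip().split("\n")
        assert lines[0].split("\t") == list(RealismReport.COLUMNS)
        assert lines[1].split("\t")[2] == "NA"


class TestClusterMatch:
    def test_identical_data_matches_perfectly(self):
        rng = np.random.default_rng(10)
        X = _expr(rng.normal(size=(30, 50)))
        table = cluster_match(X, X, k=10, seed=0)
        assert (table["shared_genes"] == table["real_size"]).all()
        assert table["shared_genes"].sum() == 50

    def test_sample_permutation_leaves_counts(self):
        rng = np.random.default_rng(11)
        X = _expr(rng.normal(size=(30, 40)))
        perm = rng.permutation(30)
        Z = ExpressionMatrix(
            X.values[perm], list(X.gene_ids),
            [X.sample_ids[i] for i in perm],
        )
        a = cluster_match(X, X, k=5, seed=1)
        b = cluster_match(X, Z, k=5, seed=1)
        assert a["shared_genes"].sum() == b["shared_genes"].sum()

    def test_k_larger_than_gene_count_rejected(self):
        rng = np.random.default_rng(12)
        X = _expr(rng.normal(size=(10, 4)))
        with pytest.raises(ValueError, match="k="):
            cluster_match(X, X, k=10)


class TestTstrClassification:
    def _labelled(self, seed, m=300, separation=4.0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, size=m)
        vals = rng.normal(size=(m, 10))
        vals[:, 0] += separation * y
        return _expr(vals), np.where(y == 1, "disease", "normal")

    def test_separable_fixture_reaches_high_auc(self):
        Z, yz = self._labelled(0)
        X, yx = self._labelled(1)
        res = tstr_classification(Z, yz, X, yx, n_runs=2, seed=0)
        assert res["auc_mean"] > 0.95

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(2)
        Z, yz = self._labelled(3, separation=0.0)
        X, yx = self._labelled(4, separation=0.0)
        res = tstr_classification(Z, rng.permutation(yz), X, yx, n_runs=2, seed=1)
        assert abs(res["auc_mean"] - 0.5) < 0.12

    def test_run_averaging_reports_spread(self):
        Z, yz = self._labelled(5)
        X, yx = self._labelled(6)
        res = tstr_classification(Z, yz, X, yx, n_runs=5, seed=2)
        assert len(res["auc_runs"]) == 5 and res["n_runs"] == 5
        assert res["auc_sd"] >= 0.0 and res["f1_sd"] >= 0.0

    def test_single_class_rejected(self):
        Z, _ = self._labelled(7)
        X, yx = self._labelled(8)
        with pytest.raises(ValueError, match="two classes"):
            tstr_classification(Z, ["same"] * Z.n_samples, X, yx)
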