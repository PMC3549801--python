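import numpy as np
import pytest

from cisnet import (
    CoRegulatoryNetwork,
    EnrichmentResult,
    build_coreg_network,
    compare_networks,
    evaluate_model_per_array,
    fit_expression_model,
    gene_similarity,
    intersect_networks,
    network_from_edgelist,
    pr_curve,
    select_top_motifs,
)
from cisnet.coexpression import ExpressionMatrix
from cisnet.evaluation import plot_pr_curve


def make_result(scores, gene_ids=None, motifs=None):
    scores = np.asarray(scores, dtype=float)
    return EnrichmentResult(
        gene_ids=gene_ids or [f"g{i}" for i in range(scores.shape[0])],
        motifs=motifs or [f"M{j:02d}" for j in range(scores.shape[1])],
        pvalues=np.full(scores.shape, 0.5),
        scores=scores,
    )


class TestGeneSimilarity:
    def test_identical_rows_give_one(self):
        sim = gene_similarity(make_result([[1, 2, 3], [1, 2, 3]]))
        assert sim[0, 1] == pytest.approx(1.0)

    def test_reversed_rows_give_minus_one(self):
        sim = gene_similarity(make_result([[1, 2, 3], [3, 2, 1]]))
        assert sim[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_rows_marked_undefined(self):
        sim = gene_similarity(make_result([[1, 1, 1], [1, 2, 3], [0, 1, 5]]))
        assert np.isnan(sim[0, 1]) and np.isnan(sim[2, 0])
        assert np.isfinite(sim[1, 2])
        assert sim[0, 0] == 1.0  # diagonal stays defined


class TestCoregNetwork:
    sim3 = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.6], [0.1, 0.6, 1.0]])

    def test_threshold_one_gives_empty_network(self):
        net = build_coreg_network(self.sim3, 1.0, ["a", "b", "c"])
        assert net.edges == set()

    def test_threshold_below_minus_one_gives_complete_graph(self):
        net = build_coreg_network(self.sim3, -1.5, ["a", "b", "c"])
        assert len(net.edges) == 3

    def test_simple_thresholding(self):
        net = build_coreg_network(self.sim3, 0.5, ["a", "b", "c"])
        assert net.edges == {("a", "b"), ("b", "c")}

    def test_nan_entries_never_edges(self):
        sim = self.sim3.copy()
        sim[0, 1] = sim[1, 0] = np.nan
        net = build_coreg_network(sim, -2.0, ["a", "b", "c"])
        assert ("a", "b") not in net.edges
        assert len(net.edges) == 2


class TestIntersectAndCompare:
    def test_identical_node_sets_unchanged(self):
        n1 = CoRegulatoryNetwork(["a", "b"], {("a", "b")})
        n2 = CoRegulatoryNetwork(["a", "b"], set())
        r1, r2 = intersect_networks(n1, n2)
        assert r1.edges == n1.edges and set(r2.gene_ids) == {"a", "b"}

    def test_edges_outside_common_genes_dropped(self):
        n1 = CoRegulatoryNetwork(["a", "b", "c"], {("a", "b")})
        n2 = CoRegulatoryNetwork(["b", "c", "d"], {("b", "c")})
        r1, r2 = intersect_networks(n1, n2)
        assert set(r1.gene_ids) == {"b", "c"}
        assert r1.edges == set()
        assert r2.edges == {("b", "c")}

    def test_disjoint_node_sets_rejected(self):
        n1 = CoRegulatoryNetwork(["a"], set())
        n2 = CoRegulatoryNetwork(["b"], set())
        with pytest.raises(ValueError):
            intersect_networks(n1, n2)

    def test_identity_comparison(self):
        genes = list("abcde")
        edges = {("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")}
        m = compare_networks(
            CoRegulatoryNetwork(genes, set(edges)),
            CoRegulatoryNetwork(genes, set(edges)),
        )
        assert (m.TP, m.FP, m.FN, m.TN) == (4, 0, 0, 6)
        assert m.PPV == 1.0 and m.TPR == 1.0

    def test_hand_enumerated_confusion_matrix(self):
        genes = list("abcd")
        m = compare_networks(
            CoRegulatoryNetwork(genes, {("a", "b"), ("b", "c")}),
            CoRegulatoryNetwork(genes, {("b", "c"), ("c", "d")}),
        )
        assert (m.TP, m.FP, m.FN, m.TN) == (1, 1, 1, 3)
        assert m.PPV == 0.5 and m.TPR == 0.5

    def test_empty_prediction_degenerate_conventions(self):
        genes = list("abc")
        m = compare_networks(
            CoRegulatoryNetwork(genes, set()),
            CoRegulatoryNetwork(genes, {("a", "b")}),
        )
        assert m.TP == 0 and m.PPV == 0.0 and m.TPR == 0.0

    def test_differing_node_sets_rejected(self):
        with pytest.raises(ValueError):
            compare_networks(
                CoRegulatoryNetwork(["a", "b"], set()),
                CoRegulatoryNetwork(["a", "c"], set()),
            )

    def test_confusion_identities_on_random_pairs(self, rng):
        genes = [f"g{i}" for i in range(10)]
        pairs = [
            (genes[i], genes[j])
            for i in range(10)
            for j in range(i + 1, 10)
        ]
        total = len(pairs)
        for _ in range(1000):
            e1 = {p for p in pairs if rng.random() < 0.3}
            e2 = {p for p in pairs if rng.random() < 0.3}
            m = compare_networks(
                CoRegulatoryNetwork(genes, e1), CoRegulatoryNetwork(genes, e2)
            )
            assert m.TP + m.FP == len(e1)
            assert m.TP + m.FN == len(e2)
            assert m.TP + m.FP + m.TN + m.FN == total
            assert m.PPV == (m.TP / len(e1) if e1 else 0.0)
            assert m.TPR == (m.TP / len(e2) if e2 else 0.0)

    def test_comparison_invariant_under_relabeling(self, rng):
        genes = [f"g{i}" for i in range(8)]
        pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]]
        e1 = {p for p in pairs if rng.random() < 0.4}
        e2 = {p for p in pairs if rng.random() < 0.4}
        m = compare_networks(
            CoRegulatoryNetwork(genes, e1), CoRegulatoryNetwork(genes, e2)
        )
        mapping = {g: f"x{i}" for i, g in enumerate(genes)}

        def relabel(edges):
            return {tuple(sorted((mapping[a], mapping[b]))) for a, b in edges}

        m2 = compare_networks(
            CoRegulatoryNetwork(list(mapping.values()), relabel(e1)),
            CoRegulatoryNetwork(list(mapping.values()), relabel(e2)),
        )
        assert (m.TP, m.FP, m.TN, m.FN) == (m2.TP, m2.FP, m2.TN, m2.FN)


class TestPrCurve:
    genes = list("abcd")
    reference = CoRegulatoryNetwork(genes, {("b", "c"), ("c", "d")})
    sim = np.array(
        [
            [1.0, 0.9, 0.2, -0.5],
            [0.9, 1.0, 0.7, 0.0],
            [0.2, 0.7, 1.0, 0.4],
            [-0.5, 0.0, 0.4, 1.0],
        ]
    )

    def test_threshold_above_max_gives_empty_prediction(self):
        table = pr_curve(self.sim, self.genes, self.reference, thresholds=[0.95])
        assert table.iloc[0]["PPV"] == 0.0 and table.iloc[0]["TPR"] == 0.0

    def test_threshold_below_min_gives_full_recall(self):
        table = pr_curve(self.sim, self.genes, self.reference, thresholds=[-0.9])
        assert table.iloc[0]["TPR"] == 1.0

    def test_matches_compare_networks_per_threshold(self):
        table = pr_curve(
            self.sim, self.genes, self.reference, thresholds=[0.65, 0.3]
        )
        for _, row in table.iterrows():
            pred = build_coreg_network(self.sim, row["threshold"], self.genes)
            m = compare_networks(pred, self.reference)
            assert (row["TP"], row["FP"], row["TN"], row["FN"]) == (
                m.TP, m.FP, m.TN, m.FN,
            )

    def test_auto_sweep_recall_monotone(self):
        table = pr_curve(self.sim, self.genes, self.reference, thresholds="auto")
        assert (table["threshold"].diff().dropna() <= 0).all()
        assert (table["TPR"].diff().dropna() >= -1e-12).all()

    def test_plot_written(self, tmp_path):
        table = pr_curve(self.sim, self.genes, self.reference, thresholds="auto")
        out = tmp_path / "pr.png"
        plot_pr_curve(table, out)
        assert out.stat().st_size > 0


class TestFeatureSelection:
    def test_perfectly_correlated_column_ranks_first(self, rng):
        y = rng.normal(size=20)
        scores = rng.normal(size=(20, 5))
        scores[:, 3] = y
        result = make_result(scores)
        assert select_top_motifs(result, y, 1) == [result.motifs[3]]

    def test_anticorrelated_column_selected_with_absolute(self, rng):
        y = rng.normal(size=20)
        scores = rng.normal(size=(20, 5)) * 0.01
        scores[:, 2] = -y
        result = make_result(scores)
        assert select_top_motifs(result, y, 1) == [result.motifs[2]]
        signed = select_top_motifs(result, y, 1, absolute=False)
        assert signed != [result.motifs[2]]

    def test_all_zero_variance_returns_empty(self):
        result = make_result(np.ones((5, 3)))
        assert select_top_motifs(result, np.arange(5.0), 2) == []

    def test_tie_broken_lexicographically(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        col = y.copy()
        result = make_result(
            np.column_stack([col, col]), motifs=["MB", "MA"]
        )
        assert select_top_motifs(result, y, 1) == ["MA"]


class TestRegression:
    def test_noiseless_recovery(self, rng):
        scores = np.abs(rng.normal(size=(50, 4)))
        result = make_result(scores, motifs=["AAAAAA", "CCCCCC", "GGGGGG", "TTTTTT"])
        y = 2.0 * scores[:, 0] + 1.0
        fit = fit_expression_model(result, y, n_features=1)
        assert fit.selected_motifs == ["AAAAAA"]
        assert fit.coefficients[0] == pytest.approx(2.0, abs=1e-8)
        assert fit.intercept == pytest.approx(1.0, abs=1e-8)
        assert fit.rmse == pytest.approx(0.0, abs=1e-8)
        assert fit.pcc == pytest.approx(1.0, abs=1e-8)

    def test_pure_noise_gives_small_pcc(self, rng):
        scores = rng.normal(size=(2000, 3))
        result = make_result(scores)
        y = rng.normal(size=2000)
        fit = fit_expression_model(result, y, n_features=3)
        assert abs(fit.pcc) < 0.15

    def test_intercept_only_model(self, rng):
        y = rng.normal(size=30)
        result = make_result(rng.normal(size=(30, 3)))
        fit = fit_expression_model(result, y, n_features=0)
        assert fit.selected_motifs == []
        assert fit.intercept == pytest.approx(y.mean())
        assert fit.rmse == pytest.approx(y.std())

    def test_coefficient_error_shrinks_with_n(self, rng):
        errors = []
        for n in (100, 400, 1600):
            scores = rng.normal(size=(n, 3))
            beta = np.array([1.5, -2.0, 0.5])
            y = scores @ beta + 0.3 + rng.normal(0, 1.0, size=n)
            result = make_result(scores)
            fit = fit_expression_model(result, y, n_features=3)
            coef = np.array(
                [fit.coefficients[fit.selected_motifs.index(m)]
                 for m in result.motifs]
            )
            errors.append(np.sqrt(np.mean((coef - beta) ** 2)))
        assert errors[0] > errors[1] > errors[2]

    def test_per_array_report_shape_and_determinism(self, rng):
        scores = rng.normal(size=(40, 6))
        result = make_result(scores)
        values = np.column_stack([scores @ rng.normal(size=6) for _ in range(2)])
        values = np.column_stack([values, values[:, 0]])  # duplicated array
        expr = ExpressionMatrix(result.gene_ids, ["a1", "a2", "a1copy"], values)
        report = evaluate_model_per_array(result, expr, n_features=2)
        assert list(report["array_id"]) == ["a1", "a2", "a1copy", "mean"]
        first = report.iloc[0]
        dup = report.iloc[2]
        assert first["rmse"] == pytest.approx(dup["rmse"])
        assert first["pcc"] == pytest.approx(dup["pcc"])

    def test_planted_linear_arrays_recovered(self, rng):
        # arrays linear in 3 planted columns + noise sigma = 0.1
        n = 200
        scores = np.abs(rng.normal(size=(n, 10)))
        result = make_result(scores)
        arrays = []
        for _ in range(4):
            w = rng.normal(size=3)
            arrays.append(scores[:, :3] @ w + rng.normal(0, 0.1, size=n))
        expr = ExpressionMatrix(
            result.gene_ids, [f"a{j}" for j in range(4)], np.column_stack(arrays)
        )
        report = evaluate_model_per_array(result, expr, n_features=3)
        mean_pcc = report[report["array_id"] == "mean"]["pcc"].iloc[0]
        assert mean_pcc > 0.9

    def test_gene_intersection_logged_and_applied(self, rng):
        scores = rng.normal(size=(10, 3))
        result = make_result(scores)
        expr = ExpressionMatrix(
            result.gene_ids[:6] + ["other"],
            ["a1", "a2", "a3"],
            rng.normal(size=(7, 3)),
        )
        report = evaluate_model_per_array(result, expr, n_features=1)
        assert len(report) == 4  # 3 arrays + mean

    def test_empty_gene_intersection_rejected(self, rng):
        result = make_result(rng.normal(size=(4, 2)))
        expr = ExpressionMatrix(["x1", "x2", "x3"], ["a1", "a2", "a3"],
                                rng.normal(size=(3, 3)))
        with pytest.raises(ValueError):
            evaluate_model_per_array(result, expr, n_features=1)


def test_reference_network_edgelist_reader(tmp_path):
    path = tmp_path / "ref.tsv"
    path.write_text("a\tb\nb\ta\nc\td\t0.7\n")
    net = network_from_edgelist(path)
    assert net.edges == {("a", "b"), ("c", "d")}
    assert set(net.gene_ids) == {"a", "b", "c", "d"}
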