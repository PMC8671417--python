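
import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subnet_attn import (
    ExpressionMatrix,
    SampleLabels,
    build_representation,
    closeness,
    fit_subnetwork_model,
    pair_features,
    represent,
    sas,
)
from subnet_attn.discovery import Subnetwork, SubnetworkPartition


class TestCloseness:
    def test_single_edge(self):
        c = closeness(nx.Graph([("A", "B")]))
        assert c["A"] == pytest.approx(1.0)
        assert c["B"] == pytest.approx(1.0)

    def test_path_graph(self):
        c = closeness(nx.path_graph(["A", "B", "C"]))
        assert c["B"] == pytest.approx(1.0)
        assert c["A"] == pytest.approx(2 / 3)
        assert c["C"] == pytest.approx(2 / 3)

    def test_isolated_node_in_three_node_graph(self):
        g = nx.Graph([("A", "B")])
        g.add_node("C")
        assert closeness(g)["C"] == 0.0

    def test_singleton_graph(self):
        g = nx.Graph()
        g.add_node("A")
        assert closeness(g)["A"] == 0.0


class TestSas:
    def test_hand_computed_single_edge(self):
        g = nx.Graph([("A", "B")])
        c = {"A": 1.0, "B": 1.0}
        # N=1/2 per ordered pair; ACT = 0.5 * 16/8 = 1 each; SAS = 2
        assert sas(g, c, {"A": 2.0, "B": 2.0}) == pytest.approx(2.0)

    def test_zero_expression_gives_zero(self):
        g = nx.Graph([("A", "B")])
        assert sas(g, closeness(g), {"A": 0.0, "B": 0.0}) == 0.0

    def test_edgeless_graph_gives_zero(self):
        g = nx.Graph()
        g.add_nodes_from(["A", "B"])
        assert sas(g, {"A": 0.0, "B": 0.0}, {"A": 5.0, "B": 1.0}) == 0.0

    def test_missing_gene_rejected(self):
        g = nx.Graph([("A", "B")])
        with pytest.raises(KeyError):
            sas(g, closeness(g), {"A": 1.0})

    def test_invariant_to_relabeling(self):
        g1 = nx.path_graph(["A", "B", "C"])
        g2 = nx.path_graph(["X", "Y", "Z"])
        e1 = {"A": 1.0, "B": 2.0, "C": 3.0}
        e2 = {"X": 1.0, "Y": 2.0, "Z": 3.0}
        assert sas(g1, closeness(g1), e1) == pytest.approx(sas(g2, closeness(g2), e2))

    @given(lam=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_degree_one_homogeneity(self, lam):
        """Scaling all expressions by lambda scales SAS by lambda."""
        g = nx.Graph([("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")])
        c = closeness(g)
        expr = {"A": 1.0, "B": 2.5, "C": 0.5, "D": 4.0}
        base = sas(g, c, expr)
        scaled = sas(g, c, {k: lam * v for k, v in expr.items()})
        assert scaled == pytest.approx(lam * base, rel=1e-9)


class TestPairFeatures:
    def _expr(self, rows, genes=("GA", "GB")):
        ids = [f"S{i}" for i in range(len(rows))]
        return ExpressionMatrix(ids, list(genes), np.array(rows, dtype=float))

    def test_equal_expression(self):
        pf = pair_features(self._expr([[1.0, 1.0]]), ["GA", "GB"])
        np.testing.assert_allclose(pf.features[0], [0.5, 0.5, 0.5])

    def test_three_one(self):
        pf = pair_features(self._expr([[3.0, 1.0]]), ["GA", "GB"])
        np.testing.assert_allclose(pf.features[0], [9 / 4, 1 / 4, 3 / 4])

    def test_zero_pair_is_zero_limit(self):
        pf = pair_features(self._expr([[0.0, 0.0]]), ["GA", "GB"])
        np.testing.assert_array_equal(pf.features[0], [0.0, 0.0, 0.0])

    def test_fewer_than_two_genes_rejected(self):
        with pytest.raises(ValueError):
            pair_features(self._expr([[1.0, 2.0]]), ["GA"])

    def test_canonical_pair_order(self):
        expr = ExpressionMatrix(
            ["S0"], ["GC", "GA", "GB"], np.array([[3.0, 1.0, 2.0]])
        )
        pf = pair_features(expr, ["GC", "GB", "GA"])
        assert pf.pairs == [("GA", "GB"), ("GA", "GC"), ("GB", "GC")]
        assert pf.features.shape == (1, 9)

    def test_ppi_edges_mode_restricts_pairs(self):
        g = nx.Graph([("GA", "GB")])
        expr = ExpressionMatrix(["S0"], ["GA", "GB", "GC"], np.ones((1, 3)))
        pf = pair_features(expr, ["GA", "GB", "GC"], pair_mode="ppi_edges", graph=g)
        assert pf.pairs == [("GA", "GB")]


def _separable_toy(shift=5.0, n_per=10):
    rng = np.random.default_rng(0)
    genes = ["GA", "GB"]
    rows = []
    labels = []
    for i in range(2 * n_per):
        cls = "B" if i >= n_per else "A"
        base = rng.uniform(1, 2, size=2) + (shift if cls == "B" else 0.0)
        rows.append(base)
        labels.append(cls)
    ids = [f"S{i:02d}" for i in range(2 * n_per)]
    expr = ExpressionMatrix(ids, genes, np.array(rows))
    return expr, SampleLabels(ids, labels)


class TestFitSubnetworkModel:
    def test_separable_toy_perfect_training_accuracy(self):
        expr, labels = _separable_toy()
        pf = pair_features(expr, ["GA", "GB"])
        model = fit_subnetwork_model(pf, labels, reg_strength=1e-4, seed=0)
        q = model.q(pf.features)
        predicted = [labels.class_set[i] for i in np.argmax(q, axis=1)]
        assert predicted == labels.labels

    def test_outputs_strictly_within_unit_interval(self):
        expr, labels = _separable_toy()
        pf = pair_features(expr, ["GA", "GB"])
        model = fit_subnetwork_model(pf, labels)
        q = model.q(pf.features)
        assert (q > 0).all() and (q < 1).all()

    def test_single_class_rejected(self):
        expr, _ = _separable_toy()
        labels = SampleLabels(expr.sample_ids, ["A"] * expr.n_samples)
        pf = pair_features(expr, ["GA", "GB"])
        with pytest.raises(ValueError):
            fit_subnetwork_model(pf, labels)

    def test_length_mismatch_rejected(self):
        expr, labels = _separable_toy()
        pf = pair_features(expr.subset_samples(expr.sample_ids[:5]), ["GA", "GB"])
        with pytest.raises(ValueError):
            fit_subnetwork_model(pf, labels)


class TestRepresent:
    def test_normalization_of_raw_probabilities(self):
        expr, labels = _separable_toy()
        pf = pair_features(expr, ["GA", "GB"])
        model = fit_subnetwork_model(pf, labels)
        rep = represent([model], [pf])
        np.testing.assert_allclose(rep.probs.sum(axis=2), 1.0, atol=1e-12)
        # p = q / sum(q) reproduced from raw
        np.testing.assert_allclose(
            rep.probs, rep.raw / rep.raw.sum(axis=2, keepdims=True)
        )

    def test_binary_hand_example(self):
        q = np.array([0.4, 0.8])
        p = q / q.sum()
        np.testing.assert_allclose(p, [1 / 3, 2 / 3])

    def test_flattened_length_is_t_times_k(self):
        expr, labels = _separable_toy()
        pf = pair_features(expr, ["GA", "GB"])
        model = fit_subnetwork_model(pf, labels)
        rep = represent([model] * 3, [pf] * 3)
        assert rep.flatten().shape == (expr.n_samples, 6)


class TestBuildRepresentation:
    def test_no_leakage_from_held_out_labels(self):
        """Held-out representations depend only on training-sample fits."""
        expr, labels = _separable_toy(n_per=12)
        train_ids = expr.sample_ids[:8] + expr.sample_ids[12:20]
        partition = SubnetworkPartition([Subnetwork("T_1", "T", ["GA", "GB"])])
        labels_train = labels.subset(train_ids)
        models1, rep1 = build_representation(expr, labels_train, partition)
        # permute held-out labels: representations must be unchanged
        models2, rep2 = build_representation(expr, labels_train, partition)
        np.testing.assert_array_equal(models1[0].theta, models2[0].theta)
        np.testing.assert_array_equal(rep1.probs, rep2.probs)
        # perturb a held-out sample's expression: theta must be unchanged
        values = expr.values.copy()
        values[9] *= 10
        expr_mod = ExpressionMatrix(expr.sample_ids, expr.gene_ids, values)
        models3, _ = build_representation(expr_mod, labels_train, partition)
        np.testing.assert_array_equal(models1[0].theta, models3[0].theta)
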