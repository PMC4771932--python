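import numpy as np
import pandas as pd
import pytest
from scipy import stats

from decaywood.cooccurrence import (
    build_network,
    correlation_matrix,
    export_network,
    filter_genera,
    network_stats,
)
from decaywood.tables_io import CountMatrix


def make_counts(arr, genera=None):
    arr = np.asarray(arr)
    genera = genera or [f"g{j}" for j in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(
        arr, index=[f"s{i}" for i in range(arr.shape[0])], columns=genera))


class TestFilterGenera:
    def test_total_below_threshold_removed(self):
        cm = make_counts([[2, 5], [2, 0]])  # totals 4 and 5
        kept = filter_genera(cm, min_representatives=5)
        assert kept.taxon_ids == ["g1"]

    def test_boundary_kept(self):
        cm = make_counts([[5, 1], [0, 0]])
        assert "g0" in filter_genera(cm, 5).taxon_ids

    def test_hand_counted_fixture(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(2, 10, size=(4, 10))
        counts[:, [2, 5, 8]] = 1  # three genera with total 4 < 5
        counts[0, [2, 5, 8]] = 1
        counts[1:, [2, 5, 8]] = [[1, 1, 1], [1, 1, 1], [1, 1, 1]]
        cm = make_counts(counts)
        assert len(filter_genera(cm, 5).taxon_ids) == 7

    def test_prevalence_mode(self):
        cm = make_counts([[9, 1], [0, 1], [0, 1]])
        kept = filter_genera(cm, min_representatives=2, mode="samples")
        assert kept.taxon_ids == ["g1"]

    def test_empty_result_errors(self):
        cm = make_counts([[1, 1], [1, 1]])
        with pytest.raises(ValueError, match="threshold"):
            filter_genera(cm, 100)


class TestCorrelationMatrix:
    def test_hand_pearson(self):
        abund = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [1.0, 3, 2, 4]})
        r, p = correlation_matrix(abund)
        assert r.loc["x", "y"] == pytest.approx(0.8)

    def test_diagonal_is_one(self):
        rng = np.random.default_rng(1)
        abund = pd.DataFrame(rng.uniform(size=(6, 4)))
        r, _ = correlation_matrix(abund)
        assert np.allclose(np.diag(r), 1.0)

    def test_perfect_negative(self):
        x = np.array([1.0, 2, 3, 4, 5])
        abund = pd.DataFrame({"x": x, "y": -x, "z": [5, 1, 4, 2, 3.0]})
        r, p = correlation_matrix(abund)
        assert r.loc["x", "y"] == pytest.approx(-1.0)
        assert p.loc["x", "y"] < 1e-10

    def test_p_matches_scipy(self):
        rng = np.random.default_rng(2)
        abund = pd.DataFrame(rng.uniform(size=(10, 3)),
                             columns=["a", "b", "c"])
        r, p = correlation_matrix(abund)
        for g1, g2 in [("a", "b"), ("a", "c"), ("b", "c")]:
            expect = stats.pearsonr(abund[g1], abund[g2])
            assert r.loc[g1, g2] == pytest.approx(expect.statistic)
            assert p.loc[g1, g2] == pytest.approx(expect.pvalue, rel=1e-8)

    def test_constant_genus_excluded_with_warning(self, caplog):
        abund = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 2, 2, 2],
                              "c": [4.0, 3, 2, 1]})
        with caplog.at_level("WARNING"):
            r, _ = correlation_matrix(abund)
        assert "b" not in r.columns

    def test_too_few_samples_errors(self):
        abund = pd.DataFrame({"a": [1.0, 2, 3], "b": [3.0, 2, 1]})
        with pytest.raises(ValueError, match=">= 4"):
            correlation_matrix(abund)


def matrices_from(r_vals, p_vals, genera):
    r = pd.DataFrame(r_vals, index=genera, columns=genera)
    p = pd.DataFrame(p_vals, index=genera, columns=genera)
    return r, p


class TestBuildNetwork:
    def test_boundary_r_excluded(self):
        genera = ["a", "b"]
        r, p = matrices_from([[1.0, 0.80], [0.80, 1.0]],
                             [[0.0, 0.001], [0.001, 0.0]], genera)
        net = build_network(r, p)
        assert net.number_of_edges() == 0

    def test_high_r_high_p_excluded(self):
        genera = ["a", "b"]
        r, p = matrices_from([[1.0, 0.95], [0.95, 1.0]],
                             [[0.0, 0.20], [0.20, 0.0]], genera)
        assert build_network(r, p).number_of_edges() == 0

    def test_negative_edge_included_with_sign(self):
        genera = ["a", "b"]
        r, p = matrices_from([[1.0, -0.9], [-0.9, 1.0]],
                             [[0.0, 0.01], [0.01, 0.0]], genera)
        net = build_network(r, p)
        assert net.edges["a", "b"]["sign"] == "negative"

    def test_planted_edges_recovered_exactly(self):
        # five planted near-duplicate pairs among noise genera
        rng = np.random.default_rng(42)
        n = 19
        cols = {}
        planted = []
        for k in range(5):
            base = rng.normal(size=n)
            cols[f"p{k}a"] = base
            cols[f"p{k}b"] = base + rng.normal(scale=0.05, size=n)
            planted.append((f"p{k}a", f"p{k}b"))
        for k in range(6):
            cols[f"noise{k}"] = rng.normal(size=n)
        abund = pd.DataFrame(cols)
        r, p = correlation_matrix(abund)
        net = build_network(r, p)
        got = {tuple(sorted(e)) for e in net.edges}
        assert got == {tuple(sorted(e)) for e in planted}

    def test_genus_order_invariance(self):
        rng = np.random.default_rng(3)
        abund = pd.DataFrame(rng.uniform(size=(10, 6)),
                             columns=list("abcdef"))
        abund["b"] = abund["a"] * 1.01 + 0.001
        r1, p1 = correlation_matrix(abund)
        perm = list("fedcba")
        r2, p2 = correlation_matrix(abund[perm])
        n1 = build_network(r1, p1)
        n2 = build_network(r2, p2)
        assert {tuple(sorted(e)) for e in n1.edges} == \
            {tuple(sorted(e)) for e in n2.edges}

    def test_kingdom_tags_attached(self):
        genera = ["bac1", "fun1"]
        r, p = matrices_from([[1.0, 0.99], [0.99, 1.0]],
                             [[0.0, 0.001], [0.001, 0.0]], genera)
        net = build_network(r, p, kingdoms={"bac1": "bacteria",
                                            "fun1": "fungi"})
        assert net.nodes["bac1"]["kingdom"] == "bacteria"
        assert net.nodes["fun1"]["kingdom"] == "fungi"


class TestNetworkStats:
    def test_triangle(self):
        genera = list("abc")
        r = pd.DataFrame(0.9, index=genera, columns=genera)
        p = pd.DataFrame(0.001, index=genera, columns=genera)
        net = build_network(r, p)
        s = network_stats(net)
        assert s["n_nodes"] == 3 and s["n_edges"] == 3
        assert s["average_degree"] == pytest.approx(2.0)

    def test_star(self):
        genera = ["hub", "l1", "l2", "l3", "l4"]
        r = pd.DataFrame(0.0, index=genera, columns=genera)
        p = pd.DataFrame(1.0, index=genera, columns=genera)
        for leaf in genera[1:]:
            r.loc["hub", leaf] = r.loc[leaf, "hub"] = 0.95
            p.loc["hub", leaf] = p.loc[leaf, "hub"] = 0.001
        s = network_stats(build_network(r, p))
        assert s["degree"]["hub"] == 4
        assert s["average_degree"] == pytest.approx(8 / 5)
        assert s["key_nodes"][0] == "hub"

    def test_empty_network_zeros(self):
        import networkx as nx
        s = network_stats(nx.Graph())
        assert s["n_nodes"] == 0 and s["average_degree"] == 0.0


class TestExportRoundTrip:
    def test_edges_recompute_from_abundances(self, tmp_path):
        rng = np.random.default_rng(7)
        abund = pd.DataFrame(rng.uniform(size=(12, 5)),
                             columns=list("abcde"))
        abund["b"] = abund["a"] + rng.normal(scale=0.02, size=12)
        r, p = correlation_matrix(abund)
        net = build_network(r, p)
        edge_path = tmp_path / "edges.tsv"
        export_network(net, edge_path=edge_path,
                       node_path=tmp_path / "nodes.tsv",
                       graphml_path=tmp_path / "net.graphml")
        edges = pd.read_csv(edge_path, sep="\t")
        assert len(edges) == net.number_of_edges() > 0
        for _, row in edges.iterrows():
            expect = stats.pearsonr(abund[row["source"]],
                                    abund[row["target"]])
            assert row["r"] == pytest.approx(expect.statistic)
            assert row["p"] == pytest.approx(expect.pvalue, rel=1e-6)
        import networkx as nx
        g = nx.read_graphml(tmp_path / "net.graphml")
        assert g.number_of_edges() == net.number_of_edges()
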