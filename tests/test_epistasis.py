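"""Remove-one epistasis scan, pair testing and network export."""

import numpy as np
import pytest

import snpforest as sf
from snpforest.epistasis import read_edge_table


def _edge(i, j, deltas, base=1.0):
    return sf.InteractionEdge(snp_i=i, snp_j=j, delta_per_rep=np.asarray(deltas, float),
                              baseline_importance=base)


class TestInteractionScan:
    def test_counting_contract(self):
        """k=3 SNPs, 2 replicates: exactly 6 ordered pairs with 2 deltas each."""
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, size=(60, 3)).astype(np.float32)
        y = X[:, 0] + rng.normal(size=60)
        edges = sf.interaction_scan(X, y, replicates=2,
                                    config=sf.RFConfig(n_trees=30, seed=0))
        assert len(edges) == 6
        assert all(e.delta_per_rep.shape == (2,) for e in edges)
        assert {(e.snp_i, e.snp_j) for e in edges} == {
            (a, b) for a in ("snp0", "snp1", "snp2")
            for b in ("snp0", "snp1", "snp2") if a != b
        }

    def test_requires_three_snps_and_two_replicates(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 3, size=(60, 2)).astype(np.float32)
        y = rng.normal(size=60)
        with pytest.raises(ValueError, match="at least 3"):
            sf.interaction_scan(X, y)
        X3 = rng.integers(0, 3, size=(60, 3)).astype(np.float32)
        with pytest.raises(ValueError, match="replicates"):
            sf.interaction_scan(X3, y, replicates=1)

    def test_planted_product_pair_is_synergistic(self):
        """A pure product-term pair has the largest |mean delta| and a
        negative (synergistic) sign."""
        rng = np.random.default_rng(3)
        n = 300
        X = rng.integers(0, 3, size=(n, 10)).astype(np.float32)
        a, b = X[:, 0].astype(float), X[:, 1].astype(float)
        code = (a - a.mean()) * (b - b.mean())
        y = 1.2 * code + rng.normal(size=n) * code.std() * 0.8
        edges = sf.interaction_scan(X, y, replicates=3,
                                    config=sf.RFConfig(n_trees=120, seed=3))
        best = max(edges, key=lambda e: abs(e.mean_delta))
        assert {best.snp_i, best.snp_j} == {"snp0", "snp1"}
        assert best.mean_delta < 0
        assert best.direction == "synergistic"


class TestTestInteractions:
    def test_zero_deltas_give_no_edge(self):
        edges = [
            _edge("a", "b", [0, 0, 0, 0, 0]),
            _edge("b", "a", [0, 0, 0, 0, 0]),
            _edge("a", "c", [0, 0, 0, 0, 0]),
            _edge("c", "a", [0, 0, 0, 0, 0]),
            _edge("b", "c", [0, 0, 0, 0, 0]),
            _edge("c", "b", [0, 0, 0, 0, 0]),
        ]
        net = sf.test_interactions(edges)
        assert edges[0].t_stat == 0.0
        assert edges[0].p_value == 1.0
        assert net.graph.number_of_edges() == 0

    def test_known_deltas_t_and_p(self):
        """deltas (1..5): t = mean/(sd/sqrt(5)) = 4.2426, p(df=4) ~ 0.0132."""
        edges = [
            _edge("a", "b", [1, 2, 3, 4, 5]),
            _edge("b", "a", [0.1, -0.1, 0.05, -0.05, 0.0]),
            _edge("a", "c", [0.1, -0.1, 0.2, -0.2, 0.0]),
            _edge("c", "a", [0.0, 0.1, -0.1, 0.05, -0.05]),
            _edge("b", "c", [0.2, -0.2, 0.1, -0.1, 0.0]),
            _edge("c", "b", [0.0, 0.0, 0.1, -0.1, 0.05]),
        ]
        net = sf.test_interactions(edges, alpha=0.5)
        assert edges[0].t_stat == pytest.approx(4.2426, abs=1e-4)
        assert edges[0].p_value == pytest.approx(0.0132, abs=5e-4)
        # the (a,b) edge enters via its more significant direction
        assert net.graph.has_edge("a", "b")
        d = net.graph.edges["a", "b"]
        assert d["direction"] == "antagonistic"
        assert d["weight"] == pytest.approx(3.0)
        assert d["source"] == "a" and d["removed"] == "b"

    def test_discordant_pair_flagged_and_excluded(self):
        edges = [
            _edge("a", "b", [1.0, 1.1, 0.9, 1.05, 0.95]),
            _edge("b", "a", [-1.0, -1.1, -0.9, -1.05, -0.95]),
            _edge("a", "c", [0.1, -0.1, 0.0, 0.05, -0.05]),
            _edge("c", "a", [0.1, -0.1, 0.0, 0.05, -0.05]),
            _edge("b", "c", [0.1, -0.1, 0.0, 0.05, -0.05]),
            _edge("c", "b", [0.1, -0.1, 0.0, 0.05, -0.05]),
        ]
        net = sf.test_interactions(edges, alpha=0.05)
        assert ("a", "b") in net.discordant
        assert not net.graph.has_edge("a", "b")

    def test_ordered_pair_table_complete(self):
        edges = [_edge(a, b, [0.1, 0.2, 0.0]) for a in "abc" for b in "abc" if a != b]
        net = sf.test_interactions(edges)
        assert len(net.ordered_pairs) == 6
        assert set(net.ordered_pairs.columns) >= {"snp_i", "snp_j", "mean_delta",
                                                  "t", "p", "q", "direction"}


class TestExportNetwork:
    def _network(self, edges, alpha=0.05):
        return sf.test_interactions(edges, alpha=alpha)

    def test_empty_network_header_only(self, tmp_path):
        edges = [_edge(a, b, [0, 0, 0]) for a in "abc" for b in "abc" if a != b]
        net = self._network(edges)
        paths = sf.export_network(net, tmp_path)
        lines = paths["edges"].read_text().strip().split("\n")
        assert len(lines) == 1  # header only
        assert paths["sif"].read_text() == ""

    def test_single_edge_tsv_and_sif(self, tmp_path):
        edges = [
            _edge("snpA", "snpB", [-1.0, -1.1, -0.9, -1.05, -0.95]),
            _edge("snpB", "snpA", [0.01, -0.01, 0.0, 0.005, -0.005]),
            _edge("snpA", "snpC", [0.1, -0.1, 0.0, 0.05, -0.05]),
            _edge("snpC", "snpA", [0.1, -0.1, 0.0, 0.05, -0.05]),
            _edge("snpB", "snpC", [0.1, -0.1, 0.0, 0.05, -0.05]),
            _edge("snpC", "snpB", [0.1, -0.1, 0.0, 0.05, -0.05]),
        ]
        net = self._network(edges)
        assert net.graph.number_of_edges() == 1
        paths = sf.export_network(net, tmp_path)
        lines = paths["edges"].read_text().strip().split("\n")
        assert len(lines) == 2
        assert paths["sif"].read_text().strip() == "snpA\tsynergy\tsnpB"

    def test_round_trip_reproduces_edges(self, tmp_path):
        rng = np.random.default_rng(4)
        names = [f"s{j}" for j in range(4)]
        edges = []
        for a in names:
            for b in names:
                if a != b:
                    edges.append(_edge(a, b, rng.normal(0.5, 0.1, size=5)))
        net = self._network(edges, alpha=0.2)
        paths = sf.export_network(net, tmp_path)
        df = read_edge_table(paths["edges"])
        got = {frozenset((r.snp_i, r.snp_j)) for r in df.itertuples()}
        want = {frozenset((u, v)) for u, v in net.graph.edges()}
        assert got == want
        assert np.allclose(
            sorted(df.weight),
            sorted(d["weight"] for *_, d in net.graph.edges(data=True)),
        )
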