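"""Gene networks: construction, six centralities vs enumeration, algebra."""
import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import epinet as ep


def _net(edges, genes=None):
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, weight=0.1)
    if genes is None:
        genes = sorted(g.nodes)
    else:
        g.add_nodes_from(genes)
    return ep.GeneNetwork(g, tuple(genes))


def _scan_result(rows, alpha_star=0.01):
    cols = ["snp_a", "snp_b", "gene_a", "gene_b", "intragenic", "n_used",
            "V_P", "relative_epistasis", "p_epistasis", "h2_a", "h2_b",
            "testable", "dropped", "flags"]
    for c in ep.COMPONENTS:
        cols += [f"V_{c}", f"beta_{c}"]
    table = pd.DataFrame(rows)
    for c in cols:
        if c not in table.columns:
            table[c] = 0.0
    return ep.ScanResult("sub1", "diastolic", 100, alpha_star, table,
                         pd.DataFrame(), len(rows))


def _pair_row(snp_a, snp_b, gene_a, gene_b, rel, p, intragenic=False):
    return {"snp_a": snp_a, "snp_b": snp_b, "gene_a": gene_a,
            "gene_b": gene_b, "relative_epistasis": rel, "p_epistasis": p,
            "intragenic": intragenic, "testable": True}


class TestBuildGeneNetwork:
    def test_possible_gene_pairs_23(self):
        net = _net([], genes=[f"G{i:02d}" for i in range(23)])
        assert net.n_possible == 253

    def test_94_links_is_37_percent(self):
        genes = [f"G{i:02d}" for i in range(23)]
        pairs = list(itertools.combinations(genes, 2))[:94]
        net = _net(pairs, genes=genes)
        assert net.n_edges == 94
        assert 100 * net.fraction_of_possible == pytest.approx(37.2, abs=0.05)

    def test_empty_scan_gives_isolated_genes(self):
        scan = _scan_result([_pair_row("a", "b", "GA", "GB", 0.2, 0.5)])
        net = ep.build_gene_network(scan, alpha_star=1e-6,
                                    genes=["GA", "GB", "GC"])
        assert net.n_edges == 0
        assert set(net.graph.nodes) == {"GA", "GB", "GC"}

    def test_max_edge_curation_keeps_largest_pair(self):
        scan = _scan_result([
            _pair_row("a1", "b1", "GA", "GB", 0.10, 1e-9),
            _pair_row("a2", "b2", "GA", "GB", 0.30, 1e-8),
        ])
        net = ep.build_gene_network(scan, curation="max-edge")
        assert net.graph["GA"]["GB"]["weight"] == pytest.approx(0.30)

    def test_intragenic_pairs_never_become_edges(self):
        scan = _scan_result([
            _pair_row("a1", "a2", "GA", "GA", 0.5, 1e-12, intragenic=True),
            _pair_row("a1", "b1", "GA", "GB", 0.2, 1e-9),
        ])
        net = ep.build_gene_network(scan)
        assert list(net.graph.edges) == [("GA", "GB")]

    def test_representative_snp_curation_deterministic(self):
        scan = _scan_result([
            _pair_row("a1", "b1", "GA", "GB", 0.10, 1e-9),
            _pair_row("a1", "c1", "GA", "GC", 0.20, 1e-9),
            _pair_row("a2", "b1", "GA", "GB", 0.40, 1e-9),
        ])
        net = ep.build_gene_network(scan, curation="representative-snp")
        # a1 joins two genes (most interactions) -> representative of GA;
        # the a2-b1 edge drops even though its variance is larger
        assert net.graph.has_edge("GA", "GB")
        assert net.graph["GA"]["GB"]["weight"] == pytest.approx(0.10)
        assert net.graph.has_edge("GA", "GC")

    def test_curated_count_bounded_by_raw(self, rng):
        rows = []
        genes = [f"G{i}" for i in range(6)]
        for gi, gj in itertools.combinations(range(6), 2):
            for s in range(2):
                rows.append(_pair_row(f"s{gi}_{s}", f"s{gj}_{s}",
                                      genes[gi], genes[gj],
                                      float(rng.uniform(0.01, 0.5)),
                                      float(rng.uniform(0, 0.02))))
        scan = _scan_result(rows)
        raw = len(scan.significant)
        for mode in ("max-edge", "representative-snp"):
            net = ep.build_gene_network(scan, curation=mode)
            assert net.n_edges <= raw

    def test_unknown_curation_mode(self):
        with pytest.raises(ValueError, match="curation"):
            ep.build_gene_network(_scan_result([]), curation="best")


# ---------------------------------------------------------------------------
# brute-force centrality oracles (simple-path enumeration, independent of
# the BFS/DP implementation path)
# ---------------------------------------------------------------------------

def _brute_shortest_paths(G, s, t):
    paths = list(nx.all_simple_paths(G, s, t))
    if s == t or not paths:
        return None, []
    d = min(len(p) - 1 for p in paths)
    return d, [p for p in paths if len(p) - 1 == d]


def _brute_centralities(G, nodes):
    n = len(nodes)
    dist = {v: {u: np.inf for u in nodes} for v in nodes}
    geod = {}
    for s, t in itertools.combinations(nodes, 2):
        d, paths = _brute_shortest_paths(G, s, t)
        if d is not None:
            dist[s][t] = dist[t][s] = d
            geod[(s, t)] = paths
    for v in nodes:
        dist[v][v] = 0
    betw = {v: 0.0 for v in nodes}
    stress = {v: 0.0 for v in nodes}
    for (s, t), paths in geod.items():
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(v in p for p in paths)
            stress[v] += through
            betw[v] += through / len(paths)
    clo = {}
    for v in nodes:
        reach = [u for u in nodes if u != v and np.isfinite(dist[v][u])]
        total = sum(dist[v][u] for u in reach)
        clo[v] = len(reach) / total if total > 0 else 0.0
    cen = {}
    for v in nodes:
        comp = [u for u in nodes if u != v and np.isfinite(dist[v][u])]
        if not comp:
            cen[v] = 0.0
            continue
        vals = []
        for u in comp:
            gv = sum(dist[w][v] < dist[w][u] for w in nodes)
            gu = sum(dist[w][u] < dist[w][v] for w in nodes)
            vals.append(gv - gu)
        cen[v] = min(vals)
    return dist, betw, stress, clo, cen


def _random_graph(rng, n):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < 0.4:
            g.add_edge(i, j, weight=0.5)
    return g


class TestCentralityOracle:
    def test_three_path_analytic_values(self):
        net = _net([("A", "B"), ("B", "C")])
        c = ep.centrality_indices(net)
        assert c.loc["B", "betweenness"] == 1.0
        assert c.loc["B", "stress"] == 1.0
        assert c.loc["B", "degree"] == 2.0
        assert c.loc["B", "closeness"] == 1.0
        assert c.loc["A", "closeness"] == pytest.approx(2 / 3)

    def test_exhaustive_four_node_graphs(self):
        """All 64 labeled 4-node graphs match simple-path enumeration."""
        nodes = list("WXYZ")
        pairs = list(itertools.combinations(nodes, 2))
        for mask in range(64):
            g = nx.Graph()
            g.add_nodes_from(nodes)
            for b, (u, v) in enumerate(pairs):
                if mask >> b & 1:
                    g.add_edge(u, v, weight=0.2)
            net = ep.GeneNetwork(g, tuple(nodes))
            c = ep.centrality_indices(net)
            _, betw, stress, clo, cen = _brute_centralities(g, nodes)
            for v in nodes:
                assert c.loc[v, "betweenness"] == pytest.approx(betw[v])
                assert c.loc[v, "stress"] == pytest.approx(stress[v])
                assert c.loc[v, "closeness"] == pytest.approx(clo[v])
                assert c.loc[v, "centroid"] == pytest.approx(cen[v])

    @pytest.mark.parametrize("n", [6, 7, 8])
    def test_random_graphs_up_to_eight_nodes(self, rng, n):
        for _ in range(8):
            g = _random_graph(rng, n)
            net = ep.GeneNetwork(g, tuple(range(n)))
            c = ep.centrality_indices(net)
            _, betw, stress, clo, cen = _brute_centralities(g, list(range(n)))
            for v in range(n):
                assert c.loc[v, "betweenness"] == pytest.approx(betw[v])
                assert c.loc[v, "stress"] == pytest.approx(stress[v])
                assert c.loc[v, "closeness"] == pytest.approx(clo[v])
                assert c.loc[v, "centroid"] == pytest.approx(cen[v])

    def test_katz_matches_truncated_series(self, rng):
        for n in (4, 6, 8):
            g = _random_graph(rng, n)
            if g.number_of_edges() == 0:
                continue
            net = ep.GeneNetwork(g, tuple(range(n)))
            c = ep.centrality_indices(net)
            A = nx.to_numpy_array(g, nodelist=range(n), weight=None)
            lam = np.max(np.abs(np.linalg.eigvalsh(A)))
            alpha = 0.85 / lam
            acc = np.zeros((n, n))
            P = np.eye(n)
            for _ in range(200):
                P = P @ (alpha * A)
                acc += P
            np.testing.assert_allclose(c["katz"].to_numpy(),
                                       acc @ np.ones(n), atol=1e-8)

    def test_katz_divergent_alpha_rejected(self):
        net = _net([("A", "B"), ("B", "C")])
        with pytest.raises(ValueError, match="diverges"):
            ep.centrality_indices(net, katz_alpha=1.0)

    def test_vitality_wiener_difference(self):
        # square with one diagonal: removing a degree-2 corner keeps the
        # rest connected; Wiener difference computed by hand
        net = _net([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A"),
                    ("A", "C")])
        c = ep.centrality_indices(net)
        G = net.graph
        w_full = sum(d for _, lengths in nx.all_pairs_shortest_path_length(G)
                     for d in lengths.values()) / 2
        H = G.copy()
        H.remove_node("D")
        w_sub = sum(d for _, lengths in nx.all_pairs_shortest_path_length(H)
                    for d in lengths.values()) / 2
        assert c.loc["D", "closeness_vitality"] == pytest.approx(
            w_full - w_sub)

    def test_vitality_disconnect_sentinel(self):
        net = _net([("A", "B"), ("B", "C")])
        c = ep.centrality_indices(net)
        assert bool(c.loc["B", "vitality_disconnects"])
        assert np.isnan(c.loc["B", "closeness_vitality"])

    def test_relabeling_invariance(self, rng):
        g = _random_graph(rng, 7)
        names = [f"N{i}" for i in range(7)]
        g = nx.relabel_nodes(g, dict(enumerate(names)))
        net = ep.centrality_indices(ep.GeneNetwork(g, tuple(names)))
        perm = list(np.random.default_rng(1).permutation(names))
        mapping = dict(zip(names, perm))
        g2 = nx.relabel_nodes(g, mapping)
        net2 = ep.centrality_indices(ep.GeneNetwork(g2, tuple(perm)))
        for v in names:
            for col in ("degree", "closeness", "betweenness", "stress",
                        "centroid", "katz"):
                assert net.loc[v, col] == pytest.approx(
                    net2.loc[mapping[v], col], abs=1e-9)


class TestNetworkAlgebra:
    def test_merge_idempotent_and_identity(self):
        x = _net([("A", "B"), ("B", "C")])
        empty = _net([], genes=["A", "B", "C"])
        assert ep.merge_networks([x]).n_edges == x.n_edges
        merged = ep.merge_networks([x, empty])
        assert set(merged.graph.edges) == set(x.graph.edges)

    def test_merge_disjoint_adds_counts(self):
        a = _net([("A", "B")], genes=list("ABCD"))
        b = _net([("C", "D")], genes=list("ABCD"))
        assert ep.merge_networks([a, b]).n_edges == 2

    def test_merge_takes_max_weight_commutatively(self):
        g1 = nx.Graph(); g1.add_edge("A", "B", weight=0.2)
        g2 = nx.Graph(); g2.add_edge("A", "B", weight=0.7)
        n1 = ep.GeneNetwork(g1, ("A", "B"))
        n2 = ep.GeneNetwork(g2, ("A", "B"))
        m12 = ep.merge_networks([n1, n2])
        m21 = ep.merge_networks([n2, n1])
        assert m12.graph["A"]["B"]["weight"] == 0.7
        assert m21.graph["A"]["B"]["weight"] == 0.7

    def test_subtract_self_annihilates(self):
        x = _net([("A", "B"), ("B", "C")])
        assert ep.subtract_network(x, x).n_edges == 0

    def test_subtract_empty_is_identity(self):
        x = _net([("A", "B"), ("B", "C")])
        empty = _net([], genes=["A", "B", "C"])
        out = ep.subtract_network(x, empty)
        assert set(out.graph.edges) == set(x.graph.edges)

    def test_subtraction_set_algebra(self, rng):
        genes = [f"G{i}" for i in range(8)]
        pairs = list(itertools.combinations(genes, 2))
        for _ in range(10):
            ea = [p for p in pairs if rng.random() < 0.4]
            eb = [p for p in pairs if rng.random() < 0.4]
            a, b = _net(ea, genes), _net(eb, genes)
            diff = ep.subtract_network(a, b)
            inter = len(set(map(frozenset, ea)) & set(map(frozenset, eb)))
            assert a.n_edges == diff.n_edges + inter

    def test_no_self_loops_and_weight_domain(self):
        g = nx.Graph()
        g.add_edge("A", "A", weight=0.5)
        with pytest.raises(ValueError, match="self-loop"):
            ep.GeneNetwork(g, ("A",))
        g = nx.Graph()
        g.add_edge("A", "B", weight=1.5)
        with pytest.raises(ValueError, match="weight"):
            ep.GeneNetwork(g, ("A", "B"))


class TestReadWrite:
    def test_pajek_layout(self, tmp_path):
        net = _net([("A", "B"), ("B", "C")])
        p = ep.write_network(net, tmp_path / "x.net", "pajek")
        text = p.read_text()
        assert text.startswith("*Vertices 3")
        assert "*Edges" in text
        assert len([l for l in text.splitlines()
                    if l and l[0].isdigit() and len(l.split()) == 3]) == 2

    @pytest.mark.parametrize("fmt,name", [("pajek", "x.net"),
                                          ("graphml", "x.graphml"),
                                          ("tsv", "x.tsv")])
    def test_round_trip_exact(self, tmp_path, fmt, name):
        g = nx.Graph()
        g.add_edge("GA", "GB", weight=0.25,
                   provenance=[{"subpopulation": "s1", "trait": "diastolic",
                                "snp_a": "a1", "snp_b": "b1", "p": 1e-8}])
        g.add_edge("GB", "GC", weight=0.5209,
                   provenance=[{"subpopulation": "s1", "trait": "diastolic",
                                "snp_a": "b2", "snp_b": "c1", "p": 1e-9}])
        net = ep.GeneNetwork(g, ("GA", "GB", "GC"))
        back = ep.read_network(ep.write_network(net, tmp_path / name, fmt),
                               fmt)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert set(map(frozenset, back.graph.edges)) == \
            set(map(frozenset, net.graph.edges))
        for u, v in net.graph.edges:
            assert back.graph[u][v]["weight"] == net.graph[u][v]["weight"]

    def test_graphml_is_namespaced_xml(self, tmp_path):
        from lxml import etree
        net = _net([("A", "B")])
        p = ep.write_network(net, tmp_path / "x.graphml", "graphml")
        root = etree.parse(str(p)).getroot()
        assert root.tag == "{http://graphml.graphdrawing.org/xmlns}graphml"

    def test_unknown_format_lists_supported(self, tmp_path):
        net = _net([("A", "B")])
        with pytest.raises(ValueError, match="pajek"):
            ep.write_network(net, tmp_path / "x.bin", "parquet")
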