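"""Gene-level epistasis networks: construction, centralities, algebra.

Nodes are the panel genes; an undirected edge joins two genes when at
least one significant inter-genic SNP pair links them, weighted by the
maximal relative epistatic variance among those pairs (a fraction of the
stratum's phenotypic variance, in (0, 1]).  Shortest-path centralities
are computed on the unweighted topology: the epistatic weights select
edges but do not define path lengths.

Six centrality indices are provided (closeness, betweenness, stress,
centroid value, Katz status and closeness vitality), plus degree, along
with merge (edge union, max weight) and subtraction (removing a core
network's gene pairs) for comparing the epistasis network against the
known metabolic backbone.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

EDGE_COLUMNS = ("gene_a", "gene_b", "weight", "subpopulation", "trait",
                "snp_a", "snp_b", "p")

FORMATS = ("pajek", "graphml", "tsv")

#: Sentinel reported when removing a node splits its component, so the
#: Wiener-index difference is undefined.
DISCONNECTS = "disconnects"


@dataclasses.dataclass
class GeneNetwork:
    """Undirected gene network with epistasis-weighted edges.

    ``graph`` carries one node per panel gene (isolated genes included)
    and per-edge attributes ``weight`` (maximal relative epistatic
    variance) and ``provenance`` (list of dicts naming the
    subpopulation, trait and SNP pair behind the edge).
    """

    graph: nx.Graph
    genes: tuple

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        g = nx.Graph()
        g.add_nodes_from(self.genes)
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop on gene {u!r}")
            if u not in self.genes or v not in self.genes:
                raise ValueError(f"edge {u}-{v} outside the gene universe")
            w = float(d.get("weight", np.nan))
            if not 0.0 < w <= 1.0:
                raise ValueError(f"edge {u}-{v} weight {w} outside (0, 1]")
            g.add_edge(u, v, weight=w,
                       provenance=list(d.get("provenance", [])))
        self.graph = g

    # -- views ---------------------------------------------------------
    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_possible(self) -> int:
        m = len(self.genes)
        return m * (m - 1) // 2

    @property
    def fraction_of_possible(self) -> float:
        return self.n_edges / self.n_possible if self.n_possible else 0.0

    def edges_frame(self) -> pd.DataFrame:
        rows = []
        for u, v, d in sorted(self.graph.edges(data=True)):
            a, b = sorted((u, v))
            prov = d.get("provenance") or [{}]
            first = prov[0]
            rows.append({"gene_a": a, "gene_b": b, "weight": d["weight"],
                         "subpopulation": first.get("subpopulation", ""),
                         "trait": first.get("trait", ""),
                         "snp_a": first.get("snp_a", ""),
                         "snp_b": first.get("snp_b", ""),
                         "p": first.get("p", np.nan)})
        return pd.DataFrame(rows, columns=list(EDGE_COLUMNS))

    def plot(self, ax=None):
        """Spring-layout sketch of the network (node size ~ degree)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 7))
        pos = nx.spring_layout(self.graph, seed=0)
        deg = dict(self.graph.degree())
        nx.draw_networkx(self.graph, pos=pos, ax=ax, node_color="#9ecae1",
                         node_size=[100 + 60 * deg[n] for n in self.graph],
                         font_size=7, edge_color="#777777")
        ax.set_axis_off()
        return ax


# ---------------------------------------------------------------------------
# construction from scan results
# ---------------------------------------------------------------------------

def build_gene_network(scan, alpha_star: float | None = None,
                       curation: str = "max-edge",
                       genes: Sequence[str] | None = None) -> GeneNetwork:
    """Collapse significant inter-genic SNP pairs to a gene network.

    ``curation`` is either ``"max-edge"`` (per gene pair keep the SNP
    pair with maximal relative epistatic variance) or
    ``"representative-snp"`` (per gene first select the SNP with the
    most significant inter-genic interactions — ties broken by larger
    maximal variance, then lexicographic id — then keep only the
    representatives' edges).  An empty scan yields a valid edgeless
    network over the gene universe.
    """
    if curation not in ("max-edge", "representative-snp"):
        raise ValueError(f"unknown curation mode {curation!r}")
    alpha = scan.alpha_star if alpha_star is None else alpha_star
    sig = scan.table
    if not sig.empty:
        sig = sig[sig["testable"] & ~sig["intragenic"]
                  & (sig["p_epistasis"] <= alpha)
                  & (sig["relative_epistasis"] > 0)]
    if genes is None:
        # fall back to the genes seen in the pair table
        genes = sorted(set(sig["gene_a"]).union(sig["gene_b"])) if not sig.empty else []
    genes = tuple(sorted(set(genes)))

    if curation == "representative-snp" and not sig.empty:
        reps = {}
        per_snp: dict[str, list] = {}
        for _, row in sig.iterrows():
            per_snp.setdefault(row["snp_a"], []).append(row)
            per_snp.setdefault(row["snp_b"], []).append(row)
        by_gene: dict[str, list] = {}
        for snp, rows in per_snp.items():
            gene = rows[0]["gene_a"] if rows[0]["snp_a"] == snp else rows[0]["gene_b"]
            by_gene.setdefault(gene, []).append(
                (len(rows), max(r["relative_epistasis"] for r in rows), snp))
        for gene, cands in by_gene.items():
            # most interactions, then larger max variance, then lexicographic
            cands.sort(key=lambda t: (-t[0], -t[1], t[2]))
            reps[gene] = cands[0][2]
        keep = sig.apply(lambda r: reps.get(r["gene_a"]) == r["snp_a"]
                         and reps.get(r["gene_b"]) == r["snp_b"], axis=1)
        sig = sig[keep]

    g = nx.Graph()
    g.add_nodes_from(genes)
    if not sig.empty:
        for _, row in sig.sort_values(
                ["relative_epistasis", "snp_a", "snp_b"],
                ascending=[False, True, True]).iterrows():
            a, b = sorted((row["gene_a"], row["gene_b"]))
            prov = {"subpopulation": scan.subpop_id, "trait": scan.trait_name,
                    "snp_a": row["snp_a"], "snp_b": row["snp_b"],
                    "p": float(row["p_epistasis"])}
            if g.has_edge(a, b):
                g[a][b]["provenance"].append(prov)
            else:
                g.add_edge(a, b, weight=float(row["relative_epistasis"]),
                           provenance=[prov])
    return GeneNetwork(g, genes)


# ---------------------------------------------------------------------------
# centrality indices
# ---------------------------------------------------------------------------

def _path_counts(G: nx.Graph, nodes: list) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs geodesic distances and shortest-path counts (BFS DAG DP)."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in nodes:
        si = idx[s]
        dist[si, si] = 0
        sigma[si, si] = 1.0
        frontier = [s]
        d = 0
        while frontier:
            nxt = []
            for u in frontier:
                for w in G[u]:
                    wi = idx[w]
                    if np.isinf(dist[si, wi]):
                        dist[si, wi] = d + 1
                        nxt.append(w)
                    if dist[si, wi] == d + 1:
                        sigma[si, wi] += sigma[si, idx[u]]
            frontier = nxt
            d += 1
    return dist, sigma


def _wiener(dist: np.ndarray) -> float:
    """Sum of finite pairwise distances over unordered pairs."""
    finite = np.where(np.isfinite(dist), dist, 0.0)
    return float(finite.sum() / 2.0)


def centrality_indices(net: GeneNetwork,
                       katz_alpha: float | None = None) -> pd.DataFrame:
    """Seven node-centrality indices on the unweighted topology.

    closeness: (c-1)/sum of distances within the node's component of
    size c (0 for isolated nodes); betweenness and stress: fractional
    and absolute counts of shortest paths through the node; centroid
    value: min over co-component nodes u of (#nodes strictly closer to v)
    minus (#strictly closer to u); Katz: row sums of
    sum_{k>=1} alpha^k A^k with alpha = 0.85/lambda_max by default;
    closeness vitality: Wiener-index change on node removal, with the
    string sentinel column flagging removals that split a component.
    """
    G = net.graph
    nodes = list(net.genes)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    dist, sigma = _path_counts(G, nodes)

    degree = np.array([G.degree(v) for v in nodes], dtype=float)

    closeness = np.zeros(n)
    for i in range(n):
        reach = np.isfinite(dist[i]) & (np.arange(n) != i)
        total = dist[i, reach].sum()
        closeness[i] = reach.sum() / total if total > 0 else 0.0

    betweenness = np.zeros(n)
    stress = np.zeros(n)
    for vi in range(n):
        for si in range(n):
            if si == vi:
                continue
            for ti in range(si + 1, n):
                if ti == vi or not np.isfinite(dist[si, ti]):
                    continue
                if dist[si, vi] + dist[vi, ti] == dist[si, ti]:
                    through = sigma[si, vi] * sigma[vi, ti]
                    stress[vi] += through
                    betweenness[vi] += through / sigma[si, ti]

    centroid = np.zeros(n)
    for vi in range(n):
        comp = [u for u in range(n)
                if u != vi and np.isfinite(dist[vi, u])]
        if not comp:
            centroid[vi] = 0.0
            continue
        vals = []
        for ui in comp:
            gamma_v = int(np.sum(dist[:, vi] < dist[:, ui]))
            gamma_u = int(np.sum(dist[:, ui] < dist[:, vi]))
            vals.append(gamma_v - gamma_u)
        centroid[vi] = min(vals)

    A = nx.to_numpy_array(G, nodelist=nodes, weight=None)
    if A.any():
        lam_max = float(np.max(np.abs(np.linalg.eigvalsh(A))))
        alpha = 0.85 / lam_max if katz_alpha is None else katz_alpha
        if alpha >= 1.0 / lam_max:
            raise ValueError(
                f"Katz alpha {alpha} >= 1/lambda_max = {1.0 / lam_max}; "
                "the series diverges")
        katz = np.linalg.solve(np.eye(n) - alpha * A,
                               alpha * A @ np.ones(n))
    else:
        katz = np.zeros(n)

    vitality = np.full(n, np.nan)
    splits = np.zeros(n, dtype=bool)
    w_full = _wiener(dist)
    for vi, v in enumerate(nodes):
        comp_nodes = [u for u in range(n) if np.isfinite(dist[vi, u])]
        H = G.copy()
        H.remove_node(v)
        rest = [nodes[u] for u in comp_nodes if u != vi]
        if rest and not nx.is_connected(H.subgraph(rest)):
            splits[vi] = True
            continue
        d2, _ = _path_counts(H, [u for u in nodes if u != v])
        vitality[vi] = w_full - _wiener(d2)

    out = pd.DataFrame({
        "degree": degree, "closeness": closeness,
        "betweenness": betweenness, "stress": stress,
        "centroid": centroid, "katz": katz,
        "closeness_vitality": vitality,
        "vitality_disconnects": splits,
    }, index=pd.Index(nodes, name="gene"))
    return out


# ---------------------------------------------------------------------------
# network algebra
# ---------------------------------------------------------------------------

def merge_networks(nets: Iterable[GeneNetwork]) -> GeneNetwork:
    """Edge union over a shared gene universe; merged weight = max."""
    nets = list(nets)
    if not nets:
        raise ValueError("nothing to merge")
    genes = tuple(sorted(set().union(*(set(n.genes) for n in nets))))
    g = nx.Graph()
    g.add_nodes_from(genes)
    for net in nets:
        for u, v, d in net.graph.edges(data=True):
            if g.has_edge(u, v):
                g[u][v]["weight"] = max(g[u][v]["weight"], d["weight"])
                g[u][v]["provenance"].extend(d.get("provenance", []))
            else:
                g.add_edge(u, v, weight=d["weight"],
                           provenance=list(d.get("provenance", [])))
    return GeneNetwork(g, genes)


def subtract_network(a: GeneNetwork, b: GeneNetwork) -> GeneNetwork:
    """Edges of ``a`` whose gene pair is absent from ``b``; nodes kept.

    This is the core-network subtraction: removing the known metabolic
    backbone from the merged epistasis network leaves the putative
    superimposed regulatory links.
    """
    genes = tuple(sorted(set(a.genes).union(b.genes)))
    g = nx.Graph()
    g.add_nodes_from(genes)
    for u, v, d in a.graph.edges(data=True):
        if not b.graph.has_edge(u, v):
            g.add_edge(u, v, **d)
    return GeneNetwork(g, genes)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_network(net: GeneNetwork, path, fmt: str = "tsv") -> Path:
    """Write a network as Pajek .net, GraphML or a TSV edge list.

    The TSV and GraphML forms keep the first-provenance columns; Pajek
    keeps nodes, edges and weights (1-based vertex numbering).
    """
    path = Path(path)
    if fmt == "pajek":
        lines = [f"*Vertices {len(net.genes)}"]
        index = {g: i + 1 for i, g in enumerate(net.genes)}
        for g_, i in index.items():
            lines.append(f'{i} "{g_}"')
        lines.append("*Edges")
        for u, v, d in sorted(net.graph.edges(data=True)):
            a, b = sorted((index[u], index[v]))
            lines.append(f"{a} {b} {d['weight']:.10g}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "graphml":
        g = nx.Graph()
        g.add_nodes_from(net.genes)
        for u, v, d in net.graph.edges(data=True):
            g.add_edge(u, v, weight=float(d["weight"]),
                       provenance=json.dumps(d.get("provenance", []),
                                             sort_keys=True))
        nx.write_graphml(g, path)
    elif fmt == "tsv":
        net.edges_frame().to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}; supported: {FORMATS}")
    return path


def read_network(path, fmt: str = "tsv",
                 genes: Sequence[str] | None = None) -> GeneNetwork:
    """Read a network previously written by :func:`write_network`."""
    path = Path(path)
    if fmt == "pajek":
        lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
        n = int(lines[0].split()[1])
        names = {}
        for ln in lines[1:1 + n]:
            num, name = ln.split(maxsplit=1)
            names[int(num)] = name.strip().strip('"')
        g = nx.Graph()
        g.add_nodes_from(names.values())
        for ln in lines[2 + n:]:
            a, b, w = ln.split()
            g.add_edge(names[int(a)], names[int(b)], weight=float(w))
        return GeneNetwork(g, genes if genes is not None else tuple(names.values()))
    if fmt == "graphml":
        g0 = nx.read_graphml(path)
        g = nx.Graph()
        g.add_nodes_from(g0.nodes())
        for u, v, d in g0.edges(data=True):
            g.add_edge(u, v, weight=float(d["weight"]),
                       provenance=json.loads(d.get("provenance", "[]")))
        return GeneNetwork(g, genes if genes is not None else tuple(sorted(g.nodes())))
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        node_set = set(df["gene_a"]).union(df["gene_b"]) if len(df) else set()
        if genes is not None:
            node_set |= set(genes)
        g = nx.Graph()
        g.add_nodes_from(sorted(node_set))
        for _, row in df.iterrows():
            prov = [{"subpopulation": row["subpopulation"], "trait": row["trait"],
                     "snp_a": row["snp_a"], "snp_b": row["snp_b"],
                     "p": row["p"]}]
            g.add_edge(row["gene_a"], row["gene_b"],
                       weight=float(row["weight"]), provenance=prov)
        return GeneNetwork(g, tuple(sorted(node_set)))
    raise ValueError(f"unknown format {fmt!r}; supported: {FORMATS}")
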