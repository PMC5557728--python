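"""Haplotype reduction and abundance-weighted minimum spanning trees.

Haplotypes are first reduced by CD-HIT-style greedy clustering at a sequence
identity threshold (99% by default), pairwise mutational distances are counted
over a common alignment (substitutions plus indel events), and a minimum
spanning tree is built with Kruskal's algorithm under deterministic
tie-breaking. Edges of weight k are expanded with k-1 intermediate "step"
nodes so every drawn edge is a single mutational step, matching the classic
haplotype-network display where node size encodes abundance.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._align import global_aligner, global_identity
from .errors import ParameterError
from .popstats import HapRow, HaplotypeTable, align_monomers, pair_differences, _rows_to_matrix

DEFAULT_CLUSTER_IDENTITY = 0.99


@dataclass
class Cluster:
    representative_id: str
    representative_seq: str
    member_ids: list[str]
    abundance: int
    species: str = ""
    origin: str = "illumina"


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    threshold: float

    def __len__(self) -> int:
        return len(self.clusters)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.representative_id, c.species, c.origin, c.abundance,
              len(c.member_ids), ",".join(c.member_ids)) for c in self.clusters],
            columns=["representative", "species", "origin", "abundance",
                     "n_members", "members"])


def greedy_cluster(rows: Sequence[HapRow],
                   threshold: float = DEFAULT_CLUSTER_IDENTITY) -> ClusterSet:
    """CD-HIT-style greedy incremental clustering.

    Sequences are visited sorted by (abundance desc, length desc, sequence);
    each joins the first existing cluster whose representative it matches at
    identity >= threshold (identity = matches / columns of a global pairwise
    alignment), else founds a new cluster. Cluster abundance is the summed
    member count. Deterministic given the input rows.
    """
    if not 0.0 < threshold <= 1.0:
        raise ParameterError("threshold must be in (0, 1]")
    ordered = sorted(rows, key=lambda r: (-r.count, -len(r.sequence), r.sequence))
    aligner = global_aligner()
    clusters: list[Cluster] = []
    for row in ordered:
        placed = False
        for cl in clusters:
            if global_identity(row.sequence, cl.representative_seq, aligner) >= threshold:
                cl.member_ids.append(row.haplotype_id)
                cl.abundance += row.count
                placed = True
                break
        if not placed:
            clusters.append(Cluster(row.haplotype_id, row.sequence,
                                    [row.haplotype_id], row.count,
                                    row.species, row.origin))
    return ClusterSet(clusters, threshold)


def pairwise_differences(alignment: Sequence[str]) -> np.ndarray:
    """Symmetric matrix of mutational distances over aligned rows.

    d_ij = mismatching columns where both symbols are bases, plus the number
    of maximal gap runs present in exactly one of the two rows (each indel
    counted as one event).
    """
    mat = _rows_to_matrix(list(alignment))
    n = mat.shape[0]
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d_sub, events, _ = pair_differences(mat[i], mat[j])
            d[i, j] = d[j, i] = d_sub + events
    return d


@dataclass
class MSTGraph:
    """Expanded minimum spanning tree with unit-step edges.

    ``graph`` holds haplotype nodes (attributes: species, origin, abundance,
    is_step_node=0) and intermediate step nodes (is_step_node=1); every edge is
    one mutational step. ``weighted_edges`` are the pre-expansion MST edges.
    """

    graph: nx.Graph
    weighted_edges: list[tuple[str, str, int]]

    @property
    def total_weight(self) -> int:
        return sum(w for _, _, w in self.weighted_edges)

    def haplotype_nodes(self) -> list[str]:
        return [n for n, a in self.graph.nodes(data=True) if not a.get("is_step_node")]

    def step_nodes(self) -> list[str]:
        return [n for n, a in self.graph.nodes(data=True) if a.get("is_step_node")]


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        return True


def build_mst(distances: np.ndarray, labels: Sequence[str],
              node_attrs: dict[str, dict] | None = None) -> MSTGraph:
    """Kruskal MST with deterministic tie-breaking, expanded to unit steps.

    Edges are processed sorted by (weight, lexicographic node-id pair); an
    accepted edge of weight k is expanded into k unit-step edges through k-1
    intermediate step nodes. Node attributes (species, origin, abundance) are
    taken from ``node_attrs`` keyed by label.
    """
    labels = list(labels)
    if len(labels) == 0:
        raise ParameterError("build_mst requires at least one node")
    distances = np.asarray(distances)
    if distances.shape != (len(labels), len(labels)):
        raise ParameterError("distance matrix shape does not match labels")
    node_attrs = node_attrs or {}

    g = nx.Graph()
    for lab in labels:
        attrs = node_attrs.get(lab, {})
        g.add_node(lab, species=str(attrs.get("species", "")),
                   origin=str(attrs.get("origin", "")),
                   abundance=int(attrs.get("abundance", 1)),
                   is_step_node=0)

    edges = []
    idx = {lab: i for i, lab in enumerate(labels)}
    for i, u in enumerate(labels):
        for j in range(i + 1, len(labels)):
            v = labels[j]
            a, b = sorted((u, v))
            edges.append((int(distances[i, j]), a, b))
    edges.sort()

    uf = _UnionFind(labels)
    accepted = []
    for w, u, v in edges:
        if uf.union(u, v):
            accepted.append((u, v, w))
    accepted.sort(key=lambda e: (e[2], e[0], e[1]))

    for u, v, w in accepted:
        if w <= 1:
            g.add_edge(u, v, weight=max(w, 0))
            continue
        prev = u
        for s in range(1, w):
            step = f"step|{u}|{v}|{s}"
            g.add_node(step, species="", origin="", abundance=0, is_step_node=1)
            g.add_edge(prev, step, weight=1)
            prev = step
        g.add_edge(prev, v, weight=1)
    return MSTGraph(g, accepted)


def same_species_edge_fraction(mst: MSTGraph) -> float:
    """Fraction of pre-expansion MST edges joining same-species haplotypes."""
    edges = mst.weighted_edges
    if not edges:
        return float("nan")
    g = mst.graph
    same = sum(1 for u, v, _ in edges
               if g.nodes[u]["species"] == g.nodes[v]["species"])
    return same / len(edges)


def species_coherence_test(mst: MSTGraph, n_permutations: int = 999,
                           seed: int = 0) -> tuple[float, float]:
    """Permutation test for species clustering along the MST.

    Shuffles species labels across haplotype nodes and compares the observed
    same-species edge fraction with the permutation distribution. Returns
    (observed fraction, one-sided p-value for 'observed is high').
    """
    rng = np.random.default_rng(seed)
    observed = same_species_edge_fraction(mst)
    nodes = mst.haplotype_nodes()
    species = [mst.graph.nodes[n]["species"] for n in nodes]
    edge_idx = [(nodes.index(u), nodes.index(v)) for u, v, _ in mst.weighted_edges]
    count_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(species))
        shuffled = [species[i] for i in perm]
        frac = sum(1 for i, j in edge_idx if shuffled[i] == shuffled[j]) / len(edge_idx)
        if frac >= observed:
            count_ge += 1
    p = (count_ge + 1) / (n_permutations + 1)
    return observed, p


def export_graph(mst: MSTGraph, gml_path, node_table_path=None) -> None:
    """Write the expanded graph as GML plus an optional TSV node table."""
    try:
        nx.write_gml(mst.graph, str(gml_path))
    except OSError as exc:
        raise ParameterError(f"could not write GML to {gml_path}: {exc}") from exc
    if node_table_path is not None:
        rows = [(n, a["species"], a["origin"], a["abundance"], a["is_step_node"])
                for n, a in mst.graph.nodes(data=True)]
        pd.DataFrame(rows, columns=["node", "species", "origin", "abundance",
                                    "is_step_node"]).to_csv(
            node_table_path, sep="\t", index=False)


def load_graph(gml_path) -> nx.Graph:
    return nx.read_gml(str(gml_path))


def table_to_rows(table: HaplotypeTable) -> list[HapRow]:
    return list(table.rows)
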