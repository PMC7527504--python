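"""Haplotype networks: minimum spanning network, median joining, rho dating.

A *minimum spanning network* (MSN) over the distinct haplotypes of a
nucleotide alignment is the union of all minimum spanning trees of the
Hamming-distance graph; with a relaxation ``epsilon > 0`` an edge is also
kept when its endpoints are only connected by edges more than ``epsilon``
mutations cheaper.

The *median-joining* network iterates Bandelt-style: starting from the
ε-relaxed MSN, median (per-site majority consensus) vectors of connected
node triples are added whenever they reduce the cost of connecting the
triple, and unhelpful medians are pruned, until a fixed point.  Medians
never increase the minimal spanning cost, so the final network's
spanning length is at most the MST length over the observed haplotypes.

The *rho statistic* of an ancestral node against a descendant set is the
mean shortest-path mutation count, converted to years by dividing by the
mutation rate ``mu`` (mutations per year); with the S-allele rate
``mu = 1e-3`` an age in years is 1000 × rho.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections import Counter
from pathlib import Path

import networkx as nx

from .alignment import Alignment

__all__ = [
    "HaplotypeNetwork",
    "RhoAge",
    "minimum_spanning_network",
    "median_joining_network",
    "rho_age",
    "write_network_tsv",
    "write_network_graphml",
]


def hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


@dataclasses.dataclass
class HaplotypeNetwork:
    """A haplotype network.

    ``graph`` nodes are haplotype sequences (strings); node attributes:
    ``label`` (representative id or ``median_k``), ``count`` (sample
    multiplicity, 0 for medians), ``members`` (ids collapsed into the
    node), ``is_median``.  Edge attribute ``weight`` is the mutation
    count (positive integer).
    """

    graph: nx.Graph

    @property
    def observed(self) -> list[str]:
        return [h for h, d in self.graph.nodes(data=True) if not d["is_median"]]

    @property
    def medians(self) -> list[str]:
        return [h for h, d in self.graph.nodes(data=True) if d["is_median"]]

    def label_of(self, hap: str) -> str:
        return self.graph.nodes[hap]["label"]

    def node_by_label(self, label: str) -> str:
        for h, d in self.graph.nodes(data=True):
            if d["label"] == label or label in d["members"]:
                return h
        raise KeyError(f"no network node labelled {label!r}; "
                       f"known labels: {sorted(d['label'] for _, d in self.graph.nodes(data=True))}")

    @property
    def total_mutation_length(self) -> int:
        """Sum of edge weights of a minimum spanning tree of the network."""
        mst = nx.minimum_spanning_tree(self.graph, weight="weight")
        return int(sum(d["weight"] for _, _, d in mst.edges(data=True)))


def _collapse(haplotypes: Alignment) -> dict[str, list[str]]:
    """Map distinct sequence -> sorted list of member ids."""
    groups: dict[str, list[str]] = {}
    for rec in haplotypes:
        if set(rec.seq) - set("ACGT"):
            raise ValueError(
                f"haplotype {rec.id!r} contains non-ACGT states; "
                "strip gaps/ambiguities first"
            )
        groups.setdefault(rec.seq, []).append(rec.id)
    return {h: sorted(ids) for h, ids in groups.items()}


def _msn_edges(nodes: list[str], epsilon: int = 0) -> list[tuple[str, str, int]]:
    """ε-relaxed union-of-all-MSTs edge set over Hamming distances.

    An edge (u, v, w) is kept iff u and v are not connected using only
    edges of weight < w − ε; at ε = 0 this is exactly the criterion for
    membership in at least one minimum spanning tree.
    """
    pairs = [(u, v, hamming(u, v)) for u, v in itertools.combinations(nodes, 2)]
    kept = []
    for u, v, w in pairs:
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from((a, b) for a, b, x in pairs if x < w - epsilon)
        if not nx.has_path(g, u, v):
            kept.append((u, v, w))
    return kept


def _build(nodes: dict[str, list[str]], medians: list[str],
           epsilon: int) -> HaplotypeNetwork:
    g = nx.Graph()
    for h, ids in nodes.items():
        g.add_node(h, label=ids[0], count=len(ids), members=ids, is_median=False)
    for k, h in enumerate(medians, start=1):
        g.add_node(h, label=f"median_{k}", count=0, members=[], is_median=True)
    for u, v, w in _msn_edges(list(g.nodes), epsilon):
        g.add_edge(u, v, weight=w)
    return HaplotypeNetwork(graph=g)


def minimum_spanning_network(
    haplotypes: Alignment, epsilon: int = 0
) -> HaplotypeNetwork:
    """Minimum spanning network of the distinct haplotypes.

    Identical sequences are collapsed into one node carrying their
    multiplicity; a single distinct haplotype yields a single-node
    network.
    """
    groups = _collapse(haplotypes)
    return _build(groups, [], epsilon)


def _median_vector(a: str, b: str, c: str) -> str:
    out = []
    for x, y, z in zip(a, b, c):
        cnt = Counter((x, y, z))
        state, k = cnt.most_common(1)[0]
        out.append(state if k >= 2 else x)  # 3-way tie impossible within a triple? keep a
    return "".join(out)


def median_joining_network(
    haplotypes: Alignment, epsilon: int = 0, max_iter: int = 100
) -> HaplotypeNetwork:
    """Median-joining network (Bandelt-style) of the distinct haplotypes.

    Each round rebuilds the ε-relaxed MSN over observed + median nodes,
    scans connected triples (two incident edges sharing a node), and adds
    the median vector with the largest cost reduction — the triple's star
    cost through the median must undercut its current two-edge connection.
    After convergence, median nodes whose removal leaves the spanning
    cost unchanged are pruned.
    """
    groups = _collapse(haplotypes)
    medians: list[str] = []
    for _ in range(max_iter):
        net = _build(groups, medians, epsilon)
        g = net.graph
        best_gain = 0
        best_median: str | None = None
        for v in g.nodes:
            for u, w in itertools.combinations(g.neighbors(v), 2):
                m = _median_vector(u, v, w)
                if m in g.nodes:
                    continue
                star = hamming(u, m) + hamming(v, m) + hamming(w, m)
                current = g[u][v]["weight"] + g[v][w]["weight"]
                gain = current - star
                if gain > best_gain or (gain == best_gain and gain > 0
                                        and (best_median is None or m < best_median)):
                    best_gain = gain
                    best_median = m
        if best_median is None:
            break
        medians.append(best_median)
    # prune medians that no longer reduce the spanning cost
    changed = True
    while changed:
        changed = False
        net = _build(groups, medians, epsilon)
        base = net.total_mutation_length
        for m in list(medians):
            trial = [x for x in medians if x != m]
            if _build(groups, trial, epsilon).total_mutation_length <= base:
                medians = trial
                changed = True
                break
    return _build(groups, medians, epsilon)


# ---------------------------------------------------------------------------
# Rho dating
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class RhoAge:
    """Mutational age of an ancestral node relative to descendants."""

    ancestor: str
    descendants: tuple[str, ...]
    rho: float
    mu: float
    age_years: float


def rho_age(
    net: HaplotypeNetwork,
    ancestor: str,
    descendants: list[str],
    mu: float = 1e-3,
) -> RhoAge:
    """Rho statistic and age of ``ancestor`` against ``descendants``.

    ``ancestor``/``descendants`` are node labels (or member ids).  Rho is
    the mean shortest-path mutation count from the ancestor; the age in
    years is ``rho / mu`` with ``mu`` in mutations per year.
    """
    if mu <= 0:
        raise ValueError("mutation rate mu must be positive")
    anc = net.node_by_label(ancestor)
    total = 0.0
    for d in descendants:
        node = net.node_by_label(d)
        try:
            total += nx.shortest_path_length(net.graph, anc, node, weight="weight")
        except nx.NetworkXNoPath:
            raise ValueError(f"descendant {d!r} unreachable from {ancestor!r}")
    rho = total / len(descendants) if descendants else 0.0
    return RhoAge(
        ancestor=ancestor,
        descendants=tuple(descendants),
        rho=rho,
        mu=mu,
        age_years=rho / mu,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_network_tsv(net: HaplotypeNetwork, edge_path: str | Path,
                      node_path: str | Path) -> None:
    """Write edge list (source, target, weight) and node table TSVs."""
    g = net.graph
    with Path(edge_path).open("w") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, d in sorted(g.edges(data=True),
                              key=lambda e: (g.nodes[e[0]]["label"],
                                             g.nodes[e[1]]["label"])):
            fh.write(f"{g.nodes[u]['label']}\t{g.nodes[v]['label']}\t{d['weight']}\n")
    with Path(node_path).open("w") as fh:
        fh.write("label\tcount\tis_median\tmembers\n")
        for h, d in sorted(g.nodes(data=True), key=lambda nd: nd[1]["label"]):
            fh.write(f"{d['label']}\t{d['count']}\t{int(d['is_median'])}\t"
                     f"{','.join(d['members'])}\n")


def write_network_graphml(net: HaplotypeNetwork, path: str | Path) -> None:
    g = nx.Graph()
    for h, d in net.graph.nodes(data=True):
        g.add_node(d["label"], count=d["count"], is_median=int(d["is_median"]),
                   members=",".join(d["members"]))
    for u, v, d in net.graph.edges(data=True):
        g.add_edge(net.graph.nodes[u]["label"], net.graph.nodes[v]["label"],
                   weight=int(d["weight"]))
    nx.write_graphml(g, str(path))
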