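"""Poisson-corrected protein distances and UPGMA with bootstrap.

The evolutionary distance between two aligned protein sequences is the
Poisson correction ``d = -ln(1 - p)`` of the proportion ``p`` of
differing amino-acid sites, in units of substitutions per site.
Ambiguous positions (gaps or ``X``) are removed per sequence pair
(pairwise deletion) by default, matching the convention of the common
tree-building tools; complete deletion is available by flag.

UPGMA agglomerates by group-size-weighted (arithmetic average) cluster
distances; ties are broken on the lexicographically smallest member
labels so the topology is reproducible.  Bootstrap support is the
percentage of column-resampled replicate trees containing each clade of
the original tree.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np

from .alignment import Alignment

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "poisson_distance",
    "upgma",
    "bootstrap_upgma",
    "tree_clades",
    "is_ultrametric",
]


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    """A labelled symmetric distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "labels", tuple(self.labels))
        k = len(self.labels)
        if d.shape != (k, k):
            raise ValueError(f"matrix shape {d.shape} does not match {k} labels")
        if not np.all(np.isfinite(d)):
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])


@dataclasses.dataclass
class TreeNode:
    """A rooted (binary for internal nodes) tree with branch lengths."""

    name: str | None = None
    children: list["TreeNode"] = dataclasses.field(default_factory=list)
    branch_length: float = 0.0
    support: float | None = None  # bootstrap %, internal nodes only
    height: float = 0.0           # agglomeration height (root-to-tip span)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def walk(self) -> Iterable["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def to_newick(self, digits: int = 6) -> str:
        def fmt(node: TreeNode, root: bool) -> str:
            if node.is_leaf:
                body = node.name or ""
            else:
                inner = ",".join(fmt(c, False) for c in node.children)
                label = "" if node.support is None else f"{node.support:.0f}"
                body = f"({inner}){label}"
            if root:
                return body
            return f"{body}:{node.branch_length:.{digits}f}"

        return fmt(self, True) + ";"


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

_AMBIGUOUS = {"-", "X", "*"}


def poisson_distance(
    prot_aln: Alignment, deletion: str = "pairwise"
) -> DistanceMatrix:
    """Poisson-corrected amino-acid distance matrix.

    ``deletion`` is ``"pairwise"`` (default: ambiguous positions removed
    per sequence pair) or ``"complete"`` (columns with any ambiguity
    removed once for all pairs).  Raises if a pair differs at every
    compared site (p >= 1, distance undefined).
    """
    if prot_aln.kind != "protein":
        raise ValueError("poisson_distance expects a protein alignment")
    seqs = [r.seq for r in prot_aln.records]
    n = len(seqs)
    if deletion == "complete":
        keep = [j for j in range(prot_aln.length)
                if not any(s[j] in _AMBIGUOUS for s in seqs)]
        seqs = ["".join(s[j] for j in keep) for s in seqs]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diffs = valid = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in _AMBIGUOUS or b in _AMBIGUOUS:
                    continue
                valid += 1
                if a != b:
                    diffs += 1
            if valid == 0:
                raise ValueError(
                    f"no comparable sites between {prot_aln.ids[i]!r} "
                    f"and {prot_aln.ids[j]!r}"
                )
            p = diffs / valid
            if p >= 1.0:
                raise ValueError(
                    f"p = 1 between {prot_aln.ids[i]!r} and {prot_aln.ids[j]!r}; "
                    "Poisson distance undefined"
                )
            d[i, j] = d[j, i] = -np.log1p(-p)
    return DistanceMatrix(labels=prot_aln.ids, d=d)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma(dm: DistanceMatrix) -> TreeNode:
    """Build an ultrametric UPGMA tree from a distance matrix.

    Group-size-weighted arithmetic-average agglomeration; among equally
    close cluster pairs the one with the lexicographically smallest
    (member label) pair is merged, making the output deterministic.
    """
    k = len(dm.labels)
    if k < 2:
        raise ValueError("UPGMA requires at least 2 labels")
    clusters: dict[int, TreeNode] = {
        i: TreeNode(name=lab, height=0.0) for i, lab in enumerate(dm.labels)
    }
    sizes = {i: 1 for i in range(k)}
    minlab = {i: dm.labels[i] for i in range(k)}  # lexic. smallest member label
    dist = {frozenset((i, j)): float(dm.d[i, j])
            for i in range(k) for j in range(i + 1, k)}
    next_id = k
    while len(clusters) > 1:
        # pick minimal-distance pair; tie-break on sorted member labels
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted(minlab[i] for i in kv[0]))),
        )
        pair, dmin = best
        i, j = sorted(pair, key=lambda c: minlab[c])
        height = dmin / 2.0
        a, b = clusters.pop(i), clusters.pop(j)
        a.branch_length = height - a.height
        b.branch_length = height - b.height
        parent = TreeNode(children=[a, b], height=height)
        # update distances to the new cluster (weighted average)
        ni, nj = sizes.pop(i), sizes.pop(j)
        for other in list(clusters):
            dio = dist.pop(frozenset((i, other)))
            djo = dist.pop(frozenset((j, other)))
            dist[frozenset((next_id, other))] = (ni * dio + nj * djo) / (ni + nj)
        del dist[pair]
        clusters[next_id] = parent
        sizes[next_id] = ni + nj
        minlab[next_id] = min(minlab[i], minlab[j])
        del minlab[i], minlab[j]
        next_id += 1
    return clusters.popitem()[1]


def tree_clades(tree: TreeNode) -> set[frozenset[str]]:
    """Leaf-label sets of all internal nodes except the root."""
    root_leaves = frozenset(tree.leaf_names())
    clades = set()
    for node in tree.walk():
        if node.is_leaf:
            continue
        clade = frozenset(node.leaf_names())
        if clade != root_leaves:
            clades.add(clade)
    return clades


def is_ultrametric(tree: TreeNode, tol: float = 1e-9) -> bool:
    """All root-to-leaf path lengths equal within ``tol``."""

    def depths(node: TreeNode, acc: float) -> list[float]:
        acc += node.branch_length
        if node.is_leaf:
            return [acc]
        out: list[float] = []
        for c in node.children:
            out.extend(depths(c, acc))
        return out

    d = [x - tree.branch_length for x in depths(tree, 0.0)]
    return max(d) - min(d) <= tol


def bootstrap_upgma(
    prot_aln: Alignment,
    replicates: int = 500,
    seed: int | None = None,
    deletion: str = "pairwise",
) -> TreeNode:
    """UPGMA tree with bootstrap supports from column resampling.

    Columns are resampled with replacement ``replicates`` times with a
    seeded generator (one ``integers`` draw of the column index vector
    per replicate, in replicate order); support for each internal clade
    of the original tree is the percentage of replicate trees containing
    it.  ``replicates=0`` returns the tree without supports.
    """
    tree = upgma(poisson_distance(prot_aln, deletion=deletion))
    if replicates <= 0:
        return tree
    rng = np.random.default_rng(seed)
    L = prot_aln.length
    seqs = [r.seq for r in prot_aln.records]
    counts: dict[frozenset[str], int] = {c: 0 for c in tree_clades(tree)}
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        boot = Alignment(
            tuple(
                dataclasses.replace(r, seq="".join(s[j] for j in cols))
                for r, s in zip(prot_aln.records, seqs)
            ),
            kind="protein",
        )
        try:
            btree = upgma(poisson_distance(boot, deletion=deletion))
        except ValueError:
            continue  # degenerate resample (all-ambiguous pair); skip
        bclades = tree_clades(btree)
        for c in counts:
            if c in bclades:
                counts[c] += 1
    for node in tree.walk():
        if node.is_leaf:
            continue
        clade = frozenset(node.leaf_names())
        if clade in counts:
            node.support = 100.0 * counts[clade] / replicates
    return tree
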