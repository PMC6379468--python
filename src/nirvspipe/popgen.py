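"""Shared-allele distances between populations and bootstrapped NJ trees.

Each population carries, per locus, a set of allele labels (size/sequence
classes; an explicit ``null`` allele records locus absence).  The distance
between two populations is one minus the mean per-locus Dice sharing
coefficient:

    DAS(A, B) = 1 - (1/L) * sum_l 2 |A_l & B_l| / (|A_l| + |B_l|)

Trees are built by Saitou-Nei neighbor joining on the DAS matrix, with
bipartition support from bootstrap resampling of loci (1000 replicates by
default).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .core import NirvsLocus

NULL_ALLELE = "null"


class AlleleTable:
    """Populations x loci mapping to non-empty sets of allele labels."""

    def __init__(self, data: Mapping[str, Mapping[str, Iterable[str]]]):
        if not data:
            raise ValueError("empty allele table")
        loci = None
        self._data: dict[str, dict[str, frozenset[str]]] = {}
        for pop, per_locus in data.items():
            row = {locus: frozenset(alleles) for locus, alleles in per_locus.items()}
            for locus, alleles in row.items():
                if not alleles:
                    raise ValueError(f"empty allele set for {pop!r}/{locus!r}")
            if loci is None:
                loci = set(row)
            elif set(row) != loci:
                raise ValueError(f"population {pop!r} has a different locus set")
            self._data[pop] = row
        self._loci = sorted(loci or ())
        if not self._loci:
            raise ValueError("allele table has no loci")

    @property
    def populations(self) -> list[str]:
        return list(self._data)

    @property
    def loci(self) -> list[str]:
        return list(self._loci)

    def alleles(self, population: str, locus: str) -> frozenset[str]:
        return self._data[population][locus]

    def subset(self, loci: Iterable[str]) -> "AlleleTable":
        loci = list(loci)
        if not loci:
            raise ValueError("subset leaves no loci")
        missing = [l for l in loci if l not in self._data[self.populations[0]]]
        if missing:
            raise ValueError(f"loci not in table: {missing}")
        return AlleleTable(
            {pop: {l: self._data[pop][l] for l in loci} for pop in self._data}
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "AlleleTable":
        """CSV with columns population, locus, alleles (semicolon-separated)."""
        data: dict[str, dict[str, set[str]]] = {}
        with open(path, newline="") as handle:
            for row in csv.DictReader(handle):
                alleles = {a for a in row["alleles"].split(";") if a}
                data.setdefault(row["population"], {})[row["locus"]] = alleles
        return cls(data)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(["population", "locus", "alleles"])
            for pop in self.populations:
                for locus in self.loci:
                    writer.writerow([pop, locus, ";".join(sorted(self.alleles(pop, locus)))])


def das_distance(
    a: Mapping[str, frozenset[str]] | Mapping[str, set[str]],
    b: Mapping[str, frozenset[str]] | Mapping[str, set[str]],
    loci: Sequence[str] | None = None,
) -> float:
    """Shared-allele distance between two per-locus allele-set profiles.

    ``loci`` may repeat entries (bootstrap resampling); by default the
    common locus set is used once each.
    """
    if loci is None:
        if set(a) != set(b):
            raise ValueError("profiles cover different loci")
        loci = sorted(a)
    if len(loci) == 0:
        raise ValueError("no loci")
    total = 0.0
    for locus in loci:
        sa, sb = set(a[locus]), set(b[locus])
        total += 2 * len(sa & sb) / (len(sa) + len(sb))
    return 1.0 - total / len(loci)


def das_matrix(
    table: AlleleTable, loci: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Symmetric DAS matrix over the table's populations."""
    pops = table.populations
    n = len(pops)
    mat = np.zeros((n, n))
    profiles = {p: {l: table.alleles(p, l) for l in table.loci} for p in pops}
    use = list(loci) if loci is not None else table.loci
    for i in range(n):
        for j in range(i + 1, n):
            d = das_distance(profiles[pops[i]], profiles[pops[j]], use)
            mat[i, j] = mat[j, i] = d
    return mat, pops


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class TreeNode:
    """Node of an unrooted tree (represented with a trifurcating root)."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(child._newick() for child in self.children)
        label = "" if self.support is None else f"{self.support:.3g}"
        return f"({inner}){label}:{self.length:.6g}"


def neighbor_joining(matrix: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree (trifurcating root).

    Negative branch-length estimates are clamped to zero with the deficit
    moved to the sister branch.  Ties in the Q criterion break on the
    smallest (i, j) index pair, so the result is deterministic.
    """
    D = np.array(matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or len(labels) != n:
        raise ValueError("matrix must be square and match labels")
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if not np.allclose(D, D.T):
        raise ValueError("matrix must be symmetric")
    nodes: list[TreeNode] = [TreeNode(name=label) for label in labels]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sums = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * D[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        # reuse slot i for the new node
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
            D[i, k] = D[k, i] = dk
        nodes[i] = parent
        active.remove(j)
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    li, lj, lk = max(li, 0.0), max(lj, 0.0), max(lk, 0.0)
    nodes[i].length, nodes[j].length, nodes[k].length = li, lj, lk
    return TreeNode(children=[nodes[i], nodes[j], nodes[k]])


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def patristic_distances(tree: TreeNode) -> tuple[np.ndarray, list[str]]:
    """Leaf-to-leaf path-length matrix of a tree."""
    leaves = tree.leaves()
    names = [leaf.name for leaf in leaves]
    paths: dict[str, dict[TreeNode, float]] = {}

    def walk(node: TreeNode, dist_from_root: float, ancestry: list[tuple[TreeNode, float]]):
        ancestry = ancestry + [(node, dist_from_root)]
        if node.is_leaf:
            paths[node.name] = {anc: dist_from_root - d for anc, d in ancestry}
        for child in node.children:
            walk(child, dist_from_root + child.length, ancestry)

    walk(tree, 0.0, [])
    n = len(names)
    mat = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            pa, pb = paths[names[a]], paths[names[b]]
            shared = set(pa) & set(pb)
            # distance through the deepest common ancestor
            d = min(pa[anc] + pb[anc] for anc in shared)
            mat[a, b] = mat[b, a] = d
    return mat, names


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalized as the side not holding
    the lexicographically smallest leaf."""
    all_leaves = set(tree.leaf_names())
    anchor = min(all_leaves)
    out: set[frozenset[str]] = set()

    def walk(node: TreeNode):
        for child in node.children:
            side = set(child.leaf_names())
            if 2 <= len(side) <= len(all_leaves) - 2:
                canon = side if anchor not in side else all_leaves - side
                out.add(frozenset(canon))
            walk(child)

    walk(tree)
    return out


def annotate_support(
    tree: TreeNode, support: Mapping[frozenset[str], float]
) -> TreeNode:
    """Attach bootstrap support to internal edges (in place)."""
    all_leaves = set(tree.leaf_names())
    anchor = min(all_leaves)

    def walk(node: TreeNode):
        for child in node.children:
            if not child.is_leaf:
                side = set(child.leaf_names())
                if 2 <= len(side) <= len(all_leaves) - 2:
                    canon = side if anchor not in side else all_leaves - side
                    child.support = support.get(frozenset(canon), 0.0)
            walk(child)

    walk(tree)
    return tree


def bootstrap_tree(
    table: AlleleTable, n_reps: int = 1000, seed: int | None = None
) -> TreeNode:
    """NJ tree from the full table with locus-bootstrap bipartition support.

    Loci are resampled with replacement ``n_reps`` times from a single
    seeded stream; the support of an internal edge is the fraction of
    replicate trees containing its bipartition.
    """
    if len(table.populations) < 3:
        raise ValueError("need >= 3 populations")
    rng = np.random.default_rng(seed)
    loci = table.loci
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        picks = [loci[i] for i in rng.integers(0, len(loci), size=len(loci))]
        mat, pops = das_matrix(table, picks)
        rep_tree = neighbor_joining(mat, pops)
        for bipart in bipartitions(rep_tree):
            counts[bipart] = counts.get(bipart, 0) + 1
    mat, pops = das_matrix(table)
    tree = neighbor_joining(mat, pops)
    support = {b: c / n_reps for b, c in counts.items()}
    return annotate_support(tree, support)


def subset_tree(
    table: AlleleTable,
    loci_meta: Sequence[NirvsLocus],
    predicate: Callable[[NirvsLocus], bool],
    n_reps: int = 1000,
    seed: int | None = None,
) -> TreeNode:
    """Bootstrap NJ tree on the loci satisfying ``predicate`` (e.g. one viral
    family or one genomic context)."""
    keep = [l.locus_id for l in loci_meta if predicate(l) and l.locus_id in set(table.loci)]
    if not keep:
        raise ValueError("locus filter leaves nothing to analyse")
    return bootstrap_tree(table.subset(keep), n_reps=n_reps, seed=seed)


def write_distance_matrix(mat: np.ndarray, labels: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("\t" + "\t".join(labels) + "\n")
        for i, label in enumerate(labels):
            handle.write(label + "\t" + "\t".join(f"{v:.6g}" for v in mat[i]) + "\n")
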