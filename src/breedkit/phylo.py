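"""Genotype distances and distance-based tree building.

The individual-level distance is allele sharing: d(i, j) is the mean of
|g_i - g_j| / 2 over SNPs non-missing in both individuals, i.e. one
minus identity-by-state similarity. Trees are built by Neighbor-Joining
(Saitou & Nei agglomeration, exact on additive matrices), BioNJ
(variance-weighted reduction) or UPGMA (average linkage, ultrametric),
with SNP-bootstrap support on internal branches.

Determinism: agglomeration ties are broken by the lowest (row, col)
index pair; negative NJ branch estimates are clamped to zero with the
deficit moved onto the sibling edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hapmap_io import BreedkitError, GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "ibs_distance",
    "neighbor_joining",
    "bionj",
    "upgma",
    "bootstrap_support",
]


@dataclass
class DistanceMatrix:
    individual_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise BreedkitError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise BreedkitError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise BreedkitError("distance matrix diagonal must be zero")
        if (self.values < -1e-12).any():
            raise BreedkitError("distances must be non-negative")


@dataclass
class TreeNode:
    """Node of a phylogenetic tree; ``length`` is the edge to the parent."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Rooted representation of a (possibly unrooted) tree.

    NJ/BioNJ trees carry a trifurcating root and should be read as
    unrooted; UPGMA trees are genuinely rooted and ultrametric.
    """

    root: TreeNode
    rooted: bool = False

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def rec(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            for c in node.children:
                rec(c)

        rec(self.root)
        return out

    def leaf_names(self) -> list[str]:
        names = [lf.name for lf in self.leaves()]
        if any(n is None or n == "" for n in names):
            raise BreedkitError("tree has an unlabelled leaf")
        return names  # type: ignore[return-value]

    def to_newick(self) -> str:
        self.leaf_names()  # raises on unlabelled leaves

        def fmt_len(x: float) -> str:
            return f"{x:.10g}"

        def rec(node: TreeNode, top: bool) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                inner = ",".join(rec(c, False) for c in node.children)
                label = "" if node.support is None else fmt_len(node.support)
                s = f"({inner}){label}"
            if top:
                return s
            return f"{s}:{fmt_len(node.length)}"

        if self.root.is_leaf:
            return f"{self.root.name}:{fmt_len(self.root.length)};"
        return rec(self.root, True) + ";"

    # -- path lengths and splits ----------------------------------------
    def leaf_distance_matrix(self) -> DistanceMatrix:
        """Pairwise sum of branch lengths between leaves."""
        names = self.leaf_names()
        index = {n: i for i, n in enumerate(names)}
        n = len(names)
        D = np.zeros((n, n))

        def below(node: TreeNode) -> list[tuple[int, float]]:
            # returns (leaf index, distance to this node); fills D on merge
            if node.is_leaf:
                return [(index[node.name], 0.0)]
            groups = []
            for c in node.children:
                g = [(i, d + c.length) for i, d in below(c)]
                groups.append(g)
            merged: list[tuple[int, float]] = []
            for gi, g in enumerate(groups):
                for gj in range(gi + 1, len(groups)):
                    for i, di in g:
                        for j, dj in groups[gj]:
                            D[i, j] = D[j, i] = di + dj
                merged.extend(g)
            return merged

        below(self.root)
        return DistanceMatrix(names, D)

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial unrooted splits, each named by the side not
        containing the lexicographically first leaf."""
        names = self.leaf_names()
        all_leaves = frozenset(names)
        ref = min(names)
        splits: set[frozenset[str]] = set()

        def rec(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            side = frozenset().union(*(rec(c) for c in node.children))
            if node is not self.root and 2 <= len(side) <= len(names) - 2:
                canon = side if ref not in side else all_leaves - side
                splits.add(canon)
            return side

        rec(self.root)
        return splits

    def clades(self) -> set[frozenset[str]]:
        """Leaf sets below internal nodes (for rooted-tree support)."""
        out: set[frozenset[str]] = set()

        def rec(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            s = frozenset().union(*(rec(c) for c in node.children))
            if node is not self.root and len(s) >= 2:
                out.add(s)
            return s

        rec(self.root)
        return out


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def ibs_distance(G: GenotypeMatrix) -> DistanceMatrix:
    """Allele-sharing distance: 1 - identity-by-state similarity.

    d(i, j) averages |g_i - g_j| / 2 over SNPs typed in both; a pair
    with no shared non-missing SNP is an error.
    """
    X = np.asarray(G.dosages, dtype=float)
    n = X.shape[0]
    M = ~np.isnan(X)
    Xz = np.nan_to_num(X)
    D = np.zeros((n, n))
    for i in range(n):
        shared = M[i] & M
        cnt = shared.sum(axis=1)
        diff = np.where(shared, np.abs(Xz[i] - Xz), 0.0).sum(axis=1)
        zero = np.nonzero(cnt == 0)[0]
        bad = [j for j in zero if j != i]
        if bad:
            raise BreedkitError(
                f"no shared non-missing SNPs between {G.individual_ids[i]!r} "
                f"and {G.individual_ids[bad[0]]!r}"
            )
        with np.errstate(invalid="ignore"):
            D[i] = diff / cnt / 2.0
    D[np.arange(n), np.arange(n)] = 0.0
    D = (D + D.T) / 2.0
    return DistanceMatrix(list(G.individual_ids), D)


# ---------------------------------------------------------------------------
# Tree builders
# ---------------------------------------------------------------------------


def _clamp_pair(b_i: float, b_j: float) -> tuple[float, float]:
    # negative estimate -> 0, deficit moved to the sibling edge
    if b_i < 0:
        b_j += b_i
        b_i = 0.0
    if b_j < 0:
        b_i += b_j
        b_j = 0.0
    return max(b_i, 0.0), max(b_j, 0.0)


def _argmin_pair(Q: np.ndarray) -> tuple[int, int]:
    """Lowest (row, col) pair attaining the matrix minimum (i < j)."""
    n = Q.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = Q[iu]
    best = vals.min()
    # ties: np.argmax on the boolean picks the first True in row-major
    # order of the upper triangle, i.e. the lowest (row, col) pair
    k = int(np.argmax(vals <= best + 1e-12 * max(1.0, abs(best))))
    return int(iu[0][k]), int(iu[1][k])


def _nj_like(D: DistanceMatrix, weighted: bool) -> PhyloTree:
    n = len(D.individual_ids)
    if n < 3:
        raise BreedkitError("NJ/BioNJ requires at least 3 taxa")
    d = np.array(D.values, dtype=float)
    v = np.array(D.values, dtype=float)  # variance proxy (BioNJ)
    nodes = [TreeNode(name=i) for i in D.individual_ids]

    while len(nodes) > 3:
        r = d.sum(axis=1)
        size = len(nodes)
        Q = (size - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = _argmin_pair(Q)
        b_i = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (size - 2))
        b_j = d[i, j] - b_i
        b_i, b_j = _clamp_pair(b_i, b_j)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = b_i, b_j

        others = [k for k in range(size) if k not in (i, j)]
        if weighted and v[i, j] > 1e-12:
            lam = 0.5 + (v[j, others].sum() - v[i, others].sum()) / (
                2.0 * (size - 2) * v[i, j]
            )
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5
        d_new = np.empty(len(others))
        v_new = np.empty(len(others))
        for idx, k in enumerate(others):
            if weighted:
                d_new[idx] = lam * (d[i, k] - b_i) + (1 - lam) * (d[j, k] - b_j)
            else:
                d_new[idx] = (d[i, k] + d[j, k] - d[i, j]) / 2.0
            v_new[idx] = lam * v[i, k] + (1 - lam) * v[j, k] - lam * (1 - lam) * v[i, j]
        d_new = np.clip(d_new, 0.0, None)

        keep = others
        d = d[np.ix_(keep, keep)]
        v = v[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        v = np.pad(v, ((0, 1), (0, 1)))
        d[-1, :-1] = d[:-1, -1] = d_new
        v[-1, :-1] = v[:-1, -1] = v_new
        nodes = [nodes[k] for k in keep] + [parent]

    # three remaining nodes: close with the three-point formulas
    a, b, c = nodes
    e_a = (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0
    e_b = (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0
    e_c = (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0
    a.length, b.length, c.length = (max(e, 0.0) for e in (e_a, e_b, e_c))
    root = TreeNode(children=[a, b, c])
    return PhyloTree(root, rooted=False)


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining; exact on additive distance matrices."""
    return _nj_like(D, weighted=False)


def bionj(D: DistanceMatrix) -> PhyloTree:
    """BioNJ: NJ selection with variance-weighted matrix reduction."""
    return _nj_like(D, weighted=True)


def upgma(D: DistanceMatrix) -> PhyloTree:
    """Average-linkage agglomeration; rooted, ultrametric (height = d/2)."""
    n = len(D.individual_ids)
    if n < 2:
        raise BreedkitError("UPGMA requires at least 2 taxa")
    d = np.array(D.values, dtype=float)
    nodes = [TreeNode(name=i) for i in D.individual_ids]
    heights = [0.0] * n
    sizes = [1] * n

    while len(nodes) > 1:
        work = d.copy()
        np.fill_diagonal(work, np.inf)
        i, j = _argmin_pair(work)
        h = d[i, j] / 2.0
        nodes[i].length = h - heights[i]
        nodes[j].length = h - heights[j]
        parent = TreeNode(children=[nodes[i], nodes[j]])
        others = [k for k in range(len(nodes)) if k not in (i, j)]
        d_new = (sizes[i] * d[i, others] + sizes[j] * d[j, others]) / (
            sizes[i] + sizes[j]
        )
        d = d[np.ix_(others, others)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = d[:-1, -1] = d_new
        new_size = sizes[i] + sizes[j]
        nodes = [nodes[k] for k in others] + [parent]
        heights = [heights[k] for k in others] + [h]
        sizes = [sizes[k] for k in others] + [new_size]

    return PhyloTree(nodes[0], rooted=True)


_BUILDERS = {"nj": neighbor_joining, "bionj": bionj, "upgma": upgma}


def bootstrap_support(
    G: GenotypeMatrix,
    builder: str = "nj",
    B: int = 100,
    seed: int = 0,
) -> PhyloTree:
    """Full-data tree with SNP-bootstrap support on internal branches.

    SNP columns are resampled with replacement B times; the support of
    each internal edge of the full-data tree is the percentage of
    replicate trees containing the same bipartition (clade, for the
    rooted UPGMA case).
    """
    if B < 1:
        raise BreedkitError("B must be >= 1")
    if builder not in _BUILDERS:
        raise BreedkitError(f"unknown builder {builder!r}")
    build = _BUILDERS[builder]
    tree = build(ibs_distance(G))
    splitter = PhyloTree.clades if builder == "upgma" else PhyloTree.bipartitions

    rng = np.random.default_rng(seed)
    m = G.n_snps
    counts: dict[frozenset[str], int] = {s: 0 for s in splitter(tree)}
    for _ in range(B):
        cols = rng.integers(0, m, size=m)
        Gb = GenotypeMatrix(
            list(G.individual_ids),
            G.snps.iloc[cols].assign(id=[f"b{t}" for t in range(m)]).reset_index(drop=True),
            G.dosages[:, cols],
        )
        rep_splits = splitter(build(ibs_distance(Gb)))
        for s in counts:
            if s in rep_splits:
                counts[s] += 1

    names = tree.leaf_names()
    all_leaves = frozenset(names)
    ref = min(names)

    def annotate(node: TreeNode, is_root: bool) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        side = frozenset().union(*(annotate(c, False) for c in node.children))
        if not is_root:
            if builder == "upgma":
                key = side if len(side) >= 2 else None
            else:
                key = None
                if 2 <= len(side) <= len(names) - 2:
                    key = side if ref not in side else all_leaves - side
            if key is not None and key in counts:
                node.support = 100.0 * counts[key] / B
        return side

    annotate(tree.root, True)
    return tree
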