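"""16S-distance phylogenetics: p-distances, neighbour-joining, bootstrap.

Distances are uncorrected p-distances (mismatching sites / compared sites)
computed on gap-free alignment columns; ``N`` positions are excluded
pairwise.  Trees are built by standard neighbour-joining with negative
branch-length estimates clamped to zero and a deterministic tie rule (the
lexicographically smallest taxon pair wins).  Pairwise distances can be
discretised into bands by cutting the rank-ordered distance sequence at its
largest gaps, and orthology-versus-distance decay is fitted as
``y = a * exp(-b * d)`` by linear regression on ``log y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "MultipleAlignment",
    "DistanceMatrix",
    "DistanceBands",
    "TreeNode",
    "read_alignment",
    "strip_gap_columns",
    "p_distance_matrix",
    "jc_distance_matrix",
    "nj_tree",
    "tree_splits",
    "patristic_matrix",
    "bootstrap_support",
    "discretise_distances",
    "fit_exponential",
    "BAND_LABELS_K4",
]

BAND_LABELS_K4 = ("genus", "family", "sub-order", "order")

_ALPHABET = set("ACGTN-")


@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length gapped nucleotide rows, one per taxon."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        bad = set("".join(self.rows)) - _ALPHABET
        if bad:
            raise ValueError(f"invalid alignment characters: {sorted(bad)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if not np.all(np.isfinite(d)):
            raise ValueError("non-finite distances")
        object.__setattr__(self, "d", d)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])


@dataclass(frozen=True)
class DistanceBands:
    """Discretised pairwise distances."""

    k: int
    boundaries: tuple[float, ...]
    assignment: dict[tuple[str, str], str]
    labels: tuple[str, ...]


@dataclass
class TreeNode:
    """A node of an (un)rooted phylogenetic tree."""

    name: Optional[str] = None
    length: float = 0.0  # branch to parent
    children: list["TreeNode"] = field(default_factory=list)

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def to_newick(self, support: Optional[Mapping[frozenset, float]] = None) -> str:
        def fmt(node: TreeNode, root: bool) -> str:
            if not node.children:
                label = node.name or ""
            else:
                inner = ",".join(fmt(c, False) for c in node.children)
                label = f"({inner})"
                if support is not None and not root:
                    key = frozenset(node.leaf_names())
                    if key in support:
                        label += f"{support[key]:g}"
            return label if root else f"{label}:{node.length:g}"

        return fmt(self, True) + ";"


def read_alignment(path: str | Path) -> MultipleAlignment:
    """Read an aligned nucleotide FASTA file."""
    records = list(SeqIO.parse(path, "fasta"))
    return MultipleAlignment(
        taxa=tuple(r.id for r in records),
        rows=tuple(str(r.seq).upper() for r in records),
    )


def strip_gap_columns(a: MultipleAlignment) -> MultipleAlignment:
    """Remove every column containing a gap in any row."""
    if not a.rows:
        return a
    arr = np.array([list(r) for r in a.rows])
    keep = ~(arr == "-").any(axis=0)
    if not keep.any():
        raise ValueError("no-ungapped-columns")
    stripped = arr[:, keep]
    return MultipleAlignment(a.taxa, tuple("".join(row) for row in stripped))


def _pairwise_p(x: np.ndarray, y: np.ndarray) -> float:
    usable = (x != "N") & (y != "N") & (x != "-") & (y != "-")
    total = int(usable.sum())
    if total == 0:
        return 0.0
    return float((x[usable] != y[usable]).sum()) / total


def p_distance_matrix(a: MultipleAlignment) -> DistanceMatrix:
    """Uncorrected substitution frequency per compared site."""
    arr = np.array([list(r) for r in a.rows])
    n = len(a.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pairwise_p(arr[i], arr[j])
    return DistanceMatrix(a.taxa, d)


def jc_distance_matrix(a: MultipleAlignment) -> DistanceMatrix:
    """Jukes-Cantor corrected distances (optional alternative model)."""
    p = p_distance_matrix(a)
    with np.errstate(invalid="raise"):
        arg = 1.0 - 4.0 * p.d / 3.0
        if np.any(arg <= 0):
            raise ValueError("p-distance too large for Jukes-Cantor correction")
        d = -0.75 * np.log(arg)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(a.taxa, d)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbour-joining tree (unrooted; returned rooted at a trifurcation).

    Negative branch-length estimates are clamped to zero.  When several
    pairs minimise the Q criterion the pair whose smallest contained taxon
    names sort first is joined, making the reconstruction deterministic.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbour-joining requires at least 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    keys: list[str] = list(dm.taxa)  # smallest leaf name per active node
    d = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                tie = tuple(sorted((keys[i], keys[j])))
                cand = (q, tie, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    nodes[i].length = max(li, 0.0)
    nodes[j].length = max(lj, 0.0)
    nodes[k].length = max(lk, 0.0)
    order = sorted((i, j, k), key=lambda x: keys[x])
    return TreeNode(children=[nodes[x] for x in order])


def patristic_matrix(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances."""
    leaves = sorted(tree.leaf_names())
    index = {name: i for i, name in enumerate(leaves)}
    n = len(leaves)
    d = np.zeros((n, n))

    def walk(node: TreeNode) -> dict[str, float]:
        if not node.children:
            return {node.name: 0.0}
        below: dict[str, float] = {}
        child_maps = [walk(c) for c in node.children]
        for c, cmap in zip(node.children, child_maps):
            for name in cmap:
                cmap[name] += c.length
        for a_i in range(len(child_maps)):
            for b_i in range(a_i + 1, len(child_maps)):
                for na, da in child_maps[a_i].items():
                    for nb, db in child_maps[b_i].items():
                        d[index[na], index[nb]] = d[index[nb], index[na]] = da + db
        for cmap in child_maps:
            below.update(cmap)
        return below

    walk(tree)
    return DistanceMatrix(tuple(leaves), d)


def tree_splits(tree: TreeNode, min_length: float = 1e-12) -> set[frozenset]:
    """Non-trivial bipartitions of the leaf set induced by internal edges.

    Each split is represented by the leaf-name side *not* containing the
    alphabetically first taxon.  Internal edges of (near-)zero length are
    ignored, so star-like trees yield no splits.
    """
    all_leaves = sorted(tree.leaf_names())
    if not all_leaves:
        return set()
    ref = all_leaves[0]
    n = len(all_leaves)
    splits: set[frozenset] = set()

    def walk(node: TreeNode) -> None:
        for c in node.children:
            if c.children:
                side = frozenset(c.leaf_names())
                if 2 <= len(side) <= n - 2 and c.length > min_length:
                    splits.add(side if ref not in side else frozenset(all_leaves) - side)
            walk(c)

    walk(tree)
    return splits


def bootstrap_support(
    a: MultipleAlignment, n: int = 1000, seed: int = 0
) -> dict[frozenset, float]:
    """Bootstrap support (%) for the splits of the point-estimate NJ tree.

    Columns are resampled with replacement ``n`` times; support for a split
    is the percentage of replicate trees containing it.
    """
    point = nj_tree(p_distance_matrix(a))
    targets = tree_splits(point)
    if not targets:
        return {}
    counts = {s: 0 for s in targets}
    rng = np.random.default_rng(seed)
    arr = np.array([list(r) for r in a.rows])
    n_cols = arr.shape[1]
    for _ in range(n):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep = MultipleAlignment(
            a.taxa, tuple("".join(row) for row in arr[:, cols])
        )
        rep_splits = tree_splits(nj_tree(p_distance_matrix(rep)))
        for s in targets:
            if s in rep_splits:
                counts[s] += 1
    return {s: 100.0 * c / n for s, c in counts.items()}


def discretise_distances(
    pairs: Sequence[tuple[tuple[str, str], float]], k: int = 4
) -> DistanceBands:
    """Cut rank-ordered distances at their k-1 largest adjacent gaps.

    With ``k == 4`` the bands are labelled genus < family < sub-order <
    order in ascending distance; otherwise ``band1..bandk``.  The result is
    invariant to the input order of ``pairs``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = sorted({v for _, v in pairs})
    if len(values) < k:
        raise ValueError(f"need at least {k} distinct distances, got {len(values)}")

    if k == 1:
        boundaries: tuple[float, ...] = ()
    else:
        gaps = [(values[i + 1] - values[i], i) for i in range(len(values) - 1)]
        chosen = sorted(sorted(gaps, key=lambda g: (-g[0], g[1]))[: k - 1], key=lambda g: g[1])
        boundaries = tuple((values[i] + values[i + 1]) / 2.0 for _, i in chosen)

    labels = BAND_LABELS_K4 if k == 4 else tuple(f"band{i + 1}" for i in range(k))
    assignment = {
        pair: labels[int(np.searchsorted(boundaries, dist))] for pair, dist in pairs
    }
    return DistanceBands(k=k, boundaries=boundaries, assignment=assignment, labels=labels)


def fit_exponential(
    points: Sequence[tuple[float, float]]
) -> tuple[float, float, float]:
    """Fit ``y = a * exp(-b * d)`` by least squares on ``log y``.

    Returns ``(a, b, rms_log_residual)``.  Raises on fewer than two points
    or non-positive fractions.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    d = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.any(y <= 0):
        raise ValueError("orthology fractions must be positive")
    slope, intercept = np.polyfit(d, np.log(y), 1)
    resid = np.log(y) - (slope * d + intercept)
    return float(np.exp(intercept)), float(-slope), float(np.sqrt(np.mean(resid**2)))
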