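"""Cross-genome clustering of TCS proteins into orthologue/paralogue groups.

Similarity between two proteins is the number of identical aligned residues
in a global alignment (affine gap penalties, free end gaps) divided by the
length of the shorter sequence — the semantics of greedy incremental
clustering tools.  Clustering is greedy: proteins are processed longest
first and join the first cluster whose representative they match at or above
the cut-off.  A two-tier scheme (default 0.90 / 0.30) automates curation:
low-tier clusters containing within-genome paralogue multiplicity are split
into their high-tier refinements.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .focus_builder import Focus
from .genome_io import GenomeBundle, ProteinRecord
from .tcs_classify import TCSProtein

__all__ = [
    "SimilarityScore",
    "OrthoCluster",
    "align_identity",
    "pairwise_similarity",
    "greedy_cluster",
    "two_tier_cluster",
    "reciprocal_best_hits",
    "flag_clusters",
    "orthology_fraction",
]

#: Gap of length L costs GAP_OPEN + L * GAP_EXTEND.
GAP_OPEN = 10.0
GAP_EXTEND = 1.0

_NEG = -1.0e30

_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_BLOSUM.alphabet)
_CODE = np.full(128, _ALPHABET.index("X"), dtype=np.int64)
for _i, _c in enumerate(_ALPHABET):
    _CODE[ord(_c)] = _i
_SCORES = np.array(_BLOSUM, dtype=np.float64)


@dataclass(frozen=True)
class SimilarityScore:
    """Symmetric pairwise similarity in [0, 1]."""

    a_id: str
    b_id: str
    similarity: float


@dataclass
class OrthoCluster:
    """A cross-genome cluster of putative orthologues/paralogues."""

    cluster_id: str
    members: list[tuple[str, str]]  # (genome_id, protein_id)
    representative: str
    tier: float
    flags: frozenset[str] = frozenset()

    def genomes(self) -> set[str]:
        return {g for g, _ in self.members}

    def multiplicity(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for g, _ in self.members:
            counts[g] = counts.get(g, 0) + 1
        return counts


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def align_identity(
    a: str,
    b: str,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> tuple[float, int]:
    """Global alignment (free end gaps) of two protein sequences.

    Returns ``(score, identities)`` where the score uses BLOSUM62 with an
    affine gap costing ``gap_open + L * gap_extend`` for length L, and end
    gaps are free.  The traceback is deterministic: ties prefer the
    match/mismatch state, then a gap in the second sequence, then a gap in
    the first.

    Three dynamic-programming matrices are kept (Gotoh): ``M`` ends in an
    aligned pair, ``X`` ends in a gap consuming ``a``, ``Y`` ends in a gap
    consuming ``b``.  The ``Y`` row recurrence is evaluated with a running
    maximum so each row is a vector operation.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    ea, eb = _encode(a), _encode(b)
    n, m = len(ea), len(eb)
    openf = gap_open + gap_extend  # first gap residue
    c = gap_extend

    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    Y[0, 1:] = 0.0  # free leading gap in a
    X[1:, 0] = 0.0  # free leading gap in b

    sub = _SCORES[ea][:, eb]  # n x m substitution scores

    js = np.arange(m + 1, dtype=np.float64)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = sub[i - 1] + prev_best[:-1]
        X[i, 1:] = np.maximum(M[i - 1, 1:] - openf, X[i - 1, 1:] - c)
        h1 = np.maximum(M[i], X[i])
        run = np.maximum.accumulate(h1 + c * js)
        Y[i, 1:] = run[:-1] - openf - c * (js[1:] - 1.0)

    H = np.maximum(np.maximum(M, X), Y)

    # deterministic choice of end cell: (n, m) first, then last row right to
    # left, then last column bottom to top (trailing gaps are free)
    best = max(H[n, :].max(), H[:, m].max())
    start: Optional[tuple[int, int]] = None
    if H[n, m] == best:
        start = (n, m)
    if start is None:
        for j in range(m - 1, -1, -1):
            if H[n, j] == best:
                start = (n, j)
                break
    if start is None:
        for i in range(n - 1, -1, -1):
            if H[i, m] == best:
                start = (i, m)
                break
    assert start is not None

    identities = 0
    i, j = start
    state = "M" if M[i, j] == best else ("X" if X[i, j] == best else "Y")
    while i > 0 and j > 0:
        if state == "M":
            if ea[i - 1] == eb[j - 1]:
                identities += 1
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            if M[i, j] == target:
                state = "M"
            elif X[i, j] == target:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            if M[i - 1, j] - openf == X[i, j]:
                state = "M"
            else:
                state = "X"
            i -= 1
        else:  # Y
            if M[i, j - 1] - openf == Y[i, j]:
                state = "M"
            elif X[i, j - 1] - openf == Y[i, j]:
                state = "X"
            else:
                state = "Y"
            j -= 1
    return float(best), identities


def pairwise_similarity(a: ProteinRecord, b: ProteinRecord) -> SimilarityScore:
    """Fraction of identical aligned residues over the shorter sequence."""
    if not a.sequence or not b.sequence:
        raise ValueError("cannot compare empty sequences")
    if a.sequence == b.sequence:
        sim = 1.0
    else:
        _, identities = align_identity(a.sequence, b.sequence)
        sim = identities / min(a.length, b.length)
    return SimilarityScore(a.protein_id, b.protein_id, sim)


def _cluster_order(proteins: Sequence[tuple[str, ProteinRecord]]) -> list[tuple[str, ProteinRecord]]:
    return sorted(proteins, key=lambda gp: (-gp[1].length, gp[1].protein_id))


def greedy_cluster(
    proteins: Sequence[tuple[str, ProteinRecord]],
    cutoff: float,
    prefix: str = "C",
    _cache: Optional[dict[tuple[int, int], float]] = None,
) -> list[OrthoCluster]:
    """Greedy incremental clustering against cluster representatives.

    ``proteins`` is a list of ``(genome_id, ProteinRecord)``.  Proteins are
    processed longest first (ties by ascending protein id); each joins the
    first existing cluster whose representative it matches at or above
    ``cutoff``, otherwise it founds a new cluster and becomes its
    representative.
    """
    if not (0.0 < cutoff <= 1.0):
        raise ValueError("cutoff must be in (0, 1]")
    cache = _cache if _cache is not None else {}

    def sim(a: ProteinRecord, b: ProteinRecord) -> float:
        key = (id(a), id(b))  # call-local; protein ids may repeat across genomes
        if key not in cache:
            cache[key] = pairwise_similarity(a, b).similarity
        return cache[key]

    clusters: list[OrthoCluster] = []
    reps: list[ProteinRecord] = []
    for genome_id, prot in _cluster_order(proteins):
        placed = False
        for cl, rep in zip(clusters, reps):
            if sim(prot, rep) >= cutoff:
                cl.members.append((genome_id, prot.protein_id))
                placed = True
                break
        if not placed:
            clusters.append(
                OrthoCluster(
                    cluster_id=f"{prefix}{len(clusters):04d}",
                    members=[(genome_id, prot.protein_id)],
                    representative=prot.protein_id,
                    tier=cutoff,
                )
            )
            reps.append(prot)
    return clusters


def two_tier_cluster(
    proteins: Sequence[tuple[str, ProteinRecord]],
    high: float = 0.90,
    low: float = 0.30,
) -> list[OrthoCluster]:
    """Two-tier clustering with automated curation splitting.

    Low-tier clusters are kept unless a genome contributes more than one
    member, in which case the cluster is replaced by its intersection with
    the high-tier clustering (paralogues stay together only when they meet
    the high cut-off).  Emitted clusters record the tier they came from.
    """
    if not high > low:
        raise ValueError("high cutoff must exceed low cutoff")
    cache: dict[tuple[int, int], float] = {}
    low_clusters = greedy_cluster(proteins, low, prefix="L", _cache=cache)
    high_clusters = greedy_cluster(proteins, high, prefix="H", _cache=cache)
    high_of: dict[tuple[str, str], str] = {}
    for hc in high_clusters:
        for member in hc.members:
            high_of[member] = hc.cluster_id

    out: list[OrthoCluster] = []
    counter = 0
    for lc in low_clusters:
        if all(v <= 1 for v in lc.multiplicity().values()):
            out.append(replace(lc, cluster_id=f"T{counter:04d}"))
            counter += 1
            continue
        groups: dict[str, list[tuple[str, str]]] = {}
        for member in lc.members:
            groups.setdefault(high_of[member], []).append(member)
        for hid in sorted(groups):
            members = groups[hid]
            rep = next(
                hc.representative for hc in high_clusters if hc.cluster_id == hid
            )
            rep = rep if any(pid == rep for _, pid in members) else members[0][1]
            out.append(
                OrthoCluster(
                    cluster_id=f"T{counter:04d}",
                    members=members,
                    representative=rep,
                    tier=high,
                )
            )
            counter += 1
    return out


def reciprocal_best_hits(
    genome_a: Sequence[ProteinRecord],
    genome_b: Sequence[ProteinRecord],
) -> list[tuple[str, str]]:
    """Pairs where each protein is the other's unique best cross-genome hit.

    Ties for the best score on either side disqualify the pair.
    """
    if not genome_a or not genome_b:
        return []
    sims = np.array(
        [[pairwise_similarity(a, b).similarity for b in genome_b] for a in genome_a]
    )
    pairs: list[tuple[str, str]] = []
    for i, a in enumerate(genome_a):
        row = sims[i]
        j = int(np.argmax(row))
        if (row == row[j]).sum() > 1:
            continue
        col = sims[:, j]
        if (col == col.max()).sum() > 1 or int(np.argmax(col)) != i:
            continue
        pairs.append((a.protein_id, genome_b[j].protein_id))
    return pairs


_SIZE_DIFF_AA = 100


def flag_clusters(
    clusters: Sequence[OrthoCluster],
    bundles: Mapping[str, GenomeBundle],
    tcs: Mapping[str, Mapping[str, TCSProtein]],
    foci: Mapping[str, Sequence[Focus]],
    size_diff_aa: int = _SIZE_DIFF_AA,
) -> list[OrthoCluster]:
    """Mark clusters whose members differ in length, architecture, family,
    gene organisation, or per-genome multiplicity.

    Singleton clusters never carry flags.
    """
    category_of: dict[tuple[str, str], str] = {}
    for genome_id, genome_foci in foci.items():
        for f in genome_foci:
            for pid in f.member_protein_ids:
                category_of[(genome_id, pid)] = f.category.value

    out = []
    for cl in clusters:
        flags: set[str] = set()
        if len(cl.members) > 1:
            lengths = [bundles[g].proteins[pid].length for g, pid in cl.members]
            if max(lengths) - min(lengths) > size_diff_aa:
                flags.add("SIZE_DIFF")
            archs = {tcs[g][pid].architecture for g, pid in cl.members}
            if len(archs) > 1:
                flags.add("ARCH_DIFF")
            families = {
                tcs[g][pid].rr_family
                for g, pid in cl.members
                if tcs[g][pid].rr_family is not None
            }
            if len(families) > 1:
                flags.add("FAMILY_DIFF")
            categories = {
                category_of[(g, pid)] for g, pid in cl.members if (g, pid) in category_of
            }
            if len(categories) > 1:
                flags.add("ORG_DIFF")
            if any(v >= 2 for v in cl.multiplicity().values()):
                flags.add("MULTIPLICITY")
        out.append(replace(cl, flags=frozenset(flags)))
    return out


def orthology_fraction(
    clusters: Sequence[OrthoCluster], genome_a: str, genome_b: str
) -> float:
    """Fraction of the two genomes' proteins found in shared clusters."""
    total = 0
    shared = 0
    for cl in clusters:
        n_ab = sum(1 for g, _ in cl.members if g in (genome_a, genome_b))
        total += n_ab
        if {genome_a, genome_b} <= cl.genomes():
            shared += n_ab
    return shared / total if total else 0.0
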