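import numpy as np
import pytest
from Bio.Align import substitution_matrices

from tcskit.genome_io import ProteinRecord
from tcskit.ortho_cluster import (
    align_identity,
    flag_clusters,
    greedy_cluster,
    orthology_fraction,
    pairwise_similarity,
    reciprocal_best_hits,
    two_tier_cluster,
)

from conftest import AA, bundle_from_layout, rand_protein_seq

_B62 = substitution_matrices.load("BLOSUM62")


def oracle_align(a: str, b: str, gap_open=10.0, gap_extend=1.0):
    """Plain loop-based Gotoh oracle with the documented model and tie rules:
    free end gaps, BLOSUM62, gap of length L costs open + L*extend,
    traceback preferring match state, then gap-in-a, then gap-in-b."""
    n, m = len(a), len(b)
    NEG = -1.0e30
    openf, c = gap_open + gap_extend, gap_extend
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for j in range(1, m + 1):
        Y[0][j] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1]][b[j - 1]]
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] - openf, X[i - 1][j] - c)
            Y[i][j] = max(M[i][j - 1] - openf, X[i][j - 1] - openf, Y[i][j - 1] - c)
    H = lambda i, j: max(M[i][j], X[i][j], Y[i][j])
    best = max(max(H(n, j) for j in range(m + 1)), max(H(i, m) for i in range(n + 1)))
    start = None
    if H(n, m) == best:
        start = (n, m)
    if start is None:
        for j in range(m - 1, -1, -1):
            if H(n, j) == best:
                start = (n, j)
                break
    if start is None:
        for i in range(n - 1, -1, -1):
            if H(i, m) == best:
                start = (i, m)
                break
    i, j = start
    state = "M" if M[i][j] == best else ("X" if X[i][j] == best else "Y")
    identities = 0
    while i > 0 and j > 0:
        if state == "M":
            if a[i - 1] == b[j - 1]:
                identities += 1
            target = M[i][j] - _B62[a[i - 1]][b[j - 1]]
            i, j = i - 1, j - 1
            state = "M" if M[i][j] == target else ("X" if X[i][j] == target else "Y")
        elif state == "X":
            state = "M" if M[i - 1][j] - openf == X[i][j] else "X"
            i -= 1
        else:
            if M[i][j - 1] - openf == Y[i][j]:
                state = "M"
            elif X[i][j - 1] - openf == Y[i][j]:
                state = "X"
            else:
                state = "Y"
            j -= 1
    return best, identities


def prot(pid: str, seq: str) -> ProteinRecord:
    return ProteinRecord.make(pid, seq)


def mutate(seq: str, frac: float, rng) -> str:
    out = list(seq)
    k = int(round(frac * len(seq)))
    for i in rng.choice(len(seq), size=k, replace=False):
        choices = [x for x in AA if x != out[i]]
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


# --- pairwise similarity ----------------------------------------------------


def test_identical_sequences_similarity_one(rng):
    s = rand_protein_seq(rng, 80)
    assert pairwise_similarity(prot("a", s), prot("b", s)).similarity == 1.0


def test_shorter_length_denominator(rng):
    junk = rand_protein_seq(rng, 60)
    sim = pairwise_similarity(prot("a", "ACDEFG"), prot("b", "ACDEFG" + junk))
    assert sim.similarity == 1.0


def test_empty_sequence_errors():
    with pytest.raises(ValueError):
        pairwise_similarity(prot("a", ""), prot("b", "ACD"))


def test_symmetry(rng):
    for _ in range(10):
        x = rand_protein_seq(rng, int(rng.integers(20, 60)))
        y = mutate(x, 0.4, rng)[: int(rng.integers(15, 60))]
        if not y:
            continue
        assert (
            pairwise_similarity(prot("a", x), prot("b", y)).similarity
            == pairwise_similarity(prot("a", y), prot("b", x)).similarity
        )


def test_alignment_against_independent_oracle(rng):
    """200 random pairs <=60 aa: score and identity match the loop oracle."""
    for _ in range(200):
        la, lb = int(rng.integers(5, 61)), int(rng.integers(5, 61))
        a = rand_protein_seq(rng, la)
        if rng.random() < 0.5:
            b = rand_protein_seq(rng, lb)
        else:  # related pair: mutated/truncated copy
            b = mutate(a, float(rng.uniform(0, 0.5)), rng)[:lb]
        score, ident = align_identity(a, b)
        oscore, oident = oracle_align(a, b)
        assert score == oscore
        assert ident == oident


# --- greedy clustering ------------------------------------------------------


def test_three_identical_one_cluster(rng):
    s = rand_protein_seq(rng, 100)
    cls = greedy_cluster([("g1", prot("A", s)), ("g2", prot("B", s)), ("g3", prot("C", s))], 0.9)
    assert len(cls) == 1 and len(cls[0].members) == 3


def test_greedy_hand_trace(rng):
    base = rand_protein_seq(rng, 100)
    a = prot("A", base)
    b = prot("B", mutate(base, 0.05, rng))  # ~0.95 to A
    c = prot("C", rand_protein_seq(rng, 100))  # ~0.05 to both
    assert pairwise_similarity(a, b).similarity >= 0.9
    assert pairwise_similarity(a, c).similarity < 0.3
    cls = greedy_cluster([("g1", a), ("g1", b), ("g2", c)], 0.9)
    member_sets = sorted(tuple(sorted(p for _, p in cl.members)) for cl in cls)
    assert member_sets == [("A", "B"), ("C",)]


def test_cutoff_one_all_distinct(rng):
    ps = [("g", prot(f"P{i}", rand_protein_seq(rng, 60))) for i in range(5)]
    cls = greedy_cluster(ps, 1.0)
    assert all(len(c.members) == 1 for c in cls) and len(cls) == 5


def test_greedy_partition_and_determinism(rng):
    ps = []
    for fam in range(4):
        base = rand_protein_seq(rng, int(rng.integers(80, 200)))
        for i in range(3):
            ps.append((f"g{i}", prot(f"F{fam}_{i}", mutate(base, 0.05, rng))))
    c1 = greedy_cluster(ps, 0.5)
    c2 = greedy_cluster(list(reversed(ps)), 0.5)
    ids1 = sorted(sorted(p for _, p in c.members) for c in c1)
    ids2 = sorted(sorted(p for _, p in c.members) for c in c2)
    assert ids1 == ids2  # input order irrelevant given the sorting rule
    all_members = [p for c in c1 for _, p in c.members]
    assert sorted(all_members) == sorted(p.protein_id for _, p in ps)


# --- two-tier ---------------------------------------------------------------


def test_two_tier_keeps_divergent_pair(rng):
    base = rand_protein_seq(rng, 150)
    a = prot("A1", base)
    b = prot("B1", mutate(base, 0.45, rng))
    sim = pairwise_similarity(a, b).similarity
    assert 0.3 <= sim < 0.9
    cls = two_tier_cluster([("gA", a), ("gB", b)])
    assert len(cls) == 1 and cls[0].tier == 0.30


def test_two_tier_splits_paralogue_cluster(rng):
    base = rand_protein_seq(rng, 150)
    a1 = prot("A1", base)
    a2 = prot("A2", mutate(base, 0.04, rng))  # in-genome duplicate ~0.96
    b1 = prot("B1", mutate(base, 0.55, rng))  # distant orthologue ~0.45
    cls = two_tier_cluster([("gA", a1), ("gA", a2), ("gB", b1)])
    member_sets = sorted(tuple(sorted(p for _, p in cl.members)) for cl in cls)
    assert member_sets == [("A1", "A2"), ("B1",)]
    dup_cluster = next(c for c in cls if len(c.members) == 2)
    assert dup_cluster.tier == 0.90


def test_two_tier_all_dissimilar_singletons(rng):
    ps = [("g", prot(f"P{i}", rand_protein_seq(rng, 80))) for i in range(4)]
    cls = two_tier_cluster(ps)
    assert all(len(c.members) == 1 for c in cls)


def test_high_refines_low_on_random_families(rng):
    for trial in range(8):
        ps = []
        for fam in range(int(rng.integers(2, 5))):
            base = rand_protein_seq(rng, int(rng.integers(100, 250)))
            for i in range(int(rng.integers(1, 4))):
                ps.append(
                    (f"g{i % 2}", prot(f"t{trial}f{fam}m{i}", mutate(base, float(rng.uniform(0, 0.15)), rng)))
                )
        low = greedy_cluster(ps, 0.30)
        high = greedy_cluster(ps, 0.90)
        low_of = {p: i for i, c in enumerate(low) for _, p in c.members}
        for hc in high:
            assert len({low_of[p] for _, p in hc.members}) == 1


# --- reciprocal best hits ---------------------------------------------------


def test_rbh_simple(rng):
    base1, base2 = rand_protein_seq(rng, 100), rand_protein_seq(rng, 120)
    a = [prot("A1", base1), prot("A2", base2)]
    b = [prot("B1", mutate(base1, 0.1, rng)), prot("B2", mutate(base2, 0.1, rng))]
    assert sorted(reciprocal_best_hits(a, b)) == [("A1", "B1"), ("A2", "B2")]


def test_rbh_asymmetric_excluded(rng):
    # brute force over the score table: A1's best is B1 but B1 prefers A2
    base = rand_protein_seq(rng, 100)
    a2 = prot("A2", base)
    a1 = prot("A1", mutate(base, 0.2, rng))
    b1 = prot("B1", mutate(base, 0.05, rng))
    sims = {
        (x.protein_id, y.protein_id): pairwise_similarity(x, y).similarity
        for x in (a1, a2)
        for y in (b1,)
    }
    assert sims[("A2", "B1")] > sims[("A1", "B1")]
    pairs = reciprocal_best_hits([a1, a2], [b1])
    assert pairs == [("A2", "B1")]


def test_rbh_tie_excluded(rng):
    s = rand_protein_seq(rng, 80)
    pairs = reciprocal_best_hits([prot("A1", s), prot("A2", s)], [prot("B1", s)])
    assert pairs == []


def test_rbh_empty():
    assert reciprocal_best_hits([], []) == []


# --- flags and orthology fraction ------------------------------------------


def _flag_setup(rng, arch_b="T", tail_b=0, family_a="OmpR", family_b="OmpR"):
    ba = bundle_from_layout("ga", [("+", "T"), ("+", "R", {"rr_family": family_a})], seed=1)
    bb = bundle_from_layout(
        "gb", [("+", arch_b, {"extra_tail": tail_b}), ("+", "R", {"rr_family": family_b})], seed=2
    )
    from tcskit.focus_builder import build_foci
    from tcskit.tcs_classify import classify_protein

    bundles = {"ga": ba, "gb": bb}
    tcs = {g: {pid: classify_protein(p) for pid, p in b.proteins.items()} for g, b in bundles.items()}
    foci = {g: build_foci(b, tcs[g]) for g, b in bundles.items()}
    return bundles, tcs, foci


def _cluster_of(members, bundles):
    from tcskit.ortho_cluster import OrthoCluster

    return OrthoCluster("c1", members, members[0][1], 0.3)


def test_flag_size_diff(rng):
    bundles, tcs, foci = _flag_setup(rng, tail_b=150)
    cl = _cluster_of([("ga", "ga_p0000"), ("gb", "gb_p0000")], bundles)
    (flagged,) = flag_clusters([cl], bundles, tcs, foci)
    assert "SIZE_DIFF" in flagged.flags


def test_flag_arch_diff(rng):
    bundles, tcs, foci = _flag_setup(rng, arch_b="RT")
    cl = _cluster_of([("ga", "ga_p0000"), ("gb", "gb_p0000")], bundles)
    (flagged,) = flag_clusters([cl], bundles, tcs, foci)
    assert "ARCH_DIFF" in flagged.flags


def test_flag_family_diff(rng):
    bundles, tcs, foci = _flag_setup(rng, family_b="LytTR")
    cl = _cluster_of([("ga", "ga_p0001"), ("gb", "gb_p0001")], bundles)
    (flagged,) = flag_clusters([cl], bundles, tcs, foci)
    assert "FAMILY_DIFF" in flagged.flags


def test_no_flags_when_identical(rng):
    bundles, tcs, foci = _flag_setup(rng)
    cl = _cluster_of([("ga", "ga_p0000"), ("gb", "gb_p0000")], bundles)
    (flagged,) = flag_clusters([cl], bundles, tcs, foci)
    assert flagged.flags == frozenset()


def test_singleton_cluster_never_flagged(rng):
    bundles, tcs, foci = _flag_setup(rng, tail_b=500)
    cl = _cluster_of([("ga", "ga_p0000")], bundles)
    (flagged,) = flag_clusters([cl], bundles, tcs, foci)
    assert flagged.flags == frozenset()


def test_flag_multiplicity(rng):
    bundles, tcs, foci = _flag_setup(rng)
    cl = _cluster_of([("ga", "ga_p0000"), ("ga", "ga_p0001"), ("gb", "gb_p0000")], bundles)
    (flagged,) = flag_clusters([cl], bundles, tcs, foci)
    assert "MULTIPLICITY" in flagged.flags


def _fake_clusters(spec):
    from tcskit.ortho_cluster import OrthoCluster

    return [
        OrthoCluster(f"c{i}", members, members[0][1], 0.3)
        for i, members in enumerate(spec)
    ]


def test_orthology_fraction_all_paired():
    cls = _fake_clusters([[("A", f"a{i}"), ("B", f"b{i}")] for i in range(5)])
    assert orthology_fraction(cls, "A", "B") == 1.0


def test_orthology_fraction_counting():
    cls = _fake_clusters(
        [[("A", f"a{i}"), ("B", f"b{i}")] for i in range(4)]
        + [[("A", "a9")], [("B", "b9")]]
    )
    assert orthology_fraction(cls, "A", "B") == 0.8


def test_orthology_fraction_disjoint():
    cls = _fake_clusters([[("A", "a1")], [("B", "b1")]])
    assert orthology_fraction(cls, "A", "B") == 0.0
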