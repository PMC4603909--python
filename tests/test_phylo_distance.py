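import itertools

import numpy as np
import pytest

from tcskit.phylo_distance import (
    BAND_LABELS_K4,
    DistanceMatrix,
    MultipleAlignment,
    bootstrap_support,
    discretise_distances,
    fit_exponential,
    jc_distance_matrix,
    nj_tree,
    p_distance_matrix,
    patristic_matrix,
    strip_gap_columns,
    tree_splits,
)

NT = "ACGT"


def rand_dna(rng, n):
    return "".join(rng.choice(list(NT), size=n))


def mutate_dna(seq, p, rng):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < p:
            out[i] = rng.choice([c for c in NT if c != out[i]])
    return "".join(out)


# --- gap stripping ----------------------------------------------------------


def test_strip_no_gaps_identity():
    a = MultipleAlignment(("x", "y"), ("ACGT", "ACGA"))
    assert strip_gap_columns(a) == a


def test_strip_single_gap_column():
    a = MultipleAlignment(("x", "y"), ("A-GT", "ACGA"))
    s = strip_gap_columns(a)
    assert s.rows == ("AGT", "AGA")


def test_strip_matches_bruteforce(rng):
    for _ in range(20):
        n, m = int(rng.integers(2, 6)), int(rng.integers(5, 40))
        rows = [
            "".join(rng.choice(list(NT + "-"), size=m, p=[0.22] * 4 + [0.12]))
            for _ in range(n)
        ]
        keep = [j for j in range(m) if all(r[j] != "-" for r in rows)]
        if not keep:
            with pytest.raises(ValueError):
                strip_gap_columns(MultipleAlignment(tuple(f"t{i}" for i in range(n)), tuple(rows)))
            continue
        expected = tuple("".join(r[j] for j in keep) for r in rows)
        got = strip_gap_columns(MultipleAlignment(tuple(f"t{i}" for i in range(n)), tuple(rows)))
        assert got.rows == expected


def test_strip_all_gapped_errors():
    with pytest.raises(ValueError, match="no-ungapped-columns"):
        strip_gap_columns(MultipleAlignment(("x", "y"), ("A-", "-A")))


# --- p distance -------------------------------------------------------------


def test_p_distance_identical_rows():
    a = MultipleAlignment(("x", "y"), ("ACGTACGT", "ACGTACGT"))
    assert p_distance_matrix(a).d[0, 1] == 0.0


def test_p_distance_direct_count():
    a = MultipleAlignment(("x", "y"), ("AAAAAAAAAA", "AAAAAAAAAC"))
    assert p_distance_matrix(a).d[0, 1] == pytest.approx(0.1)


def test_p_distance_n_excluded_pairwise():
    a = MultipleAlignment(("x", "y"), ("ANAA", "ACCA"))
    # column 2 dropped for this pair: 1 mismatch over 3 sites
    assert p_distance_matrix(a).d[0, 1] == pytest.approx(1 / 3)


def test_p_distance_random_against_column_scan(rng):
    for _ in range(20):
        m = int(rng.integers(10, 60))
        rows = tuple(
            "".join(rng.choice(list(NT + "N"), size=m, p=[0.23] * 4 + [0.08]))
            for _ in range(3)
        )
        a = MultipleAlignment(("x", "y", "z"), rows)
        dm = p_distance_matrix(a)
        for i, j in itertools.combinations(range(3), 2):
            mism = usable = 0
            for ci, cj in zip(rows[i], rows[j]):
                if "N" in (ci, cj):
                    continue
                usable += 1
                mism += ci != cj
            expected = mism / usable if usable else 0.0
            assert dm.d[i, j] == pytest.approx(expected)


def test_p_distance_metric_properties(rng):
    rows = tuple(rand_dna(rng, 50) for _ in range(4))
    dm = p_distance_matrix(MultipleAlignment(("a", "b", "c", "d"), rows))
    assert np.allclose(dm.d, dm.d.T)
    assert np.all(dm.d >= 0) and np.all(dm.d <= 1)
    assert np.all(np.diag(dm.d) == 0)


def test_jc_distance_exceeds_p_distance(rng):
    base = rand_dna(rng, 400)
    rows = (base, mutate_dna(base, 0.2, rng))
    a = MultipleAlignment(("x", "y"), rows)
    p = p_distance_matrix(a).d[0, 1]
    jc = jc_distance_matrix(a).d[0, 1]
    assert jc > p > 0


# --- neighbour joining ------------------------------------------------------


def random_additive_tree(rng, n_taxa):
    """Independent oracle: build a random binary tree, return its leaf
    distance matrix computed by explicit path sums."""
    nodes = [{"name": f"t{i}", "children": []} for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a_len = float(rng.uniform(0.5, 5.0))
        b_len = float(rng.uniform(0.5, 5.0))
        parent = {"name": None, "children": [(a, a_len), (b, b_len)]}
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]

    dists = {}

    def collect(node):
        if not node["children"]:
            return {node["name"]: 0.0}
        maps = []
        for child, blen in node["children"]:
            cmap = {k: v + blen for k, v in collect(child).items()}
            maps.append(cmap)
        for m1, m2 in itertools.combinations(maps, 2):
            for x, dx in m1.items():
                for y, dy in m2.items():
                    dists[frozenset((x, y))] = dx + dy
        out = {}
        for m in maps:
            out.update(m)
        return out

    collect(nodes[0])
    taxa = tuple(sorted(f"t{i}" for i in range(n_taxa)))
    d = np.zeros((n_taxa, n_taxa))
    for i, x in enumerate(taxa):
        for j, y in enumerate(taxa):
            if i != j:
                d[i, j] = dists[frozenset((x, y))]
    return DistanceMatrix(taxa, d)


def test_nj_four_taxon_topology():
    taxa = ("A", "B", "C", "D")
    # ((A,B),(C,D)) with internal branch 2
    d = np.array(
        [[0, 2, 7, 7], [2, 0, 7, 7], [7, 7, 0, 2], [7, 7, 2, 0]], float
    )
    tree = nj_tree(DistanceMatrix(taxa, d))
    assert tree_splits(tree) == {frozenset({"C", "D"})}
    assert np.allclose(patristic_matrix(tree).d, d)


def test_nj_three_taxa_closed_form():
    taxa = ("A", "B", "C")
    d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
    tree = nj_tree(DistanceMatrix(taxa, d))
    assert np.allclose(patristic_matrix(tree).d, d)
    lengths = {c.name: c.length for c in tree.children}
    assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}


def test_nj_fewer_than_three_taxa_errors():
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(("A", "B"), np.array([[0, 1], [1, 0]], float)))


@pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
def test_nj_recovers_additive_matrices(n_taxa, rng):
    for _ in range(5):
        dm = random_additive_tree(rng, n_taxa)
        tree = nj_tree(dm)
        pm = patristic_matrix(tree)
        assert pm.taxa == dm.taxa
        assert np.abs(pm.d - dm.d).max() < 1e-9


def test_nj_simulation_recovery(rng):
    from tcskit.synthetic_data import SimulationConfig, evolve_along_tree, simulate_ancestor

    cfg = SimulationConfig(
        seed=42, tree="((A:0.02,B:0.02):0.06,(C:0.02,D:0.02):0.06);", ssu_length=4000
    )
    anc = simulate_ancestor(cfg)
    tips, _ = evolve_along_tree(anc, cfg)
    taxa = tuple(sorted(tips))
    aln = MultipleAlignment(taxa, tuple(tips[t].ssu_rrna for t in taxa))
    tree = nj_tree(p_distance_matrix(aln))
    # the tree must separate (A,B) from (C,D); with 4 taxa either side of the
    # single internal edge represents that split
    splits = tree_splits(tree)
    assert frozenset({"C", "D"}) in splits or frozenset({"A", "B"}) in splits


# --- bootstrap --------------------------------------------------------------


def test_bootstrap_identical_sequences_empty():
    rows = ("ACGT" * 20,) * 4
    a = MultipleAlignment(("a", "b", "c", "d"), rows)
    assert bootstrap_support(a, 50, seed=1) == {}


def test_bootstrap_two_clades_high_support(rng):
    base = rand_dna(rng, 500)
    clade2 = mutate_dna(base, 0.15, rng)
    rows = tuple(
        mutate_dna(src, 0.01, rng) for src in (base, base, clade2, clade2)
    )
    a = MultipleAlignment(("a1", "a2", "b1", "b2"), rows)
    support = bootstrap_support(a, 200, seed=7)
    assert support, "expected at least one split"
    for s, pct in support.items():
        assert 0.0 <= pct <= 100.0
    key = frozenset({"b1", "b2"})
    assert support.get(key, 0.0) >= 95.0


# --- discretisation ---------------------------------------------------------


def test_discretise_planted_bands():
    values = [0.01, 0.012, 0.05, 0.055, 0.12, 0.13, 0.22, 0.23]
    pairs = [((f"a{i}", f"b{i}"), v) for i, v in enumerate(values)]
    bands = discretise_distances(pairs, 4)
    assert bands.labels == BAND_LABELS_K4
    got = [bands.assignment[p] for p, _ in pairs]
    assert got == ["genus"] * 2 + ["family"] * 2 + ["sub-order"] * 2 + ["order"] * 2
    assert 0.012 < bands.boundaries[0] < 0.05
    assert 0.055 < bands.boundaries[1] < 0.12
    assert 0.13 < bands.boundaries[2] < 0.22


def test_discretise_all_equal_errors():
    pairs = [((f"a{i}", "b"), 0.5) for i in range(6)]
    with pytest.raises(ValueError):
        discretise_distances(pairs, 4)


def test_discretise_k1_single_band():
    pairs = [((f"a{i}", "b"), v) for i, v in enumerate([0.1, 0.2, 0.9])]
    bands = discretise_distances(pairs, 1)
    assert set(bands.assignment.values()) == {"band1"}


def test_discretise_permutation_invariant(rng):
    values = sorted(rng.uniform(0, 1, size=12))
    pairs = [((f"a{i}", f"b{i}"), float(v)) for i, v in enumerate(values)]
    ref = discretise_distances(pairs, 4)
    for _ in range(5):
        perm = list(pairs)
        rng.shuffle(perm)
        assert discretise_distances(perm, 4).assignment == ref.assignment


# --- exponential fit --------------------------------------------------------


def test_fit_noiseless_recovery():
    pts = [(d, 0.9 * np.exp(-25 * d)) for d in (0.01, 0.04, 0.09, 0.18)]
    a, b, resid = fit_exponential(pts)
    assert abs(a - 0.9) < 1e-6 and abs(b - 25) < 1e-6 and resid < 1e-9


def test_fit_two_points_exact():
    a, b, resid = fit_exponential([(0.0, 1.0), (1.0, 0.5)])
    assert resid == pytest.approx(0.0, abs=1e-12)
    assert a == pytest.approx(1.0)
    assert b == pytest.approx(np.log(2))


def test_fit_noisy_matches_regression_oracle(rng):
    d = rng.uniform(0, 0.3, size=15)
    y = 0.8 * np.exp(-12 * d) * np.exp(rng.normal(0, 0.05, size=15))
    a, b, _ = fit_exponential(list(zip(d, y)))
    # independent oracle: normal equations on (d, log y)
    X = np.vstack([d, np.ones_like(d)]).T
    beta = np.linalg.solve(X.T @ X, X.T @ np.log(y))
    assert b == pytest.approx(-beta[0], rel=1e-9)
    assert a == pytest.approx(np.exp(beta[1]), rel=1e-9)


def test_fit_rejects_nonpositive():
    with pytest.raises(ValueError):
        fit_exponential([(0.1, 0.0), (0.2, 0.5)])
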