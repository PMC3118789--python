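import math

import numpy as np
import pytest

from mitocomp.phylogeny import (
    DistanceMatrix,
    SaturationError,
    bootstrap_nj,
    gc3_by_taxon,
    k2p_distance,
    neighbor_joining,
    place_shift,
)
from mitocomp.synthetic_data import simulate_alignment

from .oracles import patristic_distances


def _seq_with_counts(n, ts, tv):
    a = "A" * n
    b = "G" * ts + "C" * tv + "A" * (n - ts - tv)
    return a, b


def test_k2p_identical_is_zero():
    assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0


def test_k2p_closed_form_value():
    a, b = _seq_with_counts(100, 10, 5)  # P = 0.1, Q = 0.05
    assert math.isclose(k2p_distance(a, b), 0.17018, abs_tol=5e-6)


def test_k2p_pure_transition_reduction():
    rng = np.random.default_rng(0)
    for _ in range(10):
        p = float(rng.uniform(0.01, 0.45))
        n = 1000
        ts = int(round(p * n))
        a, b = _seq_with_counts(n, ts, 0)
        expected = -0.5 * math.log(1 - 2 * ts / n)
        assert math.isclose(k2p_distance(a, b), expected, rel_tol=1e-12)


def test_k2p_monotone_in_transition_proportion():
    prev = -1.0
    for ts in (0, 5, 10, 20, 30):
        a, b = _seq_with_counts(200, ts, 10)
        d = k2p_distance(a, b)
        assert d > prev
        prev = d


def test_k2p_saturation_error():
    a = "A" * 100
    b = "G" * 60 + "A" * 40
    with pytest.raises(SaturationError):
        k2p_distance(a, b)


def test_k2p_pairwise_deletion_of_gaps_and_n():
    assert k2p_distance("ACGT-N", "ACGTAC") == 0.0


ADDITIVE_4 = DistanceMatrix(
    taxa=list("ABCD"),
    d=np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
    ),
)


def test_nj_recovers_known_additive_tree():
    tree = neighbor_joining(ADDITIVE_4)
    assert tree.canonical_splits() == {frozenset("AB")}
    d = patristic_distances(tree)
    assert math.isclose(d[frozenset("AB")], 3.0, abs_tol=1e-9)
    assert math.isclose(d[frozenset("CD")], 7.0, abs_tol=1e-9)


def test_nj_exact_on_random_additive_matrices():
    """NJ must reconstruct every random additive matrix exactly (n <= 6)."""
    rng = np.random.default_rng(5)
    for n_leaves in (4, 5, 6):
        for _ in range(10):
            taxa = [f"t{i}" for i in range(n_leaves)]
            true_d, true_splits = _random_additive_matrix(rng, taxa)
            tree = neighbor_joining(DistanceMatrix(taxa=taxa, d=true_d))
            assert tree.canonical_splits() == true_splits
            got = patristic_distances(tree)
            for i in range(n_leaves):
                for j in range(i + 1, n_leaves):
                    assert math.isclose(
                        got[frozenset((taxa[i], taxa[j]))],
                        true_d[i, j],
                        abs_tol=1e-8,
                    )


def _random_additive_matrix(rng, taxa):
    """Random binary tree with positive lengths -> (distances, splits)."""
    import itertools

    nodes = {t: frozenset([t]) for t in taxa}
    dist = {t: {t: 0.0} for t in taxa}
    leaf_sets = []
    members = {t: [t] for t in taxa}
    depth = {t: {t: 0.0} for t in taxa}  # leaf -> distance to cluster root
    clusters = list(taxa)
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        a, b = clusters[i], clusters[j]
        la, lb = rng.uniform(0.1, 2.0), rng.uniform(0.1, 2.0)
        new = a + "|" + b
        members[new] = members[a] + members[b]
        depth[new] = {}
        for leaf in members[a]:
            depth[new][leaf] = depth[a][leaf] + la
        for leaf in members[b]:
            depth[new][leaf] = depth[b][leaf] + lb
        for x in members[a]:
            for y in members[b]:
                dist.setdefault(x, {})[y] = depth[a][x] + la + depth[b][y] + lb
                dist.setdefault(y, {})[x] = dist[x][y]
        if 1 < len(members[new]) < len(taxa) - 1:
            leaf_sets.append(frozenset(members[new]))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [new]
    n = len(taxa)
    d = np.zeros((n, n))
    for ii in range(n):
        for jj in range(n):
            if ii != jj:
                d[ii, jj] = dist[taxa[ii]][taxa[jj]]
    all_taxa = frozenset(taxa)
    splits = {
        min(s, all_taxa - s, key=lambda x: sorted(x))
        for s in leaf_sets
        if 1 < len(s) < n - 1
    }
    return d, splits


def test_nj_isomorphic_under_label_permutation():
    tree1 = neighbor_joining(ADDITIVE_4)
    perm = [2, 0, 3, 1]
    taxa = [ADDITIVE_4.taxa[i] for i in perm]
    d = ADDITIVE_4.d[np.ix_(perm, perm)]
    tree2 = neighbor_joining(DistanceMatrix(taxa=taxa, d=d))
    assert tree1.canonical_splits() == tree2.canonical_splits()


def test_nj_three_taxa_solves_three_point_equations():
    d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
    tree = neighbor_joining(DistanceMatrix(taxa=list("ABC"), d=d))
    got = patristic_distances(tree)
    assert math.isclose(got[frozenset("AB")], 2.0, abs_tol=1e-9)
    assert math.isclose(got[frozenset("AC")], 3.0, abs_tol=1e-9)
    assert math.isclose(got[frozenset("BC")], 5.0, abs_tol=1e-9)


def test_nj_rejects_too_few_taxa():
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(taxa=["A", "B"], d=np.zeros((2, 2))))


def test_nj_matches_skbio_on_random_matrices():
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sk_nj

    rng = np.random.default_rng(11)
    for _ in range(5):
        n = 6
        x = rng.uniform(0.1, 1.0, size=(n, n))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0)
        taxa = [f"t{i}" for i in range(n)]
        ours = neighbor_joining(DistanceMatrix(taxa=taxa, d=d))
        sk_tree = sk_nj(SkDM(d, ids=taxa))
        sk_splits = set()
        all_taxa = frozenset(taxa)
        for node in sk_tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < n - 1:
                sk_splits.add(min(side, all_taxa - side, key=lambda s: sorted(s)))
        assert ours.canonical_splits() == sk_splits


def test_bootstrap_deterministic_per_seed():
    aln, _ = simulate_alignment(
        "((A:0.1,B:0.1):0.3,(C:0.1,D:0.1):0.3,(E:0.1,F:0.1):0.3);",
        n_codons=120,
        seed=4,
    )
    t1 = bootstrap_nj(aln, n_reps=50, seed=9)
    t2 = bootstrap_nj(aln, n_reps=50, seed=9)
    assert t1.to_newick() == t2.to_newick()


def test_bootstrap_support_invariant_under_taxon_reordering():
    aln, _ = simulate_alignment(
        "((A:0.1,B:0.1):0.4,(C:0.1,D:0.1):0.4,(E:0.1,F:0.1):0.4);",
        n_codons=150,
        seed=6,
    )
    t1 = bootstrap_nj(aln, n_reps=50, seed=3)
    t2 = bootstrap_nj(list(reversed(aln)), n_reps=50, seed=3)

    def supports(tree):
        all_taxa = frozenset(tree.taxa)
        return {
            min(s, all_taxa - s, key=lambda x: sorted(x)): node.support
            for s, node in tree.bipartitions().items()
        }

    s1, s2 = supports(t1), supports(t2)
    assert set(s1) == set(s2)
    # same splits recovered; support values are seeded per resampling order
    for k in s1:
        assert abs(s1[k] - s2[k]) <= 15


def test_strong_internal_edges_get_high_support():
    aln, truth = simulate_alignment(
        "((A:0.05,B:0.05):0.2,(C:0.05,D:0.05):0.2,(E:0.05,F:0.05):0.2);",
        n_codons=400,
        seed=8,
    )
    tree = bootstrap_nj(aln, n_reps=500, seed=1)
    found = {
        min(s, frozenset(tree.taxa) - s, key=lambda x: sorted(x)): n.support
        for s, n in tree.bipartitions().items()
    }
    assert set(found) == set(truth["true_splits"])
    assert all(v >= 95 for v in found.values())


def test_gc3_by_taxon_extremes_and_frame_check():
    res = gc3_by_taxon([("x", "AAGTTC")])
    assert res["x"].gc3 == 100.0
    with pytest.raises(ValueError):
        gc3_by_taxon([("y", "AAGT")])


def _toy_tree():
    d = np.array(
        [[0, 0.1, 0.5, 0.5], [0.1, 0, 0.5, 0.5], [0.5, 0.5, 0, 0.1], [0.5, 0.5, 0.1, 0]]
    )
    return neighbor_joining(DistanceMatrix(taxa=list("ABCD"), d=d))


def test_place_shift_on_clade_edge():
    tree = _toy_tree()
    placement = place_shift(tree, {"A": 50, "B": 47, "C": 10, "D": 5}, cut=30)
    assert placement.monophyletic
    assert placement.edge == frozenset("AB")


def test_place_shift_flags_non_monophyly():
    tree = _toy_tree()
    placement = place_shift(tree, {"A": 50, "B": 10, "C": 47, "D": 5}, cut=30)
    assert not placement.monophyletic
    assert placement.edge is None


def test_place_shift_rejects_bad_cut():
    tree = _toy_tree()
    with pytest.raises(ValueError):
        place_shift(tree, {"A": 1, "B": 1, "C": 1, "D": 1}, cut=0)
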