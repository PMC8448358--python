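import math

import numpy as np
import pytest

from kskid.msa import Alignment
from kskid.phylo import (DistanceMatrix, SaturationError, bootstrap_support,
                         distance_matrix, divergence_summary, is_monophyletic,
                         k2p_distance, nj_tree, read_newick, write_newick)


def test_k2p_identical():
    d, p, q, n = k2p_distance("A" * 100, "A" * 100)
    assert (d, p, q, n) == (0.0, 0.0, 0.0, 100)


def test_k2p_single_transition_closed_form():
    a = "AAAAAAAAAA"
    b = "GAAAAAAAAA"
    d, p, q, n = k2p_distance(a, b)
    assert p == pytest.approx(0.1)
    assert q == 0.0
    assert d == pytest.approx(-0.5 * math.log(0.8), abs=1e-9)


def test_k2p_single_transversion_closed_form():
    a = "AAAAAAAAAA"
    b = "CAAAAAAAAA"
    d, p, q, n = k2p_distance(a, b)
    assert (p, q) == (0.0, pytest.approx(0.1))
    assert d == pytest.approx(-0.5 * math.log(0.9 * math.sqrt(0.8)),
                              abs=1e-9)


def test_k2p_pairwise_deletion():
    d, p, q, n = k2p_distance("A-GRAA", "AAGAAA")
    assert n == 4  # gap and ambiguity columns dropped for the pair
    assert d == 0.0


def test_k2p_no_comparable_sites():
    with pytest.raises(ValueError, match="comparable"):
        k2p_distance("----", "AAAA")


def test_k2p_saturation():
    with pytest.raises(SaturationError):
        k2p_distance("AAAA", "GGGG")


def test_k2p_at_least_p_distance():
    rng = np.random.default_rng(7)
    for _ in range(50):
        n = 200
        a = "".join(rng.choice(list("ACGT"), n))
        b = "".join(rng.choice(list("ACGT"), n))
        try:
            d, p, q, _ = k2p_distance(a, b)
        except SaturationError:
            continue
        assert d >= (p + q) - 1e-12


def test_distance_matrix_embeds_closed_forms():
    aln = Alignment(ids=["a", "b", "c"],
                    rows=["AAAAAAAAAA", "GAAAAAAAAA", "CAAAAAAAAA"])
    dm = distance_matrix(aln)
    assert dm.get("a", "b") == pytest.approx(-0.5 * math.log(0.8))
    assert dm.get("a", "c") == pytest.approx(
        -0.5 * math.log(0.9 * math.sqrt(0.8)))
    assert np.allclose(dm.d, dm.d.T)
    assert np.all(np.diag(dm.d) == 0)


def test_divergence_summary_single_species_is_error():
    dm = distance_matrix(Alignment(ids=["a", "b"],
                                   rows=["A" * 10, "G" + "A" * 9]))
    with pytest.raises(ValueError):
        divergence_summary(dm, {"a": "x", "b": "x"})


def test_divergence_summary_one_pair():
    dm = distance_matrix(Alignment(ids=["a", "b"],
                                   rows=["A" * 10, "G" + "A" * 9]))
    s = divergence_summary(dm, {"a": "x", "b": "y"})
    assert s.min == s.max == pytest.approx(0.11157, abs=1e-4)
    assert s.max_rounded == 0.11
    (bin_,) = [b for b in s.histogram if b[2] > 0]
    assert bin_[0] == pytest.approx(0.10)
    assert bin_[1] == pytest.approx(0.15)
    assert bin_[2] == 1.0


def test_divergence_max_monotone_under_additions(default_dataset,
                                                 default_alignment):
    from kskid.phylo import distance_matrix as dmf
    species_of = default_dataset.species_of()
    ids = default_alignment.ids
    prev = None
    for n in (10, 18, len(ids)):
        sub = Alignment(ids=ids[:n], rows=default_alignment.rows[:n])
        s = divergence_summary(dmf(sub), species_of)
        if prev is not None:
            assert s.max >= prev - 1e-12
        prev = s.max


# ---- NJ oracles -----------------------------------------------------------

def random_additive_tree(rng, n_taxa):
    """Random unrooted binary tree: edge list + leaf names, built by
    attaching leaves to random edges; returns patristic distances."""
    import itertools
    next_internal = [0]

    def new_internal():
        next_internal[0] += 1
        return f"__i{next_internal[0]}"

    labels = [f"t{i}" for i in range(n_taxa)]
    center = new_internal()
    edges = {}
    for leaf in labels[:3]:
        edges[(center, leaf)] = rng.uniform(0.1, 1.0)
    for leaf in labels[3:]:
        (u, v) = list(edges)[rng.integers(len(edges))]
        w = edges.pop((u, v))
        mid = new_internal()
        split = rng.uniform(0.2, 0.8)
        edges[(u, mid)] = w * split
        edges[(mid, v)] = w * (1 - split)
        edges[(mid, leaf)] = rng.uniform(0.1, 1.0)
    adj = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    dist = {}
    for src in labels:
        seen = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, w in adj[node]:
                if nb not in seen:
                    seen[nb] = seen[node] + w
                    stack.append(nb)
        dist[src] = seen
    d = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            d[i, j] = dist[a][b]
    return labels, d


def tree_patristic(tree):
    """Leaf-leaf distances induced by a PhyloTree (additivity oracle)."""
    dm = tree.root.tip_tip_distances()
    ids = list(dm.ids)
    return ids, np.asarray(dm.data)


def test_nj_three_taxa_closed_form():
    ids = ["A", "B", "C"]
    d = np.array([[0.0, 0.3, 0.5],
                  [0.3, 0.0, 0.6],
                  [0.5, 0.6, 0.0]])
    dm = DistanceMatrix(ids=ids, d=d, comparable_sites=np.ones((3, 3)))
    tree = nj_tree(dm)
    lengths = {t.name: t.length for t in tree.root.tips()}
    assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
    assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
    assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)


def test_nj_recovers_known_quartet():
    # tree ((A:1,B:2):1,(C:3,D:4)) -> additive matrix
    ids = ["A", "B", "C", "D"]
    d = np.array([
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 7, 0],
    ], dtype=float)
    dm = DistanceMatrix(ids=ids, d=d, comparable_sites=np.ones((4, 4)))
    tree = nj_tree(dm)
    assert frozenset({"A", "B"}) in tree.bipartitions() or \
        frozenset({"C", "D"}) in tree.bipartitions()
    pids, pd = tree_patristic(tree)
    order = [pids.index(x) for x in ids]
    assert np.allclose(pd[np.ix_(order, order)], d, atol=1e-9)


@pytest.mark.parametrize("n_taxa", [4, 5, 6])
def test_nj_reconstructs_random_additive_matrices(n_taxa):
    """On additive input NJ must return the generating tree exactly
    (topology via the patristic-distance identity)."""
    rng = np.random.default_rng(n_taxa)
    for _ in range(30):
        labels, d = random_additive_tree(rng, n_taxa)
        dm = DistanceMatrix(ids=labels, d=d,
                            comparable_sites=np.ones_like(d))
        tree = nj_tree(dm)
        pids, pd = tree_patristic(tree)
        order = [pids.index(x) for x in labels]
        assert np.allclose(pd[np.ix_(order, order)], d, atol=1e-8)


def test_nj_matches_skbio_topology():
    """Independent cross-check of the NJ implementation on tie-free
    random matrices (with ties the NJ topology is not unique and the two
    implementations may legitimately differ)."""
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sk_nj

    rng = np.random.default_rng(3)
    labels, d = random_additive_tree(rng, 10)
    d = d + rng.uniform(0, 0.01, size=d.shape)  # break exact additivity
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    dm = DistanceMatrix(ids=labels, d=d, comparable_sites=np.ones_like(d))
    mine = nj_tree(dm)
    theirs = sk_nj(SkDM(dm.d, ids=dm.ids))
    ref = min(dm.ids)
    leaves = set(dm.ids)

    def bipartitions(root):
        out = set()
        for node in root.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if ref in side:
                side = frozenset(leaves - side)
            if 2 <= len(side) <= len(leaves) - 2:
                out.add(side)
        return out

    assert set(mine.bipartitions()) == bipartitions(theirs)


def test_nj_requires_complete_matrix():
    d = np.zeros((3, 3))
    d[0, 1] = d[1, 0] = np.nan
    dm = DistanceMatrix(ids=list("abc"), d=d,
                        comparable_sites=np.ones((3, 3)),
                        saturated=[("a", "b")])
    with pytest.raises(ValueError):
        nj_tree(dm)


# ---- bootstrap ------------------------------------------------------------

def test_bootstrap_identity_resample_gives_full_support(default_dataset,
                                                        default_alignment):
    tree = bootstrap_support(default_alignment, replicates=1, seed=5,
                             identity_resample=True)
    supports = [getattr(n, "support", None)
                for n in tree.root.non_tips(include_self=False)]
    internal = [s for s in supports if s is not None]
    assert internal and all(s == 100.0 for s in internal)


def test_bootstrap_deterministic_per_seed(default_alignment):
    t1 = bootstrap_support(default_alignment, replicates=20, seed=11)
    t2 = bootstrap_support(default_alignment, replicates=20, seed=11)
    s1 = sorted(n.support for n in t1.root.non_tips(include_self=False)
                if getattr(n, "support", None) is not None)
    s2 = sorted(n.support for n in t2.root.non_tips(include_self=False)
                if getattr(n, "support", None) is not None)
    assert s1 == s2


def test_bootstrap_species_clades_supported(default_dataset,
                                            default_alignment):
    """Deep interspecific divergence: every species clade must be a
    strongly supported bipartition."""
    tree = bootstrap_support(default_alignment, replicates=100, seed=2)
    species_of = default_dataset.species_of()
    bps = tree.bipartitions()
    leaves = tree.leaves()
    ref = min(leaves)
    for sp in set(species_of.values()):
        members = frozenset(i for i, s in species_of.items() if s == sp)
        side = members if ref not in members else frozenset(leaves - members)
        if not (2 <= len(side) <= len(leaves) - 2):
            continue
        assert side in bps, sp
        assert bps[side].support >= 95.0


# ---- monophyly & newick ---------------------------------------------------

def _quartet_tree():
    ids = ["A", "B", "C", "D"]
    d = np.array([
        [0, 2, 6, 6],
        [2, 0, 6, 6],
        [6, 6, 0, 2],
        [6, 6, 2, 0],
    ], dtype=float)
    dm = DistanceMatrix(ids=ids, d=d, comparable_sites=np.ones((4, 4)))
    return nj_tree(dm)


def test_monophyly_enumeration():
    tree = _quartet_tree()
    assert is_monophyletic(tree, ["A"], "D")
    assert is_monophyletic(tree, ["A", "B"], "D")
    assert not is_monophyletic(tree, ["A", "C"], "D")


def test_monophyly_errors():
    tree = _quartet_tree()
    with pytest.raises(ValueError):
        is_monophyletic(tree, ["Z"], "D")
    with pytest.raises(ValueError):
        is_monophyletic(tree, [], "D")


def test_species_monophyly_on_synthetic_tree(default_dataset,
                                             default_alignment):
    dm = distance_matrix(default_alignment)
    tree = nj_tree(dm)
    species_of = default_dataset.species_of()
    outgroup = default_alignment.ids[0]
    for sp in set(species_of.values()):
        members = [i for i, s in species_of.items()
                   if s == sp and i != outgroup]
        if species_of[outgroup] == sp:
            continue
        assert is_monophyletic(tree, members, outgroup), sp


def test_newick_three_leaf_star():
    ids = ["A", "B", "C"]
    d = np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]], dtype=float)
    dm = DistanceMatrix(ids=ids, d=d, comparable_sites=np.ones((3, 3)))
    text = write_newick(nj_tree(dm))
    assert text.startswith("(") and text.endswith(");")
    assert {"A", "B", "C"} <= set(text.replace("(", " ").replace(")", " ")
                                  .replace(",", " ").replace(":", " ")
                                  .split())


def test_newick_round_trip_random_trees():
    rng = np.random.default_rng(0)
    for _ in range(50):
        labels, d = random_additive_tree(rng, int(rng.integers(4, 8)))
        dm = DistanceMatrix(ids=labels, d=d,
                            comparable_sites=np.ones_like(d))
        tree = nj_tree(dm)
        back = read_newick(write_newick(tree))
        assert back.leaves() == tree.leaves()
        pids, pd = tree_patristic(tree)
        bids, bd = tree_patristic(back)
        order = [bids.index(x) for x in pids]
        assert np.allclose(bd[np.ix_(order, order)], pd, atol=1e-5)


def test_newick_supports_serialized_in_range(default_alignment):
    tree = bootstrap_support(default_alignment, replicates=10, seed=1)
    text = write_newick(tree)
    back = read_newick(text)
    supports = [n.support for n in back.root.non_tips(include_self=True)
                if getattr(n, "support", None) is not None]
    assert supports and all(0.0 <= s <= 100.0 for s in supports)
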