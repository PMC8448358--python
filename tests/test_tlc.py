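import itertools

import numpy as np
import pytest

from kskid.simulate import SimulationConfig, simulate_fingerprints
from kskid.tlc import (FingerprintMatrix, assign_by_cluster, binary_distance,
                       hcluster, read_band_matrix, write_band_matrix)


def _matrix(rows, ids=None, rf=None):
    cells = np.array(rows)
    ids = ids or [f"s{i}" for i in range(cells.shape[0])]
    rf = rf if rf is not None else (np.arange(cells.shape[1]) + 1) / (
        cells.shape[1] + 1)
    return FingerprintMatrix(sample_ids=ids, rf_bins=rf, cells=cells)


def test_read_band_matrix(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text("sample\t0.10\t0.30\t0.50\nA\t1\t0\t1\nB\t0\t1\t1\n")
    m = read_band_matrix(p)
    assert m.sample_ids == ["A", "B"]
    assert list(m.rf_bins) == [0.10, 0.30, 0.50]


def test_read_band_matrix_nonbinary_cell(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text("sample\t0.1\t0.2\nA\t1\t2\n")
    with pytest.raises(ValueError, match="non-binary"):
        read_band_matrix(p)


def test_read_band_matrix_duplicate_rf(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text("sample\t0.1\t0.1\nA\t1\t0\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_band_matrix(p)


def test_read_band_matrix_sorts_rf(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text("sample\t0.5\t0.1\nA\t1\t0\nB\t0\t1\n")
    m = read_band_matrix(p)
    assert list(m.rf_bins) == [0.1, 0.5]
    assert m.row("A").tolist() == [0, 1]


def test_band_matrix_round_trip(tmp_path):
    m = _matrix([[1, 0, 1], [0, 1, 1]])
    p = tmp_path / "m.tsv"
    write_band_matrix(m, p)
    back = read_band_matrix(p)
    assert back.sample_ids == m.sample_ids
    assert np.array_equal(back.cells, m.cells)


def test_all_zero_row_dropped_with_warning(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text("sample\t0.1\t0.2\nA\t1\t0\nB\t0\t0\n")
    with pytest.warns(UserWarning, match="all-zero"):
        m = read_band_matrix(p)
    assert m.sample_ids == ["A"]


def test_binary_distances():
    m = _matrix([[1, 1, 0], [1, 0, 1], [1, 1, 1], [0, 0, 0]],
                ids=["a", "b", "c", "z"])
    dj = binary_distance(m, "jaccard")
    assert dj.get("a", "b") == pytest.approx(2 / 3)
    assert dj.get("a", "a") == 0.0
    assert dj.get("c", "z") == 1.0
    dsm = binary_distance(m, "simple_matching")
    assert dsm.get("a", "b") == pytest.approx(2 / 3)


def test_jaccard_both_empty_rows_is_zero():
    m = _matrix([[0, 0], [0, 0]], ids=["a", "b"])
    assert binary_distance(m, "jaccard").get("a", "b") == 0.0


def test_two_sample_single_merge():
    m = _matrix([[1, 1, 0], [1, 0, 1]], ids=["a", "b"])
    dend = hcluster(binary_distance(m))
    assert len(dend.merges) == 1
    assert dend.merges[0].height == pytest.approx(2 / 3)


def test_first_merge_is_closest_pair_for_all_linkages():
    import numpy as np
    from kskid.phylo import DistanceMatrix
    d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
    dm = DistanceMatrix(ids=["a", "b", "c"], d=d,
                        comparable_sites=np.ones((3, 3)))
    for linkage in ("single", "complete", "average"):
        dend = hcluster(dm, linkage)
        first = set(dend.merges[0].left) | set(dend.merges[0].right)
        assert first == {"a", "b"}  # tie (a,b) vs (b,c) broken by ids


def brute_force_agglomerate(ids, d0, linkage):
    """Oracle: recompute cluster-cluster distances from the original
    matrix at every step (no Lance-Williams recursion)."""
    idx = {s: i for i, s in enumerate(ids)}
    clusters = [(s,) for s in ids]

    def cdist(a, b):
        vals = [d0[idx[x], idx[y]] for x in a for y in b]
        if linkage == "single":
            return min(vals)
        if linkage == "complete":
            return max(vals)
        return sum(vals) / len(vals)

    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            key = (cdist(a, b), min(min(a), min(b)), max(min(a), min(b)))
            if best is None or key < best[0]:
                best = (key, a, b)
        (h, _, _), a, b = best
        merges.append((h, frozenset(a), frozenset(b)))
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(tuple(sorted(a + b)))
    return merges


@pytest.mark.parametrize("linkage", ["single", "complete", "average"])
def test_hcluster_matches_brute_force_oracle(linkage):
    """Merge sequences on 20 random binary matrices equal the from-scratch
    agglomeration oracle."""
    rng = np.random.default_rng(17)
    for _ in range(20):
        cells = rng.integers(0, 2, size=(6, 8))
        cells[cells.sum(axis=1) == 0, 0] = 1
        m = _matrix(cells.tolist())
        dm = binary_distance(m)
        dend = hcluster(dm, linkage)
        oracle = brute_force_agglomerate(m.sample_ids, dm.d, linkage)
        mine = [(mg.height, frozenset(mg.left), frozenset(mg.right))
                for mg in dend.merges]
        for (h1, a1, b1), (h2, a2, b2) in zip(mine, oracle):
            assert h1 == pytest.approx(h2)
            assert {a1, b1} == {a2, b2}


def test_merge_heights_monotone():
    rng = np.random.default_rng(23)
    for linkage in ("complete", "average"):
        cells = rng.integers(0, 2, size=(8, 10))
        cells[cells.sum(axis=1) == 0, 0] = 1
        dend = hcluster(binary_distance(_matrix(cells.tolist())), linkage)
        heights = [m.height for m in dend.merges]
        assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))


def test_duplicate_row_merges_first_at_zero():
    m = _matrix([[1, 0, 1], [1, 0, 1], [0, 1, 0]], ids=["a", "b", "c"])
    dend = hcluster(binary_distance(m))
    assert dend.merges[0].height == 0.0
    assert set(dend.merges[0].left) | set(dend.merges[0].right) == {"a", "b"}


def test_dendrogram_invariant_under_row_permutation():
    rng = np.random.default_rng(5)
    cells = rng.integers(0, 2, size=(6, 9))
    cells[cells.sum(axis=1) == 0, 0] = 1
    # distinct rows so that merge order is tie-free up to relabeling
    m1 = _matrix(cells.tolist())
    perm = rng.permutation(6)
    m2 = _matrix(cells[perm].tolist(),
                 ids=[m1.sample_ids[i] for i in perm])
    d1 = hcluster(binary_distance(m1))
    d2 = hcluster(binary_distance(m2))
    sets1 = [frozenset(m.left) | frozenset(m.right) for m in d1.merges]
    sets2 = [frozenset(m.left) | frozenset(m.right) for m in d2.merges]
    assert sets1 == sets2


def test_assign_identical_to_reference():
    m = _matrix([[1, 0, 1], [1, 0, 1], [0, 1, 0], [0, 1, 1]],
                ids=["refA", "unk1", "refB", "unk2"])
    dend = hcluster(binary_distance(m))
    calls = assign_by_cluster(dend, {"refA": "X", "refB": "Y"}, k=2)
    by_sample = {c.sample: c.species for c in calls}
    assert by_sample == {"unk1": "X", "unk2": "Y"}


def test_assign_mixed_reference_cluster_unresolved():
    m = _matrix([[1, 0, 1], [1, 0, 1], [1, 0, 1]],
                ids=["refA", "refB", "unk"])
    dend = hcluster(binary_distance(m))
    calls = assign_by_cluster(dend, {"refA": "X", "refB": "Y"}, k=2)
    (call,) = [c for c in calls if c.sample == "unk"]
    assert call.species == "unresolved"


def test_assign_k_below_species_count_is_error():
    m = _matrix([[1, 0], [0, 1], [1, 1]], ids=["a", "b", "u"])
    dend = hcluster(binary_distance(m))
    with pytest.raises(ValueError):
        assign_by_cluster(dend, {"a": "X", "b": "Y"}, k=1)


def test_authentic_panel_clusters_species_pure():
    """A noise-free matrix shaped like the authentic TLC panel (5/2/2
    reference lanes) cuts into species-pure clusters at k=3."""
    cfg = SimulationConfig(seed=9, flip_noise=0.0)
    species_of = {**{f"BA{i}": "BA" for i in range(1, 6)},
                  "SA1": "SA", "SA2": "SA", "ZA1": "ZA", "ZA2": "ZA"}
    m, truth = simulate_fingerprints(cfg, species_of)
    dend = hcluster(binary_distance(m))
    for cluster in dend.cut(3):
        species = {species_of[s] for s in cluster}
        assert len(species) == 1


def test_fingerprint_hca_recovery_over_replicates():
    """With default flip noise, cluster-based assignment recovers >=90%
    of unknown samples over 50 seeds."""
    correct = total = 0
    for seed in range(50):
        cfg = SimulationConfig(seed=seed)
        refs = {"BA1": "BA", "BA2": "BA", "SA1": "SA", "SA2": "SA",
                "ZA1": "ZA", "ZA2": "ZA"}
        truth = {"CK1": "BA", "CK2": "SA", "CK3": "ZA", "CK4": "ZA"}
        m, _ = simulate_fingerprints(cfg, {**refs, **truth})
        dend = hcluster(binary_distance(m))
        for call in assign_by_cluster(dend, refs):
            total += 1
            correct += call.species == truth[call.sample]
    assert correct / total >= 0.90
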