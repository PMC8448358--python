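"""Binary TLC-fingerprint clustering and reference-based assignment.

A thin-layer chromatography run is reduced to a binary matrix: rows are
samples, columns are Rf bins (retention factors in [0, 1]), cells record
band presence (1) or absence (0).  Samples are clustered by agglomerative
hierarchical clustering on a binary distance (Jaccard by default — band
presence is the informative signal — or simple matching), and an unknown
sample inherits the species of its cluster's reference samples when those
references are species-pure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phylo import DistanceMatrix


@dataclass
class FingerprintMatrix:
    """Samples x Rf-bins binary band matrix (Rf strictly increasing)."""

    sample_ids: list[str]
    rf_bins: np.ndarray
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.rf_bins = np.asarray(self.rf_bins, dtype=float)
        self.cells = np.asarray(self.cells)
        if self.cells.shape != (len(self.sample_ids), len(self.rf_bins)):
            raise ValueError("cell matrix shape mismatch")
        if not np.all(np.isin(self.cells, (0, 1))):
            raise ValueError("cells must be 0/1")
        if np.any(self.rf_bins < 0) or np.any(self.rf_bins > 1):
            raise ValueError("Rf values must lie in [0, 1]")
        if np.any(np.diff(self.rf_bins) <= 0):
            raise ValueError("Rf values must be strictly increasing")

    def drop_empty_rows(self) -> "FingerprintMatrix":
        keep = self.cells.sum(axis=1) > 0
        if not keep.all():
            dropped = [s for s, k in zip(self.sample_ids, keep) if not k]
            warnings.warn(f"dropping all-zero fingerprint row(s): {dropped}")
        return FingerprintMatrix(
            sample_ids=[s for s, k in zip(self.sample_ids, keep) if k],
            rf_bins=self.rf_bins, cells=self.cells[keep])

    def row(self, sid: str) -> np.ndarray:
        return self.cells[self.sample_ids.index(sid)]


def read_band_matrix(path: str | Path, *,
                     drop_empty: bool = True) -> FingerprintMatrix:
    """Read a TSV band matrix: first column sample id, remaining headers
    numeric Rf values; columns are reordered to ascending Rf."""
    with open(path) as fh:
        raw_header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(raw_header)) != len(raw_header):
        raise ValueError(f"{path}: duplicate Rf header values")
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        rf = np.array([float(c) for c in raw_header])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric Rf header: {exc}")
    order = np.argsort(rf)
    cells = df.to_numpy()
    if not np.all(np.isin(cells, (0, 1))):
        bad = cells[~np.isin(cells, (0, 1))][0]
        raise ValueError(f"{path}: non-binary cell value {bad!r}")
    m = FingerprintMatrix(sample_ids=[str(i) for i in df.index],
                          rf_bins=rf[order], cells=cells[:, order])
    return m.drop_empty_rows() if drop_empty else m


def write_band_matrix(m: FingerprintMatrix, path: str | Path) -> None:
    df = pd.DataFrame(m.cells, index=m.sample_ids,
                      columns=[f"{rf:g}" for rf in m.rf_bins])
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def binary_distance(m: FingerprintMatrix,
                    metric: str = "jaccard") -> DistanceMatrix:
    """Pairwise binary distances between fingerprint rows.

    ``jaccard``: 1 - |intersection| / |union| of presence sets (0 when both
    rows are all-absent); ``simple_matching``: Hamming distance / columns.
    """
    if len(m.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    x = m.cells.astype(bool)
    n = len(m.sample_ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "jaccard":
                union = np.logical_or(x[i], x[j]).sum()
                inter = np.logical_and(x[i], x[j]).sum()
                dij = 0.0 if union == 0 else 1.0 - inter / union
            elif metric == "simple_matching":
                dij = np.logical_xor(x[i], x[j]).sum() / x.shape[1]
            else:
                raise ValueError(f"unknown metric {metric!r}")
            d[i, j] = d[j, i] = dij
    sites = np.full((n, n), x.shape[1], dtype=int)
    return DistanceMatrix(ids=list(m.sample_ids), d=d,
                          comparable_sites=sites)


@dataclass(frozen=True)
class Merge:
    height: float
    left: tuple[str, ...]   # member ids of the left cluster
    right: tuple[str, ...]  # member ids of the right cluster


@dataclass
class Dendrogram:
    """Agglomerative merge sequence over samples.

    ``merges`` are in merge order; cluster membership at any cut is
    recoverable by replaying them."""

    sample_ids: list[str]
    merges: list[Merge]
    linkage: str
    metric: str

    def cut(self, k: int) -> list[set[str]]:
        """Cluster membership after cutting into ``k`` clusters."""
        n = len(self.sample_ids)
        if not (1 <= k <= n):
            raise ValueError(f"k={k} out of range for {n} leaves")
        clusters: list[set[str]] = [{s} for s in self.sample_ids]
        for merge in self.merges[: n - k]:
            left = set(merge.left)
            right = set(merge.right)
            clusters = [c for c in clusters if c != left and c != right]
            clusters.append(left | right)
        return clusters

    def newick(self) -> str:
        """Export as Newick with branch lengths derived from merge heights
        (each child's branch spans from its own height to the parent's)."""
        height: dict[tuple[str, ...], float] = {}
        node: dict[tuple[str, ...], str] = {}
        for s in self.sample_ids:
            height[(s,)] = 0.0
            node[(s,)] = s
        for m in self.merges:
            lk, rk = m.left, m.right
            text = (f"({node.pop(lk)}:{m.height - height.pop(lk):.6f},"
                    f"{node.pop(rk)}:{m.height - height.pop(rk):.6f})")
            key = tuple(sorted(lk + rk))
            node[key] = text
            height[key] = m.height
        return next(iter(node.values())) + ";"


def hcluster(dm: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering with Lance-Williams updates.

    ``single``: minimum, ``complete``: maximum, ``average``: size-weighted
    mean (UPGMA).  At each step the closest pair is merged; exact distance
    ties are broken by the lexicographically smallest (min member id, max
    member id) pair.
    """
    if linkage not in ("single", "complete", "average"):
        raise ValueError(f"unknown linkage {linkage!r}")
    if not dm.complete:
        raise ValueError("clustering requires a complete distance matrix")
    members: dict[str, tuple[str, ...]] = {s: (s,) for s in dm.ids}
    dist: dict[frozenset, float] = {}
    ids = list(dm.ids)
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            dist[frozenset((a, ids[j]))] = float(dm.d[i, j])
    merges: list[Merge] = []
    active = sorted(members)
    while len(active) > 1:
        best_key = None
        best_pair = None
        for i, a in enumerate(active):
            for j in range(i + 1, len(active)):
                b = active[j]
                dij = dist[frozenset((a, b))]
                key = (dij, min(a, b), max(a, b))
                if best_key is None or key < best_key:
                    best_key = key
                    best_pair = (a, b)
        a, b = best_pair
        h = best_key[0]
        na, nb = len(members[a]), len(members[b])
        new_rep = min(a, b)
        other_rep = max(a, b)
        merges.append(Merge(height=h, left=members[a], right=members[b]))
        for c in active:
            if c in (a, b):
                continue
            dac = dist.pop(frozenset((a, c)))
            dbc = dist.pop(frozenset((b, c)))
            if linkage == "single":
                dnew = min(dac, dbc)
            elif linkage == "complete":
                dnew = max(dac, dbc)
            else:
                dnew = (na * dac + nb * dbc) / (na + nb)
            dist[frozenset((new_rep, c))] = dnew
        dist.pop(frozenset((a, b)))
        members[new_rep] = tuple(sorted(members[a] + members[b]))
        del members[other_rep]
        active.remove(other_rep)
    return Dendrogram(sample_ids=list(dm.ids), merges=merges,
                      linkage=linkage, metric="precomputed")


@dataclass(frozen=True)
class ClusterCall:
    sample: str
    species: str  # species label or "unresolved"
    supporting_references: tuple[str, ...]
    cut_k: int


def assign_by_cluster(dend: Dendrogram, references: Mapping[str, str],
                      k: int | None = None) -> list[ClusterCall]:
    """Assign non-reference samples by co-clustering with references.

    The dendrogram is cut into ``k`` clusters (default: the number of
    distinct reference species); an unknown inherits its cluster's
    reference species iff those references are species-pure, otherwise it
    is ``unresolved``.
    """
    ref_species = set(references.values())
    if k is None:
        k = len(ref_species)
    if k < len(ref_species):
        raise ValueError(f"k={k} below the number of reference species "
                         f"({len(ref_species)})")
    leaves = set(dend.sample_ids)
    missing = set(references) - leaves
    if missing:
        raise ValueError(f"reference ids missing from dendrogram: {missing}")
    calls = []
    for cluster in dend.cut(k):
        refs_here = sorted(r for r in cluster if r in references)
        species_here = {references[r] for r in refs_here}
        label = (species_here.pop() if len(species_here) == 1
                 else "unresolved")
        for sample in sorted(cluster):
            if sample in references:
                continue
            calls.append(ClusterCall(sample=sample, species=label,
                                     supporting_references=tuple(refs_here),
                                     cut_k=k))
    calls.sort(key=lambda c: c.sample)
    return calls


def cluster_calls_tsv(calls: Sequence[ClusterCall]) -> str:
    lines = ["sample\tassigned_species\tsupporting_references\tcut_k"]
    for c in calls:
        lines.append(f"{c.sample}\t{c.species}\t"
                     f"{','.join(c.supporting_references) or '-'}\t{c.cut_k}")
    return "\n".join(lines) + "\n"
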