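"""K2P distances, neighbor-joining trees, bootstrap supports, monophyly.

Distances are Kimura 2-parameter (K2P): the substitution model separates
transitions (A<->G, C<->T; proportion P) from transversions (proportion Q)
and corrects for multiple hits,

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

in substitutions/site.  Pairwise deletion is the default: a column counts
for a pair only when both rows carry an unambiguous A/C/G/T.  Trees are
built by the Saitou-Nei neighbor-joining agglomeration with the
Studier-Keppler selection criterion; supports come from column-resampling
bootstrap replicates mapped back onto the original tree's bipartitions.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from skbio.tree import TreeNode

from .msa import Alignment
from .records import UNAMBIGUOUS

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


class SaturationError(ValueError):
    """K2P correction undefined: observed divergence beyond the model's
    valid range (log of a non-positive number)."""


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix in substitutions/site.

    Saturated pairs are recorded as NaN and listed in ``saturated``;
    ``comparable_sites[i, j]`` is the number of columns counted for the
    pair."""

    ids: list[str]
    d: np.ndarray
    comparable_sites: np.ndarray
    saturated: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(self.d)
        if not np.array_equal(finite, finite.T) or not np.allclose(
                self.d[finite & finite.T], self.d.T[finite & finite.T]):
            raise ValueError("distance matrix must be symmetric")
        if np.any(self.d[finite] < 0):
            raise ValueError("distances must be non-negative")

    @property
    def complete(self) -> bool:
        return not self.saturated and bool(np.all(np.isfinite(self.d)))

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.ids.index(a), self.ids.index(b)])

    def to_tsv(self) -> str:
        lines = ["\t".join(["id", *self.ids])]
        for rid, row in zip(self.ids, self.d):
            lines.append("\t".join([rid, *(f"{v:.6f}" for v in row)]))
        return "\n".join(lines) + "\n"


def k2p_distance(row_a: str, row_b: str) -> tuple[float, float, float, int]:
    """K2P distance between two equal-length gapped rows.

    Returns ``(d, P, Q, n_sites)`` where P and Q are the transition and
    transversion proportions over the ``n_sites`` pairwise-comparable
    columns.  Raises :class:`SaturationError` when the correction is
    undefined and ``ValueError`` when no column is comparable.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must be equal length")
    n = ts = tv = 0
    for a, b in zip(row_a, row_b):
        if a in UNAMBIGUOUS and b in UNAMBIGUOUS:
            n += 1
            if a != b:
                if (a, b) in TRANSITIONS:
                    ts += 1
                else:
                    tv += 1
    if n == 0:
        raise ValueError("no comparable sites between the two rows")
    p = ts / n
    q = tv / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P undefined for P={p:.3f}, Q={q:.3f} (saturated pair)")
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return max(d, 0.0), p, q, n


def distance_matrix(aln: Alignment, *, deletion: str = "pairwise") -> DistanceMatrix:
    """All-pairs K2P distances for an alignment.

    ``deletion="complete"`` first drops every column in which any row has a
    gap or ambiguity; the default ``"pairwise"`` counts each pair's columns
    independently.  Saturated pairs become NaN entries (with a warning);
    a pair with zero comparable sites is an error.
    """
    if aln.n_rows < 2:
        raise ValueError("need at least 2 rows")
    rows = aln.rows
    if deletion == "complete":
        keep = [all(ch in UNAMBIGUOUS for ch in col) for col in zip(*rows)]
        rows = ["".join(ch for ch, k in zip(row, keep) if k) for row in rows]
        if not rows[0]:
            raise ValueError("complete deletion removed every column")
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")
    n = aln.n_rows
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    saturated: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                dij, _, _, nij = k2p_distance(rows[i], rows[j])
            except SaturationError:
                saturated.append((aln.ids[i], aln.ids[j]))
                d[i, j] = d[j, i] = np.nan
                continue
            except ValueError:
                raise ValueError(
                    f"pair ({aln.ids[i]!r}, {aln.ids[j]!r}) has zero "
                    "comparable sites")
            d[i, j] = d[j, i] = dij
            sites[i, j] = sites[j, i] = nij
    if saturated:
        warnings.warn(f"{len(saturated)} saturated pair(s) excluded: "
                      f"{saturated[:5]}")
    return DistanceMatrix(ids=list(aln.ids), d=d, comparable_sites=sites,
                          saturated=saturated)


@dataclass(frozen=True)
class DivergenceSummary:
    """Interspecific K2P divergence: all between-species pair distances,
    their range, and a binned relative-frequency histogram."""

    distances: tuple[float, ...]
    min: float
    max: float
    max_rounded: float
    histogram: tuple[tuple[float, float, float], ...]  # (lo, hi, rel freq)


def divergence_summary(dm: DistanceMatrix, species_of: Mapping[str, str],
                       *, bin_width: float = 0.05) -> DivergenceSummary:
    """Summarise between-species distances (within-species pairs ignored)."""
    dist = []
    for i, a in enumerate(dm.ids):
        for j in range(i + 1, len(dm.ids)):
            b = dm.ids[j]
            if species_of[a] != species_of[b]:
                v = dm.d[i, j]
                if np.isfinite(v):
                    dist.append(float(v))
    if not dist:
        raise ValueError("no interspecific pair in the matrix")
    lo, hi = min(dist), max(dist)
    n_bins = max(1, int(math.floor(hi / bin_width)) + 1)
    counts = [0] * n_bins
    for v in dist:
        counts[min(int(v // bin_width), n_bins - 1)] += 1
    hist = tuple(
        (k * bin_width, (k + 1) * bin_width, c / len(dist))
        for k, c in enumerate(counts)
    )
    return DivergenceSummary(
        distances=tuple(dist), min=lo, max=hi,
        max_rounded=round(hi, 2), histogram=hist,
    )


def histogram_tsv(summary: DivergenceSummary) -> str:
    lines = ["bin_start\tbin_end\trelative_frequency"]
    for lo, hi, f in summary.histogram:
        lines.append(f"{lo:.2f}\t{hi:.2f}\t{f:.4f}")
    return "\n".join(lines) + "\n"


@dataclass
class PhyloTree:
    """Unrooted tree with branch lengths in substitutions/site and optional
    internal-branch supports in percent of bootstrap replicates."""

    root: TreeNode
    ids: list[str]
    n_replicates: int | None = None
    n_skipped: int = 0

    def leaves(self) -> set[str]:
        return {t.name for t in self.root.tips()}

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Canonical internal bipartitions: each maps the side *not*
        containing the lexicographically smallest leaf to its defining
        node."""
        all_leaves = self.leaves()
        ref = min(all_leaves)
        n = len(all_leaves)
        out: dict[frozenset, TreeNode] = {}
        for node in self.root.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if ref in side:
                side = frozenset(all_leaves - side)
            if 2 <= len(side) <= n - 2:
                out[side] = node
        return out


def nj_tree(dm: DistanceMatrix, *, allow_negative: bool = False) -> PhyloTree:
    """Saitou-Nei neighbor joining with the Studier-Keppler criterion.

    The pair minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j is joined at each
    step; ties are broken by the lexicographically smallest id pair (each
    cluster represented by its smallest member id).  Negative branch
    lengths are clamped to 0 unless ``allow_negative``.
    """
    if not dm.complete:
        raise ValueError("NJ requires a complete distance matrix")
    n0 = len(dm.ids)
    if n0 < 3:
        raise ValueError("NJ needs at least 3 taxa")

    def clamp(x: float) -> float:
        return x if allow_negative else max(x, 0.0)

    d = dm.d.copy()
    nodes = [TreeNode(name=rid) for rid in dm.ids]
    reps = list(dm.ids)

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                pair = tuple(sorted((reps[i], reps[j])))
                key = (q, pair)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dnew = (d[i, :] + d[j, :] - d[i, j]) / 2.0
        keep = [k for k in range(n) if k not in (i, j)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]

    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = clamp((dab + dac - dbc) / 2.0)
    b.length = clamp((dab + dbc - dac) / 2.0)
    c.length = clamp((dac + dbc - dab) / 2.0)
    root = TreeNode(children=[a, b, c])
    return PhyloTree(root=root, ids=list(dm.ids))


def bootstrap_support(aln: Alignment, *, replicates: int = 1000,
                      seed: int = 0,
                      identity_resample: bool = False,
                      matrix_fn: Callable[[Alignment], DistanceMatrix]
                      = distance_matrix) -> PhyloTree:
    """NJ tree with column-resampling bootstrap supports.

    Supports are mapped onto the original tree's internal bipartitions as
    the percentage of successful replicates containing the same
    bipartition.  Replicates whose distance matrix is saturated or
    incomplete are skipped and counted in ``n_skipped``.
    ``identity_resample`` forces every replicate to reuse the original
    columns (test mode: every support must then be 100).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    tree = nj_tree(matrix_fn(aln))
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    successful = 0
    skipped = 0
    length = aln.length
    for _ in range(replicates):
        cols = (np.arange(length) if identity_resample
                else rng.integers(0, length, size=length))
        rows = ["".join(row[c] for c in cols) for row in aln.rows]
        try:
            rep_dm = matrix_fn(Alignment(ids=list(aln.ids), rows=rows))
            if not rep_dm.complete:
                raise SaturationError("incomplete replicate matrix")
            rep_tree = nj_tree(rep_dm)
        except (SaturationError, ValueError):
            skipped += 1
            continue
        successful += 1
        rep_bps = set(rep_tree.bipartitions())
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    if successful == 0:
        raise SaturationError("every bootstrap replicate was skipped")
    for bp, node in target.items():
        node.support = 100.0 * counts[bp] / successful
    tree.n_replicates = successful
    tree.n_skipped = skipped
    return tree


def is_monophyletic(tree: PhyloTree, leaf_subset: Sequence[str],
                    outgroup_id: str) -> bool:
    """True iff ``leaf_subset`` is exactly one side of some branch of the
    tree rooted at ``outgroup_id``."""
    leaves = tree.leaves()
    subset = set(leaf_subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    if not subset <= leaves:
        raise ValueError(f"subset contains non-leaves: {subset - leaves}")
    if outgroup_id not in leaves:
        raise ValueError(f"outgroup {outgroup_id!r} is not a leaf")
    if outgroup_id in subset:
        raise ValueError("outgroup must not be part of the tested subset")
    if len(subset) == 1:
        return True
    for node in tree.root.traverse(include_self=False):
        side = {t.name for t in node.tips()}
        if side == subset or (leaves - side) == subset:
            return True
    return False


def _newick_node(node: TreeNode) -> str:
    if node.is_tip():
        label = node.name or ""
    else:
        support = getattr(node, "support", None)
        label = "" if support is None else str(int(round(support)))
    inner = ""
    if not node.is_tip():
        inner = "(" + ",".join(_newick_node(c) for c in node.children) + ")"
    length = "" if node.length is None else f":{node.length:.6f}"
    return f"{inner}{label}{length}"


def write_newick(tree: PhyloTree) -> str:
    """Serialize with branch lengths; integer supports become internal node
    labels."""
    return "(" + ",".join(_newick_node(c) for c in tree.root.children) + ");"


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string back into a :class:`PhyloTree` (internal node
    labels are interpreted as integer supports when numeric)."""
    root = TreeNode.read(io.StringIO(text), convert_underscores=False)
    for node in root.non_tips(include_self=True):
        if node.name is not None:
            try:
                node.support = float(node.name)
            except ValueError:
                pass
    ids = sorted(t.name for t in root.tips())
    return PhyloTree(root=root, ids=ids)
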