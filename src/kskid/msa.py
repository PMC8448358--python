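"""Multiple sequence alignment, region slicing and site classification.

The alignment stage mirrors the usual barcoding workflow: build (or ingest)
a multiple alignment of the reference ITS sequences, slice it into the
ITS1 / 5.8S / ITS2 sub-alignments, and summarise each candidate barcode by
its site classes (conserved, variable, parsimony-informative, singleton).

The MSA is a deterministic progressive alignment: sequences are added one
at a time by globally aligning each to the majority-consensus of the
running alignment, with gaps propagated ("once a gap, always a gap").  An
externally produced aligned FASTA can be ingested verbatim instead, so
alignments hand-edited in other software are reproducible exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .records import UNAMBIGUOUS, RegionPartition, SequenceRecord, read_fasta


@dataclass(frozen=True)
class Scoring:
    """Affine alignment scheme: first gap position costs ``gap_open``,
    each further position ``gap_extend``."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5


@dataclass
class Alignment:
    """An ordered multiple alignment: parallel lists of ids and equal-length
    gapped rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must be parallel")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate row ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, rid: str) -> str:
        try:
            return self.rows[self.ids.index(rid)]
        except ValueError:
            raise KeyError(f"no row with id {rid!r}")

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace("-", "")


@dataclass(frozen=True)
class SiteStats:
    """Per-region alignment summary in the style of barcode-property tables."""

    aligned_length: int
    length_range: tuple[int, int]
    conserved: int
    variable: int
    parsimony_informative: int
    singleton: int

    def __post_init__(self) -> None:
        if self.parsimony_informative + self.singleton != self.variable:
            raise ValueError("PI + singleton must equal variable")
        if self.conserved + self.variable > self.aligned_length:
            raise ValueError("site classes exceed aligned length")


def _global_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def pairwise_align(a: str, b: str,
                   scoring: Scoring = Scoring()) -> tuple[str, str, float]:
    """Optimal global alignment of two sequences under the affine scheme.

    Returns the two gapped rows and the alignment score.  Tie-breaking among
    co-optimal alignments is deterministic (the aligner's first reported
    alignment); the score is tie-independent.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _global_aligner(scoring)
    best = aligner.align(a, b)[0]
    return str(best[0]), str(best[1]), float(best.score)


def _consensus(rows: Sequence[str]) -> str:
    """Columnwise majority character over non-gap symbols (ties broken
    alphabetically); an all-gap column yields the first row's gap."""
    out = []
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for ch in col:
            if ch != "-":
                counts[ch] = counts.get(ch, 0) + 1
        if counts:
            out.append(min(counts, key=lambda c: (-counts[c], c)))
        else:
            out.append("-")
    return "".join(out)


def progressive_msa(records: Sequence[SequenceRecord],
                    scoring: Scoring = Scoring()) -> Alignment:
    """Deterministic progressive MSA.

    Guide order: the longest sequence first (ties by id), then the rest by
    descending global-alignment score against that anchor (ties by id).
    Each sequence is added by aligning it to the consensus of the running
    alignment; gap columns opened in the consensus are propagated into every
    existing row.
    """
    if len(records) < 2:
        raise ValueError("progressive MSA needs at least 2 records")
    anchor = min(records, key=lambda r: (-len(r.residues), r.id))
    rest = [r for r in records if r.id != anchor.id]
    scores = {
        r.id: pairwise_align(anchor.residues, r.residues, scoring)[2]
        for r in rest
    }
    rest.sort(key=lambda r: (-scores[r.id], r.id))

    ids = [anchor.id]
    rows = [anchor.residues]
    for rec in rest:
        cons = _consensus(rows)
        g_cons, g_new, _ = pairwise_align(cons, rec.residues, scoring)
        # propagate consensus gaps into existing rows
        new_rows = []
        for row in rows:
            out = []
            it = iter(row)
            for ch in g_cons:
                out.append("-" if ch == "-" else next(it))
            new_rows.append("".join(out))
        rows = new_rows
        rows.append(g_new)
        ids.append(rec.id)
    return Alignment(ids=ids, rows=rows)


def read_aligned_fasta(path: str | Path) -> Alignment:
    """Ingest an externally produced aligned FASTA verbatim."""
    records = read_fasta(path, allow_gaps=True)
    return Alignment(ids=[r.id for r in records],
                     rows=[r.residues for r in records])


def write_aligned_fasta(aln: Alignment, path: str | Path,
                        *, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(aln.ids, aln.rows):
            fh.write(f">{rid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i:i + width] + "\n")


def _ungapped_positions(row: str) -> list[int]:
    """For each column, the 0-based ungapped position of the residue there,
    or -1 for gap columns."""
    pos = -1
    out = []
    for ch in row:
        if ch != "-":
            pos += 1
            out.append(pos)
        else:
            out.append(-1)
    return out


def slice_region(aln: Alignment,
                 partitions: Mapping[str, RegionPartition],
                 region: str, *, missing: str = "error") -> Alignment:
    """Extract the sub-alignment of one region (``its1``/``r5_8s``/``its2``).

    Kept columns are the union, over rows, of columns holding that row's
    region residues.  Within a kept column, a residue of some *other* row
    that falls outside that row's own region is masked to a gap, so each
    sliced row ungaps exactly to its region substring.  A row without a
    partition is an error by default; ``missing="keep"`` instead retains
    such a row's residues in every kept column (useful for outgroups whose
    region structure is unknown — their homologous stretch shares the kept
    columns).
    """
    if region == "full":
        return Alignment(ids=list(aln.ids), rows=list(aln.rows))
    if missing not in ("error", "keep"):
        raise ValueError(f"unknown missing policy {missing!r}")
    for rid in aln.ids:
        if rid not in partitions and missing == "error":
            raise KeyError(f"no region partition for row {rid!r}")
    in_region: list[list[bool]] = []
    keep = [False] * aln.length
    for rid, row in zip(aln.ids, aln.rows):
        if rid not in partitions:
            in_region.append([True] * aln.length)
            continue
        lo, hi = partitions[rid].region(region)
        flags = [lo <= p < hi for p in _ungapped_positions(row)]
        in_region.append(flags)
        for c, f in enumerate(flags):
            if f:
                keep[c] = True
    cols = [c for c in range(aln.length) if keep[c]]
    new_rows = []
    for flags, row in zip(in_region, aln.rows):
        new_rows.append("".join(row[c] if flags[c] else "-" for c in cols))
    return Alignment(ids=list(aln.ids), rows=new_rows)


def classify_sites(aln: Alignment) -> SiteStats:
    """Classify alignment columns into conserved / variable / PI / singleton.

    Only unambiguous A/C/G/T states are counted; a row showing a gap or an
    ambiguity code at a column is ignored *for that column* (sitewise
    deletion).  Columns with fewer than two countable rows are excluded from
    both conserved and variable counts.
    """
    if aln.n_rows == 0 or aln.length == 0:
        raise ValueError("cannot classify an empty alignment")
    conserved = variable = pi = 0
    for col in zip(*aln.rows):
        counts: dict[str, int] = {}
        for ch in col:
            if ch in UNAMBIGUOUS:
                counts[ch] = counts.get(ch, 0) + 1
        countable = sum(counts.values())
        if countable < 2:
            continue
        if len(counts) == 1:
            conserved += 1
        else:
            variable += 1
            if sum(1 for n in counts.values() if n >= 2) >= 2:
                pi += 1
    ungapped_lengths = [len(r.replace("-", "")) for r in aln.rows]
    return SiteStats(
        aligned_length=aln.length,
        length_range=(min(ungapped_lengths), max(ungapped_lengths)),
        conserved=conserved,
        variable=variable,
        parsimony_informative=pi,
        singleton=variable - pi,
    )


def site_stats_table(stats: Mapping[str, SiteStats]) -> str:
    """Render region SiteStats as a TSV block (regions as columns)."""
    regions = list(stats)
    lines = ["\t".join(["property", *regions])]

    def fmt_pct(n: int, total: int) -> str:
        return f"{n} ({100.0 * n / total:.2f}%)" if total else str(n)

    lines.append("\t".join(
        ["length_range_bp", *(f"{s.length_range[0]}-{s.length_range[1]}"
                              for s in stats.values())]))
    lines.append("\t".join(
        ["aligned_length_bp", *(str(s.aligned_length) for s in stats.values())]))
    for prop in ("conserved", "variable", "parsimony_informative", "singleton"):
        lines.append("\t".join(
            [prop, *(fmt_pct(getattr(s, prop), s.aligned_length)
                     for s in stats.values())]))
    return "\n".join(lines) + "\n"
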