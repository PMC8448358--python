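"""Sequence records, sample metadata and ITS region partitioning.

The unit of data is a single nuclear ribosomal ITS sequence (ITS1 + 5.8S +
ITS2) attached to a sample of known or unknown botanical origin.  Sequences
come in as plain FASTA; sample metadata (species, role, GenBank accession)
comes in as a tab-separated sample sheet.  Because the three spacer/gene
boundaries are rarely annotated in deposited sequences, the partition of a
raw ITS sequence into ITS1 / 5.8S / ITS2 is recovered by locally aligning a
conserved 5.8S core ("probe") against the sequence: the best-scoring probe
placement becomes the 5.8S interval, the flanks become ITS1 and ITS2.

Coordinates are 0-based half-open throughout the library; user-facing
reports convert to 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import Align

IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN-")
UNAMBIGUOUS = frozenset("ACGT")

ROLES = ("authentic", "commercial", "outgroup", "negative_control")


class PartitionError(ValueError):
    """Raised when the 5.8S probe cannot be placed inside a sequence."""


@dataclass
class SequenceRecord:
    """One ITS (or flanked template) sequence with sample metadata.

    ``role`` follows the study design: *authentic* reference vouchers,
    *commercial* market samples of unknown origin, one *outgroup*, and
    *negative_control* congeners.
    """

    id: str
    residues: str
    species: str = "unknown"
    role: str = "commercial"
    accession: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues must be non-empty")
        self.residues = self.residues.upper().replace("U", "T")
        for pos, ch in enumerate(self.residues):
            if ch not in IUPAC_ALPHABET:
                raise ValueError(
                    f"record {self.id!r}: invalid character {ch!r} "
                    f"at position {pos + 1}"
                )
        if self.role not in ROLES:
            raise ValueError(
                f"record {self.id!r}: unknown role {self.role!r}; "
                f"expected one of {ROLES}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass(frozen=True)
class RegionPartition:
    """ITS1 / 5.8S / ITS2 intervals on one ungapped sequence (0-based,
    half-open, contiguous)."""

    its1: tuple[int, int]
    r5_8s: tuple[int, int]
    its2: tuple[int, int]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.as_dict().items():
            if not (0 <= lo < hi):
                raise ValueError(f"{name} interval {lo, hi} is empty or invalid")
        if self.its1[1] != self.r5_8s[0] or self.r5_8s[1] != self.its2[0]:
            raise ValueError("intervals must be contiguous (ITS1|5.8S|ITS2)")

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {"its1": self.its1, "r5_8s": self.r5_8s, "its2": self.its2}

    def region(self, name: str) -> tuple[int, int]:
        try:
            return self.as_dict()[name]
        except KeyError:
            raise KeyError(f"unknown region {name!r}; expected its1/r5_8s/its2")

    @property
    def length(self) -> int:
        return self.its2[1]


@dataclass(frozen=True)
class SampleInfo:
    species: str
    role: str
    accession: str | None = None


def read_fasta(path: str | Path, *, allow_gaps: bool = False,
               sheet: Mapping[str, SampleInfo] | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    The header token before the first whitespace becomes the record id;
    residues are upper-cased and U is mapped to T.  ``allow_gaps=False``
    rejects ``-`` characters (raw, unaligned input).  If a ``sheet`` mapping
    is given, species/role/accession are filled from it.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        rid = header.split()[0]
        if not rid:
            raise ValueError(f"{path}: FASTA entry with empty id")
        if rid in seen:
            raise ValueError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        residues = "".join(chunks)
        if not allow_gaps and "-" in residues:
            raise ValueError(
                f"{path}: record {rid!r} contains gap characters; "
                "gaps are only allowed in aligned FASTA"
            )
        info = sheet.get(rid) if sheet else None
        records.append(
            SequenceRecord(
                id=rid,
                residues=residues,
                species=info.species if info else "unknown",
                role=info.role if info else "commercial",
                accession=info.accession if info else None,
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line)
    flush()
    if not records:
        raise ValueError(f"{path}: empty FASTA file")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                *, width: int = 70) -> None:
    """Write records as FASTA (id-only headers, fixed line wrap)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def read_sample_sheet(path: str | Path) -> dict[str, SampleInfo]:
    """Parse a tab-separated sample sheet with header ``id species role
    [accession]`` into a mapping id -> :class:`SampleInfo`."""
    path = Path(path)
    mapping: dict[str, SampleInfo] = {}
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise ValueError(f"{path}: empty sample sheet")
        cols = header_line.rstrip("\n").split("\t")
        required = ["id", "species", "role"]
        for col in required:
            if col not in cols:
                raise ValueError(f"{path}: missing required column {col!r}")
        idx = {c: i for i, c in enumerate(cols)}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            rid = parts[idx["id"]].strip()
            species = parts[idx["species"]].strip()
            role = parts[idx["role"]].strip()
            accession = None
            if "accession" in idx and idx["accession"] < len(parts):
                accession = parts[idx["accession"]].strip() or None
            if role not in ROLES:
                raise ValueError(
                    f"{path}:{lineno}: unknown role {role!r}; "
                    f"expected one of {ROLES}"
                )
            if rid in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate sample id {rid!r}")
            mapping[rid] = SampleInfo(species=species, role=role,
                                      accession=accession)
    return mapping


def read_region_overrides(path: str | Path,
                          lengths: Mapping[str, int]) -> dict[str, RegionPartition]:
    """Read explicit per-record region coordinates.

    TSV with header ``id its1_end r5_8s_end`` where the two ends are 1-based
    *inclusive* (so ``its1_end`` is the last ITS1 base).  ``lengths`` maps
    each id to its ungapped sequence length (needed for the ITS2 end).
    """
    out: dict[str, RegionPartition] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for col in ("id", "its1_end", "r5_8s_end"):
            if col not in idx:
                raise ValueError(f"{path}: missing column {col!r}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rid = parts[idx["id"]]
            its1_end = int(parts[idx["its1_end"]])
            r58_end = int(parts[idx["r5_8s_end"]])
            if rid not in lengths:
                raise ValueError(f"{path}: id {rid!r} has no known length")
            out[rid] = RegionPartition(
                its1=(0, its1_end),
                r5_8s=(its1_end, r58_end),
                its2=(r58_end, lengths[rid]),
            )
    return out


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def partition_its(record: SequenceRecord, r5_8s_probe: str,
                  *, min_identity: float = 0.70) -> RegionPartition:
    """Partition an ungapped ITS sequence using a conserved 5.8S core probe.

    The probe is placed by best local alignment; the matched span on the
    record becomes the 5.8S interval.  Placement with identity below
    ``min_identity`` (fraction of probe positions matched identically) or a
    match touching either end of the sequence (which would leave an empty
    ITS1 or ITS2) raises :class:`PartitionError`.
    """
    probe = r5_8s_probe.upper().replace("U", "T")
    if len(probe) < 50:
        raise ValueError("5.8S probe must be at least 50 nt")
    seq = record.residues
    if "-" in seq:
        raise ValueError(f"record {record.id!r} must be ungapped")
    aln = _local_aligner().align(seq, probe)
    best = aln[0]
    target_blocks, query_blocks = best.aligned
    matches = 0
    for (ts, te), (qs, qe) in zip(target_blocks, query_blocks):
        for off in range(te - ts):
            if seq[ts + off] == probe[qs + off]:
                matches += 1
    identity = matches / len(probe)
    if identity < min_identity:
        raise PartitionError(
            f"record {record.id!r}: best 5.8S probe placement has identity "
            f"{identity:.2f} < {min_identity:.2f}"
        )
    start = int(target_blocks[0][0])
    end = int(target_blocks[-1][1])
    if start == 0 or end == len(seq):
        raise PartitionError(
            f"record {record.id!r}: 5.8S match touches the sequence end "
            "(empty ITS1 or ITS2 flank)"
        )
    return RegionPartition(its1=(0, start), r5_8s=(start, end),
                           its2=(end, len(seq)))


def warn_missing_ids(sheet: Mapping[str, SampleInfo],
                     records: Iterable[SequenceRecord]) -> None:
    """Warn (not fail) on sheet ids with no matching FASTA record."""
    have = {r.id for r in records}
    for rid in sheet:
        if rid not in have:
            warnings.warn(f"sample sheet id {rid!r} has no FASTA record")
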