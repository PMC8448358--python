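"""Intraspecific variant calling and haplotype assignment.

Within one species' alignment rows, every column at which members differ —
by base, by IUPAC ambiguity code, or by gap versus base — is a variant
position.  Ambiguity codes arising from direct sequencing of heterozygous
templates (R, Y, W, ...) are treated as *distinct fifth states* and never
expanded: two sequences reading T and Y at the same position carry
different haplotypes.  Haplotypes are groups of members with identical
state vectors over the variant positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .msa import Alignment


@dataclass
class SNPTable:
    """Variant table for one species.

    ``positions`` are 1-based columns on the species alignment;
    ``kinds`` labels each position ``"substitution"`` or ``"indel"``;
    ``states[m]`` is member *m*'s state vector (verbatim characters);
    ``ungapped_positions[m]`` maps each variant position back onto member
    *m*'s own ungapped sequence (1-based; None where the member has a gap).
    """

    species: str
    member_ids: list[str]
    positions: list[int]
    kinds: list[str]
    states: dict[str, tuple[str, ...]]
    ungapped_positions: dict[str, tuple[int | None, ...]] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("positions must be strictly increasing")
        for pos_idx in range(len(self.positions)):
            observed = {self.states[m][pos_idx] for m in self.member_ids}
            if len(observed) < 2:
                raise ValueError(
                    f"position {self.positions[pos_idx]} is not variable")


@dataclass(frozen=True)
class HaplotypeAssignment:
    haplotype_id: int
    members: tuple[str, ...]
    signature: tuple[str, ...]


def call_variants(aln: Alignment, members: Sequence[str],
                  species: str = "") -> SNPTable:
    """Find all columns at which the given members differ.

    Any state difference counts, including ambiguity codes and gap-vs-base.
    A column where at least one member has a gap (and others a base) is an
    ``indel`` column; otherwise ``substitution``.
    """
    if len(members) < 2:
        raise ValueError("need at least 2 members to call variants")
    rows = {}
    for m in members:
        rows[m] = aln.row(m)  # KeyError -> missing member surfaces here
    positions: list[int] = []
    kinds: list[str] = []
    states: dict[str, list[str]] = {m: [] for m in members}
    for c in range(aln.length):
        col = {m: rows[m][c] for m in members}
        if len(set(col.values())) < 2:
            continue
        positions.append(c + 1)
        kinds.append("indel" if "-" in col.values() else "substitution")
        for m in members:
            states[m].append(col[m])
    ungapped: dict[str, tuple[int | None, ...]] = {}
    for m in members:
        cum = 0
        per_col = []
        for ch in rows[m]:
            cum += ch != "-"
            per_col.append(cum if ch != "-" else None)
        ungapped[m] = tuple(per_col[p - 1] for p in positions)
    return SNPTable(
        species=species,
        member_ids=list(members),
        positions=positions,
        kinds=kinds,
        states={m: tuple(v) for m, v in states.items()},
        ungapped_positions=ungapped,
    )


def assign_haplotypes(table: SNPTable) -> list[HaplotypeAssignment]:
    """Group members by exact signature equality.

    Haplotype ids start at 1 and follow the order in which each signature
    first occurs along ``member_ids``.  An empty table yields a single
    haplotype containing every member.
    """
    order: list[tuple[str, ...]] = []
    groups: dict[tuple[str, ...], list[str]] = {}
    for m in table.member_ids:
        sig = table.states.get(m, ())
        if sig not in groups:
            groups[sig] = []
            order.append(sig)
        groups[sig].append(m)
    return [
        HaplotypeAssignment(haplotype_id=i + 1, members=tuple(groups[sig]),
                            signature=sig)
        for i, sig in enumerate(order)
    ]


def snp_table_tsv(table: SNPTable,
                  haplotypes: list[HaplotypeAssignment] | None = None) -> str:
    """Render the variant table (one row per member, one column per
    position), optionally prefixed with the haplotype id."""
    if haplotypes is None:
        haplotypes = assign_haplotypes(table)
    hap_of = {m: h.haplotype_id for h in haplotypes for m in h.members}
    header = ["haplotype", "id", *map(str, table.positions)]
    lines = ["\t".join(header)]
    for m in table.member_ids:
        lines.append("\t".join(
            [str(hap_of[m]), m, *table.states.get(m, ())]))
    return "\n".join(lines) + "\n"
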