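"""In-silico multiplex PCR: binding-site search, product enumeration and
species calling from virtual gel profiles.

A primer binds where its mismatch count against the template (total, and
within a short 3'-terminal window whose mismatches abort polymerase
extension) stays within the configured rules.  Products are all
forward-site x reverse-site pairs within the size limit; the resulting
band list is read like a gel: an internal-control band plus one species
band identifies the species, an internal-control band alone is the
negative-control pattern (plant DNA, none of the panel species), and no
internal control at all is an amplification failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .primers import PrimerCandidate, PrimerSet, reverse_complement


@dataclass(frozen=True)
class BindingRules:
    """Mismatch tolerances for a qualifying binding site."""

    max_total_mismatches: int = 2
    max_three_prime_mismatches: int = 0
    three_prime_window: int = 3


@dataclass(frozen=True)
class BindingSite:
    primer: str
    template: str
    strand: str  # plus | minus
    interval: tuple[int, int]
    total_mismatches: int
    three_prime_mismatches: int


@dataclass(frozen=True)
class SpeciesCall:
    status: str  # identified | negative_control_pattern | amplification_failure | ambiguous
    species: str | None = None
    evidence: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.status == "identified") != (self.species is not None):
            raise ValueError("species must be set iff status is 'identified'")


@dataclass
class GelProfile:
    """Virtual gel lane: bands sorted descending by length (gel order)."""

    template: str
    bands: list[tuple[int, str, str]]  # (length bp, forward, reverse)
    call: SpeciesCall | None = None

    def lengths(self) -> list[int]:
        return [b[0] for b in self.bands]


def _mismatches(primer: str, window: str, w: int) -> tuple[int, int]:
    """Total and 3'-window mismatches of a primer against an equal-length
    template window (both 5'->3'; template N mismatches everything)."""
    total = sum(1 for a, b in zip(primer, window)
                if a != b or b == "N")
    tail = primer[-w:] if w else ""
    tail_win = window[-w:] if w else ""
    three = sum(1 for a, b in zip(tail, tail_win) if a != b or b == "N")
    return total, three


def find_binding_sites(template: str, primer: PrimerCandidate,
                       rules: BindingRules = BindingRules()) -> list[BindingSite]:
    """Scan both strands of an ungapped template for qualifying sites.

    On the plus strand the primer is compared directly to the template
    window; on the minus strand it is compared to the window's reverse
    complement.  A primer longer than the template yields an empty list.
    """
    template = template.upper()
    seq = primer.sequence
    L = len(seq)
    out: list[BindingSite] = []
    if L > len(template):
        return out
    w = rules.three_prime_window
    for i in range(len(template) - L + 1):
        window = template[i:i + L]
        total, three = _mismatches(seq, window, w)
        if (total <= rules.max_total_mismatches
                and three <= rules.max_three_prime_mismatches):
            out.append(BindingSite(primer.name, "", "plus", (i, i + L),
                                   total, three))
        total, three = _mismatches(seq, reverse_complement(window), w)
        if (total <= rules.max_total_mismatches
                and three <= rules.max_three_prime_mismatches):
            out.append(BindingSite(primer.name, "", "minus", (i, i + L),
                                   total, three))
    return out


def simulate_multiplex(template, primer_set: PrimerSet,
                       rules: BindingRules = BindingRules(),
                       max_product_bp: int = 2000) -> GelProfile:
    """Enumerate all products of the full panel on one template.

    Products pair any plus-strand site with any minus-strand site such
    that ``plus.start < minus.end`` and the product length
    ``minus.end - plus.start`` does not exceed ``max_product_bp``; bands
    are deduplicated by (length, primer pair).
    """
    tid = getattr(template, "id", "")
    seq = getattr(template, "residues", template)
    plus: list[BindingSite] = []
    minus: list[BindingSite] = []
    for primer in primer_set.all_primers():
        for site in find_binding_sites(seq, primer, rules):
            (plus if site.strand == "plus" else minus).append(site)
    bands: set[tuple[int, str, str]] = set()
    for p in plus:
        for m in minus:
            if p.interval[0] < m.interval[1]:
                length = m.interval[1] - p.interval[0]
                if length <= max_product_bp:
                    bands.add((length, p.primer, m.primer))
    ordered = sorted(bands, key=lambda b: (-b[0], b[1], b[2]))
    return GelProfile(template=tid, bands=ordered)


def call_species(profile: GelProfile,
                 expected: Mapping[str, tuple[int, int]],
                 tolerance_bp: int = 10) -> SpeciesCall:
    """Read a gel lane against the expected per-species band table.

    The internal-control band must match (within tolerance) the internal
    size of some species, else the lane is an amplification failure.
    Exactly one matched species band identifies the species; none is the
    negative-control pattern; two or more is ambiguous.
    """
    if not expected:
        raise ValueError("expected band table must be non-empty")
    lengths = profile.lengths()
    internal_hits = [
        f"internal~{bp}bp ({sp})"
        for sp, (bp, _) in expected.items()
        if any(abs(l - bp) <= tolerance_bp for l in lengths)
    ]
    if not internal_hits:
        return SpeciesCall(status="amplification_failure")
    matched = {}
    for sp, (_, species_bp) in expected.items():
        hits = [l for l in lengths if abs(l - species_bp) <= tolerance_bp]
        if hits:
            matched[sp] = hits[0]
    evidence = tuple(internal_hits[:1]) + tuple(
        f"{sp}~{l}bp" for sp, l in sorted(matched.items()))
    if len(matched) == 1:
        sp = next(iter(matched))
        return SpeciesCall(status="identified", species=sp, evidence=evidence)
    if not matched:
        return SpeciesCall(status="negative_control_pattern",
                           evidence=evidence)
    return SpeciesCall(status="ambiguous", evidence=evidence)


def profile_tsv(profiles: list[GelProfile]) -> str:
    lines = ["template\tlength_bp\tforward\treverse"]
    for prof in profiles:
        for length, fwd, rev in prof.bands:
            lines.append(f"{prof.template}\t{length}\t{fwd}\t{rev}")
    return "\n".join(lines) + "\n"


def calls_tsv(calls: Mapping[str, SpeciesCall]) -> str:
    lines = ["sample\tstatus\tspecies\tevidence"]
    for sid, call in calls.items():
        lines.append(f"{sid}\t{call.status}\t{call.species or '-'}\t"
                     f"{';'.join(call.evidence) or '-'}")
    return "\n".join(lines) + "\n"
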