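"""Species-specific primer design for multiplex PCR.

The multiplex panel follows the classical rDNA design for distinguishing
plants that share one vernacular name: a conserved forward primer in the
5.8S gene plus a universal reverse primer in 26S amplify an
internal-control product from *any* plant template, while one reverse
primer per species, whose 3' terminus sits on an ITS2 site diagnostic for
that species, yields a shorter species product only from its own target.
On a gel, "internal control only" therefore means "plant DNA present but
none of the reference species" — distinguishable from a failed PCR.

Design is enumeration-and-rank over candidate windows anchored on
discriminating alignment columns, filtered by length, GC content and
melting temperature, and ranked by 3'-window mismatches against the
non-target taxa.

Melting temperatures use nearest-neighbor thermodynamics (SantaLucia 1997
unified stacking parameters, Owczarzy 2004 salt correction) under a fixed
calibrated condition set (50 mM monovalent salt, 120 nM oligo); the
Wallace 2+4 rule is available as a secondary method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.SeqUtils import MeltingTemp as _mt

from .msa import Alignment
from .records import UNAMBIGUOUS, SequenceRecord

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")

#: IUPAC code for each unordered base pair (heterozygous positions).
AMBIGUITY_OF_PAIR = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("GT"): "K", frozenset("AC"): "M",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """(#G + #C) / length; rejects empty or ambiguous sequences."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    bad = set(seq) - UNAMBIGUOUS
    if bad:
        raise ValueError(f"ambiguous characters in primer sequence: {bad}")
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class TmConditions:
    """Solution conditions for the nearest-neighbor duplex model.

    ``na_mM``: monovalent cation concentration; ``oligo_nM`` /
    ``complement_nM``: strand concentrations (primer in large excess over
    template, so the complement term is 0).
    """

    na_mM: float = 50.0
    oligo_nM: float = 120.0
    complement_nM: float = 0.0


#: Conditions under which the nearest-neighbor model reproduces the
#: published panel's Tm column (calibrated once; see
#: scripts/calibrate_tm.py).
CALIBRATED_CONDITIONS = TmConditions()


def melting_temp(seq: str, method: str = "nearest_neighbor",
                 conditions: TmConditions | None = None) -> float:
    """Oligo melting temperature in degrees Celsius.

    ``wallace``: 2(A+T) + 4(G+C).  ``nearest_neighbor``: duplex Tm from
    unified nearest-neighbor dH/dS stacking parameters with initiation
    terms and salt correction under ``conditions`` (default: the calibrated
    set).
    """
    seq = seq.upper()
    if not seq or set(seq) - UNAMBIGUOUS:
        raise ValueError("primer must be a non-empty A/C/G/T string")
    if method == "wallace":
        at = seq.count("A") + seq.count("T")
        gc = seq.count("G") + seq.count("C")
        return 2.0 * at + 4.0 * gc
    if method == "nearest_neighbor":
        if len(seq) < 8:
            raise ValueError("nearest-neighbor model needs length >= 8")
        cond = conditions or CALIBRATED_CONDITIONS
        return float(_mt.Tm_NN(
            seq, nn_table=_mt.DNA_NN3, saltcorr=6,
            Na=cond.na_mM, K=0, Tris=0, Mg=0,
            dnac1=cond.oligo_nM, dnac2=cond.complement_nM,
        ))
    raise ValueError(f"unknown Tm method {method!r}")


@dataclass
class PrimerCandidate:
    """A primer stored 5'->3' as synthesized (reverse primers are the
    reverse complement of the template top strand)."""

    name: str
    sequence: str
    strand: str  # forward | reverse
    target_interval: tuple[int, int] | None = None
    gc: float = field(init=False)
    tm: float = field(init=False)
    three_prime_discriminating: bool = False
    per_taxon_mismatches: dict[str, tuple[int, int]] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("forward", "reverse"):
            raise ValueError("strand must be 'forward' or 'reverse'")
        self.sequence = self.sequence.upper()
        self.gc = gc_content(self.sequence)
        self.tm = melting_temp(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


#: The published KSK multiplex panel (forward 5.8S anchor, universal 26S
#: reverse, and the three species-specific ITS2 reverse primers).
MULTIPLEX_PANEL: dict[str, tuple[str, str]] = {
    "KSKITSF": ("5.8S rDNA anchor (forward)", "TCTCGCATCGATGAAGAA"),
    "ITS4": ("universal 26S rDNA reverse", "TCCTCCGCTTATTGATATGC"),
    "BeAITS2R": ("Betula alnoides specific", "CCAATTTCTGCCCCACT"),
    "StAITS2R": ("Strychnos axillaris specific", "ATCCTCTCCAGCGACAGA"),
    "ZiAITS2R": ("Ziziphus attopensis specific", "CCGGGGACCTACGTTTT"),
}

#: Universal ITS forward primer used to amplify the whole region from the
#: flanking 18S gene.
ITS5S_SEQUENCE = "CCTTATCATTTAGAGGAAGGAG"


def panel_primer(name: str) -> PrimerCandidate:
    purpose, seq = MULTIPLEX_PANEL[name]
    strand = "forward" if name == "KSKITSF" else "reverse"
    return PrimerCandidate(name=name, sequence=seq, strand=strand)


def scan_discriminating_sites(aln: Alignment, target: str,
                              others: Sequence[str],
                              species_of: Mapping[str, str]) -> list[int]:
    """Alignment columns (0-based) where every target row shares one
    unambiguous base and every row of every other listed taxon differs."""
    target_rows = [r for i, r in zip(aln.ids, aln.rows)
                   if species_of.get(i) == target]
    if not target_rows:
        raise ValueError(f"target taxon {target!r} absent from alignment")
    other_rows = [r for i, r in zip(aln.ids, aln.rows)
                  if species_of.get(i) in set(others)]
    if not other_rows:
        raise ValueError("no rows for the non-target taxa")
    sites = []
    for c in range(aln.length):
        states = {r[c] for r in target_rows}
        if len(states) != 1:
            continue
        base = next(iter(states))
        if base not in UNAMBIGUOUS:
            continue
        if all(r[c] != base for r in other_rows):
            sites.append(c)
    return sites


@dataclass(frozen=True)
class PrimerConstraints:
    length: tuple[int, int] = (17, 25)
    gc: tuple[float, float] = (0.40, 0.60)
    tm: tuple[float, float] = (48.0, 58.0)
    tm_target: float = 52.0
    three_prime_window: int = 5
    min_other_mismatches: int = 1


@dataclass
class DesignResult:
    candidates: list[PrimerCandidate]
    report: str = ""


def _taxon_consensus(aln: Alignment, species_of: Mapping[str, str],
                     taxon: str) -> str:
    rows = [r for i, r in zip(aln.ids, aln.rows)
            if species_of.get(i) == taxon]
    out = []
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        out.append(min(counts, key=lambda c: (-counts[c], c)))
    return "".join(out)


def design_species_primer(aln: Alignment, target: str,
                          others: Sequence[str],
                          species_of: Mapping[str, str],
                          constraints: PrimerConstraints = PrimerConstraints(),
                          ) -> DesignResult:
    """Enumerate and rank reverse species-specific primer candidates.

    Every candidate's 3' terminus (on the reverse strand) sits on a
    discriminating column ``c``; the primer is the reverse complement of
    the target consensus over alignment columns ``[c, c + length)``.
    Windows containing target-internal variation, gaps or ambiguity codes
    are disqualified.  Ranking: most 3'-window mismatches against the worst
    non-target taxon first, then Tm closest to the set target, then
    shortest, then leftmost.
    """
    sites = scan_discriminating_sites(aln, target, others, species_of)
    report_lines = []
    if not sites:
        return DesignResult([], "no discriminating site between "
                                f"{target} and {list(others)}")
    target_rows = [r for i, r in zip(aln.ids, aln.rows)
                   if species_of.get(i) == target]
    consensi = {t: _taxon_consensus(aln, species_of, t) for t in others}
    lo_len, hi_len = constraints.length
    w = constraints.three_prime_window
    candidates = []
    n_window_fail = n_filter_fail = 0
    for c in sites:
        for length in range(lo_len, hi_len + 1):
            if c + length > aln.length:
                continue
            window = [row[c:c + length] for row in target_rows]
            if len(set(window)) != 1:
                n_window_fail += 1
                continue
            top = window[0]
            if set(top) - UNAMBIGUOUS:
                n_window_fail += 1
                continue
            primer_seq = reverse_complement(top)
            gc = gc_content(primer_seq)
            if not (constraints.gc[0] <= gc <= constraints.gc[1]):
                n_filter_fail += 1
                continue
            if constraints.tm[0] > constraints.tm[1]:
                n_filter_fail += 1
                continue
            tm = melting_temp(primer_seq)
            if not (constraints.tm[0] <= tm <= constraints.tm[1]):
                n_filter_fail += 1
                continue
            per_taxon = {}
            for t, cons in consensi.items():
                other = cons[c:c + length]
                total = sum(a != b for a, b in zip(top, other))
                three_p = sum(a != b for a, b in
                              zip(top[:w], other[:w]))
                per_taxon[t] = (total, three_p)
            worst_3p = min(mp[1] for mp in per_taxon.values())
            if worst_3p < constraints.min_other_mismatches:
                n_filter_fail += 1
                continue
            cand = PrimerCandidate(
                name=f"{target}_ITS2R_c{c + 1}_{length}",
                sequence=primer_seq, strand="reverse",
                target_interval=(c, c + length),
                three_prime_discriminating=True,
                per_taxon_mismatches=per_taxon,
            )
            candidates.append((worst_3p, abs(tm - constraints.tm_target),
                               length, c, cand))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
    ranked = [c[-1] for c in candidates]
    if not ranked:
        report_lines.append(
            f"{target}: {len(sites)} discriminating site(s) but no window "
            f"satisfied the constraints ({n_window_fail} windows with "
            f"target variation/ambiguity, {n_filter_fail} failed "
            "length/GC/Tm/mismatch filters); consider relaxing GC "
            f"{constraints.gc}, Tm {constraints.tm} or length "
            f"{constraints.length}")
    return DesignResult(ranked, "\n".join(report_lines))


@dataclass
class PrimerSet:
    """The assembled multiplex: shared forward anchor, universal reverse
    (internal control) and one reverse primer per species, with the
    expected amplicon sizes on each species template."""

    forward_anchor: PrimerCandidate
    universal_reverse: PrimerCandidate
    species_reverse: dict[str, PrimerCandidate]
    expected_amplicons: dict[str, tuple[int, int]]  # species -> (internal, species)
    max_tm_spread: float = 6.0

    def __post_init__(self) -> None:
        seqs = [self.forward_anchor.sequence, self.universal_reverse.sequence,
                *(p.sequence for p in self.species_reverse.values())]
        if len(set(seqs)) != len(seqs):
            raise ValueError("primers in the set must be mutually distinct")
        for sp, (internal, species) in self.expected_amplicons.items():
            if internal <= species:
                raise ValueError(
                    f"{sp}: internal-control product ({internal} bp) must "
                    f"exceed the species product ({species} bp)")
        tms = [self.forward_anchor.tm, self.universal_reverse.tm,
               *(p.tm for p in self.species_reverse.values())]
        spread = max(tms) - min(tms)
        if spread > self.max_tm_spread:
            raise ValueError(
                f"Tm spread {spread:.2f} C exceeds the allowed "
                f"{self.max_tm_spread:.2f} C")

    def all_primers(self) -> list[PrimerCandidate]:
        return [self.forward_anchor, self.universal_reverse,
                *self.species_reverse.values()]


def assemble_multiplex_set(forward_anchor: PrimerCandidate,
                           universal_reverse: PrimerCandidate,
                           species_reverse: Mapping[str, PrimerCandidate],
                           templates: Mapping[str, SequenceRecord],
                           *, min_separation_bp: int = 30,
                           max_tm_spread: float = 6.0,
                           rules=None) -> PrimerSet:
    """Validate a panel by in-silico PCR on one template per species.

    Expected amplicons are computed from primer binding sites on each
    species template; the assembly fails if any internal/species or
    species/species band pair is closer than ``min_separation_bp`` (bands
    must be resolvable on a gel) or if the panel's Tm spread exceeds
    ``max_tm_spread``.
    """
    from .pcr import BindingRules, find_binding_sites

    rules = rules or BindingRules()
    expected: dict[str, tuple[int, int]] = {}
    for sp, template in templates.items():
        fwd_sites = [s for s in find_binding_sites(
            template.residues, forward_anchor, rules) if s.strand == "plus"]
        uni_sites = [s for s in find_binding_sites(
            template.residues, universal_reverse, rules)
            if s.strand == "minus"]
        if sp not in species_reverse:
            raise ValueError(f"no species primer for template {sp!r}")
        sp_sites = [s for s in find_binding_sites(
            template.residues, species_reverse[sp], rules)
            if s.strand == "minus"]
        if not fwd_sites or not uni_sites or not sp_sites:
            raise ValueError(
                f"{sp}: missing binding site on its own template "
                f"(forward={len(fwd_sites)}, universal={len(uni_sites)}, "
                f"species={len(sp_sites)})")
        fstart = fwd_sites[0].interval[0]
        internal = uni_sites[-1].interval[1] - fstart
        species_bp = sp_sites[0].interval[1] - fstart
        expected[sp] = (internal, species_bp)

    sizes = sorted((bp, sp) for sp, (_, bp) in expected.items())
    for (a, sa), (b, sb) in zip(sizes, sizes[1:]):
        if b - a < min_separation_bp:
            raise ValueError(
                f"species bands clash: {sa} ({a} bp) vs {sb} ({b} bp) "
                f"closer than {min_separation_bp} bp")
    for sp, (internal, species_bp) in expected.items():
        if internal - species_bp < min_separation_bp:
            raise ValueError(
                f"{sp}: species band ({species_bp} bp) too close to the "
                f"internal control ({internal} bp)")
    return PrimerSet(
        forward_anchor=forward_anchor,
        universal_reverse=universal_reverse,
        species_reverse=dict(species_reverse),
        expected_amplicons=expected,
        max_tm_spread=max_tm_spread,
    )


def primer_report_tsv(pset: PrimerSet) -> str:
    """Panel report: name, purpose, sequence (grouped in triplets), GC, Tm."""
    lines = ["name\tpurpose\tsequence\tgc\ttm_C"]

    def triplets(s: str) -> str:
        return " ".join(s[i:i + 3] for i in range(0, len(s), 3))

    rows = [(pset.forward_anchor, "forward anchor (5.8S)"),
            (pset.universal_reverse, "universal reverse (26S, internal control)")]
    rows += [(p, f"{sp} specific (ITS2)")
             for sp, p in pset.species_reverse.items()]
    for primer, purpose in rows:
        lines.append(f"{primer.name}\t{purpose}\t{triplets(primer.sequence)}"
                     f"\t{primer.gc:.3f}\t{primer.tm:.2f}")
    return "\n".join(lines) + "\n"
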