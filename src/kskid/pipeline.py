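"""End-to-end workflows: barcode evaluation and two-route identification.

``evaluate_barcodes`` reproduces the reference-database stage: align the
authentic ITS sequences, slice the candidate barcode regions, classify
sites, compare interspecific K2P divergence, and verify the selected
region by an NJ bootstrap tree with per-species monophyly checks.

``identify`` runs the two identification routes on unknown market
samples: the molecular route (design the species-specific multiplex panel
from the references, run in-silico PCR on each unknown template, read the
virtual gel) and the chemical route (hierarchical clustering of binary
TLC fingerprints against reference lanes), then reports per-sample
agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import msa, pcr, phylo, primers, tlc
from .records import (RegionPartition, SampleInfo, SequenceRecord,
                      partition_its)

REGIONS = ("full", "its1", "its2")
REGION_LABELS = {"full": "ITS", "its1": "ITS1", "its2": "ITS2"}


@dataclass
class BarcodeReport:
    site_stats: dict[str, msa.SiteStats]
    divergence: dict[str, phylo.DivergenceSummary]
    ranking: list[str]                      # region labels, best first
    selected_region: str
    tree: phylo.PhyloTree | None
    monophyly: dict[str, bool]
    newick: str | None = None

    def summary(self) -> str:
        lines = ["Barcode evaluation", "=================="]
        for region, stats in self.site_stats.items():
            div = self.divergence[region]
            lines.append(
                f"{region}: aligned {stats.aligned_length} bp, "
                f"variable {stats.variable}, PI "
                f"{stats.parsimony_informative}, interspecific K2P "
                f"{div.min:.2f}-{div.max_rounded:.2f} subst/site "
                f"({100 * div.min:.0f}-{100 * div.max_rounded:.0f}%)")
        lines.append("ranking by interspecific max: "
                     + " > ".join(self.ranking))
        lines.append(f"selected region: {self.selected_region}")
        for sp, mono in self.monophyly.items():
            lines.append(f"monophyly[{sp}]: {'yes' if mono else 'NO'}")
        return "\n".join(lines) + "\n"


def _partitions_for(records: Sequence[SequenceRecord],
                    probe: str | None,
                    partitions: Mapping[str, RegionPartition] | None,
                    ) -> dict[str, RegionPartition]:
    if partitions is not None:
        return dict(partitions)
    if probe is None:
        raise ValueError("either a 5.8S probe or explicit partitions "
                         "are required")
    return {rec.id: partition_its(rec, probe) for rec in records}


def evaluate_barcodes(records: Sequence[SequenceRecord],
                      sheet: Mapping[str, SampleInfo],
                      *, probe: str | None = None,
                      partitions: Mapping[str, RegionPartition] | None = None,
                      bootstrap_replicates: int = 1000,
                      seed: int = 0,
                      outgroup: str | None = None) -> BarcodeReport:
    """Compare the candidate barcode regions and verify the best by tree
    topology."""
    authentic = [r for r in records
                 if sheet.get(r.id, SampleInfo("", "commercial")).role
                 == "authentic"]
    species_of = {r.id: sheet[r.id].species for r in authentic}
    if len(set(species_of.values())) < 2:
        raise ValueError("barcode evaluation needs authentic samples of "
                         "at least 2 species")
    parts = _partitions_for(authentic, probe, partitions)
    aln = msa.progressive_msa(authentic)

    site_stats: dict[str, msa.SiteStats] = {}
    divergence: dict[str, phylo.DivergenceSummary] = {}
    region_alns: dict[str, msa.Alignment] = {}
    for region in REGIONS:
        label = REGION_LABELS[region]
        sub = msa.slice_region(aln, parts, region)
        region_alns[label] = sub
        site_stats[label] = msa.classify_sites(sub)
        dm = phylo.distance_matrix(sub)
        divergence[label] = phylo.divergence_summary(dm, species_of)
    ranking = sorted(divergence,
                     key=lambda r: (-divergence[r].max, r))
    selected = ranking[0]

    tree = None
    newick = None
    monophyly: dict[str, bool] = {}
    tree_records = list(authentic)
    if outgroup is not None:
        og = [r for r in records if r.id == outgroup]
        if not og:
            raise ValueError(f"outgroup {outgroup!r} not among the records")
        tree_records += og
    if len(tree_records) >= 3:
        tree_aln = msa.progressive_msa(tree_records)
        if selected != "ITS":
            # outgroups may lack a partition (no recognisable 5.8S): their
            # residues in the kept columns stand in for the region
            region_key = {v: k for k, v in REGION_LABELS.items()}[selected]
            tree_aln = msa.slice_region(tree_aln, parts, region_key,
                                        missing="keep")
        tree = phylo.bootstrap_support(tree_aln,
                                       replicates=bootstrap_replicates,
                                       seed=seed)
        newick = phylo.write_newick(tree)
        if outgroup is not None:
            for sp in sorted(set(species_of.values())):
                members = [i for i, s in species_of.items() if s == sp]
                monophyly[sp] = phylo.is_monophyletic(tree, members,
                                                      outgroup)
    return BarcodeReport(site_stats=site_stats, divergence=divergence,
                         ranking=ranking, selected_region=selected,
                         tree=tree, monophyly=monophyly, newick=newick)


def design_reference_panel(
        records: Sequence[SequenceRecord],
        sheet: Mapping[str, SampleInfo],
        templates: Mapping[str, SequenceRecord],
        *, probe: str | None = None,
        partitions: Mapping[str, RegionPartition] | None = None,
        constraints: primers.PrimerConstraints = primers.PrimerConstraints(),
        rules: pcr.BindingRules = pcr.BindingRules(),
        min_separation_bp: int = 30,
        max_tm_spread: float = 6.0,
        max_candidates_per_species: int = 12) -> primers.PrimerSet:
    """Design the species-specific multiplex panel from the references.

    The forward 5.8S anchor and universal 26S reverse are the published
    universal primers; one reverse primer per species is designed on the
    ITS2 sub-alignment.  Candidate combinations are tried in rank order
    until one satisfies the gel-separation and Tm-spread constraints.
    ``templates`` maps each species to one flanked reference template.
    """
    authentic = [r for r in records
                 if sheet.get(r.id, SampleInfo("", "commercial")).role
                 == "authentic"]
    species_of = {r.id: sheet[r.id].species for r in authentic}
    species = sorted(set(species_of.values()))
    parts = _partitions_for(authentic, probe, partitions)
    aln = msa.progressive_msa(authentic)
    its2 = msa.slice_region(aln, parts, "its2")

    per_species: dict[str, list[primers.PrimerCandidate]] = {}
    for sp in species:
        others = [s for s in species if s != sp]
        result = primers.design_species_primer(
            its2, sp, others, species_of, constraints)
        if not result.candidates:
            raise ValueError(
                f"no primer candidate for {sp}: {result.report}")
        # one candidate per 3'-anchor column: candidates sharing a column
        # give near-identical product sizes, so only distinct columns add
        # useful options to the band-separation search
        seen_cols: set[int] = set()
        diverse = []
        for cand in result.candidates:
            col = cand.target_interval[0]
            if col not in seen_cols:
                seen_cols.add(col)
                diverse.append(cand)
        per_species[sp] = diverse[:max_candidates_per_species]

    forward = primers.panel_primer("KSKITSF")
    universal = primers.panel_primer("ITS4")

    def combos():
        # breadth-first over rank indices: cheap combinations first
        max_rank = max(len(c) for c in per_species.values())
        for total in range(len(species) * (max_rank - 1) + 1):
            for idx in _compositions(total, len(species)):
                if all(i < len(per_species[sp])
                       for i, sp in zip(idx, species)):
                    yield {sp: per_species[sp][i]
                           for i, sp in zip(idx, species)}

    last_error: Exception | None = None
    for attempt, chosen in enumerate(combos()):
        if attempt >= 2000:
            break
        try:
            return primers.assemble_multiplex_set(
                forward, universal, chosen, templates,
                min_separation_bp=min_separation_bp,
                max_tm_spread=max_tm_spread, rules=rules)
        except ValueError as exc:
            last_error = exc
    raise ValueError(f"no primer combination satisfied the multiplex "
                     f"constraints; last failure: {last_error}")


def _compositions(total: int, parts: int):
    """All tuples of ``parts`` non-negative ints summing to ``total``."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first, *rest)


@dataclass
class IdentificationRow:
    sample: str
    molecular_status: str          # call status or "n/a"
    molecular_species: str | None
    hca_species: str | None        # species, "unresolved" or None ("n/a")
    verdict: str                   # concordant | discordant | molecular_only
                                   # | chemical_only | unidentified


@dataclass
class IdentificationReport:
    rows: list[IdentificationRow]
    panel: primers.PrimerSet | None
    gel_profiles: dict[str, pcr.GelProfile] = field(default_factory=dict)
    dendrogram: tlc.Dendrogram | None = None

    def to_tsv(self) -> str:
        lines = ["sample\tmolecular_status\tmolecular_species\t"
                 "hca_species\tverdict"]
        for r in self.rows:
            lines.append(f"{r.sample}\t{r.molecular_status}\t"
                         f"{r.molecular_species or '-'}\t"
                         f"{r.hca_species or '-'}\t{r.verdict}")
        return "\n".join(lines) + "\n"


def identify(unknown_templates: Sequence[SequenceRecord] | None = None,
             panel: primers.PrimerSet | None = None,
             band_matrix: tlc.FingerprintMatrix | None = None,
             fingerprint_references: Mapping[str, str] | None = None,
             *, rules: pcr.BindingRules = pcr.BindingRules(),
             tolerance_bp: int = 10,
             hca_metric: str = "jaccard",
             hca_linkage: str = "average") -> IdentificationReport:
    """Identify unknown samples by the molecular and/or chemical route."""
    molecular_available = unknown_templates is not None and panel is not None
    chemical_available = (band_matrix is not None
                          and fingerprint_references is not None)
    if not molecular_available and not chemical_available:
        raise ValueError("no identification route available: need a primer "
                         "panel with templates and/or a band matrix with "
                         "references")

    profiles: dict[str, pcr.GelProfile] = {}
    molecular: dict[str, pcr.SpeciesCall] = {}
    if molecular_available:
        for rec in unknown_templates:
            profile = pcr.simulate_multiplex(rec, panel, rules)
            profile.call = pcr.call_species(
                profile, panel.expected_amplicons, tolerance_bp)
            profiles[rec.id] = profile
            molecular[rec.id] = profile.call

    chemical: dict[str, str] = {}
    dend = None
    if chemical_available:
        dm = tlc.binary_distance(band_matrix, hca_metric)
        dend = tlc.hcluster(dm, hca_linkage)
        for call in tlc.assign_by_cluster(dend, fingerprint_references):
            chemical[call.sample] = call.species

    rows = []
    for sample in sorted(set(molecular) | set(chemical)):
        mol = molecular.get(sample)
        mol_status = mol.status if mol else "n/a"
        mol_species = mol.species if mol else None
        hca_species = chemical.get(sample)
        if mol and mol.species and hca_species not in (None, "unresolved"):
            verdict = ("concordant" if mol.species == hca_species
                       else "discordant")
        elif mol and mol.species:
            verdict = "molecular_only"
        elif hca_species not in (None, "unresolved"):
            verdict = "chemical_only"
        else:
            verdict = "unidentified"
        rows.append(IdentificationRow(
            sample=sample, molecular_status=mol_status,
            molecular_species=mol_species, hca_species=hca_species,
            verdict=verdict))
    return IdentificationReport(rows=rows, panel=panel,
                                gel_profiles=profiles, dendrogram=dend)
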