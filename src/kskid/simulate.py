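"""Seeded synthetic datasets with known truth.

The generator emulates the structure of a three-species crude-drug
reference study: a conserved 5.8S gene flanked by two fast-evolving
spacers (ITS1, ITS2), three species radiating from a common ancestor with
deep interspecific divergence in the spacers, shallow intraspecific
variation (a few SNP columns per species, some of them IUPAC
heterozygotes, one species carrying an indel), flanked PCR templates with
18S/26S segments carrying the universal priming sites, congener
negative-control lineages, and species-signature TLC band matrices with
flip noise.

Every output is a deterministic function of the configuration (including
its seed); a truth manifest records species, haplotype, region boundaries
and planted variants so that every downstream stage can be scored without
external data.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .primers import (AMBIGUITY_OF_PAIR, ITS5S_SEQUENCE, MULTIPLEX_PANEL,
                      reverse_complement)
from .records import RegionPartition, SampleInfo, SequenceRecord, write_fasta
from .tlc import FingerprintMatrix

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the reference study design: three species sampled
    13/8/4, ITS1 ~ U[217, 262] bp, 5.8S fixed at 160 bp, ITS2 ~ U[219,
    223] bp, deep interspecific spacer divergence with a 2:1
    transition:transversion ratio (so the K2P model is the matched
    estimator), a nearly conserved 5.8S, three intraspecific variant
    columns per species with heterozygote probability 0.5, and an indel
    allowed in the second species' variant columns.
    """

    seed: int = 0
    species_codes: tuple[str, ...] = ("BA", "SA", "ZA")
    species_names: tuple[str, ...] = (
        "Betula_alnoides", "Strychnos_axillaris", "Ziziphus_attopensis")
    samples_per_species: tuple[int, ...] = (13, 8, 4)
    its1_length_range: tuple[int, int] = (217, 262)
    r5_8s_length: int = 160
    its2_length_range: tuple[int, int] = (219, 223)
    flank_18s_length: int = 60
    flank_26s_length: int = 220
    rate_its: float = 0.25
    rate_5_8s: float = 0.01
    congener_rate: float = 0.35
    n_intraspecific_snps: int = 3
    het_probability: float = 0.5
    indel_species_index: int = 1
    indel_probability: float = 1.0 / 3.0
    bands_per_species: tuple[int, int] = (6, 12)
    n_rf_bins: int = 100
    shared_band_fraction: float = 0.3
    flip_noise: float = 0.02
    anchor_offset: int = 60
    universal_site_end: int = 94

    def __post_init__(self) -> None:
        if len(self.species_codes) != len(self.samples_per_species):
            raise ValueError("species_codes and samples_per_species must "
                             "be parallel")
        for name in ("rate_its", "rate_5_8s", "congener_rate",
                     "het_probability", "indel_probability",
                     "shared_band_fraction", "flip_noise"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} must be a probability in [0,1]")
        for name in ("r5_8s_length", "flank_18s_length", "flank_26s_length",
                     "n_rf_bins"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # two lineages mutated independently at rate r sit ~2r expected
        # substitutions/site apart; beyond ~0.75 the K2P log terms start
        # collapsing on short regions
        for r in (self.rate_its, self.congener_rate):
            p_diff = 2.0 * r
            if p_diff > 0.75:
                raise ValueError(
                    f"substitution rate {r} implies expected pairwise "
                    f"differences {p_diff:.2f} > 0.75 of sites (saturated)")
        if not (0 <= self.anchor_offset
                <= self.r5_8s_length - len(MULTIPLEX_PANEL["KSKITSF"][1])):
            raise ValueError("anchor_offset places the forward-anchor site "
                             "outside the 5.8S gene")
        if self.universal_site_end > self.flank_26s_length:
            raise ValueError("universal reverse site beyond the 26S flank")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            protected: frozenset[int] = frozenset()) -> str:
    """Per-site substitution at the given rate with transition:transversion
    ratio 2:1; ``protected`` positions never change."""
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        if int(i) in protected:
            continue
        base = out[i]
        if base not in _TRANSITION:
            continue
        if rng.random() < 2.0 / 3.0:
            out[i] = _TRANSITION[base]
        else:
            out[i] = _TRANSVERSIONS[base][int(rng.integers(2))]
    return "".join(out)


def _delete_to_length(rng: np.random.Generator, seq: str,
                      target: int) -> str:
    if target > len(seq):
        raise ValueError("cannot grow a sequence by deletion")
    drop = set(rng.choice(len(seq), size=len(seq) - target, replace=False))
    return "".join(ch for i, ch in enumerate(seq) if i not in drop)


@dataclass(frozen=True)
class PlantedVariant:
    species: str
    position: int        # 0-based on the species base ITS sequence
    kind: str            # substitution | indel
    ref: str
    carrier_state: str   # alt base, IUPAC heterozygote code, or "-"
    carriers: tuple[str, ...]


@dataclass
class ReferenceDataset:
    """Everything the downstream pipeline needs, plus the ground truth."""

    config: SimulationConfig
    records: list[SequenceRecord]            # ITS sequences
    templates: list[SequenceRecord]          # 18S-flank + ITS + 26S-flank
    sample_sheet: dict[str, SampleInfo]
    partitions: dict[str, RegionPartition]   # truth boundaries (ITS coords)
    r5_8s_reference: str                     # the probe a user would supply
    variants: list[PlantedVariant]
    manifest: dict

    def species_of(self) -> dict[str, str]:
        return {sid: info.species for sid, info in self.sample_sheet.items()}

    def template_of(self) -> dict[str, SequenceRecord]:
        return {t.id: t for t in self.templates}


def _species_ancestors(cfg: SimulationConfig, rng: np.random.Generator):
    """Ancestral regions and flanks shared by all lineages."""
    anchor_seq = MULTIPLEX_PANEL["KSKITSF"][1]
    its1_anc = _random_seq(rng, cfg.its1_length_range[1])
    its2_anc = _random_seq(rng, cfg.its2_length_range[1])
    r58 = list(_random_seq(rng, cfg.r5_8s_length))
    r58[cfg.anchor_offset:cfg.anchor_offset + len(anchor_seq)] = anchor_seq
    r58_anc = "".join(r58)
    protected = frozenset(range(cfg.anchor_offset,
                                cfg.anchor_offset + len(anchor_seq)))
    flank18 = ITS5S_SEQUENCE + _random_seq(
        rng, cfg.flank_18s_length - len(ITS5S_SEQUENCE))
    uni_site = reverse_complement(MULTIPLEX_PANEL["ITS4"][1])
    f26 = list(_random_seq(rng, cfg.flank_26s_length))
    f26[cfg.universal_site_end - len(uni_site):cfg.universal_site_end] = uni_site
    flank26 = "".join(f26)
    return its1_anc, r58_anc, its2_anc, protected, flank18, flank26


def _species_lineage(cfg: SimulationConfig, rng: np.random.Generator,
                     ancestors, rate_its: float) -> tuple[str, str, str]:
    """Derive one lineage's (its1, 5.8S, its2) from the ancestors."""
    its1_anc, r58_anc, its2_anc, protected, _, _ = ancestors
    its1 = _mutate(rng, its1_anc, rate_its)
    its1 = _delete_to_length(
        rng, its1, int(rng.integers(cfg.its1_length_range[0],
                                    cfg.its1_length_range[1] + 1)))
    its2 = _mutate(rng, its2_anc, rate_its)
    its2 = _delete_to_length(
        rng, its2, int(rng.integers(cfg.its2_length_range[0],
                                    cfg.its2_length_range[1] + 1)))
    r58 = _mutate(rng, r58_anc, cfg.rate_5_8s, protected)
    return its1, r58, its2


def simulate_reference_set(config: SimulationConfig) -> ReferenceDataset:
    """Generate the authentic reference panel with its truth manifest."""
    cfg = config
    rng = np.random.default_rng([cfg.seed, 0])
    ancestors = _species_ancestors(cfg, rng)
    _, _, _, _, flank18, flank26 = ancestors

    records: list[SequenceRecord] = []
    templates: list[SequenceRecord] = []
    sheet: dict[str, SampleInfo] = {}
    partitions: dict[str, RegionPartition] = {}
    variants: list[PlantedVariant] = []
    manifest_samples: dict[str, dict] = {}

    for s_idx, (code, name, n_samples) in enumerate(zip(
            cfg.species_codes, cfg.species_names, cfg.samples_per_species)):
        its1, r58, its2 = _species_lineage(cfg, rng, ancestors, cfg.rate_its)
        base = its1 + r58 + its2
        len1, len58 = len(its1), len(r58)
        sample_ids = [f"{code}{i + 1}" for i in range(n_samples)]

        # plant intraspecific variant columns in the spacers only (the 5.8S
        # stays near-invariant, as in real rDNA)
        spacer_positions = (list(range(len1))
                            + list(range(len1 + len58, len(base))))
        sp_variants: list[PlantedVariant] = []
        if n_samples >= 2 and cfg.n_intraspecific_snps > 0:
            chosen = sorted(rng.choice(spacer_positions,
                                       size=cfg.n_intraspecific_snps,
                                       replace=False).tolist())
            for pos in chosen:
                ref = base[pos]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                is_indel = (s_idx == cfg.indel_species_index
                            and rng.random() < cfg.indel_probability)
                if is_indel:
                    state = "-"
                elif rng.random() < cfg.het_probability:
                    state = AMBIGUITY_OF_PAIR[frozenset((ref, alt))]
                else:
                    state = alt
                n_carriers = int(rng.integers(1, n_samples))
                carriers = tuple(sorted(
                    rng.choice(sample_ids, size=n_carriers,
                               replace=False).tolist()))
                sp_variants.append(PlantedVariant(
                    species=code, position=int(pos),
                    kind="indel" if is_indel else "substitution",
                    ref=ref, carrier_state=state, carriers=carriers))
        variants.extend(sp_variants)

        signatures: dict[str, tuple[str, ...]] = {}
        for sid in sample_ids:
            chars = list(base)
            deletions_before_58 = 0
            sig = []
            for var in sp_variants:
                carried = sid in var.carriers
                sig.append(var.carrier_state if carried else var.ref)
                if carried:
                    chars[var.position] = var.carrier_state
                    if var.kind == "indel" and var.position < len1:
                        deletions_before_58 += 1
            seq = "".join(ch for ch in chars if ch != "-")
            signatures[sid] = tuple(sig)
            its1_end = len1 - deletions_before_58
            r58_end = its1_end + len58
            partitions[sid] = RegionPartition(
                its1=(0, its1_end), r5_8s=(its1_end, r58_end),
                its2=(r58_end, len(seq)))
            records.append(SequenceRecord(
                id=sid, residues=seq, species=name, role="authentic"))
            templates.append(SequenceRecord(
                id=sid, residues=flank18 + seq + flank26, species=name,
                role="authentic"))
            sheet[sid] = SampleInfo(species=name, role="authentic")

        hap_ids: dict[tuple[str, ...], int] = {}
        for sid in sample_ids:
            hap_ids.setdefault(signatures[sid], len(hap_ids) + 1)
        for sid in sample_ids:
            part = partitions[sid]
            internal_bp = ((cfg.r5_8s_length - cfg.anchor_offset)
                           + (part.its2[1] - part.its2[0])
                           + cfg.universal_site_end)
            manifest_samples[sid] = {
                "species_code": code, "species": name,
                "haplotype": hap_ids[signatures[sid]],
                "its1_end": part.its1[1], "r5_8s_end": part.r5_8s[1],
                "its_length": part.length,
                "internal_control_bp": internal_bp,
            }

    manifest = {
        "config": asdict(cfg),
        "samples": manifest_samples,
        "haplotype_counts": {
            code: max(manifest_samples[sid]["haplotype"]
                      for sid in manifest_samples
                      if manifest_samples[sid]["species_code"] == code)
            for code in cfg.species_codes
        },
        "variants": [asdict(v) for v in variants],
        "anchor_offset": cfg.anchor_offset,
        "universal_site_end": cfg.universal_site_end,
    }
    return ReferenceDataset(
        config=cfg, records=records, templates=templates, sample_sheet=sheet,
        partitions=partitions, r5_8s_reference=ancestors[1],
        variants=variants, manifest=manifest)


def simulate_crude_drug_samples(
        config: SimulationConfig, dataset: ReferenceDataset,
        truth_species: Sequence[str] = ("BA", "BA", "ZA", "ZA", "ZA"),
        degradation: int | None = None,
) -> tuple[list[SequenceRecord], dict]:
    """Market-sample templates with hidden truth.

    Each entry of ``truth_species`` is a species code from the reference
    set or ``"congener"`` (an extra lineage splitting from the ancestor
    before the species radiation — the analogue of a confamilial
    adulterant).  ``degradation`` truncates each template to a random
    fragment of at most that many bp, emulating degraded crude-drug DNA.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 1])
    ancestors = _species_ancestors(cfg, np.random.default_rng([cfg.seed, 0]))
    _, _, _, _, flank18, flank26 = ancestors
    congener = None
    by_species: dict[str, list[SequenceRecord]] = {}
    for t in dataset.templates:
        code = dataset.manifest["samples"][t.id]["species_code"]
        by_species.setdefault(code, []).append(t)

    out: list[SequenceRecord] = []
    truth: dict[str, dict] = {}
    longest_expected = max(
        info["internal_control_bp"]
        for info in dataset.manifest["samples"].values())
    for i, sp in enumerate(truth_species):
        sid = f"CK{i + 1}"
        if sp == "congener":
            if congener is None:
                its1, r58, its2 = _species_lineage(
                    cfg, rng, ancestors, cfg.congener_rate)
                congener = flank18 + its1 + r58 + its2 + flank26
            seq = congener
            source = "congener"
        else:
            if sp not in by_species:
                raise ValueError(f"unknown species code {sp!r}")
            donor = by_species[sp][int(rng.integers(len(by_species[sp])))]
            seq = donor.residues
            source = donor.id
        warning = None
        if degradation is not None and degradation < len(seq):
            start = int(rng.integers(0, len(seq) - degradation + 1))
            seq = seq[start:start + degradation]
            if degradation < longest_expected:
                warning = ("fragment shorter than the longest expected "
                           "amplicon; amplification_failure expected")
                warnings.warn(f"{sid}: {warning}")
        out.append(SequenceRecord(id=sid, residues=seq, role="commercial"))
        truth[sid] = {"species": sp, "source": source, "warning": warning}
    return out, {"samples": truth}


def simulate_fingerprints(
        config: SimulationConfig,
        species_of: Mapping[str, str],
) -> tuple[FingerprintMatrix, dict]:
    """TLC band matrix for the given samples (id -> species code).

    Each species gets a signature band set on a 100-bin Rf grid: a block
    of bands shared across species (common phytochemistry) plus
    species-specific bands; per-sample cells are the signature XOR
    independent flip noise.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 2])
    species = sorted(set(species_of.values()))
    lo, hi = cfg.bands_per_species
    n_shared = int(round(cfg.shared_band_fraction * (lo + hi) / 2.0))
    pool = list(rng.permutation(cfg.n_rf_bins))
    shared = pool[:n_shared]
    pool = pool[n_shared:]
    signatures: dict[str, np.ndarray] = {}
    for sp in species:
        n_bands = int(rng.integers(lo, hi + 1))
        own = max(n_bands - n_shared, 1)
        bands = shared + pool[:own]
        pool = pool[own:]
        sig = np.zeros(cfg.n_rf_bins, dtype=int)
        sig[np.array(bands, dtype=int)] = 1
        signatures[sp] = sig
    sample_ids = list(species_of)
    cells = np.zeros((len(sample_ids), cfg.n_rf_bins), dtype=int)
    for r, sid in enumerate(sample_ids):
        flips = rng.random(cfg.n_rf_bins) < cfg.flip_noise
        cells[r] = np.logical_xor(signatures[species_of[sid]], flips)
    rf = np.round((np.arange(cfg.n_rf_bins) + 1) / (cfg.n_rf_bins + 1), 4)
    matrix = FingerprintMatrix(sample_ids=sample_ids, rf_bins=rf,
                               cells=cells)
    truth = {"signatures": {sp: signatures[sp].tolist() for sp in species},
             "species_of": dict(species_of)}
    return matrix, truth


def write_dataset(dataset: ReferenceDataset, outdir: str | Path,
                  *, force: bool = False) -> None:
    """Write the full synthetic dataset (FASTA, sheet, probe, manifest)."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty "
                              "(use force to overwrite)")
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(dataset.records, outdir / "its.fasta")
    write_fasta(dataset.templates, outdir / "templates.fasta")
    probe = SequenceRecord(id="r5_8s_reference",
                           residues=dataset.r5_8s_reference,
                           role="authentic")
    write_fasta([probe], outdir / "probe_5_8s.fasta")
    with open(outdir / "samples.tsv", "w") as fh:
        fh.write("id\tspecies\trole\taccession\n")
        for sid, info in dataset.sample_sheet.items():
            fh.write(f"{sid}\t{info.species}\t{info.role}\t"
                     f"{info.accession or ''}\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(dataset.manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def dataset_checksum(outdir: str | Path) -> str:
    """SHA-256 over the sorted file contents of a dataset directory."""
    h = hashlib.sha256()
    for path in sorted(Path(outdir).iterdir()):
        h.update(path.name.encode())
        h.update(path.read_bytes())
    return h.hexdigest()
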