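# kskid

Authentication toolkit for **Kamlang Suea Khrong (KSK)**, a Thai herbal
crude drug traded under one vernacular name but derived from three
different plants: *Betula alnoides* (BA, inner stem bark), *Strychnos
axillaris* (SA, stems) and *Ziziphus attopensis* (ZA, stems).  The three
materials are organoleptically near-indistinguishable, yet *S. axillaris*
contains strychnine-type alkaloids — so the botanical origin of market
samples matters for safety.  `kskid` implements the combined molecular +
chemical identification workflow as a reusable, tested pipeline:

1. **DNA-barcode evaluation** — align authentic nuclear ribosomal ITS
   sequences, partition them into ITS1 / 5.8S / ITS2, classify alignment
   sites (conserved / variable / parsimony-informative / singleton),
   compare the candidate barcode regions by interspecific Kimura
   2-parameter (K2P) divergence, and verify the best region by a
   neighbor-joining (NJ) bootstrap tree with per-species monophyly checks.
2. **Species-specific multiplex PCR, in silico** — design one reverse
   primer per species whose 3′ terminus sits on an ITS2 site diagnostic
   for that species, combine them with a conserved 5.8S forward anchor
   and the universal 26S reverse primer (internal control), predict
   amplicon sizes, simulate the multiplex reaction on unknown templates,
   and call species from the virtual gel band pattern.
3. **TLC-fingerprint clustering** — hierarchically cluster binary
   thin-layer-chromatography band matrices (samples × Rf bins) and assign
   unknowns to the species of their species-pure reference cluster.
4. **Synthetic data with ground truth** — a seeded generator emulating
   the full study design (sample counts, region lengths, divergence
   structure, IUPAC heterozygous haplotypes, indels, flanked PCR
   templates, congener negatives, noisy fingerprints) so every stage can
   be validated end-to-end without wet-lab data.

## The models at the core

**K2P distance.** With transition proportion *P* (A↔G, C↔T) and
transversion proportion *Q* over pairwise-comparable sites,

    d = −½ · ln((1 − 2P − Q) · √(1 − 2Q))   [substitutions/site]

Columns where either row carries a gap or IUPAC ambiguity code are
skipped per pair (pairwise deletion).

**Neighbor joining.** Saitou–Nei agglomeration with the Studier–Keppler
criterion Q(i,j) = (n−2)·d(i,j) − Σₖd(i,k) − Σₖd(j,k), deterministic
lexicographic tie-breaking, negative branch lengths clamped to zero, and
bootstrap supports (% of column-resampled replicates containing each
original-tree bipartition).

**Species-specific priming.** A site is discriminating for a target
species when all target rows share one unambiguous base and every other
row differs.  Candidate reverse primers anchor their 3′ end on such a
site (mismatch-at-3′ aborts extension), then pass length (17–25 nt), GC
(40–60 %) and Tm filters.  Melting temperatures use nearest-neighbor
thermodynamics (SantaLucia 1997 unified parameters, Owczarzy 2004 salt
correction) under a calibrated condition set (50 mM Na⁺, 120 nM oligo)
that reproduces the published panel's Tm column within 0.07 °C; see
`scripts/calibrate_tm.py`.

**Fingerprint clustering.** Jaccard distance on band-presence sets
(simple matching optional) with single / complete / average (default)
Lance–Williams agglomeration; an unknown inherits a species only from a
species-pure reference cluster.

## Worked example

Generate a synthetic study (25 authentic references of 3 species, 5
market samples) and run the pipeline:

```sh
kskid simulate --seed 1 --out demo/data
kskid evaluate-barcodes --seed 1 --out demo/eval \
    --fasta demo/data/its.fasta --sheet demo/data/samples.tsv \
    --probe demo/data/probe_5_8s.fasta
```

prints:

```
Barcode evaluation
==================
ITS: aligned 691 bp, variable 214, PI 213, interspecific K2P 0.24-0.33 subst/site (24-33%)
ITS1: aligned 294 bp, variable 101, PI 101, interspecific K2P 0.28-0.42 subst/site (28-42%)
ITS2: aligned 237 bp, variable 110, PI 109, interspecific K2P 0.43-0.60 subst/site (43-60%)
ranking by interspecific max: ITS2 > ITS1 > ITS
selected region: ITS2
```

The short ITS2 spacer shows the widest interspecific K2P range, so it is
selected for primer design — the same ordering the real reference data
shows.  Designing the panel and typing the unknowns:

```sh
kskid design-primers --seed 1 --out demo/primers \
    --fasta demo/data/its.fasta --sheet demo/data/samples.tsv \
    --probe demo/data/probe_5_8s.fasta --templates demo/data/templates.fasta
kskid insilico-pcr --seed 1 --out demo/pcr \
    --templates demo/data/unknowns.fasta --panel demo/primers
```

```
sample  status      species              evidence
CK1     identified  Betula_alnoides      internal~415bp (Betula_alnoides);Betula_alnoides~242bp
CK2     identified  Betula_alnoides      internal~415bp (Betula_alnoides);Betula_alnoides~242bp
CK3     identified  Ziziphus_attopensis  internal~415bp (Betula_alnoides);Ziziphus_attopensis~192bp
...
```

Each lane shows the ~415 bp internal-control band (proving amplifiable
plant DNA) plus one shorter species band; a congener negative control
shows the internal control only (`negative_control_pattern`), and a
template with no internal-control band is an `amplification_failure`.
`kskid tlc-cluster` and `kskid identify` run the chemical route and the
combined two-route report with per-sample concordance flags.

## Layout

- `src/kskid/records.py` — FASTA / sample-sheet I/O, ITS partitioning
- `src/kskid/msa.py` — pairwise + progressive alignment, region slicing, site stats
- `src/kskid/phylo.py` — K2P, NJ, bootstrap, monophyly, Newick
- `src/kskid/haplotypes.py` — IUPAC-aware variant calling and haplotypes
- `src/kskid/primers.py` — discriminating sites, primer design, Tm/GC, panel assembly
- `src/kskid/pcr.py` — binding sites, multiplex simulation, gel calls
- `src/kskid/tlc.py` — band matrices, binary distances, HCA, cluster calls
- `src/kskid/simulate.py` — seeded synthetic datasets with truth manifests
- `src/kskid/pipeline.py`, `cli.py`, `config.py` — orchestration and CLI

See `docs/methods.md` for the modelling decisions and their rationale.
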