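# Methods

This note records the models, parameter choices and numerical
conventions behind `kskid`, and what the synthetic validation does and
does not demonstrate.

## Sequence model and region partitioning

The unit of analysis is the nuclear ribosomal ITS region: a fast-evolving
ITS1 spacer, the conserved 5.8S gene, and a fast-evolving ITS2 spacer.
Deposited ITS sequences rarely carry annotated region boundaries, and no
universal rule exists for delimiting them, so the partition is recovered
operationally: a user-supplied conserved 5.8S core ("probe", ≥ 50 nt) is
placed by best local alignment (match +1, mismatch −1, gap open −2,
extend −0.5); the matched span becomes 5.8S and the flanks become
ITS1/ITS2.  A placement below 70 % probe identity, or one touching a
sequence end (an empty spacer), is an error rather than a guess.  An
override TSV with explicit per-record coordinates bypasses the probe
entirely.  Coordinates are 0-based half-open internally; every
user-facing report converts to 1-based positions.

## Alignment

The multiple alignment is a deterministic progressive procedure: the
longest sequence anchors; remaining sequences join in order of
descending global-alignment score to the anchor (ties by id); each joins
by global alignment against the running majority consensus, with
consensus gap columns propagated into all existing rows ("once a gap,
always a gap").  The pairwise kernel is affine global alignment
(+1/−1/−2/−0.5) with deterministic tie-breaking among co-optimal
alignments.  This is intentionally simple: reference panels here are
small (tens of sequences) and intraspecific divergence shallow, and an
externally produced aligned FASTA can be ingested verbatim when users
prefer a hand-edited alignment.

**Site classification.** Per column, only unambiguous A/C/G/T states
count; a row showing a gap or IUPAC ambiguity at a column is excluded
for that column only (sitewise deletion).  A column with ≥ 2 countable
rows is conserved (one state) or variable (≥ 2 states);
parsimony-informative needs ≥ 2 states each in ≥ 2 rows; singleton is
the remainder, so PI + singleton = variable holds by construction.
Treating ambiguity codes as missing follows the convention of standard
barcode software and keeps the counts well defined.

**Region slicing.** Because per-row region boundaries can map to
different alignment columns, the slice takes the union of columns
holding any row's region residues and masks a row's out-of-region
residues to gaps, so each sliced row ungaps exactly to its region
substring.  Rows without a partition (outgroups with no recognisable
5.8S) can optionally be kept unmasked.

## Distances and trees

K2P distances use pairwise deletion by default — robust to the known
intraspecific indel and standard for barcode gap handling; complete
deletion is available.  Saturated pairs (log of a non-positive number)
are reported and excluded from summaries rather than silently clamped.
Distances are reported in substitutions/site; percentage labels in
reports print both scales.

NJ uses the Studier–Keppler criterion with ties broken by the
lexicographically smallest id pair (clusters represented by their
smallest member id), so the topology is reproducible; negative branch
lengths are clamped at zero unless disabled.  Bootstrap supports are
mapped onto the original tree's bipartitions (not a consensus tree):
each internal branch's support is the percentage of successful
column-resampled replicates containing the same bipartition; replicates
with saturated or incomplete matrices are skipped and counted.  The
default replicate count is 1000; the tests use 100 or fewer, which is
ample for the deep, clean divergences they assert on.  Monophyly of a
leaf set is evaluated on the tree rooted at the outgroup: the set must
be exactly one side of some branch.

## Haplotypes

Within a species, every alignment column with any state difference among
members — base, IUPAC code, or gap-versus-base — is a variant position,
labelled substitution or indel.  Heterozygous-style ambiguity codes from
direct sequencing (R/Y/W) are **distinct fifth states**, never expanded:
the published variation tables distinguish a T haplotype from a Y
haplotype at the same position, which forces literal comparison.
Haplotypes are groups with identical state vectors; ids follow first
occurrence.  Positions are reported on the species alignment (1-based)
with a parallel mapping onto each member's ungapped coordinates, since
the coordinate system of printed variation tables is ambiguous.

## Primer design and in-silico PCR

The multiplex panel follows the internal-control design: conserved 5.8S
forward anchor + universal 26S reverse amplify from any plant template
(distinguishing "none of the reference species" from "failed PCR"),
while per-species ITS2 reverse primers anchor their 3′ terminus on a
discriminating site.  The anchor and universal reverse default to the
published universal rDNA primers; the species primers are designed by
enumeration and ranking, operationalising the classical manual criteria:
length 17–25 nt, GC 40–60 %, Tm 48–58 °C with a 52 °C set target,
3′-window 5 nt, ≥ 1 mismatch against every non-target taxon inside the
3′ window, ≤ 6 °C Tm spread across the panel (the published panel spans
5.16 °C).  Windows containing target-internal variation, gaps or
ambiguity codes are disqualified (no degenerate synthesis).  Panel
assembly verifies, by in-silico PCR on one template per species, that
every species band is ≥ 30 bp from the internal control and from every
other species band (gel resolvability); the combination search tries
candidate sets in rank order, keeping one candidate per 3′ column since
same-column candidates give near-identical product sizes.

**Tm model.** The published primer table prints Tm values without
stating the model.  `scripts/calibrate_tm.py` grid-searches
nearest-neighbor parameter tables, salt-correction methods and solution
conditions; the SantaLucia 1997 unified table with the Owczarzy 2004
correction at 50 mM Na⁺ / 120 nM oligo reproduces all five printed
values within 0.07 °C and is frozen as the default condition set.  The
Wallace 2(A+T)+4(G+C) rule is retained as a secondary method.

**Binding and calling rules.** A site qualifies with ≤ 2 total
mismatches and 0 mismatches in the 3′-terminal 3 nt (template N
mismatches everything); both strands are scanned.  Products pair any
plus-strand site with any minus-strand site downstream, capped at
2000 bp.  Gel reading uses ± 10 bp tolerance: internal control matched →
exactly one species band = identified, none = negative-control pattern,
several = ambiguous; no internal control = amplification failure.  The
mismatch and tolerance values are not derivable from wet-lab gels, so
they are explicit configuration echoed into every report.  No
amplification-efficiency or concentration modelling is attempted —
presence/absence only, matching qualitative gel reading.

## TLC fingerprints

The chemical route consumes a pre-binned binary matrix (samples × Rf
values in [0, 1]); Rf binning of raw chromatograms is out of scope.  The
default distance is Jaccard — band presence is the informative signal in
sparse fingerprints — with simple matching available; the default
linkage is average, with complete and single provided (the linkage
behind published dendrograms is typically unstated, so topology, not
heights, is the comparable output).  Agglomeration uses Lance–Williams
updates with exact-tie breaking by smallest member id.  Assignment cuts
the dendrogram into k clusters (default: the number of reference
species); an unknown inherits a species only from a species-pure
reference cluster, otherwise it is unresolved.

## Synthetic data: what it emulates

The generator mirrors the reference study design: 3 species sampled
13/8/4; ITS1 ~ U[217, 262] bp, 5.8S fixed 160 bp, ITS2 ~ U[219, 223] bp
(total ITS ≈ 596–645 bp); spacers diverging from a common ancestor at
0.25 substitutions/site per lineage (interspecific K2P maxima ≈ 0.4–0.7
on ITS2) with a 2:1 transition:transversion ratio, making K2P the
matched estimator; 5.8S at 0.01 with an invariant 18 nt anchor window
(universal priming sites are invariant in real rDNA, and both flanks are
fully conserved for the same reason); per-species length differences
realised as deletions from the ancestral spacers; 3 intraspecific
variant columns per species in the spacers, heterozygote probability
0.5 written directly as IUPAC codes, with the second species' variants
eligible to be indels (probability 1/3 each).  Templates append a 60 bp
18S flank (carrying the universal ITS forward site) and a 220 bp 26S
flank whose universal reverse site ends 94 nt in, fixing internal-control
products at 413–417 bp.  The congener negative is an extra lineage from
the same ancestor at rate 0.35.  Fingerprints give each species 6–12
bands on a 100-bin Rf grid, ~30 % drawn from a shared pool, with
per-cell flip noise 0.02 — chosen once as realistic band-calling
reproducibility for derivatised TLC plates.

What passing synthetic tests do **not** show: performance on real
degraded crude-drug DNA (no sequencing error, chimeras or fungal
contamination is modelled), indel evolution beyond single-column events,
chemotype variation within species (one signature per species plus
noise), or the behaviour of the probe partitioner on 5.8S variants more
diverged than the simulated 1 %.

## Determinism and problem sizes

Every stochastic step consumes a NumPy `default_rng` seeded from the
configuration (child streams `[seed, k]` per stage), and datasets
re-generated from the same seed are byte-identical.  Tests run the full
two-route study at its native size (25 references, 7 unknowns) over 20
seeds, bootstrap at 100 replicates, and the NJ/HCA oracles at 4–10 taxa
— sizes at which the brute-force oracles are exact and the suite stays
interactive.
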