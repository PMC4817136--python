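# Methods

This note documents the models, conventions and design choices behind
`intronmark`, in the order the pipeline runs them.

## Gene models and introns

Internal coordinates are 0-based half-open everywhere; emitted tables are
1-based inclusive (GFF3 convention). One transcript represents each gene
locus: the mRNA with the longest summed CDS, falling back to the longest
span. Alternative splice forms are collapsed deliberately — the markers are
anchored at the gene-locus level and an intron shared by several isoforms
should be designed once. Transposable-element association is inferred by a
case-insensitive match of "transposon"/"retrotransposon" in the gene or mRNA
`Note`/`Name` attributes; annotations carry no more structured signal.

Intron *i* occupies the gap between exon *i* and exon *i+1* in transcription
order, so for minus-strand genes the genomically rightmost gap is ordinal 1
and all reported sequences (intron, flanks) are reverse-complemented onto
the coding strand. Flank windows are `min(100, exon length)` bases — never
crossing into a neighboring intron. Introns or flanks containing N are kept
but flagged; primer design refuses windows with N. Zero-length gaps
(abutting exons) are skipped with a warning.

## Primer design

The forward primer is a window of the left flank, the reverse primer the
reverse complement of a window of the right flank, so every accepted pair
spans the target intron and `genomic_product − cdna_product = intron length`
holds by construction (the cross-module identity the test suite leans on).

Melting temperature: unified SantaLucia (1998) nearest-neighbor
thermodynamics,

    Tm = 1000·ΔH / (ΔS + 0.368·(N−1)·ln[Na+] + R·ln(C/4)) − 273.15

with ΔH/ΔS summed over propagation steps plus terminal A·T / G·C initiation
terms, [Na+] = 50 mM and C = 0.25 µM primer by default. The constants are
module-level data (`NN_DH_DS`, `INIT_AT`, `INIT_GC`) so tests can recompute
the sum by hand; the suite also cross-checks against Biopython's independent
implementation of the same table.

Hard constraints (defaults): length 18/20/27, Tm 57/60/63 °C, GC 40–60%,
homopolymer runs ≤ 4, no perfect self-complementary ≥ 8-mer (a cheap
hairpin/self-dimer proxy; a full thermodynamic dimer model is out of scope),
genomic product 100–1000 bp. The product window brackets the few-hundred-bp
products typical of intron-spanning assays; runs on the simulator use
100–2500 bp to match its 60–2000 bp intron length range (below). Expression
mode additionally requires the spliced product to be 60–100 bp so genomic
and cDNA amplicons are trivially distinguishable.

Ranking penalty (lower is better):

    penalty = Σ_primers [ w_tm·|Tm−60| + w_len·|len−20| + w_gc·dist(GC, [40,60])
              + w_end·max(0, 3'-homopolymer − 2) ] + w_Δ·|Tm_f − Tm_r|

with default weights (1, 0.5, 0.5, 0.5, 1). It is additive and strictly
monotone in each deviation (property-tested); it does not reproduce
Primer3's objective to the decimal and does not try to.

Per-gene selection keeps at most *k* markers (default 4), preferring
distinct introns first, then penalty. Marker ids (`OsISM#####`,
`OsILP#####`) are assigned in chromosome-then-position order after the
genome-wide uniqueness screen, so numbering is dense and deterministic.
Every step of design is RNG-free: identical inputs give byte-identical
tables.

## In-silico PCR

Binding tolerates ≤ 2 mismatches but requires the 3'-terminal trinucleotide
to match exactly (polymerase extension is blocked by a mismatched 3' end);
N in the template never matches. Amplicons are convergent site pairs within
`max_product` (default 3000 bp), under both primer-to-strand assignments, so
predicted length sets are invariant under reverse-complementing the
template. Primer uniqueness is judged at the amplicon level — exactly one
product genome-wide — because two sites that cannot pair productively do not
threaten specificity. Markers failing uniqueness on the reference are
dropped at design time; conversion to ILP additionally requires a single
product on the query genome.

## Homology search and gate scaling

Each intron (intron sequence only; the flanks serve primer placement) is
seeded into a query-genome k-mer index (k = 13, every 3rd position, both
orientations), seed hits are clustered by diagonal, and the top clusters are
locally aligned (match +1, mismatch −2, gap open 5, gap extend 2; a gap of
length L costs 5 + 2L). Raw scores S convert to bit scores
`(λS − ln K)/ln 2` and E-values `K·m·n·e^{−λS}` with the BLASTN-like
λ = 1.28, K = 0.46 for this scoring. A reported "E-value of 0" from BLAST is
an underflow artifact, so the gate is a finite cap.

Default gates are bit ≥ 500 and E ≤ 1e−50, appropriate for genome-scale
searches: a bit score of 500 requires roughly 270 aligned matches, so on a
real genome only long, well-conserved introns pass. On the simulator's
~10^5-base genomes that gate would categorically exclude every intron
shorter than ~300 bp; benchmark runs therefore use bit ≥ 50 and E ≤ 1e−6,
which still demands ~40 exact-equivalent matches — far beyond chance in a
10^5-base search space (expected chance alignments at that threshold:
≪ 1e−6) — while admitting the shortest (60 bp) simulated introns. The gates
scale with the search space; they are configuration, not constants.

Ambiguity: if a second, non-overlapping locus scores within 0.95× of the
best bit score the match is flagged ambiguous and excluded from ILP
conversion. Ties are broken toward the lowest (seq_id, start).

## InDel calling

For the score gate the local alignment suffices, but InDel calls come from a
second, anchored alignment: 40 bp of conserved exon flank on each side is
prepended/appended to the intron and the composite is aligned semi-globally
to a padded query window (window overhangs free, internal gaps full cost).
The anchors pin the intron boundaries — without them, a large deletion near
an intron end can be "traded" for spurious matches in flanking sequence
(cheaper in mismatches than the affine gap), which both corrupts the homolog
interval and hides the event. The test suite contains a constructed instance
of exactly this failure mode.

Gap columns merge into calls; calls are left-normalized (shifted to the
smallest reference offset preserving the alignment, the standard variant
convention) so positions are reproducible; boundary bookkeeping assigns
upstream-boundary insertions to the flank and downstream-boundary ones to
the intron so that signed call lengths always equal the homolog/reference
length difference. Calls are reported in gene-strand intron offsets and in a
VCF-like anchored table.

## ILP conversion and FLP

An ISM converts to an ILP marker iff its intron has ≥ 1 InDel call, the
homology match is unambiguous, and the primer pair yields exactly one
product on each genome. The ISM primers are reused verbatim. Net FLP
(|reference − query| amplicon length) is the primary statistic — it is the
quantity a gel resolves — with gross FLP (Σ|InDel|) alongside; the two
coincide for single-InDel introns. `assay_tier` is `gel` when net FLP ≥ 10
bp (2.5% agarose resolution) and `sequencing` for 1–9 bp. Introns whose
InDels balance to net 0 are genuinely polymorphic but gel-invisible; they
are emitted to a side table (`OsBAL#####`), not as ILP markers.

## Summary statistics

Markers/gene and markers/Mb per chromosome and overall; FLP distribution in
bins 1–4, 5–9, 10–49, 50–101, >101 bp; amplification% = amplified/tested and
polymorphism% = polymorphic/amplified per marker class; genetic-map
saturation as mean inter-marker distance = map length / marker count (the
convention under which every row of a published map table reproduces — not
length/(markers−1)). Reports round half-up to the printed precision (ratios
and percentages 1 decimal, cM 2 decimals); full-precision columns are kept
alongside, and Python's banker's rounding is deliberately not used.

## Genotype statistics

Genotype matrices are markers × accessions with cells `a`, `a/b` or `-`.
PIC uses Botstein (1980), `1 − Σp² − Σ_{i<j} 2p²_i p²_j`, with expected
heterozygosity (1 − Σp²) as a secondary column; frequencies renormalize over
non-missing calls. Nei–Li distance treats every observed allele of every
marker as a gel band (heterozygotes contribute both bands):
`D = 1 − 2·shared/(n_x + n_y)` over jointly scored markers
(pairwise deletion; a pair with no jointly scored bands is an error, not a
silent 0). Neighbor joining is the Saitou–Nei agglomeration with
lowest-index tie-breaks (deterministic), ending in an unrooted trifurcation;
on additive matrices it recovers topology and branch lengths exactly
(property-tested to n = 8, and cross-checked against dendropy's independent
NJ). Bootstrap resamples markers with replacement (default 1000 replicates,
seeded), rebuilds distance and tree, and labels each internal edge with the
percentage of replicates recovering its bipartition. Segregation screening
is Pearson χ² without continuity correction against a stated ratio (1:1 for
an F₂/F₃-style two-class screen), df = classes − 1. Relative expression is
comparative Ct: `2^−ΔΔCt` with ΔCt = Ct_target − Ct_reference per condition,
so the calibrator's fold change is identically 1.

## The synthetic-data generator

`simulate_genome_pair` emulates the study design the package targets: an
annotated reference genome and a query genome differing only inside introns.
Defaults (the study conditions, not dials): 2–8 exons/gene of 80–400 bp,
introns 60–2000 bp, random intergenic spacers of 200–1000 bp (keeping
primers single-copy unless duplications are planted), ~30% TE-associated
genes, intronic SNP rate 0.01/bp, planted InDels Poisson(0.4)/intron with
geometric lengths of mean 4.8 truncated to 1–101 bp (the size regime
intron-length polymorphisms occupy between diverged rice accessions), exon
mutation rate 0. Planted events keep a 3-bp margin from intron boundaries
and never overlap; every event is recorded in truth tables (per-variant,
per-intron, per-gene query intervals). `duplication_rate` plants verbatim
gene copies in both genomes to exercise the uniqueness screen. All
randomness flows from one seeded generator; runs are byte-reproducible.

What the simulator does **not** reproduce: real base composition and repeat
content, tandem repeats and microsatellites (where left-normalization
matters most in practice), homology between gene family members short of
exact duplication, exonic divergence, and sequencing/assembly error. Passing
the recovery benchmark therefore shows the pipeline's bookkeeping and
detection logic are exact under clean divergence of the stated magnitudes —
it does not certify performance on repeat-rich real genomes.

`simulate_genotypes` draws per-marker base allele frequencies from a flat
Dirichlet and perturbs them per group with concentration `(1−d)/d`
(Balding–Nichols style), so `d = 0` gives exchangeable groups and large `d`
nearly fixed group-private alleles; accessions are diploid draws with
independent per-cell missingness.

## Benchmark problem sizes

The recovery benchmark runs 50 genes on 2 chromosomes (~160–200 introns,
~300 kb per genome), design with product window 100–2500 bp and
`per_gene = 8` (≥ the maximum intron count, so every designable intron
competes), homology gates scaled as above, in-silico PCR cap 3000 bp. One
run takes well under a minute on one CPU; the test suite reuses a single
session-scoped run. Scored properties: 100% recall of marker-bearing
introns with net-length-changing planted InDels, exact net-FLP agreement
with truth, zero ILP calls on InDel-free pairs, and exact agreement between
the two independent FLP routes (indel-call arithmetic vs in-silico PCR).

## Known limitations

- Homology search is seed-based; homologs with no exact 13-mer in common
  (extreme divergence) would be missed — irrelevant at the divergences the
  markers target, where exons must be conserved enough for primers anyway.
- The hairpin/dimer screen is a perfect-inverted-repeat heuristic, not a
  thermodynamic model.
- Uniqueness screening is exact-arithmetic in-silico PCR with ≤ 2
  mismatches; degenerate bases and primer–template bulges are unsupported.
- Left-normalization operates within the intron; an InDel whose repeat
  context crosses the exon boundary is reported at offset 0 rather than in
  the exon (the amplicon-length prediction is unaffected).
- Linkage-group ordering, QTL mapping, and population-structure admixture
  modelling are out of scope; the genotype module ends at distances, trees,
  segregation screens and expression ratios.
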