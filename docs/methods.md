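# Methods

This note records the models, parameter choices and numerical conventions
behind `gscortho`, and what the synthetic-data tests do and do not
demonstrate about real genomes.

## Coordinate and data conventions

Gene spans are 0-based half-open internally; all GFF3 I/O is 1-based
inclusive, converted only at the boundary, and a read→write round trip
preserves coordinates exactly. One representative protein is kept per gene
— the longest CDS among a gene's transcripts — because downstream searches
need a single query per gene; isoform-aware search is out of scope. Genes
whose spliced CDS is not a multiple of three, or that contain internal
stops, are marked untranslatable: excluded from protein searches but kept
for nucleotide-level rescue.

## Alignment engine

Local alignment is exact Smith–Waterman with affine gaps (a gap of length
L costs `open + L·extend`), computed by Biopython's C `PairwiseAligner` —
no seeding heuristics, so scores are reproducible and order-independent.
Defaults are BLOSUM62 with gap open 11 / extend 1 for protein and +2/−3
with 5/2 for nucleotide, the familiar BLAST-like settings. Percent
identity is identical columns over all aligned columns *including* gap
columns — definitions vary between tools, so this one is fixed explicitly.
Thresholds act on raw score and coverage; no E-values are computed, and no
published E-value cutoff is being reproduced. Hit tables sort by
(score desc, identity desc, subject id), making rank 1 deterministic; the
test suite checks the engine against an exhaustive substring-enumeration
oracle on short sequences.

Unknown residues map to a mismatch-only symbol (protein `X`, nucleotide
`N`) with a warning; such a symbol never scores positively, even against
itself.

## RBBH stage

A forward hit must reach raw score ≥ 50 and query coverage ≥ 0.5 of the
protein to count; reciprocity is judged on rank 1 only, the strictest
reading of "reciprocal best". A tied top score in either direction is
treated as an ambiguous absence and pushed to the synteny stage rather
than resolved arbitrarily. An optional percent-identity filter
(Ensembl-style, ≥ 25%, boundary inclusive) is available but off by
default. A single-direction identity-threshold caller
(`naive_identity_calls`, default ≥ 50% identity and ≥ 0.8 coverage) is
provided as the permissive baseline for three-strategy comparisons; by
construction the rescue stage can only convert absences to presences, so
absence counts are non-increasing from naive → RBBH → RBBH+synteny.

## Synteny stage

Three flanking genes per side (nearest first) frame the expected locus.
Anchors are located by the same reciprocal protein search — an anchor must
hit back to itself, so paralogs cannot anchor a block. Retained synteny
requires at least one located anchor on each side *sharing a contig*, so
that the inter-anchor interval is defined; located anchors confined to
different contigs instead flag a contig boundary at the locus
(`UNRESOLVED_CONTIG_END` when nothing is rescued). Anchor order and
orientation are deliberately not required to be conserved — only
co-location — so local inversions do not manufacture false absences.

Rescue searches use a gentler nucleotide scheme (+1/−1, gaps 2/1, both
strands) plus protein alignment against all six translated frames of each
region. The BLAST-like +2/−3 scoring has negative expected score below
~60% nucleotide identity and fragments alignments exactly where rescue
matters most (heavy synonymous divergence); +1/−1 stays positive down to
~50% identity. Hits must still reach score ≥ 30 and ≥ 60% identity, which
random spacer sequence does not achieve at these lengths. A single hit
covering ≥ 0.8 of the gene rescues it outright; hits on two or more
contigs whose union query coverage reaches 0.8 rescue a split gene. The
0.8 combined-coverage threshold and the 50 kb `max_amplicon` ceiling for
validation are package choices, set once: 0.8 tolerates edge erosion of
local alignments while still requiring most of the gene to be found, and
50 kb mirrors what anchored PCR can practically span.

In-silico validation extracts the inter-anchor interval and scans it with
the same nucleotide and six-frame protein searches; any hit covering
≥ 0.3 of the gene contradicts the absence call, otherwise the absence is
`VALIDATED_ABSENT`. Intervals above `max_amplicon` are `NOT_VALIDATED`.

## Confidence tiers

`VALIDATED` > `HIGH` > `LOW`. An absence in species *s* is HIGH when the
gene is present in some species at divergence ≥ that of *s* ("more or
equally divergent", ties allowed): a deeper present witness makes
detection failure the less likely explanation. Because the literature
mixes per-absence and per-gene readings of this criterion, both are
computed: the tier is per-absence, and each label also carries a
gene-level flag (whether even the gene's deepest absence has a deeper
present witness).

## Synthetic clade forge

The forge emulates what the pipeline consumes, not molecular evolution.
Conserved genes substitute amino acids at rate 0.005/My (protein identity
≈ e^(−0.005·t), ~70% at 70 My — the divergence depth of the modelled
clade), with a crude exchangeability bias (70% of replacements stay within
a physico-chemical group). Synonymous codon changes accrue independently
at 3× the amino-acid-changing probability; intergenic sequence drifts at
0.004/My with occasional 1–5 bp indels. Planted losses excise the gene
body plus 50 bp margins and leave flanks adjacent; splits cut the
(diverged) CDS at its midpoint onto two contigs and drop the annotation;
contig-end events keep only a 30% CDS stub at a new contig end; extreme
divergence applies one nonsynonymous nucleotide step to 90% of codons
(protein identity ~10–25%, nucleotide ~70%) and also drops the annotation,
since annotation pipelines routinely miss such genes — making the case
reachable only through nucleotide-level rescue, which is the point of
planting it. Events must target interior genes; an event on the first or
last gene of a contig is rejected because its expected final call would be
undefined without flanks. Same seed → byte-identical genomes
(per-species generators are spawned from one seed sequence).

What the forge does **not** emulate: transposable elements and repeats,
segmental duplications and paralog families, chromosome-scale
rearrangement, intron structure, codon-usage bias, or assembly error
beyond the planted artefacts. Passing the planted-event suite therefore
shows the pipeline's logic is correct under clean conditions at ≤ 40%
protein distance; it does not bound false-call rates on repeat-rich real
assemblies.

Progeny counts are negative binomial (mean m, dispersion k, variance
m + m²/k) — count data in fertility assays are overdispersed, and the
negative binomial is the standard minimal choice; sterile classes are
exactly zero. Groups with identical parameters under the same seed
receive identical draws, so paired comparisons are exactly calibrated.

Simulated codon sets plant every change as a single-nucleotide codon step
at its own site, with polymorphism frequencies required to be exactly
representable as k/n; the planted 2×2 is then recoverable exactly at
cutoff 0, which is what makes the MKT calibration sharp.

## McDonald–Kreitman test

Polymorphism frequency is *minor-allele* frequency of the sampled
sequences — the conservative, outgroup-free reading; a derived-allele
option would need polarisation that the inputs do not guarantee. The 12%
exclusion is strict (`< 0.12` removed, `= 0.12` retained). Fixed changes
are counted against a supplied common-ancestor sequence, making divergence
lineage-specific by construction; a parsimony fallback
(`parsimony_ancestor`) resolves each site by two-of-three agreement among
focal consensus, sister and outgroup, emitting `N` (excluded downstream)
where all three disagree. Multi-step codon differences average over all
shortest mutational pathways with equal weights, excluding pathways
through stops; if every pathway passes a stop, the exclusion is dropped
rather than losing the site. Codons with gaps or ambiguity in any used
sequence are excluded and reported. Fractional pathway counts are kept in
the table; Fisher's test runs on the rounded table, with the rounding
recorded.

Fisher's two-tailed p sums hypergeometric probabilities ≤ the observed
one. Point probabilities are compared as exact integers over a common
denominator (`math.comb` numerators), so ties at the observed probability
are decided exactly rather than through a floating-point slack. Degenerate
tables (any zero margin) return p = 1.

Calibration: across 500 seeded codon sets with planted counts kept
exactly proportional (Pn/Ps = Dn/Ds), the recovered mean alpha is 0 and no
replicate rejects neutrality — any counting or filtering bug would break
the proportionality and surface here.

## Estimation statistics

The resampling protocol is fixed and documented (control index matrix of
shape (n_boot, n_control) drawn first, then the group matrix) so results
are reproducible from one integer seed. BCa uses the standard bias
correction z₀ = Φ⁻¹(fraction of resampled deltas below the observed
delta) and jackknife acceleration over both groups' leave-one-out deltas;
when z₀ is degenerate (all resamples one side) the percentile interval is
used with a warning, and all-constant inputs give a zero-width interval.
Defaults n_boot = 5000 and BCa match common estimation-graphics practice;
n_perm = 10000 so that p-values down to 10⁻⁴ are resolvable — with 5000
shuffles the smallest reportable bound would be 2×10⁻⁴. The permutation p
is (1 + #{|Δ_perm| ≥ |Δ_obs|}) / (n_perm + 1), never zero; a zero count is
reported as the bound 1/(n_perm+1). Genotypes are each compared to the
single shared control with no multiplicity correction, matching the
shared-control design the analysis reproduces. On 400 synthetic
normal-pair replicates the 95% BCa intervals cover the true difference at
the expected small-sample rate (~93–97%).

## Summary statistics

Headline absence counts treat `UNRESOLVED_CONTIG_END` as present
(conservative; switchable). A gene in several functional categories counts
once in each — categories overlap by construction of complex-enrichment
maps. Percentages are reported to two decimals. External ortholog imports
keep predictions with alignment identity ≥ 25% (boundary inclusive; the
smaller of target/query percent identity when both are given) and demote
the rest to absent, so imported matrices are comparable with the
pipeline's own callers.

## Problem sizes

The test and acceptance runs use a 40-gene, 2-contig reference descended
into 5 species (5–70 My) with eight planted events, 500-replicate MKT
calibration at 120 codons × 10 sequences, and n = 20 flies per genotype —
sizes chosen so the whole suite exercises every stage end-to-end in well
under a minute while keeping every planted regime (divergence ≤ 40%
protein distance) represented.

## Known limitations

* The pipeline assumes annotated target proteomes; a present-but-
  unannotated gene is recoverable only through the synteny stage's
  nucleotide/translated searches.
* Orthology is one-to-one by construction (RBBH); many-to-many families
  and tree-reconciliation orthology are out of scope, and a recent
  duplication in the target breaks reciprocity by design (reported with a
  `reciprocity_broken` flag rather than guessed).
* The validation analogue shares thresholds with rescue; it demonstrates
  internal consistency, not wet-lab sensitivity.
* Divergence-time input is a point estimate per species; confidence
  tiering inherits whatever error those estimates carry.
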