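# Methods

## Model and procedure

`panguide` treats guide design as a set of filters over the universe of
PAM-adjacent windows in a panel of strain genomes.

**Site enumeration.** A site is a 23-nt window whose last two bases are
GG on the forward strand, or whose first two bases are CC read in
reverse complement (the symmetric reverse-strand rule). The guide key
is the full 23-mer in guide orientation (protospacer + PAM). Windows
containing N are never sites: an ambiguous base can satisfy neither an
identity nor a mismatch count. Only the canonical SpCas9 NGG PAM is
enumerated by default; non-canonical NAG sites can be indexed behind a
flag for off-target assessment but never nominate guides.

**Gene restriction.** Guides are drawn from annotated gene regions,
with intersection (not containment) semantics: a site belongs to a gene
iff its 23-nt span overlaps the gene's annotated footprint, and an
`in_gene_fraction` field records how much of the window is inside.
Sites touching two or more distinct genes are discarded by default
(`allow_overlapping_genes = false`): cutting there cannot knock out a
single gene cleanly.

**Specificity.** An off-target is an NGG-adjacent site whose 20-nt
protospacer is within 5 mismatches of the guide (mismatches counted
uniformly across the 20-mer; PAM positions never counted). A guide is
specific iff it has exactly one perfect site (its own locus — the
single-copy requirement) and zero sites at distances 1–5. The search
is a full vectorised Hamming scan over the byte-packed table of all
PAM-adjacent windows, which is complete by construction; a partitioned
seed filter was considered and rejected because with a bound of 5
mismatches over 20 nt no 3-way split guarantees an exact segment, so
the "fallback" complete scan would run anyway. Batch queries use a
one-hot encoding and a single matrix product per block (matches =
Q·Sᵀ), which keeps whole-genome specificity assessment to seconds at
the problem sizes used here.

**Conservation.** Specific guides are grouped by their 23-mer and the
conservation level of a group is the number of genomes (home genome
included) with at least one exact occurrence, found by exact 23-mer
lookup in each genome's site table. Identity is strict: any
substitution in the 23-mer, including one that breaks the PAM,
de-conserves the target. Guides below `min_conservation_genomes = 2`
are dropped. Strict mode (default) also requires specificity in every
genome where the target occurs; lenient mode (home genome only) is
available because either reading is defensible, and the per-guide
`passes_strict` flag reports the distinction either way. Gene
assignments across genomes are reported but not required to agree;
discordant assignments are logged. The tier summary counts, for each
tier k, distinct guides at level ≥ k and distinct reference genes they
target, with percentages against the reference's annotated gene count
(the denominator choice is recorded in the report).

**Annotation transfer.** Strains without annotation receive gene models
by translated homology: exact amino-acid 5-mer seeds of each reference
protein against the six-frame translation of the target, ungapped
X-drop extension (X = 20) under BLOSUM62, significance by the
Karlin–Altschul formula with standard ungapped parameters
(λ = 0.3176, K = 0.134), threshold e ≤ 1e-10. The best-scoring locus
per protein becomes a single-interval transferred model (no intron
reconstruction — downstream stages only need the target region); locus
conflicts resolve by score, then alignment length, then gene id, which
makes transfer deterministic. A 12-column tabular loader lets an
external search program substitute for the internal one.

**Knockout bookkeeping.** Offsets are 1-based in gene-sense coordinates
with the A of ATG at position 1. Two "downstream of ATG" conventions
circulate for sense guides — protospacer 5' start and PAM start,
exactly 20 nt apart — and both are carried, labelled; antisense guides
anchor to the protospacer base nearest the ATG. (One published
antisense offset, 328 vs a textual 382, fits neither convention; the
tabulated value is used and the discrepancy simply noted.) The blunt
cut sits between protospacer positions 17 and 18, i.e. 3 bp from the
PAM, stored as a strand-independent forward-strand boundary coordinate
so reverse complementing a contig reflects it exactly. Paired-guide
deletions are the distance between two cut boundaries; observed NHEJ
junctions can be larger because of end resection (the published
Matα3 pairs: 449 bp predicted vs 523 bp sequenced, 113 vs 116), so the
prediction object carries that caveat in a `note` field. Paralog-aware
selection accepts a guide iff all its perfect sites lie in the allowed
loci, it hits every allowed locus containing the target (identical
copies are necessarily all cut), and no 1–5-mismatch site exists
elsewhere. The default ranking score is a deliberately simple
deterministic composite (GC fraction outside [0.4, 0.7] penalised,
homopolymer ≥ 4 penalised, ties broken by offset); any trained
on-target model can be injected through the same 30-nt-context hook
(4 nt upstream + 23 + 3 nt downstream).

## Synthetic strain sets

The simulator emulates the study input — several strain assemblies of
one species — at desk scale: a random ancestor with single-exon
ORF-like genes (ATG, non-stop codons, TAA; 300–600 nt; both strands),
per-strain i.i.d. substitutions at a configurable rate, and planted
features with exactly known fates: a segmental duplication private to
strain 1, an overlapping gene pair, an identical gene pair in all
strains, and engineered guide targets conserved in exactly j strains
for j = 1..n (PAM deliberately destroyed in the other strains).

Defaults are 3 strains, 24 genes, 30 kb, divergence 0.02 substitutions
per site — a realistic intra-species distance for yeast strain panels
and the regime where conservation tiers separate visibly. Planted
20-mers are re-rolled during construction until they occur the expected
number of times and sit at Hamming distance ≥ 8 from every other
PAM-adjacent protospacer in the ancestor; with that margin, random
divergence would need three coordinated substitutions at one site to
manufacture a confounding ≤ 5-mismatch neighbour, so the truth table
stays exact with overwhelming probability at any seed. Divergence is
substitution-only so planted coordinates remain valid in every strain;
an indel-free model is a simplification — real strain panels differ by
indels and structural variants, which this generator does not emulate,
so passing the planted-truth tests demonstrates the filters' logic, not
robustness to alignment-breaking variation. Gene models are single-exon;
guide discovery is intron-agnostic, so nothing downstream depends on
that simplification.

## Numerical and degenerate-input choices

- All internal coordinates are 0-based half-open; GFF3 is converted at
  the I/O boundary (1-based closed), BED is written 0-based half-open.
- Sequences shorter than 23 nt yield empty site lists, not errors;
  empty guide sets produce header-only TSVs and empty BEDs.
- Ordering is fully specified everywhere (sites by start then strand;
  transfers by score, length, id; rankings by score then offset), so
  identical inputs give byte-identical outputs.
- Multi-isoform genes collapse to the longest CDS chain; genes without
  CDS are skipped with a log line; internal stops truncate translation
  with a warning rather than failing.
- Mismatch bounds above 5 are permitted with a warning (outside the
  off-target definition this package implements).

## Problem sizes and limitations

The bundled tests and the acceptance script run on 12–50 kb synthetic
genomes with 8–24 genes per strain, sizes chosen so the whole suite
executes in well under a minute while exercising every code path; the
same code paths scale linearly in genome size and the batch specificity
step dominates at whole-genome scale. Known limitations: no bulge or
indel off-targets, no seed-region mismatch weighting, no chromatin or
efficacy modelling beyond the pluggable scorer, substitution-only
simulation, and homology transfer is best-hit one-to-one without
reciprocal filtering (secondary hits are logged, not modelled).
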