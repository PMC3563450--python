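# Methods

This note documents the models implemented in `ribodiv`, the defaults
they ship with, and the choices made where the design was genuinely open.

## Reference amplicon and ribotype panels

The unit of analysis is a single-copy reference amplicon spanning the 3'
end of the 18S gene (313 bp), the complete ITS1 (240 bp by default,
238–242 accepted) and part of the 5.8S gene (97 bp), ~650 bp in total.
Coordinates are 1-based closed intervals on the coding strand throughout;
inputs reported on the noncoding strand must be normalised before use.
ITS1 variants are additionally reported in ITS1-relative coordinates
(`[57:C>T]` means position 57 within ITS1), matching the convention of
published cluster tables.

A ribotype panel assigns genomic frequencies (summing to 1) to a set of
distinct variant profiles on the template. `derive_ribotypes` draws
profiles with exact per-region event counts; the default study panel has
three ITS1 ribotypes with 0, 1 and 3 substitutions at 70/20/10% —
divergences of 0.4–1.3% per 240 bp, the range typical of major ITS1
families in diploid plants with multiple rDNA loci.

## Platform error models

No per-base error rates are published for the amplicon datasets this
package emulates, so the defaults below are adjustable model parameters
chosen for qualitative realism, not estimates of any instrument:

| model    | sub rate | homopolymer indel p | read length | placement |
|----------|---------:|--------------------:|------------:|-----------|
| 454      | 5e-4     | 5e-3                | U(350,450)  | amplicon ends (5'/3') |
| illumina | 3e-3     | 2e-4                | 100 fixed   | uniform shotgun windows, both strands |
| sanger   | 1e-5     | 0                   | full length | full amplicon |

The 454 indel model gives each maximal homopolymer run of length k an
indel probability p·(k−1) (single-base insertion or deletion, equally
likely), so single bases never acquire indels and long runs dominate —
the characteristic pyrosequencing failure mode. Substitution errors are
rarer than indels on this platform; the 5e-4 default is consistent with
published pyrosequencing error decompositions and with the package's own
recovery contract (filtered cluster abundances within ±0.03 of panel
frequencies at n = 2000 reads). Illumina-like reads are
substitution-dominated and placed uniformly along the unit on a random
strand, emulating genomic shotgun coverage rather than amplicon
sequencing. Sanger "clones" are full-length and near-error-free
(sub rate ≤ 1e-4 enforced, no indels). FASTQ qualities are constant
placeholders; no stage uses them.

Amplicon reads anchor at the 5' (primer A) or 3' (primer B) side; only
3'-side reads (≥ 337 bp) span the whole ITS1, so ITS1 clustering
experiments simulate with `origin="three_prime"`. Not modelled: PCR
chimeras, base-quality profiles, paired-end insert sizes.

## Read mapping and variant profiles

Reads are aligned to the template by Smith–Waterman local alignment
(via Biopython's PairwiseAligner) with match +2, mismatch −3 and affine
gaps costing |open| + g·|extend| = 5 + 2g for a run of g bases. Both
orientations are scored and the better one kept (forward wins ties);
among co-optimal alignments ties break by earliest reference start, then
fewest gap runs. Mapped reads must have at most 10 mutation events
(substitution events plus gap runs — a g-base gap run is one event) and
identity ≥ 0.90 over alignment columns. The identity floor replaces a
search-engine E-value threshold that is not reproducible outside the
original software; it serves the same purpose of excluding unrelated or
highly divergent sequences, deterministically. Every input read ends up
mapped or rejected with a reason; nothing is silently dropped.

Variant extraction merges adjacent gap columns into single indel events,
left-aligns indels on the reference (so equivalent placements in
homopolymer runs collapse), assigns each event to its template region,
and never emits variants from N-containing columns (N counts as mismatch
for identity only). Because local alignment clips mismatching termini, a
substitution on the final base of a read is unrecoverable; region-level
analyses therefore restrict to reads whose alignment spans the region.

## Ribotype clustering

Region-spanning reads are grouped by identical region-restricted variant
profile (stage *raw*; substitutions and indels both distinguish
clusters). Clusters are then re-keyed on the substitution-only
sub-profile (stage *merged*) — the indel-disregarding step that collapses
pyrosequencing artefact clusters; reads whose profile is pure indel join
the reference cluster. Merging precedes singleton exclusion (stage
*filtered*) so that an indel-artefact read of a genuine ribotype is
rescued rather than discarded. Abundances are fractions of retained
reads, sorted descending with ties broken by profile notation for
deterministic output. Major ribotypes are clusters at or above a 5%
representation threshold (≥, configurable; 3% is a common screening
alternative). De novo reference-free clustering and chimera detection
are out of scope.

## Variant calling and diagnostics

Pileups count one base per aligned column, one deletion event per covered
deleted position, and one insertion event at the anchor position of each
insertion run; coverage is the A/C/G/T sum. A site is called when
coverage ≥ 4 and the most frequent non-reference allele (or indel event)
reaches frequency 0.01; at most 1000 calls are kept, by descending
frequency then position (the cap is never reached on a 650 bp template).
Calling is monotone in both thresholds. SNPs and DIPs are reported
separately. The upstream short-read mapper settings sometimes quoted with
these thresholds (seed window length, gap caps) are banding heuristics of
a particular mapper; with exact Smith–Waterman they are advisory only and
recorded as configuration passthroughs.

Abundance histograms bin SNP frequencies into (0.01,0.02], (0.02,0.05],
(0.05,0.10], (0.10,0.15], (0.15,1.0] — bins are half-open on the left so
that a call at exactly 1% is excluded ("exceeding 1%"); the exact edges
are a reconstruction and are configurable. The mutation spectrum counts
the 12 directed substitution types and collapses strand-complementary
pairs into 6 classes labelled pyrimidine-first (C→T with G→A as
`C:G>T:A`, the deamination signature). The substitution/indel diagnostic
counts *reads* carrying at least one event of each kind (a read can count
in both) and reports their ratio to one decimal; it is flagged infinite
when no read carries an indel. All rounding is half away from zero, on
the printed decimal value (so 1190/1400 → 0.9, 3/240 → 1.3%).

## Phylogeny

Major-ribotype consensus sequences (template plus profile) are compared
by p-distance over pairwise ungapped columns, optionally Jukes–Cantor
corrected (−(3/4)·ln(1 − 4p/3); entries at p ≥ 0.75 are flagged infinite).
Trees are built by neighbor joining (scikit-bio's implementation);
negative branch-length estimates are clamped to zero with the deficit
transferred to the sister edge so path lengths through the parent are
preserved. Maximum-likelihood inference is deliberately replaced by
NJ — on data of this divergence the topologies are equivalent and the
machinery is far lighter; the customary 500 replicates are run as NJ
bootstrap replicates (column resampling, support = percentage of
replicates containing each original bipartition, taxa sorted by label so
support is input-order invariant). Output is Newick with supports as
internal node labels.

The cross-species search compares each query consensus against every
target cluster (any abundance, including low-copy singletons) and
reports hits within a configurable substitution distance (default 0);
species with disjoint panels yield empty match lists. Locus-diversity
summaries report the Spearman rank correlation (midrank ties) between
locus number and major-ribotype count, with n but deliberately no
p-value — these comparisons involve a handful of species. Where a
species' loci are partly dispersed, the record is encoded as one extra
locus (e.g. "3 + dispersed" → 4), configurable by the caller.

## Concerted-evolution simulator

The genome is a list of loci, each an ordered array of units; a unit is a
(genic, spacer) pair of infinite-alleles integer labels (allele 0 =
functional ancestral state). Haplotypes are labels rather than sequences
to keep the dynamics exact and fast. Per generation:

1. each unit mutates its genic / spacer label to a fresh allele with
   probability mu_genic / mu_spacer;
2. Poisson(c_intra + c_inter) conversion events fire; each picks a
   recipient uniformly, a donor from the recipient's locus (probability
   ∝ c_intra) or a different locus (∝ c_inter), and overwrites the whole
   recipient unit with the donor;
3. a donor carrying a genic mutation is rejected with probability s.

Unit counts are conserved except by the explicit operations: whole-locus
duplication, and orphan-seeded expansion in which a founder unit grows a
new locus by Poisson(expansion_rate) self-copies per generation until a
target size, yielding an initially monomorphic array. The biological
reading: intra- exceeding inter-chromosomal homogenisation lets loci
diverge after duplication; founder expansion creates homogeneous new
arrays; selection keeps the genic channel homogeneous while the spacer
channel accumulates variants — together the proposed mechanisms for more
ITS1 ribotypes in genomes with more loci.

Fixation time is measured with mutation off, on a single locus starting
maximally diverse (every unit a distinct spacer allele), as the first
generation at which all units are identical (censored at a cap). The
implementation iterates the embedded event chain of `step` — uniform
recipient, uniform other donor, Poisson(c_intra) events per generation —
so the measured time is distributed exactly as a step-by-step run while
remaining fast at hundreds of replicates. For two units the time is
geometric with p = 1 − e^(−c), a closed form used as a unit-test oracle.
Median fixation time over 200 replicates at n = 8, 16, 32, 64 gives a
log-log slope near 2, consistent with the theoretical quadratic
dependence of tandem-array homogenisation time on copy number.

Diversity metrics count distinct haplotypes per locus and genome-wide,
the modal-haplotype fraction, and per-channel polymorphism both as
distinct allele counts and as units off the modal allele (the analogue of
reads outside the major cluster). The selection-asymmetry experiment uses
equal mutation rates (0.003/unit/generation), c_intra = 2, hard selection
s = 1, 64 units, a 1000-generation horizon and 100 seeds; rates are free
parameters chosen to express the mechanism clearly, with no claim of
quantitative fit. Not modelled: array-length change by unequal crossover,
diploidy and recombination between homologues, absolute-time calibration.

## Problem sizes and runtime

Experiments are sized to run comfortably on a single CPU: frequency
recovery uses n = 2000 reads (sampling ±3σ ≈ 0.031 on the 70% class, the
resolution the ±0.03 recovery contract requires), platform contrasts
n = 800 per platform, alignment-oracle checks 200 random pairs of length
≤ 8, NJ recovery 50 random 5–8-taxon additive trees, bootstrap 100–500
replicates, homogenisation scaling 200 replicates per array size. The
full acceptance run takes about one minute; the test suite under two.

## Known limitations

- The error models are deliberately minimal (no quality values, no PCR
  chimeras, no flow-value modelling); passing recovery tests shows the
  analysis logic is sound under the stated error regimes, not that real
  454/Illumina artefact spectra are fully captured.
- Local alignment cannot recover variants on the terminal bases of a
  read; abundance estimates carry a small deficit from error-bearing
  reads leaving their source cluster, visible at the 1–3% level.
- The simulator's conversion model copies whole units; partial-unit
  conversion tracts and crossover-mediated length change would require a
  sequence-level representation.
- Neighbor joining substitutes for maximum likelihood by design; for
  deeper divergences or rate heterogeneity an external ML tool should be
  used on the exported consensus FASTA.
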