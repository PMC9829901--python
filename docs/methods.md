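# Methods

`splicesig` implements a complete desk-scale analysis chain for two related
questions in tumour transcriptomics: (1) how much of the IRE1α-generated
*XBP1s* splice isoform is present in an RNA-seq sample, and (2) whether an
IRE1α-dependent gene signature stratifies patient survival, and how specific
that association is.  This note records the models, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
emulate.

## Targeted splice-event quantification

*XBP1s* arises when the IRE1α endoribonuclease excises a short fragment
(26 nt in human *XBP1*) from the unspliced transcript, outside the
spliceosome.  Against the unspliced reference, a read from the spliced
isoform therefore shows a single deletion of exactly the excision length at
the known junction.  The quantification model is deliberately narrow: one
transcript, one annotated event, and a splicing percentage

    spliced_percent = 100 · spliced / (spliced + unspliced)

computed over junction-informative reads only.  The denominator includes the
spliced reads themselves, which keeps the quantity a percentage in [0, 100];
reads that never reach the junction carry no information about the event and
are excluded from the ratio.

### Alignment

Reads are aligned by an affine-gap dynamic program that is global in the
read and local in the reference (free reference ends).  A gap of length L
costs `gap_open + gap_extend·L` with both defaults at 1, so a 26-nt deletion
costs 27 while the 26 matches it buys back are worth 52 — long gaps are
de-penalised, which is the core trick that makes the event visible to a
short-read aligner at all.  Remaining scoring defaults: match +2,
mismatch −3, chosen so that a single sequencing error is cheaper to absorb
as a mismatch than as an insertion–deletion pair (cost 4), which keeps
alignments clean around the junction.

Two numerical consequences of near-free gaps required explicit handling:

- **Gap barrier.**  With unrestricted gap placement the optimal alignment of
  a read whose junction anchor is short is frequently a mosaic: the tail is
  stitched across several small chance-matched gaps at lower total cost than
  the single long deletion.  Production short-read aligners suppress this
  with a gap barrier near the read ends; we do the same
  (`AlignmentParams.gap_bar`, default 10 read bases on each side of any gap,
  0 disables).  With the barrier in place, error-free simulated junction
  reads are classified to their true isoform without exception.
- **Left-aligned indel comparison.**  When the base preceding the excision
  equals its last base, the deletion can slide left at equal score.  The
  detected deletion and the annotated junction are therefore compared under
  indel-normalisation equivalence (the left/right-shift convention pileup
  and VCF tools use).
- **Deletion clustering.**  A substitution error near the junction is often
  absorbed by splitting the excision gap around a chance-matched base inside
  the excised region: converting a mismatch to a match gains 5 while an
  extra gap open costs only 1.  Deletions separated by fewer than
  `min_anchor` aligned bases are therefore merged into a cluster, and the
  spliced call tests the cluster's total deleted length and its overlap with
  the annotated excision interval rather than any single deletion op.

Both read orientations are tried and the better score kept.  A read is
`mapped` only if its score reaches `min_score_fraction` (default 0.4) of the
perfect-match score; ambiguous bases (N) never match.  The optional
`band_width` caps the reference-gap length tracked by the recurrence; the
default is unbounded, which is exact.

### Classification and thresholds

A read is **spliced** when its alignment carries a deletion cluster whose
total deleted length equals the excision length and whose span overlaps the
annotated excision interval by at least `excision_length −
position_tolerance` (tolerance 1 nt), with at least `min_anchor` (6) aligned
bases on each side of the cluster; **unspliced** when an uninterrupted
aligned run covers the ±`min_anchor` window around the junction with no
mismatches inside the window (a window mismatch is more likely a misaligned
junction read than genuine unspliced coverage, the analogue of counting only
quality-passing reference bases in a pileup); otherwise **uninformative**.
Mismatches do not interrupt an aligned run; insertions and deletions do.
Reads whose junction-flanking bases fall below Phred `min_base_quality` (13)
are uninformative.  The SAM entry point splits CIGAR `M` runs into
match/mismatch against the reference so both paths see identical evidence.

Sample-level calling mirrors pileup-style indel calling: at least
`min_supporting_reads` (3) spliced reads and an event fraction of at least
`min_event_fraction` (2·10⁻⁴) are required for `pass_threshold`; at most
`max_depth` (50 000) junction-informative reads are counted, first come
first served.  The same counting contract is applied to existing SAM/BAM
alignments by scanning CIGAR deletions (`count_from_alignments`), and the
two entry points agree exactly on round-tripped alignments.

## ssGSEA scoring

Signatures are scored per sample with the single-sample GSEA statistic:
genes are ranked by expression descending (ties broken lexicographically by
symbol so scores are deterministic), the gene at descending position k
carries rank value N−k+1, and the score is the sum over all positions of the
difference between the weighted in-set ECDF (weights `rank_value^alpha`,
alpha = 0.25) and the unweighted out-of-set ECDF.  Because the statistic is
rank-based, any strictly monotone per-sample transform of the expression
values leaves raw scores unchanged, and a sample's raw score never depends
on which other samples are present.  With `normalize` (the default, matching
the reference implementation's behaviour) the whole score matrix is divided
by its max−min range, which introduces a benign cross-sample dependence of
scale only.  Expression input is abundance-scale (FPKM-like); no internal
log transform is applied.

## Signature construction

`select_signature` applies strict inequalities — log2FC > cutoff (direction
`up`; < −cutoff for `down`), FDR < cutoff, p < cutoff — and orders genes by
|log2FC| descending.  Strictness at the boundary is a convention fixed for
determinism; `signature_grid` enumerates signatures over a cutoff grid the
way the signature was originally tuned (the shipped default, log2FC > 1 with
FDR < 1%, is the grid point selected in that analysis).  Ortholog mapping is
a plain two-column translation: unmapped genes are dropped and counted,
many-to-one collapses, one-to-many is an error unless `first_match` is
requested; no ortholog resource is bundled because the choice of resource is
a scientific decision the user must own.

## Survival analysis

Patients are ranked by score and the top/bottom `floor(n/3)` form the high
and low tertiles (`floor(n/4)` for quartiles); ties break by sample id with
a warning.  Kaplan–Meier curves, the Mantel–Cox log-rank test and Cox
proportional-hazards regression are delegated to `lifelines` (Efron tie
handling) behind this module's interface; medians are the earliest time the
survival curve reaches 0.5 (NaN if never).  The Cox group term is coded 1
for the non-reference stratum — reference `low` by default, so a hazard
ratio above 1 means the high stratum does worse.  Categorical covariates are
one-hot encoded against their lexicographically first level; a constant
covariate is rejected by name; non-convergence and separation produce a
flagged result with diagnostics rather than silent output.

### Random-signature specificity

The specificity null asks how often a random gene set of the same length
shows the survival association the true signature shows.  For each of
`n_random` draws (default 1000; 100 is equally supported as both counts
appear in the source analyses), genes are sampled uniformly without
replacement from the universe minus the true signature, scored by ssGSEA
(amortised over one precomputed ranking), tertile-stratified, and tested
high vs low.  Specificity is the fraction with p ≥ alpha — the complement
of a false-positive rate, which is the natural reading of "specificity"
here; an alternative mode counts random signatures whose p exceeds the true
signature's own p.  The high-vs-low log-rank p is used by default, with the
multivariate Cox group-term p available, since the source analyses are
ambiguous between the two.  The draw sequence is a pure function of the
seed, so results are exactly reproducible.

## Synthetic data

The generators stand in for the cohort-scale inputs (TCGA-style expression
plus clinical tables, and tumour RNA-seq FASTQs) that the pipeline consumes.

**Reads** are drawn from the spliced/unspliced transcript mixture at a known
fraction, with uniform start positions, i.i.d. substitution errors and a
constant quality string; the truth table records each read's origin and
whether it spans the junction with at least `anchor` (10, matching the gap
barrier) bases each side.  The synthetic target is a random ACGT sequence
accepted by rejection sampling only if its junction-flanking k-mers are
unique, the excised region diverges clearly from the sequence replacing it,
and — verified by exhaustive alignment — every error-free junction-spanning
read classifies to its true origin under the default aligner.  The last
check is what makes the generator's "junction reads are unambiguous"
contract actually hold: with near-free gaps, chance similarity between the
excised region and its surroundings admits equal-score alignments that no
simple sequence heuristic rules out.  Not emulated: indel sequencing errors, PCR
duplicates, GC bias, paired-end fragments, quality-score variation (quality
filtering is exercised with hand-built fixtures instead).  Passing tests
therefore demonstrate correctness of the counting machinery under a clean
substitution-error model, not robustness to real library artifacts.

**Cohorts** follow a minimal proportional-hazards generative model: gene
abundance is log-normal, `expr = exp(N(mu_g, sd))` with per-gene means
`N(3, 1)` (median abundance ≈ 20, an FPKM-like scale); the latent risk score
s_i is the standardised mean abundance of the planted signature genes; event
times are exponential with hazard `baseline_hazard · exp(beta · s_i)`
(default baseline 0.0173/month ≈ a 40-month median, a realistic overall-
survival scale for lung adenocarcinoma); censoring is Uniform(0, c) with c
solved by root-finding so the expected censoring fraction equals
`censoring_rate` (default 0.2).  Defaults n = 300 samples, 2000 genes,
signature size 50, beta = 1.  Under this model tertile stratification, Cox
recovery and the specificity null all have known behaviour, which is what
makes the calibration tests meaningful.  Negative-binomial counts,
covariate-dependent censoring and non-proportional hazards are deliberately
out of scope.

## Reproducibility and problem sizes

Every generator and resampling routine is a pure function of its config and
seed; the pipeline fans one global seed out to per-stage child seeds by
stable hashing so stages can be re-run in isolation, and each run writes a
manifest (config hash, seeds, version) sufficient to reproduce it.  The test
and acceptance workloads use desk-scale problem sizes chosen to make the
statistical bounds sharp but cheap: 200 random alignment instances against
the brute-force DP oracle, 2000 junction-spanning reads per mixture level,
2000 null cohorts of n = 60 for log-rank calibration, 50 replicates of
n = 300 for Cox recovery, and 200 random signatures on a 300 × 2000 null
cohort for the specificity calibration.

## Known limitations

- The aligner is exact but O(read × target); it is built for one transcript
  at a time, not genome-scale alignment.
- Classification assumes a single annotated event per target; co-occurring
  indels near the junction are handled only insofar as the left-alignment
  normalisation covers them.
- The immunomodulator database ships only as a small illustrative GMT
  fixture format; curating the real database is manual literature work.
- Cox diagnostics beyond convergence/separation flags (proportionality
  checks, influence measures) are out of scope.
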