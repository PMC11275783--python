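# Methods

This note records the models, parameter choices and numerical decisions
behind tdpscan, and what the synthetic-data tests do and do not
demonstrate about real tumor genomes.

## Data model and coordinates

All internal coordinates are 1-based inclusive (the SEG convention);
BEDPE and BED are converted at the IO boundary (0-based half-open).
Segments are allele-specific copy-number intervals with a cellular
fraction; a segment with minor copy number 0 **and** total copy number
> 0 is counted as LOH. Homozygously deleted segments (total 0) are
treated as absence of both alleles rather than loss of heterozygosity
of a retained allele, so they do not enter the LOH numerator.
Chromosome X is carried through IO but excluded from LOH scoring by
default, since heterozygous-SNP-based minor copy number is unreliable
there.

## Tandem-duplication calling

A simple TD is a segment < 10 Mb (strict) whose two immediate
neighbors *on the same chromosome arm* both have strictly lower total
copy number, with flank copy numbers differing by ≤ 1. Arm boundaries
come from an arm BED; a segment abutting a centromere lacks that flank
and never qualifies, as do first/last segments of an arm. In WGS mode
candidates must additionally match the two breakpoints of a
tandem-duplication-typed SV; both ends must match within a tolerance of
10 kb by default (the scale of copy-number bins), configurable down to
single-end matching or zero tolerance.

## SV typing

Junction orientation is defined as the direction the joined fragment
extends from the breakpoint. Intra-chromosomal events with span ≤ 1 kb
are removed. The decision table: (+,−) with interior mean copy number
below both outer flanks → deletion; (−,+) with interior mean above both
flanks → tandem duplication; (+,+)/(−,−) → inversion; remaining
intra-chromosomal events are balanced (all defined flanking bin values
equal, tolerance 0 on integer copy number) or unbalanced;
inter-chromosomal events are translocations. When flanking bins are
undefined (coverage gaps), orientation alone decides
deletion/tandem-duplication — this keeps events at gaps rather than
dropping them. Balanced/unbalanced events spanning > 10 Mb are treated
like translocations for gene-flanking annotation.

## Nearest-neighbor index and TDP call

The NNI is the n-weighted mean over chromosomes (with ≥ 2 TDs) of the
observed mean nearest-neighbor distance between TD midpoints divided by
the 1-D Poisson expectation L/(2n). Pooling per chromosome (rather than
concatenating coordinates genome-wide) was a genuinely open choice; the
pooled form is the default and is what the calibration targets use. The
index is scale-invariant and needs no Monte-Carlo normalization:
uniform placement gives E[NNI] ≈ 1 (within 0.1 at n = 200), coincident
midpoints give 0, and perfectly regular spacing gives 2 exactly.

TDP⁺ requires NNI > 1 (WES) or > 1.25 (WGS) **and** median TD length
> 100 kb, both strict. Samples with fewer than two TDs on every
chromosome are unevaluable. Samples below 20% purity are excluded from
analysis entirely.

## TD size grouping

Lengths are modeled in log₁₀(kb). Mixtures with 1–4 components are fit
with EM (scikit-learn), 10 restarts from k-means initialization,
tolerance 1e-6, covariance regularization 1e-6; the BIC-optimal
component count is selected with ties broken toward fewer components.
Components with mixture weight ≤ 0.1 are discarded; an optional
variance ceiling exists but is off by default (the weight rule is the
defined filter; a variance rule without a stated threshold would be an
invention). Surviving means map to bins [0,2) → 1, [2,3) → 2, [3,4] → 3
log₁₀(kb), with boundary values assigned to the higher bin. Single bins
give Groups 1–3; {1,2} → 4, {1,3} → 5, {2,3} → 6. Three distinct bins
or no in-range mean yield no group, with a warning. At least 5 lengths
are required.

## HRd scars

LOH score = LOH-segment length / total segment length, both restricted
to retained arms; an arm is dropped when its *merged* LOH coverage
exceeds 75% of the arm length (merged coverage, rather than summed
segment lengths, makes the rule robust to segment fragmentation, and
the score itself is invariant to splitting any segment in two). The
denominator is covered segment length, not the full genome, so sparse
exome coverage does not deflate the score.

Signature exposures are obtained by non-negative least squares against
a column-normalized 96-channel reference; exposures are in mutation
counts. The HRd signature proportion is (SBS3 + SBS8)/n_SNVs; the call
is unevaluable at ≤ 50 SNVs and positive only above 0.05, both strict.
A pure-SBS3 mode is available. The package ships no COSMIC data: a
deterministic *synthetic* signature generator provides distinct sparse
profiles under the same column-stochastic contract, which is sufficient
for testing the fitting and gating logic; with real catalogs, users
supply the COSMIC reference as a TSV.

## Gene allelic status

Variant filters are exactly the inclusion rules listed in the README;
calls missing ClinVar/function annotations are excluded conservatively
with a warning. For copy number, segments with cellular fraction < 0.8
are dropped unless copy-neutral (total equals rounded ploidy) or total
> 4; the gene inherits the largest-overlap surviving segment. Ploidy
rounds half-up; X-linked genes use half the rounded ploidy as
denominator. Category boundaries: amplification ≥ 2.5 (inclusive), gain
≥ 1.5 (inclusive), homozygous deletion on raw total = 0, deletion-LOH
on normalized CN strictly within (0,1) with LOH, copy-neutral LOH at
normalized 1 (float-tolerant equality) with LOH.

Event counting: each retained mutation in the gene, plus one event for
deletion-LOH/copy-neutral-LOH, plus one for a gene-body-transecting SV.
Whether a transecting SV counts toward biallelic loss is not fully
determined by the calling rules alone; it counts by default and a
config switch excludes it. Homozygous deletion is BAL regardless of
other events and is reported as the reason when mutations co-occur.
Gene-flanking SV status (1 Mb flanks; translocation-like events must
point toward the gene body) is annotated for reporting but does not
count toward BAL/MAL.

## Cohort statistics

Window enrichment uses sample-level presence/absence per 50 kb window
(a sample counts once however many TDs overlap), a two-sided χ² test of
independence without continuity correction, and an automatic Fisher
fallback when any expected cell is < 5; Bonferroni over windows with
significance at adjusted p < 0.001. The TDP⁻ universe is restricted to
samples with more than one simple TD. Oncogene tests require full
containment of the gene in a TD; TSG tests require a TD boundary inside
the gene; both use two-sided Fisher with Bonferroni at adjusted
p < 0.01. Mutual exclusivity is a one-tailed Fisher test toward
depletion of co-occurrence. All exact tests are validated against
brute-force hypergeometric/permutation enumeration oracles in the test
suite.

## TD phylogenies

Within a patient, TDs merge into one catalog event when they
reciprocally overlap ≥ 0.9 of each other's width (single-linkage over
position-sorted events; deterministic and invariant to sample order; a
one-sided mode exists). The presence matrix yields Manhattan distances
(= discordant event counts) and a neighbor-joining tree with an
all-absent "normal" pseudo-sample as germline root. Cosmetic
branch-length styling is out of scope.

## Synthetic cohorts

The generator emits what the pipeline consumes, with truth records. Key
defaults and why:

- **Genome**: 8 chromosomes, 100–240 Mb, centromere at 40% — compact
  enough for fast tests while leaving multiple arms per sample.
- **TDs**: +1 copy over an integer-ploidy baseline, tail-to-head
  breakpoint pairs, lengths log-normal in log₁₀(kb) (default sd 0.25)
  around configurable modes; every TD satisfies the calling criteria by
  construction. Placement modes: `random` (uniform; NNI ≈ 1, used for
  calibration), `dispersed` (jittered regular spacing; NNI well above
  the WGS threshold, matching the strongly over-dispersed spacing of
  genuine tandem-duplicator genomes — uniform placement cannot exceed an
  NNI threshold of 1.25, so a distinct mode is needed to simulate
  positives), and `clustered` (a few 2 Mb windows; NNI ≪ 1). Placement
  is bounded rejection sampling (1000 retries) with deterministic
  failure rather than silent overlap.
- **TDP⁺ default**: 61–161 dispersed TDs with bimodal 230 kb / 1.7 Mb
  lengths, the observed per-tumor count range and canonical Group-6
  length profile for this phenotype; **TDP⁻ default**: a few dozen
  clustered ~30 kb TDs, failing both the NNI and median-length gates.
- **LOH**: explicit per-arm events plus dispersed fill to a target
  genome fraction, applied as minor-copy-zero overlays; the realized
  fraction is exact up to clipping and recorded in truth.
- **Mutations**: multinomial 96-channel draws from signature mixtures;
  emitted VCFs carry the channel index (INFO key TNC) so catalogs can
  be rebuilt without a reference genome (trinucleotide-context
  extraction is upstream annotation, outside this package).
- **Gene events**: snv/indel/benign/weak variants, hemizygous and
  homozygous deletions, copy-neutral LOH, and transecting SVs placed
  inside named genes, with intended BAL/MAL/Intact truth computed at
  generation time. TD/LOH/background-mutation placement keeps a 1.1 Mb
  guard zone around configured genes so gene truth is never perturbed
  by background events.

What the generator does **not** emulate: read-level noise, segmentation
error, subclonal copy-number mixtures, germline contamination, complex
rearrangements (chromothripsis/chromoplexy), or realistic trinucleotide
context. Passing tests therefore demonstrate the correctness of the
decision rules and statistics under clean inputs, not robustness to
caller noise — on real data, upstream segmentation quality dominates.

## Problem sizes and runtime choices

Test and acceptance runs use desk-scale sizes chosen once: 300 TD
lengths per size-group fit, 20 seeded replicates for NNI calibration
and signature-recovery checks, 20 replicates per canonical mode for the
group-recovery property, 50 + 50 simulated genomes for the TDP
confusion matrix, and toy 2×2/5-per-group tables wherever exact
enumeration oracles are the comparison. Deterministic seeds are used
throughout; identical config + seed reproduces outputs byte-for-byte.

## Known limitations

- The balanced/unbalanced distinction uses exact integer equality of
  flanking bin values; noisy real-valued bins would need a tolerance.
- Signature fitting is plain NNLS; it does not model the sparsity
  priors or per-sample signature pre-selection of dedicated assignment
  tools, so small exposures scatter more.
- Multi-sample patients get flagged-for-review output rather than any
  automated cross-sample call reconciliation (manual curation is out of
  scope).
- Cross-genome-build harmonization is the caller's responsibility; the
  build is metadata, never converted internally.
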