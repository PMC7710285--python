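# Methods

## Scope and data model

The package analyzes subjects with two tumor specimens — `pre` (biopsy
before systemic therapy) and `post` (resection after) — each with a somatic
variant table carrying read evidence (`ref_count`, `alt_count`) and a caller
confidence score, plus optional clonotype repertoires and expression counts.
It consumes caller output, not raw reads: MAFs are computed from the
reported read counts, and no re-pileup, realignment, somatic calling,
annotation or gene-level differential expression is performed.  Loci are
keyed by (chrom, pos, ref, alt) in 1-based VCF convention, so multiallelic
sites are distinct loci.

## Union-set MAF construction

A locus enters a subject's union when its caller quality is strictly above
the threshold (default 30, separately configurable for SNVs and indels) in
at least one sample.  For every (union locus, sample) pair the matrix then
records alt/(alt+ref) from that sample's read evidence, whether or not the
locus was called there.  A pair with no evidence row, or zero depth, is NaN
("missing"), deliberately distinct from MAF 0 with evidence; downstream
observation counts treat missing as unobserved.  Matrix construction is
invariant to input record order (samples are ordered pre-first, then by id;
loci sorted by key).

## Private/shared decomposition and tests

"Observed" means alt evidence ≥ `min_alt` (default 1, i.e. frequency
greater than zero; raise it to guard against sequencing noise).  Private =
observed in exactly one of the subject's samples; shared = in two or more;
loci observed nowhere are excluded from the union size, so private(pre) +
private(post) + shared = union size holds exactly for pairs.  The private
fraction divides by the pair's union size (the alternative per-sample
denominator is not used).

The pre vs post MAF distributions are compared with a two-sample KS test
(asymptotic p-values; the vectors hold hundreds of loci).  `shared_only`
mode restricts both vectors to loci with MAF > 0 in both samples.  What
this control does and does not do is worth stating precisely, and the test
suite demonstrates both directions: it removes the zero mass and
low-frequency tail contributed by private mutations (under
private-turnover-only simulations the all-mutations test rejects more often
than the control), but a genuine purity change rescales shared MAFs too and
moves *both* modes (shown by a pure purity-shift simulation, 0.8 → 0.5).
Because pre and post values at shared loci are positively correlated, the
KS test is conservative in both modes; the turnover-only experiment
(asymmetric private rates 0.4/0.1, purity held equal, no subclone
elimination, 200 replicates) yields modest absolute rejection rates
(≈ 3% vs ≈ 0.7% at α = 0.05), with the ordering stable.

Cross-subject clustering stacks all subjects' union loci; a sample's
feature vector holds its own subject's MAFs (missing → 0) and 0 at other
subjects' loci, a true statement that the sample lacks those mutations.
Euclidean distance, complete linkage; no variance filtering.  The pairing
score counts subjects whose two samples are sister leaves.  Trees are
exported as Newick with heights converted to branch lengths.

## Statistical primitives

All tests are two-sided.  Degenerate-input policy for the paired t test:
all-zero differences report p = 1 (no evidence of change); constant nonzero
differences report the limit p = 0 with ±∞ statistic; both carry a
`degenerate` flag so callers can report rather than propagate NaN.
Wilcoxon rank-sum uses the exact null distribution when n₁+n₂ ≤ 20 without
ties, otherwise the normal approximation with tie correction.  BH
adjustment follows the step-up rule (delegated to statsmodels; verified
against a literal brute-force implementation in the tests).
Clopper-Pearson intervals come from beta quantiles; percentages round half
away from zero to whole percent (8/21 → 38%).

## Repertoire measures

Clonotype identity is the exact CDR3 amino-acid string within one chain; no
clustering of near-identical sequences.  Entropy defaults to bits (base 2,
configurable); the pre/post entropy comparison is base-invariant up to a
constant factor, so conclusions do not depend on the choice.  Morisita-Horn
is computed on the clonotype union with zero fill; both the similarity and
its complement are returned because distance-oriented implementations
report the complement.  Public clonotypes are those present in ≥ 2 samples
(configurable).

## Expression signatures

Upper-quartile normalization scales each sample so the 75th percentile of
its *nonzero* counts (linear interpolation between order statistics) equals
a common target (1000).  Note the usual composition caveat: a large
perturbation concentrated in enough genes shifts the quartile itself and
leaks an opposite-signed artifact into unperturbed genes; the simulator's
counts are depth-matched, so calibration experiments score unnormalized
counts.  Signature scores are the mean over set genes of log₂(count + 1)
(pseudocount 1, configurable), or ssGSEA: rank genes descending per sample
(rank N at the top, ties broken by gene order), accumulate the difference
between the in-set ECDF weighted by rank^α (α = 0.25) and the uniform
out-set ECDF, and sum the running difference; scores are optionally
normalized by the overall score range.  Paired pre/post testing applies the
paired t per signature and BH across signatures.

## The synthetic cohort generator

The generator defines the conditions under which the pipeline is validated.

* **Burden**: per-subject target drawn from a normal (mean 190, sd 25)
  truncated to [100, 240], matching the scale of exome studies in this
  setting; 60% of mutations are truncal.
* **Clonal architecture**: 4 subclones share a subclonal mass drawn from
  U(0.6, 0.9) of tumor cells, split by a Dirichlet(3) to avoid vanishing
  clones; the truncal clone has fraction 1.
* **MAF model**: diploid heterozygous — true MAF = purity × clone
  fraction / 2, with no copy-number effect in the default generator (a
  separate binned-depth simulator with explicit copy states serves the
  copy-ratio checks).
* **Purity**: per-specimen draws from U(0.4, 0.8) — biopsy and resection
  cellularity differ in practice; the values are a modeling choice, not an
  estimate from any dataset.  `equal_purity` and explicit `purity_pre`/
  `purity_post` exist for controlled experiments.
* **Reads and calling**: depth ~ Poisson(100) per locus and sample; alt
  reads ~ Binomial(depth, true MAF); caller quality is a noisy logistic in
  alt-read count (midpoint 5 reads, scale 1.2, sd 4, max 100), so ~8
  supporting reads reliably clear the threshold of 30 while subclonal
  mutations are called with realistic unreliability — their read evidence
  remains queryable either way.
* **Treatment effect**: `selection_strength` eliminates that fraction of
  subclones (chosen uniformly at random) in the post specimen; survivors
  keep their cell fractions and the eliminated niche regrows from
  truncal-only cells.  Keeping survivor fractions fixed is deliberate: if
  survivors expanded instead, their private mutations would become easier
  to detect and partially mask the diversity loss the statistic measures.
* **Turnover**: independent (pre, post) rates (default 0.2/0.2) of
  specimen-private mutations per subclone; post-private mutations arise
  only in surviving subclones.  Symmetric turnover with zero selection is
  the null; asymmetric turnover with zero selection isolates
  "differences confined to private mutations".
* **Reproducibility**: each subject consumes an independent child stream of
  the master seed, so cohorts are bit-reproducible and subject-level
  results are stable under cohort-size changes.

Repertoires: clone frequencies follow a power law (exponent `dominance`),
counts are multinomial; a `shared_fraction` of clonotype identities is
common to all samples, spread across the abundance spectrum but occupying
the same ranks in every sample.  Expression: negative-binomial counts
(variance m + φm², φ = 0.1) around lognormal gene baselines with a
per-subject lognormal effect inducing within-pair correlation; post samples
multiply signature genes by 2^effect.  Dispersion 0 means noise-free counts
equal to their means (the NB limit would be Poisson, which is not
deterministic), used for closed-form checks.

What the generator does *not* emulate: copy-number and LOH effects on MAF,
sequencing error (alt reads at truly absent loci), mapping artifacts,
region-to-region sampling heterogeneity within a specimen, V/D/J biology
beyond CDR3 identity, and library-size variation in expression counts.
Passing tests therefore validate the pipeline's logic and statistical
behavior under a clean clonal model, not robustness to those artifacts.

## Problem sizes used in validation

The test suite and the reproduction script run cohorts of 1–5 subjects with
~190 mutations per tumor at depth 100; selection sweeps use 20 replicates
per level across {0, 0.25, 0.5, 0.75, 1}; the KS mode comparison uses 200
single-subject replicates; signature calibration uses 10 disjoint 20-gene
signatures in a 300-gene universe with 20 pairs, 200 null and 100 power
replicates.  These sizes give stable Monte-Carlo estimates for every
qualitative assertion while keeping a full run in minutes on one CPU.

## Known limitations

* The KS p-value is asymptotic and conservative under the paired-locus
  correlation; absolute rejection rates in the controlled experiments are
  small, and the documented claims are about orderings, not levels.
* The shared-only control cannot separate a purity change from a genuine
  clonality change that preserves observation status; it only removes the
  private zero mass.
* The private fraction depends on detection: deeper sequencing observes
  more low-frequency mutations and raises both samples' fractions.
* ssGSEA constants (α, range normalization) follow the common convention
  but are configurable; scores are comparable within a run, not across
  normalization choices.
* Kaplan-Meier survival estimation and gene-level differential expression
  are intentionally out of scope.
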