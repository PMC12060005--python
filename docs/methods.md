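# Methods

This note documents the models implemented in `chromland`, the design of
the synthetic-data generator that the test suite and `scripts/acceptance.py`
run against, the numerical choices that matter, and the known limitations.
Nothing here states an empirical result that the tests or the acceptance
script do not themselves compute.

## Binarization

Counts are summarised in fixed 200-bp bins (the last bin of a chromosome
may be truncated; it still counts as one observation but its true width is
used for per-bp arithmetic).  For each mark/sample, the binarization rate
is the genome-wide mean count per bin, `lambda_hat`; a bin is called
present when its count reaches the smallest integer `c` with
`P(X >= c | Poisson(lambda_hat)) < alpha` (default `alpha = 1e-4`,
computed from the exact tail, no fold-change fallback).  An all-zero track
binarizes to all zeros with a warning.

A consequence worth knowing: because `lambda_hat` includes the enriched
bins, marks that are *both* high-amplitude and high-occupancy push their
own threshold up, and the binarized signal saturates — the present/absent
call then under-reports the true per-bin enrichment probability.  At the
default sequencing depths (background rate 0.2–0.5, enriched rate 20 per
bin) the effect is negligible below roughly 15% genome-wide occupancy per
mark and grows quickly beyond it.  The planted emission matrices used in
the package keep per-mark occupancy under this ceiling; analyses of real
tracks with very broad marks should expect the same compression.

## Chromatin-state model

The hidden chain is first-order Markov per chromosome; emissions are
independent Bernoulli per mark.  Fitting is Baum–Welch EM with scaled
forward–backward (numba-compiled kernels; results independent of
chromosome length up to floating round-off).  Initial emissions are
seeded from randomly drawn observed bin patterns (softened toward 0.5),
which spreads the starting states over patterns actually present;
transitions start sticky (0.9 self).  The best of `n_restarts` runs by
log-likelihood is kept; convergence is a relative log-likelihood change
below 1e-5.  Emissions are clipped to [1e-6, 1 − 1e-6] and transition
rows floored at 1e-10 and renormalised.  Decoding is per-bin max
posterior (ties to the lower state index); Viterbi is available behind a
flag.  `K = 1` reduces to column means exactly.

### State-number selection

Models are compared by emission-vector correlation: every state of the
richest model is matched to its maximum-Pearson-correlation state in each
simpler model, and the median of those maxima forms a curve over K; the
chosen K is the smallest whose median reaches the 0.99 plateau.  Two
implementation choices matter:

* The simpler models are fitted by **agglomerative initialisation**: the
  (K+1)-state model with its two most-correlated states merged
  (occupancy-weighted), refined by EM.  Independent random restarts at
  each K make the curve non-reproducible, because the K−1 fit has
  several near-equal local optima ("merge two profiles" vs "re-cover the
  space differently") whose curve values straddle the plateau threshold.
  The nested initialisation picks the merge family consistently and is
  the standard way to traverse a nested model family.
* Near-flat emission vectors (std < 0.02) are compared by absolute
  closeness rather than Pearson correlation, which below that variance
  floor only measures fitting noise.

Two caveats are inherent to the procedure and documented rather than
patched.  First, the richest model distributes its surplus states by an
in-sample-likelihood lottery (amplitude or co-occurrence splits of
whichever profile); when too few surplus states duplicate the profiles
that the K−1 model merges, the K−1 median can sit above 0.99 and the
curve under-selects by one (about one seed in ten on the recovery bench).
Second, on featureless data EM finds likelihood-equivalent mixture
decompositions ("carving" bins on observed marks), so the curve is only
meaningful when the data contain genuine chromatin structure; on
signal-free input every fitted state is flat and the smallest K wins.

## Signatures

Marks carry fixed roles (active: H3K27ac, H3K4me3, H4K16ac, H3K36me3;
polycomb: H3K27me3; heterochromatin: H3K9me2/3).  A mark is *enriched*
in a state when its emission probability reaches `tau = 0.5`
(configurable; the value is reported with the output).  Categories:
only-active → active; only-H3K27me3 → polycomb; H3K9me2/3 (with or
without H3K27me3) → heterochromatin; at least one active and one
repressive mark → mixed; nothing → null.  The 16 signatures are the 15
non-empty subsets of {active, polycomb, heterochromatin, mixed} plus
null-only, numbered canonically so that the broad classes occupy fixed
ranges (S1–S7 repressive, S8–S14 mixed, S15–S16 active).  The
expression-based reclassification calls a signature active when its
genes' replicate-mean TPM is above the rest of the genome by a one-sided
rank-sum test at p < 0.05 (BH-adjusted values are reported alongside; a
one-sample signed-rank test against the genomic median is also emitted,
since independent gene sets admit both readings).  Signatures with fewer
than 3 genes are skipped and default to repressive, flagged.

## Sex bias and the open/closed model

The differential-expression rule is a moderated two-sample t on
log2(TPM + 0.5) with per-gene pooled variances shrunk toward the mean
replicate variance (prior df 4), BH correction, and the biased call
requiring adjusted p < 0.05 and fold change > 2; genes at or below
0.1 TPM in both sexes are filtered.  The pseudocount 0.5 avoids infinite
ratios and deliberately compresses fold changes of near-silent genes: a
four-fold change at 0.1 TPM is not callable at any depth, which is why
the generator plants bias only on transcribed genes.  The concordance
classification crosses the two sexes' binary chromatin classes; the
open/closed test is (a) a chi-square on the bias × concordance table and
(b) per-direction Fisher 2×2 of biased genes versus the matching
discordant class.  Under an independent null the chi-square rejects at
the nominal rate (calibration is asserted in the tests at 400
replicates).

## Dosage analysis

CPKM uses fractional bin overlap for "reads on gene" and the track total
as library size.  Region enrichment reports the S0:autosome ratio of
median CPKM and a two-sided rank-sum p per sex/tissue, on replicate
means and on each replicate separately (the replicate-consistency
check).  TSS metaprofiles are strand-aware, per-million scaled,
replicate-mean combined; positions outside the chromosome are excluded
from the mean rather than zero-padded.  The peak caller keeps maximal
non-zero runs whose AUC (value × bp) exceeds the (1 − f) linear-interpolated
empirical quantile of all block AUCs (default f = 0.01); it is invariant
to positive rescaling of the track.  The motif resampling null draws B
locus sets uniformly over the genome with the observed peak-length
multiset (loci may overlap; the statistic is the sum of occurrence
overlaps) and uses the add-one estimator, floor 1/(B+1).

## Ka/Ks

Nei–Gojobori (1986): per-codon synonymous site fractions averaged over
the two sequences; multi-hit codons average over all minimal mutational
pathways excluding those through stop codons; Jukes–Cantor correction
applied separately to the synonymous and nonsynonymous proportions
(undefined, flagged, at p ≥ 3/4).  Changes that create a stop codon
count as nonsynonymous in the site tally.  Gapped codon columns are
dropped; internal stops are an error; a shared terminal stop is dropped.
The estimator is symmetric and per-site (self-concatenation invariant).
The YN-style estimator with transition/transversion and codon-frequency
corrections is a possible extension; for distribution-level comparisons
between gene groups the counting method is sufficient.

## The synthetic generator

The generator is the package's study design: every dataset is a
deterministic function of (config, seed).

**Genome.** Five 4-Mb autosomes, a 4-Mb Z whose first half is the
Z-specific stratum "S0" (hemizygous in females) and second half the
pseudoautosomal region, and a gene-free 0.3-Mb W.  1,000 genes per
autosome, 139 in S0, PAR at autosomal density; lengths 1.2–1.8 kb with a
minimum intergenic gap of 600 bp (narrow lengths and guaranteed gaps
keep peak-calling order statistics driven by enrichment rather than gene
length variance or block chaining between adjacent genes).  30% of genes
carry a TE in the body interior ("intron"), 2% a TE at the body edge
("exon", excluded from TE analyses); flags are derived from the placed
TE intervals.

**Chromatin.** One state path per tissue is drawn from a sticky chain
(self-transition 0.95) whose stationary occupancy is repressive/null-heavy
(intergenic chromatin in a repeat-rich genome; active states hold ~5%);
65% of gene bodies are overwritten with one active state per tissue, so
transcribed genes look transcribed.  The default truth has 12 states
(4 active-dominated, 1 polycomb, 2 heterochromatin, 2 mixed, 2 weak
sub-threshold, 1 null); per-mark amplitudes are budgeted so binarization
does not saturate (see above), and the four active states share a common
H4K16ac amplitude — unequal amplitudes make the S0 median CPKM hop
between per-state clusters and destabilise the enrichment ratio.  Counts
are Poisson: rate 20 where the state's per-bin Bernoulli mark draw is
on, 0.2 otherwise (tagmentation background is sparse; a denser
background bridges signal blocks into multi-gene runs that crowd the
top-AUC quota).  Replicates redraw masks and counts from the same path;
H3K27me3 gets three replicates, other marks two.

**Sex effects.** Sex-biased genes (10% of autosomal+PAR genes, gonads,
half male- half female-biased, 4-fold) are planted on transcribed genes
only.  40% of biased genes (5% of unbiased) get sex-discordant
chromatin: the favored sex's gonadal path over the gene becomes an
active state, the other sex's a repressive one.  Expression follows the
gene's pre-discordance chromatin class (log2 TPM means 6 / 3.5 / 1 / −2
for active / mixed / repressive / null, gene effect SD 1, replicate SD
0.15 ≈ 10% CV), so chromatin–expression coupling holds genome-wide while
planted-unbiased discordant genes stay expression-unbiased.

**Dosage compensation.** Female S0 H4K16ac rates are multiplied by 2.0
(the compensation boost).  84/139 S0 genes ("peak genes", drawn from the
transcriptionally active pool) carry the mark as one uniform gene-body
block at rate emission × 20 — expectation-preserving, so the
female:male contrast stays at the boost, while each block is a
contiguous high-AUC run that the top-fraction caller can rank; S0 blocks
exist only in females, autosomal blocks (3% of genes) in every sample.
S0 gene expression is equal between the sexes in expectation
(compensated), with a 2× expression bonus for peak genes in both sexes.

**Motif.** Random uniform-composition sequence; the AT-rich consensus
TTATTTAT is planted at ~60 occurrences/Mb genome-wide (< 0.1% of bases),
optionally at a configurable extra factor across S0, and inside the
planted S0 peak loci until 6% of their bases are motif.  Overlapping
placements are dropped; positions and strands are recorded.

**What the generator does not emulate.** Read-level artefacts
(mappability, GC bias, fragment-length structure, duplicates),
overdispersed counts (Poisson, not negative binomial), exon/intron
structure (gene body = transcript span), W-linked genes, genuinely
continuous chromatin states, and any correlation structure between
marks beyond what the state path induces.  Passing tests on this
generator therefore demonstrate that the pipeline's inference and
statistics behave correctly under the planted model — not that the
defaults match any particular real library.

## Problem sizes in the bundled analyses

The state-recovery bench uses 5 autosomes × 10k bins with a five-state
truth (two high-occupancy "shades" of one active profile plus three
sharp single-mark profiles), background rate 0.5 and enriched rate 20,
five EM restarts, selection over K = 2..8.  The full synthetic study
(~24 Mb, ~5.6k genes, 60 tracks) runs in seconds; the acceptance script
completes in well under a minute on one CPU.

## Degenerate inputs and tie-breaks

Zero-variance coverage vectors raise an error in replicate correlation
(r undefined) rather than propagating NaN.  Posterior ties decode to the
lower state index.  Empty chromosomes are skipped with a warning in
segmentation.  A signature with fewer than three genes is not tested.
An all-zero track binarizes to zeros with a warning.  Fisher r-to-z
clips |rho| at 1 − 1e-15.  Zero-length intervals are unrepresentable by
construction (half-open, start < end).
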