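# Methods

## Scope and data model

The pipeline consumes aligned-read evidence, not reads: per-position base
counts with a forward/reverse strand split (the DP4 convention), gene-level
IP/input count matrices with a sample sheet, BED feature/region annotations,
VCF SNP masks, and Sanger peak-height tables. Internal interval coordinates
are 0-based half-open; pileup rows and VCF records are 1-based, matching
their formats. The pileup dialect is a versioned TSV rather than raw
`samtools mpileup` text — unambiguous to parse and byte-stable under
round-trips — and carries a header flag asserting that PCR duplicates were
removed upstream; a converter from classic mpileup text is provided.

## Binding: the ratio-of-ratios test

Binding enrichment is the interaction contrast (IP/input in condition A) ÷
(IP/input in condition B). Per gene we fit a negative-binomial GLM with
design `1 + assay + condition + assay:condition` and offsets equal to log
median-of-ratios size factors; the interaction coefficient is the natural-log
ratio of ratios. Genes with zero counts in all samples are removed as
non-expressed before testing. A fold shared by every gene is absorbed by
normalization, so enrichment is only identifiable for a minority of genes —
the intended regime for IP data.

Fitting is batched iteratively-reweighted least squares across genes (shared
design, per-gene dispersion), with step-halving on likelihood decrease;
non-converged genes are flagged and their p-values set missing.

**Dispersion.** Per-gene dispersion is estimated by Cox–Reid adjusted
profile likelihood (profile over a 25-point log-spaced grid in
[1e-4, 10] with quadratic refinement), then shrunk toward a mean–dispersion
trend α(m) = a₀/m + a₁ fitted by trimmed non-negative least squares over
moderately expressed genes. Shrinkage combines genewise and trend values in
log space with inverse-variance weights; the sampling variance of a log
dispersion estimate is taken as trigamma((n−p)/2) and the prior variance as
the squared MAD of trend residuals in excess of that, floored at 0.05 so the
weight stays finite when gene dispersions are effectively homogeneous.
Genewise estimates more than 2 SD above the trend are left unshrunk so
genuinely variable genes are not anti-conservatively pulled down. This
captures the moderation idea of the established count-model tools without
reproducing either tool's exact numerics (explicitly a non-goal); the
contract is set-level behaviour — null calibration and planted-signal
recovery — which the acceptance tests measure.

**Tests.** The `lrt` method compares full vs no-interaction fits at the
shrunk (MAP) dispersion by a χ²(1) likelihood ratio. The `qlf` method fits
at the trend dispersion and refers LR/s² to F(1, df), where s² is the
Pearson-based quasi-dispersion moderated with a moments-estimated prior df
(trigamma inversion), letting the quasi-dispersion absorb gene-level
variability. Multiple testing uses Benjamini–Hochberg step-up. A transcript
is bound when it passes both routes: log₂ RoR ≥ 0.5 (inclusive) with
adjusted p < 0.05, and adjusted p ≤ 0.05 on the quasi-likelihood route. The
LFC threshold is applied post hoc to the raw interaction estimate; no
shrinkage of the estimate is performed. For genes with an entire zero
(assay, condition) cell the reported point estimate adds a 0.5 half-count to
the normalized cell means; the fit itself never uses pseudocounts.

## Editing sites

**Strand logic.** On the annotation strand, editing is A→G; for genes on the
minus strand the reference-strand signature is T→C. Positions inside
annotated features use the feature strand; unannotated positions are
evaluated under whichever convention their reference base admits, taking the
higher alt fraction when both apply.

**Confidence.** The score is the posterior probability that the true editing
fraction exceeds the sequencing error rate, under a Binomial likelihood with
a Jeffreys Beta(1/2, 1/2) prior — i.e. the upper tail of
Beta(alt+½, ref+½) above the error rate. It is monotone in alt count at
fixed coverage and in coverage at fixed fraction. This is a transparent,
testable surrogate for dedicated editing-caller confidence scores, not a
reimplementation of any caller's generative model.

**Discovery filter.** A site is a candidate when, in *every* replicate:
informative (ref+alt) coverage ≥ 20 reads, confidence ≥ 0.99, and at least
2 alt reads; and the position is not in the SNP mask. The coverage criterion
counts informative reads (ref+alt), the DP4 total. Two auxiliary guards
handle artifacts the main criteria do not: the ≥2-alt-read rule blocks
single-read errors, and sites where non-ref/non-alt reads exceed 1% of
coverage *with more than one supporting read* are discarded (the >1-read
clause keeps one stray sequencing error from vetoing a site at moderate
coverage). Unmasked positions that look heterozygous — fraction within
[0.4, 0.6] at ≥ 50 reads in every replicate — are reported with an
allelic-balance warning rather than dropped, since genuine sites can be
edited near 50%.

**Quantification and differential calling.** Editing is alt/(ref+alt);
zero informative coverage yields an undefined marker, never 0. Only sites
with ≥ 20 informative reads in all replicates of both conditions are
analysed. Replicates are paired by index; per pair r, δ_r = 100 ×
(fraction_B,r − fraction_A,r) percentage points. A site is differential iff
every |δ_r| ≥ 5 (inclusive, with a 1e-9 guard against float representation
at the boundary) and all δ_r share a sign. A per-pair tally (the relaxed
k-of-n view) is reported alongside; pairs are never merged across
directions. An unpaired mean-difference mode exists for sensitivity analysis
and is not the default.

**Annotation and binding overlap.** Region labels follow the precedence
CDS > 3′UTR > 5′UTR > noncoding-exon > intron; positions outside transcript
features are intergenic and are excluded before binning differential sites
into {decreased, increased} × {bound, unbound} by host-gene membership in
the called bound set. Repeat-region intervals are region-set inputs for the
index, not transcript annotation.

**Editing index.** For mismatch X→Y over a region set: 100 × Σ(Y reads at
reference-X positions) / Σ(total reads at those positions) — a per-site
mismatch rate weighted by site coverage. Within minus-strand regions base
identities are complemented so A→G pools antisense T→C. The numerator and
denominator are additive over disjoint subregions, and each position counts
once even if intervals overlap.

## Sanger module

Percent editing is G/(A+G) × 100 from the two peak heights; case values are
normalised to control per replicate and summarised as mean ± SEM. Input is a
measured peak-height table; chromatogram parsing is out of scope.

## Synthetic data

The generator emulates the statistical structure of the real experiment with
full ground truth: a gene-per-contig reference in which each gene carries
5′UTR/CDS/3′UTR (optional intron) and, usually, an A/T-rich repeat region
standing in for an Alu element; heterozygous SNPs at a configurable per-base
density (excluded from repeat regions by construction); editing sites
planted on sense-strand adenosines with per-condition fractions; pileups
with Poisson depth, binomial editing signal, 50/50 strand split, and
symmetric substitution error at rate/3 per non-reference base; NB gene
counts whose expectation is baseline × library factor × (IP fold per
condition), with log-normal baselines; and noisy two-peak Sanger signals.

Defaults are the study conditions the tests run under: 3 biological
replicates, NB dispersion 0.05, planted ratio-of-ratios 4 for bound genes,
editing fractions uniform on [0.10, 0.60], differential effects uniform on
[0.10, 0.30] in fraction units (≥ 10 percentage points, the regime of
interest for a ≥ 5-point rule), 70% of differential sites decreased in the
effector condition, sequencing error 1e-3, mean coverage 100 (1000 for the
estimator-recovery and null end-to-end checks). Problem sizes (genomes of
tens of kilobases, 400–2000 genes) are chosen so every check runs in
seconds to a few minutes on one CPU.

What the generator does **not** model — and hence what passing tests do not
establish about real data: mapping and alignment artifacts, coverage
autocorrelation along transcripts (depth is independent Poisson per
position; real libraries are overdispersed and 3′-biased), hyper-edited read
clusters, homozygous-alt variants (they mimic reference error, orthogonal to
the logic under test), strand-biased error, PCR duplicates (assumed removed
upstream), and any dependence between binding and editing truth — the two
are planted independently, so the binding×editing bins exercise bookkeeping,
not biology.

## Numerical and degenerate-input choices

Fitted means are clipped to e^±30; batched linear solves add 1e-10 ridge;
dispersion bounds are [1e-4, 10]. Undefined quantities (zero informative
coverage, zero index denominator, zero-signal peaks) are marked undefined
(None/NaN), never coerced to 0. BH adjustment passes missing p-values
through. Empty pileups yield empty call sets, not errors; a missing design
cell, unequal replicate counts between conditions, mismatched gene
universes, and unannotated sites in the overlap step raise typed errors.

## Known limitations

The dispersion moderation and QL construction are principled approximations,
not replicas of DESeq2/EdgeR; per-gene p-values will differ from those tools
even where set-level behaviour agrees. The likelihood-ratio test at 12
samples and 4 parameters retains mild small-sample liberality (measured
~0.053 at nominal 0.05 under the null study conditions). The confidence
model treats reads as independent Bernoulli trials; correlated errors would
inflate it. The Poisson depth model is a stand-in for the unknown empirical
coverage distribution and is flagged for sensitivity testing; the
replicate-consistency rule's operating characteristics at threshold-scale
effects (|δ| near 5 points) depend strongly on coverage, as the per-pair
tallies make visible.
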