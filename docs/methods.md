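# Methods

This note documents the statistical models, the numerical choices and the
synthetic-data generator behind lactoseq, and states what the passing test
suite does and does not demonstrate about real data.

## Transcript classification

A transcript is an ordered chain of disjoint exons on one strand
(1-based, fully closed coordinates; half-open arithmetic never leaves a
function). Class codes are assigned against a reference annotation by a
fixed priority:

1. `=` — identical intron chain on the same strand (single-exon pairs:
   identical coordinates, since there is no chain to compare);
2. `j` — multi-exon query sharing at least one identical intron
   (both boundaries, same strand) with a reference transcript;
3. `x` — any query exon overlapping any reference exon on the opposite
   strand;
4. `i` — query span fully inside a single intron of a same-strand
   reference transcript (opposite-strand intronic queries fall through:
   antisense overlap is what `x` is for, and an intronic query on the
   other strand overlaps no exon);
5. `u` — the query span overlaps no reference transcript span;
6. `other` — overlaps a reference span without satisfying any rule
   (e.g. a single-exon fragment inside a same-strand exon); discarded
   downstream.

The priority order resolves multi-rule matches deterministically; the
matched reference id is the lexicographically first among candidates, so
results are independent of storage order. Positional lncRNA subclasses
are a pure function of the class code: u → lincRNA, i → ilncRNA,
x → lncNAT, j → isolncRNA.

## Discovery cascade

Presence (count > 0 in ≥ 2 libraries; "detected" means a single mapped
fragment), abundance (FPKM ≥ 0.3 in ≥ 1 library; FPKM uses spliced length
and, by default, column totals of the full count matrix — an override
accepts externally counted library totals), class code (`=` becomes
"known" and bypasses the novelty filters), structure (spliced — not
genomic — length ≥ 200 bp and ≥ 2 exons), ORF, consensus coding call.
Thresholds (0.3 FPKM, 200 bp, 120 aa, Pfam E 10.0) are exposed as flags.

The ORF scanner finds the longest complete ATG→stop frame among the three
forward frames (stranded library preparation; a six-frame flag exists for
unstranded data). Length in amino acids counts codons from the ATG
inclusive to the stop exclusive. This is a deliberately simple scanner,
not a TransDecoder re-implementation: it has no coding-likelihood model,
so on real sequence it will call ORFs that TransDecoder would reject.
The ≥ 120 aa rule short-circuits the consensus vote; PLEK or CNIT scores
of exactly 0 satisfy neither the coding nor the non-coding rule and the
transcript is discarded as ambiguous.

## Differential expression

Size factors are plain median-of-ratios over all-positive rows (a
positive-counts fallback handles matrices without an all-positive row).
Size factors are identified only up to a common constant — they enter the
GLMs as offsets — so the meaningful invariance is that scaling one
library scales its factor relative to every other library.

Each transcript is fitted by a negative-binomial GLM (variance μ + φμ²,
log link, offset log sᵢ) under four nested designs — full
(Type + Parity + Type×Parity, 8 columns when all four parities are
present), additive, parity-only, type-only — with treatment coding
(colostrum, parity 1 reference). Effects are tested by likelihood ratio:
interaction (full vs additive), milk type (additive vs parity-only),
parity (additive vs type-only). The reported log₂ fold change for milk
type comes from the additive model so it remains interpretable when the
interaction is absent. The dam is not modelled (fixed-effects analysis of
a paired design); p-values are therefore exact for the marginal design
only.

### Dispersion

Per-transcript dispersions at a handful of samples per design cell are
the crux. The package estimates them in three layers:

1. **Raw method of moments.** Normalized counts are residualized against
   the design-cell (milk-type × parity) means; per cell, the unbiased
   variance minus the shot-noise term μ·mean(1/s) estimates φμ², and the
   squared cell mean is debiased by its own sampling variance before
   entering the denominator. This estimator is approximately unbiased but
   very noisy at 2–3 samples per cell (it is also exported as
   `estimate_dispersion`, and is accurate at the full 130-sample design).
2. **Trend.** Transcripts are binned by base mean (10 equal-occupancy
   bins); per bin, a Cox–Reid adjusted profile likelihood over a
   dispersion grid gives a far more efficient common-dispersion estimate
   than pooling the moment estimates. The per-bin values are then pooled
   through the parametric form φ(μ) = a/μ + b (non-negative least
   squares), which averages away per-bin estimation noise.
3. **Moderation.** Each raw log dispersion is shrunk toward the trend
   with a weight derived from the excess of its squared log-residual over
   the estimator's sampling variance. That sampling variance is not
   approximated analytically but measured by Monte Carlo: flat-expression
   NB transcripts are simulated at the bin's expression level and the
   trend dispersion under the actual design (fixed internal seed, so the
   result is a deterministic property of the design). When the transcripts
   genuinely share one dispersion the excess is ~0 and the trend
   dominates; heterogeneous dispersions keep most of their per-transcript
   weight.

This is moderation in the spirit of DESeq2/edgeR but it is not either
package: no Cook's-distance outlier handling, no independent filtering,
and the prior variance is a single global scalar rather than a fitted
distribution. `fit(dispersion="per_transcript")` disables moderation.

### Finite-sample correction of the LRT

With 24 samples and up to 8 fitted parameters the LRT statistic is
stochastically larger than its χ² reference (the classical Bartlett
phenomenon); uncorrected, the interaction test rejects a true null at
~0.06–0.07 instead of 0.05. The package estimates the null expectation of
each statistic by simulating flat-expression NB transcripts under the
actual design at three expression levels (batched IRLS makes thousands of
replicates cheap; fixed internal seed) and divides each observed statistic
by the interpolated expectation/df ratio. After correction the three
tests reject a simulated null at 0.043–0.060 across seeds (binomial
band ±0.010 at 1,750 null transcripts); a residual ~0.003 excess remains
for the df-3 interaction test, a known limit of mean-matching a
heavier-than-χ² tail. `fit(bartlett=False)` disables the correction.

### Multiple testing and partitions

BH step-up per effect; absent p-values (all-zero rows, failed fits) pass
through as missing and do not count toward m. DET: interaction
FDR ≤ 0.01; type FDR ≤ 0.01 and |log₂FC| ≥ 2, minus interaction DET;
parity FDR ≤ 0.01, minus interaction DET — no fold-change rule for
parity. Gene-level DEG: FDR ≤ 0.01; the milk-type set excludes
interaction DEG and genes with |log₂FC| ≤ 1.5.

## Lancaster aggregation

T = Σ φ⁻¹_{wᵢ}(pᵢ) with φ⁻¹ the **upper-tail** Gamma(wᵢ/2, scale 2)
quantile; T ~ χ²(Σwᵢ) under the null. The upper-tail reading is forced by
the Fisher special case: at w ≡ 2 the transform must be −2 ln p, and the
lower-tail quantile fails that identity. Weights are the transcript base
means, used raw (no normalization). Pairs with zero weight or missing p
are dropped before summation; a gene with nothing retained is reported
undefined (NaN) and excluded from BH rather than silently set to 1.
P-values are clipped to [1e−300, 1] before the quantile transform. A
single-transcript gene reproduces its transcript p exactly for any
positive weight (Gamma(w/2, 2) ≡ χ²(w)).

Gene log₂ fold changes cannot come from the aggregation (it only combines
p-values), so they are computed by summing transcript counts per gene and
fitting the additive-model NB type coefficient, with gene-level moment
dispersions.

## Composition, enrichment, power

Composition uses raw counts ("reads mapped"), no length correction; a
sample with zero marker reads is undefined and excluded from group means
rather than imputed. The shipped 15-marker panel keeps the symbol
"SL100A4" as printed in its source table, with an S100A4 alias accepted
on input. Enrichment is the hypergeometric upper tail including the
observed overlap, BH across terms; the default background is the set of
genes surviving the expression filters, overridable.

Power iterates α = f·m₁·power / ((m−m₁)(1−f)) — the marginal-FDR
identity solved for the per-test level — against two-sided Wald power
with SE² = (1/n)[(1/μ₀ + φ) + (1/(ρμ₀) + φ)] until the power changes by
< 1e−6. This replaces an exact NB test with a Wald approximation; at the
design point of interest (n = 65/group, ρ = 2.82, φ = 0.5, μ₀ = 10) the
power is ≈ 1 − 5·10⁻⁷ and the ≥ 0.99 conclusion is insensitive to the
approximation. Groups are assumed equal-sized, reading "65 animals" as 65
paired sample pairs. μ₀ defaults to 10 (a typical minimal average read
count for a gene considered expressed) and is exposed as a flag.

## Synthetic data

The generator's defaults mirror the target study: 65 dams (16/25/15/9 in
parities 1–4), each sampled at day 0 (colostrum) and day 10 (milk); NB
dispersion 0.5 (the study's assumed maximum); differentially expressed
fraction 0.056 for milk type (~1,000 of 17,740) and 0.03 each for parity
and interaction, with log₂ fold-change magnitudes drawn uniformly from
[1.5, 4] (type; the study's minimum detectable fold change 2.82 is
log₂ ≈ 1.5 and its DET threshold is 2), [1, 2.5] (parity) and [1.5, 3]
(interaction), random signs, and mutually exclusive effect assignment so
each transcript has one unambiguous truth label. Baselines are log-normal
(σ = 1.5, floor 10) scaled to ~2 M fragments per library; library factors
are log-normal (σ = 0.15).

Class codes are guaranteed constructively (copy a chain for `=`; drop a
terminal exon for `j`; mirror exons to the opposite strand for `x`; drop a
two-exon transcript into a widened first intron for `i`; place it in an
intergenic gap with margin for `u`), as are filter failures (a
presence-fail row is forced to one nonzero library; an abundance-fail
transcript is built ~8.5 kb long with two single-fragment libraries, so
its FPKM sits far below 0.3 at realistic totals). Sequences use a C/G/T
background with a single planted ATG…stop, so the planted ORF is provably
the only one and the scanner recovers its length exactly. Coding evidence
agrees with the planted status with probability *a*; a disagreeing
transcript has one classifier flipped (and any Pfam hit removed), which
makes the consensus ambiguous by construction.

What the generator does **not** emulate: positional read biases, multi-
isoform quantification uncertainty (counts are drawn independently per
transcript, with no shared-read ambiguity between isoforms of a gene),
dam-level random effects (samples are paired in the design sheet but
statistically independent), GC/length effects on counts, realistic
splice-graph complexity, and real sequence composition. Passing tests
therefore demonstrate correctness of the implemented rules and
calibration under the stated model — not robustness to quantification
noise or within-dam correlation.

## Scaled problem sizes

The test suite runs the DE calibration/recovery check at 12 dams
(3/3/3/3, 24 samples) × 2,000 transcripts and the discovery-funnel check
at 2,000 queries — sizes chosen so the full suite completes in about a
minute while keeping Monte-Carlo bands tight enough to be meaningful.
The full 65-dam design is the generator default and runs unchanged.

## Known limitations

* Fixed-effects analysis of a paired design: within-dam correlation is
  ignored, as in the analysis being reproduced; with strong dam effects
  real-data p-values would be optimistic.
* The interaction LRT retains a small (~0.003) excess rejection after the
  Bartlett correction at 24 samples.
* Moderation assumes a unimodal dispersion distribution around the trend;
  a contaminated mixture (e.g. a subpopulation of highly variable
  transcripts) would be over-shrunk.
* The ORF scanner and the consensus rule consume externally computed
  coding-potential scores; the package does not run CPC2/PLEK/CNIT/HMMER.
* Enrichment reproduces the over-representation statistic only; curated
  term databases and pathway-impact analyses are out of scope.
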