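# Methods

## Study design assumed throughout

Two conditions are compared: yolk-depleted (YD) and sham-punctured (SP)
zebrafish embryos.  RNA-seq time points use a paired design — each of three
embryo batches contributes exactly one YD and one SP library — and the
loader treats any other layout as an error.  The microarray time point uses
3 YD and 3 SP arrays; the default scoring path asserts this 3 + 3 design
(other designs can be loaded with `strict_design=False`, but the pairwise
median scoring itself requires 3 + 3).

## RNA-seq differential expression

**Expression filter.**  A gene is analyzed when its maximal count over all
samples of the time point is strictly greater than 5 (so a maximum of
exactly 5 is excluded).

**Normalization.**  Median-of-ratios size factors: the reference is the
per-gene geometric mean over samples, restricted to genes with no zero
count; each sample's factor is the median ratio to the reference, rescaled
so the factors' geometric mean is 1.  TMM-style weighting is deliberately
out of scope.

**Test.**  A conditioned negative-binomial exact test.  Per gene the
dispersion φ is estimated by moments from the within-condition pooled
variance of normalized counts, `(var − μ)/μ²`; raw estimates (which may be
negative at low counts) are averaged within ~20 equal-occupancy abundance
bins and the bin mean is floored at 1e−8.  Averaging before flooring
matters: flooring each gene first inflates the shared estimate and makes
the test conservative.  Given the rounded normalized group sums `a + b = s`,
the two-sided p-value sums the conditional probabilities of all splits no
more likely than the observed one, with group sums modelled as
NB(mean `n_g·μ₀`, dispersion `φ/n_g`), `μ₀ = s/(n_A+n_B)`.  For `s` beyond
20,000 the pmf is evaluated only on a ±25-SD window (plus the observed
split); outside mass is far below double precision.  The effect reported is
`log2((mean_YD + 0.5)/(mean_SP + 0.5))` on normalized counts; the 0.5
pseudocount avoids division by zero.

**Selection.**  Benjamini–Hochberg step-up adjustment; a gene passes at
FDR strictly below 0.05 *and* when the normalized YD − SP difference has
the same non-zero sign in every batch.  A zero difference counts as
inconsistent: "consistently up or down" requires a sign.  The consistency
rule uses normalized counts; raw counts would conflate library size with
direction.

Under null simulations (2000 genes, three batches, dispersion 0.1) the raw
p-values are approximately uniform (fraction below 0.05 within 0.05 ± 0.01
across seeds) and the full caller passes ≤ 2 genes — these calibration
properties are asserted in the test suite, not merely assumed.

## Microarray differential expression

Probes are kept when flagged reliable on strictly more than 2/3 of arrays
(≥ 5 of 6).  Quantile normalization maps every array onto the mean of the
sorted intensity vectors; ties within an array receive the average of the
quantile means their positions span, which makes the operation idempotent
to floating-point precision.  Probe intensities are averaged per transcript.

Per transcript, the intensity score is the mean of the YD-median and
SP-median intensities, and the DE score is the median of the nine pairwise
YD − SP differences.  Transcripts are ordered by descending intensity score
(ties broken by transcript id for determinism) and each DE score is
standardized by the mean and sample SD (n − 1) of the window of 65
transcripts centred on it.  Design choices where the procedure was open:

- the focal transcript is included in its own window, and windows are
  clamped at the edges so every window holds exactly 65 members — this keeps
  the window size constant everywhere;
- sorting is by intensity with the Z computed on DE scores; normalizing the
  DE score against its intensity neighbourhood is the reading that yields an
  intensity-dependent null model, which is the point of the statistic;
- a window with zero SD yields z = 0 and is flagged degenerate rather than
  raising;
- p-values are two-sided standard-normal tails of z — the conventional
  reference absent a stated empirical null.

Selection is at BH FDR strictly below 0.1.  On simulated arrays whose noise
SD grows linearly with descending intensity rank, the windowed Z rejects at
a rate closer to nominal than a single global Z — the property that
motivates the statistic — and this is asserted over ten seeds.

## Enrichment

Hypergeometric upper tails `P(X ≥ k)` are computed through the survival
function in log space (stable at p ≈ 1e−7).  GO enrichment tests only
molecular-function terms annotating at least two DE genes, with the universe
being the genes passing the expression threshold (not the whole genome), and
BH selection at FDR < 0.05.

The permutation overlap test replaces the DE list with B = 1000 uniform
without-replacement samples of the same size from the universe of all DE and
non-DE identifiers; `p = #(null ≥ observed)/B`, reported as `< 1/B` when no
null draw reaches the observed overlap (stored as 0.0).  When several
time-point DE lists feed one test, their identifier union is used.  The
packaged 20-gene methionine-cycle target includes all methionine-cycle
enzymes plus the DNA/RNA methyltransferases and excludes creatine kinases.
The cross-species variant reverses the sampling direction — the mouse DE
list stays fixed and B random 12-symbol sets are drawn — matching how a
homologue set of fixed size is judged against an existing DE call.

## CpG density

CpG (5′-CG-3′) counts use a position scan; CG cannot overlap itself, so scan
and non-overlapping counts coincide.  Matching is case-insensitive and `N`
never matches (sequences containing characters outside `ACGTN` are
rejected).  DE-gene counts are projected onto the all-gene ECDF
(`F(x) = #{all ≤ x}/n`) and compared with a two-sample two-sided KS test
(asymptotic p).  Windowed profiles count CpGs in consecutive 500-nt windows
from the 5′ end; the final partial window is dropped and a CG spanning a
window boundary is not credited, keeping windows strictly comparable.  The
default promoter span in the generator is 2500 nt (a 2000-nt upstream +
500-nt downstream convention around the TSS); real promoter extraction is
out of scope — sequences arrive pre-extracted in FASTA with
`gene_id|region` headers.

## qPCR helper

Per sample, a gene's normalized value is Cp(gene) minus the mean Cp of the
actb2 reference in that sample; groups are compared with an unpaired
two-sided Student's t-test (pooled variance).  Identical groups return
t = 0, p = 1 rather than a 0/0.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the analysis relies
on: NB counts (gene base means log-normal, `exp(N(4, 1.5²))`, median ≈ 55
counts; dispersion 0.1; multiplicative batch effects, log-SD 0.1); array
log-intensities `N(8, 2²)` with per-transcript noise SD
`0.25·(1 + slope·rank_frac)` rising toward dim transcripts; i.i.d.
Bernoulli(0.95) reliability flags; 30 % of transcripts carrying 2–4 probes;
uniform i.i.d. ACGT sequences whose designated "depleted" genes have each
CG thinned to survive with probability equal to the depletion factor, so
their expected CpG count is exactly factor × background.  Default universe
size is 15,000 genes, inside the 13,170–20,709 range of expressed genes per
time point; embedded set sizes are 28 (apolipoprotein-like) and 20
(methionine-like); the mouse table flags 7 of the 12 homologue symbols by
default with a 5 % background DE rate.

Not emulated: read-level sequencing artefacts, GC/length biases, probe
sequence effects, correlated gene–gene expression, realistic dinucleotide
composition, and any genuine biology linking the embedded gene sets to the
spiked DE genes.  Passing tests therefore demonstrate that the *procedures*
behave as specified under their own assumptions — calibration under the
null, power against known spikes, exactness of the combinatorial tails —
not that the biological conclusions transfer to real data.

## Problem sizes and numerical conventions

Simulation-based tests run at 500–2,000 genes (15,300 for the CpG KS power
check, matching the study-scale universe) with 5–10 seeds per property;
permutation tests use B = 200–50,000 depending on the granularity the check
needs.  All thresholds are strict inequalities (FDR < 0.05, FDR < 0.1,
count > 5, flags > 2/3).  Every generator and permutation draw is seeded;
identical seeds give byte-identical output files, and a run's manifest
records every threshold and seed needed to reproduce it exactly.

## Known limitations

- The NB exact test is a self-contained stand-in for a GLM-with-blocking
  analysis; batch structure enters only through the consistency filter, so
  strong batch effects inflate the dispersion estimate and cost power
  rather than causing false positives.
- The normal reference for the window Z is an approximation; heavy-tailed
  DE-score windows would make tail p-values optimistic.
- Permutation p-values have resolution 1/B; at B = 1000 "p = 0" means only
  p < 0.001.
- GO terms are treated as a flat list; no DAG propagation.
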