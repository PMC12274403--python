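# Methods

## Read-level mixture model

A read (or stitched molecule) over a gene covers `n` convertible reference
positions — T for plus-strand genes, A for minus-strand genes — of which
`k` are read as the specific mismatch (T→C, resp. A→G). Every convertible
position on a *labeled* read mismatches with probability `p_c + p_e`
(conversion or error), on an unlabeled read with probability `p_e`. For a
gene whose new-RNA fraction in the sample is `π`:

    P(k; n, π) = π·B(k; n, p_c + p_e) + (1 − π)·B(k; n, p_e).

The labeled-component rate is `p_c + p_e`, not `p_c`; `p_c` is always
reported net of error. A corollary used in the tests: the model is
non-identifiable exactly when `p_c = 0` (the two components coincide), in
which case the π posterior equals the prior.

Assumptions: positions within a read convert independently with a common
rate; reads are conditionally independent given π; `p_c` and `p_e` are
constant within a sample (no per-position or quality-stratified error
model — a deliberate non-goal).

## Conversion counting

`io.count_conversions` walks alignments with pysam, reconstructing the
reference per read from the MD tag (`get_aligned_pairs(with_seq=True)`),
so no genome FASTA is needed. Positions in insertions, deletions and
soft-clips are excluded; bases with quality below 20 (configurable) are
excluded from both `n` and `k`. Gene assignment is read from a per-read
tag (default `GE`); alignment and assignment are upstream concerns. All
twelve mismatch classes and per-base coverages are accumulated by gene
strand into a `MismatchProfile`. No SNP masking is applied by default; a
(chrom, position) blacklist is accepted. Internal coordinates are 0-based
half-open everywhere; BED is read natively, GTF (1-based inclusive) is
converted at the boundary, with one TSS/TES per gene (most upstream /
downstream in transcription direction across transcripts).

## Error and conversion rates

`p_e` comes from strand symmetry: the specific conversion class observed
on the opposite strand (T→C on minus-strand genes, A→G on plus-strand
genes) cannot be 4sU-induced, so its pooled rate is a direct error
estimate that needs no 4sU-free control. The single-cell default instead
averages the complementary C→T and G→A rates. Both agree under a
symmetric error process (tested).

`p_c` is fitted by EM on the two-component mixture with `p_e` held fixed
— re-estimating `p_e` jointly is poorly identified at low labeled
fractions, and the pipelines estimate it separately anyway. The E-step
computes per-read responsibilities; the M-step sets the global labeled
fraction to the mean responsibility and
`p_c = max(0, Σr·k / Σr·n − p_e)`. Initialization: π₀ = 0.1 and p_c,₀ the
pooled k/n among reads with k ≥ 2 (such reads are almost surely labeled
at realistic error rates), floored at 10·p_e. Convergence at
|Δlog-likelihood| < 1e−8, at most 1000 iterations; ascent is asserted
every iteration (tolerance 1e−9 for rounding). Reads with n = 0 are kept
in tables but excluded from EM by default. With no converted read at all,
`p_c` is unidentifiable and flagged, with the labeled fraction reported
as 0.

## Posterior for the new-RNA fraction

With a uniform prior, the π posterior for a gene is proportional to the
product of read likelihoods. Two backends satisfy one contract:

* **grid** (the oracle): joint log-likelihood on 10,001 uniform grid
  points, log-sum-exp normalization, posterior mean and equal-tailed 95%
  interval by interpolated quantiles of the discrete distribution. Cost is
  independent of read count after collapsing reads to unique (n, k) pairs.
* **mcmc**: one seeded chain of random-walk Metropolis on logit(π), with
  the Jacobian term added so the prior stays uniform on [0, 1]; 1,000
  burn-in plus 5,000 kept iterations from an initial value of 0.1
  (defaults, configurable). The proposal scale adapts toward 44%
  acceptance during burn-in only, so kept samples use a fixed kernel.
  The contract — posterior mean within 0.01 and interval endpoints within
  0.02 of the grid for genes with ≥ 50 reads — is what the tests enforce;
  sampler internals are otherwise free.

Data rules applied before inference: genes with more than 5,000 reads are
downsampled to 5,000 uniformly without replacement, seeded from (global
seed, sample, gene) so partial reruns reproduce; genes with no converted
read short-circuit to π = 0 (flagged); genes with no reads produce no
estimate. The derived "new" expression layer is total abundance × π.

Calibration: under prior-matched simulation the equal-tailed interval is
exactly calibrated by construction of the posterior; the acceptance
script measures this at 500 genes × 2,000 reads. Accuracy improves with
read count (RMSE strictly decreasing across 10 → 100 → 5,000 reads in the
acceptance suite).

## Molecule-level calls

Each molecule is tested H0: p = p_e against HA: p = p_c (p_c > p_e
required). Because the likelihood ratio is monotone in k, the
non-randomized Neyman–Pearson test rejects iff k ≥ k*(n), the smallest
count whose upper binomial tail under H0 is ≤ α = 0.05. The test is
conservative (size ≤ α); molecules with n = 0 are called old. Per-cell
new fractions and new/old count matrices (the bursting input, and the
export format for count-based DE tools) are derived from the calls.

## Sample QC

Mini-bulk (suspension-cell) samples pass iff total reads ≥ 200,000,
exonic fraction ≥ 45% and SNR = p_c/p_e > 10 (strict; p_e = 0 gives
infinite SNR, which passes). The adherent-cell drug-panel QC fails
samples with exonic fraction < 45%, reads < 1,000,000 or median credible
interval width ≥ 0.4, and drops entirely any drug left with fewer than
three passing replicates. QC is monotone: improving a metric never flips
pass to fail (property-tested). Single-cell QC thresholds are
configurable with no fixed defaults.

## Differential expression (mini-bulk)

Expression unit: log2(CPM + 1) of the new-RNA layer (the screen's
conclusions are about new RNA; raw/untransformed input is supported).
Exactly three treated replicates are compared against 10 DMSO controls
drawn without replacement from the pool, independently per compound,
seeded from (seed, compound). Because three replicates estimate variance
poorly, the mean-variance trend across genes is fitted (lowess, span 0.3;
linear available) on the pooled per-group (mean, variance) points, and
each group's variance is floored at the trend's prediction for its own
mean. Welch's t on the floored variances (robust to the asymmetric
3-vs-10 design) gives two-sided p-values; flooring can only inflate
variances, hence never shrinks p (property-tested). Across genes the
two-stage Benjamini–Krieger–Yekutieli linear step-up FDR is applied: a
first BH pass at α/(1+α) estimates the number of true nulls m0, then the
step-up runs at the rescaled level; reported q-values satisfy q ≤ α iff
the procedure rejects (when the first pass rejects nothing or everything
the m0 estimate is uninformative and m is used, the standard convention).

## Dose-response and response clustering

Per gene and drug, log2 new expression is regressed on log10(dose in nM)
across the five-dose grid (1 nM – 10 µM); untreated controls enter at a
pseudo-dose one decade below the lowest dose (0.1 nM), so "no response"
remains a flat line through the controls. Slopes are tested by two-sided
t (n − 2 df) with two-stage FDR across genes per drug. Drugs are
clustered on their gene-slope vectors with average linkage on
1 − Pearson r, cut at r = 0.33; constant-slope drugs have undefined
correlation and are dropped with a warning.

## Promoter and region enrichment

The promoter window spans 1,000 bp upstream to 100 bp downstream of the
TSS in transcription direction — width 1,100, 0-based half-open,
truncated at the chromosome start. Peak overlap requires ≥ 1 bp. Per
factor, the 2×2 table of up/down-regulated genes with/without a promoter
peak is tested with the two-sided Fisher exact test computed by exact
hypergeometric enumeration (p = sum of all tables with probability ≤ the
observed one, the standard two-sided convention); fold change is the
ratio of peak-containing fractions; BH correction across factors at 5%.
Degenerate tables (peak margin zero or full) are skipped with a reason.
The region scheme for histone-mark style analyses (our definition,
configurable) adds gene body (TSS+100 → TES) and downstream (TES →
TES+1000) windows and reports nominal plus adjusted p-values.

## Expression-matched GO overrepresentation

To avoid expression bias, backgrounds are matched by expression rank: for
each study gene, the search alternates up/down the ranking to the nearest
unused non-study gene, giving up beyond a rank distance of 100; if more
than 10% of the study set becomes unmatchable the matching aborts with a
warning. Per GO term the study/background 2×2 table is tested with
chi-square (no continuity correction) when all four expected counts
exceed ten, otherwise Fisher exact; obsolete ontology terms are excluded
from the universe; two-stage FDR across terms (the exploration-level
threshold, e.g. 50%, is a parameter). Comparing down- vs up-regulated
genes is the same call with the other set as background.

## Bursting kinetics

Labeled counts per cell at the end of a labeling window t are modeled by
the telegraph promoter: ON/OFF switching k_on/k_off, synthesis k_syn in
the ON state, first-order degradation k_deg. At labeling onset the
labeled count is zero and the promoter is at its stationary occupancy
k_on/(k_on + k_off) — the physically forced initial condition, since 4sU
addition does not perturb the promoter. The likelihood is the transient
master-equation solution on states (promoter, count 0..N), computed by
sparse matrix exponential; synthesis outflow at the truncation boundary
is allowed to leak so the mass deficit plus the boundary probability is
exactly the truncation error, and N doubles until that error is below
1e−8 (error if a cap of 20,000 states is reached).

Identifiability at realistic cell numbers forces two rates to be fixed:
k_off = 100/h (the typical fibroblast off-rate; k_off varies least
transcriptome-wide, whereas k_syn tracks burst size) and a dataset-level
k_deg = −ln(1 − fraction_new)/t from the median per-cell new fraction
(≈ 0.065/h at the 3–6% new-RNA fractions seen after 0.5–1 h labeling).
Maximum likelihood estimates (k_on, k_syn) by Nelder–Mead on log
parameters (bounds k_on ∈ [1e−4, 1e4], k_syn ∈ [1e−3, 1e7] as penalties)
from a moment initialization. The fast moment estimator used for
initialization and for permutation statistics: in the bursty regime the
Fano factor exceeds 1 by the mean burst size, so
b = max(var/mean − 1, 0.01), k_syn = b·k_off, and
k_on = mean/(b·t_eff) with t_eff = (1 − e^(−k_deg·t))/k_deg the
survival-weighted window. All-zero genes are flagged unidentifiable.

Condition comparisons permute cell labels (default 1,000 permutations,
add-one p-value convention so p is never zero) on differences of the
*fast* burst-frequency/size estimates, BH-corrected at 5% separately per
metric; significant genes are then re-fit by full ML in both conditions
and kept only if the direction of change survives refinement. Burst
frequency 1/(1/k_on + 1/k_off) and burst size k_syn/k_off.

## Synthetic data: what it emulates and what it does not

The generators reproduce exactly the statistical structure the inference
assumes: the read generator draws labels per read and conversion counts
from the two binomial components; per-read convertible-position counts
default to uniform on [20, 200] (spanning the T-content of realistic
100–150 bp reads; configurable); the telegraph simulator is an exact
event-driven (Gillespie) realization of the same master equation the
likelihood solves, so simulator/solver agreement (total variation < 0.02
at 100,000 cells over a 3×3 rate grid) is a genuine dual-route check.
The mini-bulk screen generator draws log2-scale gene baselines uniform on
[2, 12] with a monotone decreasing noise trend sd(m) = 0.1 + 1.5·e^(−m/3)
and shifts affected genes in treated wells only, exported on the linear
scale so the DE pipeline's normalization is exercised end-to-end.

Not emulated: sequencing-quality profiles, alignment and UMI-stitching
artifacts, position-dependent error rates, gene-length/GC effects,
cell-to-cell variation in labeling efficiency, extrinsic noise and cell
cycle. Passing tests therefore demonstrate correctness of the estimators
under the model's own assumptions — calibration, recovery, error control
— not robustness to the ways real libraries violate them.

## Numerical choices and problem sizes

All pmfs are evaluated in log space; mixtures via log-sum-exp. The grid
posterior uses 10,001 points. Downsampling and control-draw RNGs are
seeded from stable hashes of (seed, identifiers), kept below 2^31. Fisher
tie comparison uses a 1e−9 relative tolerance (exact-rational agreement
to 1e−10 is verified in tests for margins ≤ 200). The test and
acceptance workloads use desk-scale problem sizes chosen to make the
statistical assertions sharp: 100,000 molecules for test size, 500 genes
× 2,000 reads for interval coverage, 50,000 reads × 20 seeds for EM
recovery, 2,000 cells × 20 seeds for kinetics recovery, and 20-seed
global-null screens for FDR control.

## Known limitations

Single-chain MCMC convergence is certified only through grid agreement,
not multi-chain diagnostics (the grid is exact for this one-dimensional
posterior, so it is the stronger check). The bursting likelihood fixes
k_off and k_deg; misspecifying them biases k_on and k_syn while leaving
burst-metric *comparisons* between conditions largely intact, which is
how the results are meant to be read. The moment estimator assumes the
bursty regime and degrades for near-constitutive genes (the ML step does
not). Fold changes with a zero denominator are reported as infinite
rather than smoothed.
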