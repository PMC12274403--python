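# newrna

Quantification of newly transcribed ("new") RNA from 4sU metabolic-labeling
sequencing experiments, in mini-bulk and single-cell formats, together with
the downstream statistics used to read out *direct* transcriptional effects
of chemical compounds: variance-adjusted differential expression,
dose-response slope fitting, promoter ChIP-peak and GO enrichment, and
transcriptional-bursting kinetics.

## Who this is for

Standard RNA-seq after a short compound treatment is dominated by
pre-existing mRNA, so direct transcriptional responses are invisible.
Adding 4-thiouridine (4sU) during treatment labels RNA made in the labeling
window: after chemical alkylation, reverse transcription misreads labeled
positions, producing T→C mismatches on plus-strand genes (A→G on
minus-strand genes). This package takes aligned reads (or stitched
molecules) carrying those mismatches and turns them into per-gene new-RNA
quantities and the statistics built on them.

## The model

Each read covers `n` convertible positions and shows `k` specific
mismatches. With per-position conversion probability `p_c` (4sU-induced)
and error probability `p_e` (library/sequencing), a gene with new-RNA
fraction `π` generates reads from the two-component binomial mixture

```
P(k; n, π) = π · B(k; n, p_c + p_e) + (1 − π) · B(k; n, p_e)
```

- `p_e` is estimated from strand symmetry (the specific conversion class on
  the *opposite* strand cannot be 4sU-induced), or as the mean of the
  complementary C→T and G→A rates.
- `p_c` is estimated per sample by expectation-maximization with `p_e`
  fixed (`ConversionRateModel`).
- The posterior of `π` per gene (uniform prior) is computed by a
  deterministic grid oracle or a seeded Monte-Carlo sampler
  (`NewFractionModel`), reporting the posterior mean and 95% equal-tailed
  credible interval. Genes with more than 5,000 reads are downsampled to
  5,000; genes with no converted read report π = 0.
- Single-cell molecules are called new/old by the binomial likelihood-ratio
  test H0: p = p_e vs HA: p = p_c at α = 0.05 (`classify_molecules`).
- Bursting kinetics: labeled counts per cell follow the two-state
  (telegraph) promoter — ON/OFF switching `k_on`/`k_off`, synthesis `k_syn`
  while ON, degradation `k_deg` — starting from zero labeled molecules at
  4sU onset. The transient master-equation solution is the likelihood;
  `k_off` is fixed at 100/h, `k_deg` derived as −ln(1 − fraction_new)/t.
  Burst frequency is 1/(1/k_on + 1/k_off), burst size k_syn/k_off
  (`TelegraphModel`).

## Worked example

```python
from newrna import simulate, rates, fraction

cfg = simulate.SimulationConfig(
    n_genes=3, reads_per_gene=4000, p_c=0.02, p_e=0.001,
    pi_per_gene=[0.05, 0.3, 0.6], sample_id="well_A1", seed=11,
)
reads = simulate.simulate_reads(cfg)

fit = rates.ConversionRateModel(reads, p_e=0.001).fit()
print(fit.summary())

table = fraction.estimate_pi_table(reads, {"well_A1": (fit.p_c, fit.p_e)})
print(table[["gene_id", "pi_mean", "ci_low", "ci_high"]].round(3))
```

prints

```
Binomial mixture conversion-rate fit (EM)
=============================================
sample           well_A1
p_c              0.0201927
p_e (fixed)      0.001
snr (p_c/p_e)    20.19
pi-bar           0.3177
log-likelihood   -13717
iterations       25
converged        True

gene_id  pi_mean  ci_low  ci_high
     g0    0.050   0.041    0.059
     g1    0.299   0.281    0.317
     g2    0.608   0.589    0.628
```

The EM recovers the conversion rate (true 0.02) with a signal-to-noise
ratio p_c/p_e of 20 (samples with SNR ≤ 10 fail QC), and the per-gene
posteriors recover the simulated new-RNA fractions 0.05/0.3/0.6 with
calibrated credible intervals.

Bursting kinetics from labeled single-cell counts:

```python
from newrna import bursting
counts = simulate.simulate_telegraph_labeled(simulate.TelegraphConfig(
    k_on=2, k_off=100, k_syn=400, k_deg=0.065, t_label=1.0,
    n_cells=2000, seed=11))
print(bursting.fit_kinetics(counts, k_off=100, k_deg=0.065, t=1.0,
                            gene_id="MYC").summary())
```

```
Telegraph kinetics fit (labeled counts)
=============================================
gene              MYC
cells             2000
k_on   [/h]       2.069
k_syn  [/h]       403
k_off  [/h]       100  (fixed)
k_deg  [/h]       0.065  (fixed)
t_label [h]       1
burst frequency   2.027 /h
burst size        4.03 molecules
log-likelihood    -6173.57
converged         True
```

A command-line interface mirrors the library
(`newrna simulate|count|qc|rates|pi|classify|de|dose|enrich|burst`).

## Module map

| module         | contents |
|----------------|----------|
| `simulate`     | read-level mixture generator, mini-bulk screen generator, exact telegraph simulator |
| `io`           | SAM/BAM conversion counting (MD tags), mismatch profiles, QC rules, TSV/MTX/BED/GTF/OBO readers |
| `rates`        | strand-symmetry p_e estimators, EM `ConversionRateModel` |
| `fraction`     | mixture pmf, grid and MCMC posteriors, `NewFractionModel`, new-expression layer |
| `molecules`    | likelihood-ratio new/old calls, per-cell fractions, count matrices |
| `differential` | variance-floored Welch tests, two-stage FDR, compound DE, dose-response, response clustering |
| `enrichment`   | promoter windows, peak overlap, Fisher/chi-square enrichment, expression-matched GO |
| `bursting`     | master-equation likelihood, `TelegraphModel`, burst metrics, permutation comparisons |
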