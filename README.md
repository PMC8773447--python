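# sncrna

Post-processing toolkit for small non-coding RNA (sncRNA) profiling
studies of brain injury — the analysis layer that sits downstream of
read alignment in a chronic traumatic-brain-injury (TBI) design:
two groups of animals (TBI vs sham-operated controls, typically n = 6
per group), bulk small-RNA sequencing of brain tissue, PCR validation,
and behavioral follow-up.

It is written for researchers who have per-sample read tables, count
matrices, PCR measurements, and behavioral scores, and who want a
reproducible, tested implementation of the following stages:

- **isomiR profiling** — ungapped mapping of reads to canonical mature
  miRNAs; classification into 5′, 3′, mixed, and internal-edit variants
  by terminal shifts and substitutions; the 5%-of-total-reads retention
  rule; canonical-fraction and top-isomiR statistics.
- **tRNA-fragment (tRF) calling** — positional coverage per tRNA, a
  reproducible cleavage-site call (modal read 5′ start covering ≥ τ of
  reads, default τ = 0.5), fragment classification (3′tRF / 5′tRF /
  internal), and per-tRNA aggregate count matrices.
- **differential expression** — trimmed-mean-of-M-values (TMM) scaling
  factors, a common negative-binomial dispersion φ estimated by
  conditional maximum likelihood (variance μ + φμ²), an exact
  conditional NB test per feature, and Benjamini–Hochberg FDR.
- **seed-based target prediction** — sliding 8-nt seeds along a tRF with
  exact reverse-complement matching in 3′UTRs; canonical miRNA seed
  sites (8mer, 7mer-m8, 7mer-A1); intersection with opposite-sign DE
  genes.
- **pre-ranked GSEA** — a signed integer ranking metric (sign from fold
  change, magnitude from the p-value rank within each sign group), the
  weighted Kolmogorov–Smirnov enrichment score, and gene-set permutation
  significance.
- **PCR quantification** — ddPCR normalization (replicate mean → RNA
  input → geometric mean of four endogenous controls), qPCR 2^−ΔCt,
  group fold change, and exact Mann–Whitney tests at small n.
- **behavioral outcome** — the 0–28 composite neuroscore, water-maze
  probe-trial quadrant fractions, and Spearman correlation of molecular
  signatures with outcome.

A synthetic-data module generates every input the pipeline consumes —
negative-binomial count matrices with planted fold changes, multinomial
isomiR mixtures, tRNA alignments with a planted cleavage site, PCR
measurements, and Gaussian-copula behavioral scores with a planted rank
correlation — so the whole pipeline is testable end to end without any
sequencing download.

## Worked example

Simulate a cortex-like experiment — 300 miRNA features, 6 TBI vs 6 sham,
NB dispersion 0.1, baseline mean 500 counts, 19 planted DE features
(12 up, 7 down at |log2FC| = 1.5) — and run the DE stage:

```python
from sncrna.synthetic import SynthDesign, gen_count_matrix, gen_pcr_measurements
from sncrna import diffexpr
from sncrna.quant import ddpcr_normalize, group_fold_change, mann_whitney

planted = [(f"up{i}", 1.5) for i in range(12)] + [(f"down{i}", -1.5) for i in range(7)]
design = SynthDesign(n_features=281, planted_de=planted, nb_dispersion=0.1,
                     baseline_mean=500, rng_seed=1)
matrix = gen_count_matrix(design)
table, (n_sig, n_up, n_down) = diffexpr.run_de(matrix, fdr_threshold=0.05)
print(f"{n_sig} significant features (FDR < 0.05): {n_up} up, {n_down} down")

rec = gen_pcr_measurements(2.01, "ddpcr", rng_seed=1)          # planted 2.01x
vals = ddpcr_normalize(rec)
groups = dict(zip(rec["sample"], rec["group"]))
fc = group_fold_change(vals, groups)
u, p = mann_whitney(vals, groups)
print(f"ddPCR fold change = {fc:.2f} (Mann-Whitney U = {u:.0f}, p = {p:.4f})")
```

Output:

```
20 significant features (FDR < 0.05): 12 up, 8 down
ddPCR fold change = 2.08 (Mann-Whitney U = 36, p = 0.0022)
```

The DE stage recovers essentially the planted 19-feature signal (one
null feature slips in at FDR < 0.05, as expected at this threshold), and
the ddPCR normalization recovers the planted 2.01× effect within
sampling noise at n = 6 + 6.

Every stage is also exposed on the command line (`sncrna synth`,
`isomir`, `trf`, `de`, `targets`, `gsea`, `quant`, `outcome`, `all`);
each subcommand reads and writes plain TSV/FASTA and prints a one-line
summary.

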