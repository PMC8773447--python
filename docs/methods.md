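# Methods

This note records the models, parameter choices, and numerical
conventions behind each pipeline stage, and what the synthetic-data
generator does and does not emulate.

## Conventions

All coordinates are 0-based, half-open `[start, end)`. All sequences are
stored 5′→3′ in the DNA alphabet; RNA input (`U`) is normalized to `T`
on read-in so miRBase-style references and genomic sequences can be
compared directly. Group labels are `TBI` and `sham`.

## IsomiR profiling

A read is placed against each canonical miRNA by ungapped sliding. The
placement is parameterized by the signed start shift *s* (read 5′ end in
canonical coordinates; negative = 5′ extension) with the end shift
*e = s + len(read) − len(canonical)*. Bases inside the overlap that
differ from the canonical are internal edits; bases outside the
canonical (terminal extensions) are shifts, not edits. The budget is
|s| ≤ 4, |e| ≤ 4, and ≤ 2 internal edits — wide enough to cover every
reported variant class while rejecting unrelated reads. The best
placement minimizes (number of edits, |s| + |e|, reference input order);
a read with no placement in budget is *unmapped*, which is a value, not
an error.

Classification follows directly: canonical (s = e = 0, no edits),
3′-isomiR (e ≠ 0 only), 5′-isomiR (s ≠ 0 only), mixed (both), and
internal-edit (edits only). Templated and non-templated 3′ additions are
not distinguished — no genomic context is in scope, so all 3′ changes
are one class. A substitution at the last canonical base is an internal
edit rather than a 3′ variant; an ungapped model cannot distinguish a
terminal substitution from trim-plus-add, and the edit reading is the
minimal-event one.

The retention rule keeps a species when it reaches the retention
fraction (default 0.05, boundary inclusive — "present at 5%" reads as a
floor) of that miRNA's mapped reads in **at least one sample**; a
passing species is kept in every sample with raw counts. Evaluating
per sample and merging by union keeps group comparisons balanced: a
species abundant in one group is not silently dropped from the other.
The alternative (filter on pooled counts) is a one-line change via the
`fraction` argument semantics and was deliberately not made the default.

The top-isomiR shortlist ranks non-canonical species by summed read
count across TBI samples, takes the top 6, keeps those detected
(count > 0) in every TBI sample, and truncates to 4. The "full profile"
per-sample total (canonical + retained isomiRs) is the expression value
used for outcome correlation.

## tRF calling

Coverage is tallied as read 5′-start, 3′-end (exclusive), and depth
vectors per tRNA and sample. Reads running past the stored reference
end (a non-templated CCA on a reference stored without it) are clipped
and counted. References carry a `has_cca` flag and a variable-region
interval; the fragment-end proximity test uses the stored end, so CCA
handling is explicit in the reference, not guessed from reads.

The cleavage-site call formalizes what is usually done by eye in a
genome browser: the candidate is the modal 5′ start and the call is made
when the fraction of reads starting within ±1 nt of it reaches τ
(default 0.5) — the majority-of-reads reading of a "clear" cleavage
site. Below 50 aligned reads the caller abstains with a reason. The
fragment runs from the candidate to the modal downstream end; a fragment
whose 3′ boundary lies within 2 nt of the tRNA end is a 3′tRF (and is
snapped to the end), one starting within 2 nt of position 0 a 5′tRF,
anything else internal. On a 75-nt tRNA with variable-region cleavage at
position 48 this yields the characteristic 27-nt 3′ fragment
(length = tRNA length − cleavage position, always).

DE for tRFs is run on per-tRNA aggregate counts (one row per tRNA, all
fragment reads summed), matching the question "did fragments from this
tRNA change overall" rather than per-fragment testing.

## Differential expression

**TMM factors.** For each library against a reference library (the one
whose upper-quartile of library-size-normalized counts is closest to the
mean upper-quartile), M-values (log2 ratio of normalized counts) are
double-trimmed — 30% from each M tail, 5% from each A tail — and
averaged with inverse delta-method variance weights; the factor is the
exponentiated weighted mean, and factors are normalized to geometric
mean 1. The implementation is cross-checked in the test suite against
Bioconductor's edgeR `calcNormFactors` (agreement to ≤ 1e-4) and against
a direct transcription of the published definition.

**Dispersion.** Counts are rescaled linearly to the geometric-mean
effective library size (a quantile-free stand-in for pseudo-counts) and
a single common dispersion φ maximizes the conditional NB likelihood
given each feature's per-group total, which eliminates the per-feature
means. The search is over log φ in [10⁻⁶, 5] (bounded scalar
minimization, xatol 1e-4), with the closed-form Poisson limit
(−z·log n per feature-group) compared explicitly so φ = 0 is returned
when the data are underdispersed. Common (not tagwise) dispersion is
used: at n = 6 + 6 with a few hundred features there is little
information for stable tagwise estimates, and the acceptance surface is
simulation recovery, not bit-identity with any particular package.

**Exact test.** With equalized library sizes, the sum of n i.i.d.
NB(μ, φ) is NB(nμ, φ/n), so the group-A subtotal conditioned on the
feature total z has a computable distribution; the two-sided p doubles
the smaller tail (observed point included in both, capped at 1). φ below
1e-12 switches to the Poisson/binomial limit. log2 fold changes use
normalized group means with a pseudo-count of 0.5 — for finite values at
zero groups only; testing never sees the pseudo-count.

**FDR.** Benjamini–Hochberg step-up (delegated to statsmodels). Under a
null simulation (φ = 0.1, 6 v 6, 10⁴ features) the exact test's type-I
error at p < 0.05 is within 0.05 ± 0.01 (tested).

## Target prediction

tRF targeting slides an 8-nt seed window along the fragment (L − 7
windows) and reports every exact reverse-complement occurrence in each
3′UTR. miRNA targeting uses the canonical nt 2–8 seed with the standard
taxonomy: 7mer-m8 = revcomp(nt 2–8); 7mer-A1 = revcomp(nt 2–7) + `A` in
the UTR; 8mer = both. No conservation, context scoring, or wobble
pairing: downstream stages need a deterministic predicted set, and
anything looser than exact complementarity is unspecified. Overlapping
matches all count as positions; a gene counts once in gene lists. The
combined tRF target list for enrichment uses the *first* seed window of
each fragment, de-duplicated and sorted. The intersection filter keeps
predicted targets that are DE-significant with fold change opposite in
sign to the small RNA, reporting `k/n (percent)` with the percentage
rounded to one decimal.

## Pre-ranked enrichment

The ranking metric is a signed integer: genes are split by fold-change
sign; within each sign group genes are ordered by p-value descending, so
the least significant gene gets magnitude 1 (closest to zero) and the
most significant the largest magnitude; downregulated genes are
negative; zero-FC genes sit at 0. Ties in p break by gene identifier for
determinism.

The enrichment score is the signed extremum of the weighted KS running
sum: hits add |metric|^w / Σ_set|metric|^w (w = 1 default; a set whose
members all have metric 0 falls back to equal weights), misses subtract
1/(N − |set|). Significance uses gene-set permutation — random sets of
the observed in-list size drawn from the ranked universe — because the
ranked list, not the sample matrix, is the unit of input here. The
p-value compares the observed score with the *same-signed* part of the
null in both numerator and denominator,
p = (1 + #{same sign, |ES_null| ≥ |ES_obs|}) / (1 + #{same sign}):
normalizing a sign-conditioned count by the total permutation count
would roughly double the type-I error, whereas this form is calibrated
(measured 0.04–0.05 rejection at nominal 0.05 under the null, tested).
When several sets are tested together, BH adjustment runs across their
permutation p-values.

## PCR quantification

ddPCR: duplicate copies/20 µL wells are averaged (arithmetic mean, the
convention for absolute counts), divided by the total RNA input to the
cDNA reaction, and divided by the geometric mean of the four
RNA-input-normalized endogenous controls — in that order, so the result
is invariant to any global rescaling of copies and input. A control at
zero copies is an error (geometric mean undefined), not a silent skip.
qPCR: ΔCt = mean(target Ct) − mean(reference Ct) over replicates, value
= 2^−ΔCt; decreasing the target Ct by one doubles the value exactly.

Group fold change is the ratio of group means of per-sample normalized
values (ratio-of-means rather than mean-of-ratios: the ddPCR convention
for absolute quantities; the accompanying Mann–Whitney test uses the
per-sample values either way). Mann–Whitney U uses midranks; p is exact
by full enumeration of group assignments for group sizes ≤ 10
(tie-safe), tie-corrected normal approximation above.

## Behavioral outcome

The composite neuroscore sums seven 0–4 sub-tests (bilateral forelimb
contraflexion, hindlimb flexion, lateral pulsion, plus an
inclined-surface test) to 0–28; 28 requires every sub-test maximal.
Probe-trial records hold four quadrant times summing to 60 s (±0.5 s
tolerated for tracking loss); the correct-quadrant fraction is reported
against the 0.25 chance level. Spearman correlation is the Pearson
correlation of midranks; p is exact by permutation enumeration for
n ≤ 8 (above that the full factorial enumeration buys nothing over the
t approximation at the reported precision, so the t approximation is
used). The outcome report joins expression and behavior tables on animal
id, drops unmatched animals with a logged count, and pools groups by
default (with a per-group option), since chronic-outcome correlations
are typically computed across all animals with PCR data. The report
emits the raw signed rho; direction language ("higher expression, worse
outcome") is left to the caller because axis orientation conventions
vary.

## Synthetic data generator

The generator emulates the statistical structure of the emulated study,
with defaults fixed at its design:

- **Counts**: NB with variance μ + φμ², φ = 0.1 (typical bulk small-RNA
  overdispersion), baseline mean 500, 6 + 6 samples; planted features
  shift the TBI mean by the stated log2FC. Sequencing depth per sample
  is not a published quantity; read-level generators default to 10⁵
  reads per sample, configurable.
- **isomiR mixtures**: multinomial over explicit sequences — canonical
  plus simple 3′ variants (±1/±2 nt), the 3′-dominated pattern seen in
  brain tissue.
- **tRNA alignments**: a planted fraction of reads is exactly the 3′
  fragment from the cleavage position; the rest start uniformly
  elsewhere with 18–36 nt lengths (background degradation).
- **PCR**: log-normal copy numbers (CV 10% default) with four
  endogenous-control channels at 5% CV and no group effect, so
  geometric-mean normalization is near-neutral, as the endogenous-
  control assumption requires; qPCR Ct replicates at SD 0.2 with the
  group ΔCt offset log2(FC).
- **Behavior**: a Gaussian copula couples scores to expression ranks
  with latent Pearson ρ = 2·sin(π·r_s/6), so the *population* Spearman
  of the continuous pair equals the target exactly. Clipping to the
  0–28 integer grid (or 0–60 s) attenuates the sample Spearman only
  marginally at wide n; at study n = 12 only sign and ordering are
  meaningful, and tests treat them accordingly.

What the generator does **not** emulate: sequencing error and adapter
artifacts, mapping ambiguity between paralogous miRNAs, tRNA
modification-driven misincorporation, droplet-level Poisson statistics
in ddPCR, amplification-efficiency differences in qPCR, and any
correlation structure between features. Passing recovery tests
therefore demonstrates that the estimators are correct for the stated
models at the stated noise levels — not that the pipeline is robust to
every artifact of real sequencing data.

## Problem sizes used in the recovery suite

DE recovery uses 300 features × 12 samples over 20 seeds; PCR fold-
change recovery uses 500 Monte-Carlo replicates at n = 6 + 6; isomiR
composition uses 10⁵ reads × 6 samples; outcome-correlation recovery
uses n = 2000 simulated animals; the tRF caller check uses 100 seeds at
2000 reads each. These sizes put Monte-Carlo error comfortably inside
each stated tolerance while keeping the whole suite fast on one CPU.

## Known limitations

- The isomiR mapper is ungapped: indel-containing isomiRs map, if at
  all, as shifted or edited species.
- Common dispersion means features sharing one φ; strongly
  heteroskedastic panels would need a tagwise extension.
- The exact NB test equalizes library sizes by rounding rescaled
  counts; at very low counts the rounding granularity can perturb
  p-values slightly.
- Seed matching is exact-complementarity only; it is a deterministic
  stand-in for, not a reconstruction of, context-scored target
  databases.
- The Spearman "exact" p switches to the t approximation above n = 8.
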