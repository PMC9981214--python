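# Methods

`xenopurity` measures tumor purity — the fraction of cancer cells among all
cells of a tumor — in the two standard preclinical mouse systems, and scores
their microenvironment from expression data. This note documents the models,
their assumptions, the tunable parameters, what the synthetic-data generators
do and do not emulate, and the numerical choices made where the design was
genuinely open.

## Syngeneic purity: a binomial mixture MLE (`xenopurity.mle`)

In a syngeneic model, a mouse cancer cell line is implanted into an
immunocompetent host of the same inbred background; tumor and stroma are both
mouse, so species-based separation is impossible. What *is* available are the
SNPs that distinguish the cell line from its host strain: at such a site the
host is homozygous HH while the cell line is homozygous TT or heterozygous HT
with within-cell-line allele fractions H1 + T1 = 1.

Let θ be the cancer-cell fraction. A sequencing read drawn from the
tumor shows the cell-line allele T with probability

- θ at a HOM (TT) site,
- θ·T1 at a HET (HT) site,

so conditional on total depth the T-allele count is binomial, and up to a
θ-free constant the per-site log-likelihood is

```
HOM:  n_H·log(1 − θ)      + n_T·log(θ)
HET:  n_H·log(1 − θ·T1)   + n_T·log(θ·T1)
```

The cohort log-likelihood is the sum over sites, maximised by grid scan over
θ ∈ {0, Δ, 2Δ, …, 1}.

Assumptions: sites are independent; no copy-number alteration at the SNP
sites (a CNA changes the effective allele dosage); no mapping bias between
the two alleles; reads are exchangeable across cells. T1 defaults to 0.5
(`t1_from_cellline_counts` can estimate it from cell-line sequencing but the
default is used unless the caller overrides it).

Preprocessing follows the realities of RNA-seq depth: sites below 20 total
reads are dropped (low-depth sites are false-positive prone), and any site
deeper than 5× the median retained depth is rescaled down to exactly that
cap, preserving its allele fraction with nearest-integer rounding (ties up),
so that a handful of extremely expressed genes cannot dominate the profile.
Capping by rescale rather than by dropping keeps the site's information at
reduced weight; `cap_mode="drop"` is available for the stricter reading.

Numerical choices:

- grid step Δ = 0.001; ties broken toward the smaller θ (first grid maximum);
- 0·log 0 ≡ 0 (`scipy.special.xlogy`), so the boundary points θ = 0, 1 are
  evaluable; a boundary that contradicts the data scores −∞, never an error;
- sites sharing (genotype class, T1) are aggregated into summed counts before
  the grid scan, so cost is independent of cohort size;
- an everywhere-non-finite profile (impossible data) raises.

Closed-form oracles pin the implementation down: a HOM-only cohort has MLE
Σn_T/Σn; a balanced-HET cohort has MLE min(1, 2Σn_T/Σn). The test suite
checks the grid against both to within one grid step, plus parameter
recovery at θ ∈ {0.6, 0.8, 0.95} (500 sites, mean depth 50, half
heterozygous, 200 replicates): bias < 0.01, RMSE < 0.03, |error| < 0.02 in
≥ 95% of replicates.

The same machinery applies to patient tumors when a matched normal is
available: sites homozygous in normal and heterozygous in tumor give the
normal-cell fraction by the identical likelihood.

## PDX purity from the amplicon assay (`xenopurity.amplicon`)

For patient-derived xenografts the cancer cells are human and (after the
first passages) the stroma is mouse, so purity is the human-cell fraction.
The deep assay amplifies 108 homologous human/mouse segments with common
primer pairs and sequences them at ~3000×; every read is assignable to a
species. Purity is the **median** of the per-segment human read fractions
(even count → mean of the central pair), which tolerates a minority of
segments with amplification or mapping bias. We report a *fraction*
human/(human+mouse) rather than a human:mouse ratio, assuming equal
effective genome copies per cell, so the number is directly comparable with
every other purity in the package. Segments below `min_depth` (default 100;
the assay runs far deeper) are excluded; zero-depth segments are flagged
unusable.

## Species read classification (`xenopurity.species`)

Reads aligned to both genomes are assigned to the higher-scoring species;
equal scores (within a configurable margin, default 0) are ambiguous and
discarded, as are unmapped reads. The proportion of human reads among the
assigned reads is a purity proxy only: platform bias (human-targeted exome
capture, expression differences in RNA-seq) distorts it, which is why the
amplicon assay — not this fraction — serves as ground truth. The score
semantics (alignment score, MAPQ, mismatch count) are the caller's choice;
only the comparison is defined here.

## Germline/somatic classification (`xenopurity.variants`)

PDX cohorts lack matched normals, so germline status is inferred from
orthogonal evidence. A variant is germline if **any** of these fires
(a pure OR — evaluation order is irrelevant):

1. population allele frequency > 0.01 in dbSNP **and** gnomAD **and** ExAC;
2. cohort prevalence > 20% of tested models (strict inequality);
3. allele present in more than one of 45 other vertebrate genomes;
4. VAF < 10%.

Everything else is somatic. Choices at the open points:

- a database with no entry counts as frequency 0, so rule 1 cannot fire on
  missing evidence (`missing_af="ignore"` restricts the conjunction to the
  databases that do have entries);
- "mutation frequency" in rule 4 is read as the *variant allele fraction*
  (the cohort-frequency reading would duplicate rule 2). The rule's
  direction is unusual — it deliberately removes subclonal and noise calls
  from the somatic set — and can be disabled (`apply_low_vaf_rule=False`);
- rule 2 needs the cohort-wide prevalence table built first
  (`compute_cohort_prevalence`), counting carrier models, not calls.

Per-model clonality is summarised by the median VAF of somatic *missense*
variants, reported only for models with ≥ 30 of them. For clonal
monoallelic mutations this median is purity/2.

## Stromal/immune scoring (`xenopurity.scoring`)

The ESTIMATE approach scores two 141-gene signatures (stromal, immune) per
sample with a rank-based single-sample enrichment statistic; the ESTIMATE
score is exactly their sum, and rises as purity falls. The enrichment
statistic is implemented here directly rather than through the reference R
package: genes are ranked ascending (average ties), walked in decreasing
expression order, and the score is the summed difference between the
rank-weighted in-set ECDF (weight = rank^α, α = 0.25) and the uniform
out-of-set ECDF. No cross-sample normalisation is applied. The score is
invariant under monotone transforms of expression. A brute-force
running-sum oracle in the tests is the correctness reference (agreement to
1e−9 relative). Degenerate inputs error: an empty intersection with the
profile, or a set covering every expressed gene (out-of-set ECDF undefined).

Three versions serve the two-species reality of a PDX tumor:

- **human** — human signature genes only: purity *among the human cells*;
- **mouse** — mouse orthologs only: purity *among the mouse cells*;
- **hybrid** — per signature gene, human expression plus the sum of its
  mouse ortholog(s) (`hybridize_expression`): purity among *all* cells.

The ortholog map may be partial (the real signature maps 130/141 stromal and
141/141 immune genes); unmapped genes pass through with their human value.
One-to-many orthologs are summed; a mouse gene claimed by several human
genes is credited to each with a warning.

## Score → purity calibration (`xenopurity.calibration`)

A reference cohort with known purities supplies (ESTIMATE score, purity)
pairs; a loess curve fitted through them (statsmodels `lowess`, 3
robustifying iterations) converts new scores to purities by interpolation
inside the reference range and linear extension of the boundary slope
outside it, clamped to [0, 1]. At least 20 pairs are required; duplicate
scores are averaged after fitting so the curve is a function.

The default span is **0.3**: the smoother is locally *linear*, and on
curved references a 0.75 span leaves a curvature bias of ~0.04 purity
units, while 0.3 keeps the noise-free recovery error below 0.01 from 50
reference points up and remains stable under purity noise of sd 0.02
(R's classical loess defaults to span 0.75 with locally *quadratic* fits,
which is why that span is commonly quoted).

## Cohort statistics (`xenopurity.cohort`)

- within/between: absolute purity differences of all same-passage pairs,
  split by same vs different model, compared by two-sided Mann–Whitney U;
- early/late pairing: per model, one seeded random draw among
  earliest-passage samples and one among latest-passage samples (never the
  same physical sample), Pearson r and paired t on late − early;
- balanced strain subset: per cancer present in both host strains, both
  strains downsampled (seeded, without replacement) to the smaller count;
- strain comparison: pooled and per-cancer medians with rank-sum tests, and
  the Pearson correlation of per-cancer medians across strains;
- per-cancer summary: quartiles for cancers with ≥ 20 samples, plus the
  mean of per-cancer medians;
- purity–mutation correlation: average-rank Spearman (the packaged
  19-model syngeneic table contains tied purities, so tie handling
  matters).

Rank tests use the exact null when both groups have ≤ 20 observations and
the pooled data are tie-free, else the normal approximation (scipy). The
tests check both rank statistics against exact enumeration oracles on
inputs of size ≤ 8.

## Synthetic data (`xenopurity.simulate`)

One seeded `SimConfig` drives all generators; each generator draws from its
own decorrelated substream, so identical configs give bit-identical outputs
and hidden truth is always returned alongside the data.

| parameter | default | meaning |
|---|---|---|
| `theta_true` | 0.85 | purity (sites) / human fraction (segments) |
| `n_sites` | 500 | SNP sites or variants per table |
| `depth_mean` | 50 | mean site depth (reads), RNA-seq-like |
| `depth_dispersion` | 5 | negative-binomial size k (var = μ + μ²/k) |
| `het_fraction` | 0.5 | fraction of HET sites |
| `n_segments` | 108 | amplicon segments |
| `segment_depth` | 3000 | reads per segment |
| `n_samples` | 50 | expression / reference cohort size |
| `n_genes` | 2000 | human genes (282 signature + background) |
| `noise_sd` | 0.2 | log-normal expression noise sd |

Emulated structure:

- **SNP sites** — depth ~ negative binomial (RNA-seq depths vary by orders
  of magnitude; the depth cap exists for exactly this), T-count binomial
  with the model's success probabilities;
- **segments** — human count binomial at the true fraction, optional
  per-segment log-normal bias on the human:mouse odds;
- **expression** — each signature gene's stromal/immune signal is
  proportional to (1 − purity) and split between the residual human stroma
  and the mouse ortholog(s) in a *per-sample* proportion w_j ~ U(0.2, 0.8):
  tumors differ in how much human stroma remains, so neither species alone
  sees the whole signal and only the hybrid sum recovers it — the
  motivation for the hybrid score version. Half the background human genes
  scale with purity (cancer genes), the rest and all mouse background are
  purity-independent; everything gets log-normal noise. Expression is
  TPM-like on a linear scale;
- **variants** — germline truth spread over the four evidence channels,
  somatic VAF binomial around clonal_vaf·purity; with `ensure_separable`
  (default) draws are clamped away from the 10% boundary so labels are
  exactly recoverable, for boundary studies disable it;
- **score–purity reference** — scores spread over a stated range, purity
  from a strictly decreasing cosine-of-affine curve (clamped to [0, 1])
  plus Gaussian noise; the generating function is returned for recovery
  tests.

Not emulated — and therefore not demonstrated by passing tests: read-level
artifacts (mapping bias, which centres real clonal VAFs near 0.47 rather
than 0.5; here the clonal centre is exactly 0.5), copy-number alteration,
GC/positional depth structure, batch and library-size effects in
expression, cross-species read misassignment, and real signature-gene
biology (the synthetic signature only mirrors the 141+141 geometry and the
partial ortholog map). Recovery results on this synthetic data bound the
estimators' statistical error under the model's own assumptions, not their
robustness to these artifacts.

## Problem sizes

The default study sizes used throughout the tests and the acceptance script
— 500 sites × 200 replicates for MLE recovery, 108 segments × 3000× × 100
replicates per purity for the assay, 50-sample expression cohorts, 1,000
variants — are the scales at which the statistical claims stabilise; all
suites complete in well under a minute on one CPU.

## Known limitations

- The MLE assumes copy-neutral SNP sites and unbiased allele sampling;
  violations bias θ̂ with no internal warning.
- The profile-based estimate ships without a confidence interval; the full
  likelihood profile is returned for callers who want one.
- The enrichment statistic matches the common single-sample formulation
  with α = 0.25 and no cross-sample normalisation; scores from other
  implementations (e.g. platform-offset variants) are on a different scale
  and need their own calibration reference.
- `score_to_purity` is only as good as its reference cohort; extrapolation
  beyond the reference score range is linear and clamped, i.e. honest but
  crude.
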