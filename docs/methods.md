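# Methods

## Scope and data model

`emtmet` operates on gene × sample matrices of log2-scale expression
(`ExpressionMatrix`), one per dataset, with unique upper-case HGNC-style
gene symbols and at least two samples. Upstream read processing
(alignment, counting) is out of scope: inputs begin at probe/gene
intensity tables or count matrices. Pre-processing follows the common
microarray/RNA-seq conventions:

* **Probe collapsing** — probes mapping to the same gene are averaged
  (arithmetic mean per sample); unmapped probes are dropped; genes are
  ordered lexicographically afterwards so downstream scores are
  byte-for-byte reproducible.
* **Missing values** — a gene row with under 20 % missing entries is
  imputed with its row mean; rows at or above that threshold are dropped.
  This keeps scoring inputs complete without inventing cross-sample
  structure. The threshold is a package choice; there is no field-standard
  value.
* **log2** — `log2(x + offset)`, offset 1.0 by default (0 is rejected when
  zeros are present). Series-matrix tables whose maximum value is below 30
  are treated as already log-scale and flagged in provenance rather than
  re-transformed.
* **TPM** — counts are divided by gene length in bases and each sample
  scaled to 10⁶ (relative tolerance 10⁻⁹ enforced), then log2(x+1). The
  transform is invariant to per-sample library-size scaling.

## Scoring methods

All scorers are deterministic; ties in ranks are resolved by average
ranks everywhere.

**76GS.** Weights are re-derived per dataset as the Pearson correlation of
each signature gene with CDH1 across that dataset's samples (not fixed
published weights), the weighted expression sum is computed per sample,
and scores are centered to cohort mean zero. Requirements: CDH1 present
with non-zero variance and at least 3 samples; there is no documented
fallback for a missing anchor, so the scorer errors rather than guess.
When fewer than 76 signature genes are present, weights are computed over
the present subset (minimum coverage 50 %).

**KS.** Per sample, the two one-sided Kolmogorov–Smirnov statistics
between the mesenchymal-gene and epithelial-gene expression values are
compared; the score is the two-sample KS distance carrying the sign of
the dominant side (+ when the mesenchymal distribution is stochastically
larger), hence in [−1, 1] with positive = mesenchymal. An exact tie of
the one-sided statistics scores 0. Cell-line (218-gene) and tumor
(315-gene) epithelial/mesenchymal splits are selected per dataset
(default: cell line).

**ssGSEA.** Genes are ranked per sample (ascending average ranks, top
gene carries rank N); walking the list in descending expression order,
the enrichment score is the sum over positions of the difference between
the in-set ECDF weighted by rank^α (α = 0.25, the cited tool's
convention; configurable) and the unweighted out-of-set ECDF. The
statistic depends on ranks only, so any strictly monotone per-sample
transform leaves it unchanged. The normalised score divides each ES by
the range (max − min) of ES across the dataset's samples; because the
source analysis never defines its normalisation, the raw ES is exposed
via `normalize=False`. A single-sample (or degenerate) dataset has an
undefined range and falls back to raw ES with a warning. The
implementation agrees with `gseapy.ssgsea` (`sample_norm_method="rank"`)
to numerical precision; that agreement is asserted in a cross-check test,
never used as the implementation.

**Singscore.** The mean ascending rank *m* of the signature genes is
normalised by its analytic extremes — (|S|+1)/2 when the signature genes
are the lowest expressed, N − (|S|−1)/2 when highest — onto [0, 1] and
mapped linearly to [−1, 1]; the extremes are attained exactly.

**FAO.** The published FAO equation lives in a cited prior report and is
not reproduced in the source analysis, so the package defines a
documented default — per-gene z-scores (population SD) across the
dataset's samples, averaged with unit weights — and accepts an external
per-gene coefficient vector as data. With unit weights the cohort mean is
zero by construction. Zero-variance genes are excluded (error if all are).

**Coverage policy.** A signature scores only when ≥ 50 % of its genes are
present in the matrix; otherwise the metric is reported missing with a
warning and the panel continues. The source analysis scores heterogeneous
platforms and is silent on this; 50 % is the package's choice.

## Meta-analysis

Pearson *r* with two-sided *p* from the *t* distribution (n−2 df) on
pairwise-complete samples; no multiple-testing correction by default
(mirroring the analysis convention; a BH-FDR flag exists). Volcano
classification: POS if *r* > 0.3 and *p* < 0.05, NEG if *r* < −0.3 and
*p* < 0.05, else NS (thresholds configurable).

* **Concordance** of a metric pair: probability = max(n₊, n₋)/(n₊ + n₋)
  over significantly correlated datasets, direction = majority sign (ties
  break positive with a flag); the weighted variant multiplies by the
  significant fraction, i.e. equals max(n₊, n₋)/n_total. "Significant"
  in the denominator means clearing both thresholds, consistent with the
  volcano classes; a p-only denominator is available by flag.
* **Venn consistency**: per dataset a k-bit vector marks which of k
  chosen pairs match their expected signs; counts per pattern always
  partition the included datasets.
* **Axis counts**: per dataset, how many of the three metabolic axes
  (glycolysis, OXPHOS, FAO) correlate significantly with the hallmark-EMT
  score; fractions are over datasets with all three records.
* **Modality quadrants**: datasets with both axis–EMT correlations
  significant are assigned by the joint sign pattern; percentages are
  over assigned datasets only (the reading consistent with the reported
  percentages summing within assigned sets).
* **Group comparison**: equal-variance Student's *t* by default (the
  analysis names Student's test); Welch available by flag.

## Synthetic cohorts

The generator is a linear-Gaussian latent-factor model — the simplest
structure with controllable correlation sign and strength. Per sample a
latent EMT coordinate φ is drawn (uniform on [−1, 1] by default; a
bimodal option with modes at ±1, SD 0.3, emulates E/M cluster structure).
Expression of gene *g* is `baseline_g + c_g·φ + N(0, σ)` with per-gene
baselines N(8, 1) (log2-microarray-like), noise σ = 0.5 by default, and
group couplings: epithelial-list genes and the 76GS list −c, mesenchymal
and hallmark-EMT genes +c (c = `emt_coupling`, default 1.0), metabolic
pathways their configured couplings (defaults glycolysis +0.8,
OXPHOS/FAO/AMPK −0.8, HIF1α +0.8 — the dominant directions the analysis
machinery should recover), 200 background genes uncoupled. CDH1 is
generated as an epithelial gene and anchors the 76GS list. Signature
groups are disjoint by construction (CDH1's dual membership excepted).
Default cohort sizes used in tests and the acceptance script: 100 samples
for single-dataset sign recovery; 50 datasets × 60 samples for
concordance recovery; 200 datasets for the 70/30 modality mixture; 100
datasets (65 concordant / 35 with the hallmark-EMT coupling flipped) for
the Venn construction; 200 cells per group for the time course. These
sizes give high-powered recovery while keeping the default suite quick on
one CPU.

Cohorts draw per-dataset couplings from a mixture (binomial composition)
or an exact per-dataset override list. The time course shifts the φ mean
per group (default day0 = 0, day7 = +1, day3_withdrawal = +0.5, per-cell
SD 0.5) to emulate TGF-β EMT induction and partial reversal on
withdrawal; optional Bernoulli dropout mimics single-cell sparsity (off
by default; no negative-binomial count model).

**What passing tests do and do not show.** The generator produces
homoscedastic Gaussian log-expression with linear couplings and
exactly-known membership; real cohorts add platform effects,
heteroscedasticity, correlated gene modules, partial signature overlap
and annotation noise. Recovery results therefore validate the machinery
(sign conventions, classification, aggregation, determinism), not
effect-size estimates on real data.

## Bundled signatures

The shipped GMT files are clearly-labelled synthetic placeholders with
the published cardinalities (76; 218 = 130 E + 88 M cell line;
315 = 145 E + 170 M tumor — the E/M splits are package stand-ins, since
only the totals are published in the source analysis; 33 AMPK and 23
HIF1α targets; 14 FAO enzymes; 200-gene hallmark sets). Real gene
memberships live in MSigDB and the originally cited reports and are
deliberately not reproduced from memory; every slot is overridable with a
genuine GMT. The MSigDB release used for a real analysis is recorded by
the user's registry, not resolved by the package.

## Numerical choices and degenerate inputs

Floating-point outputs print at 9 significant digits (byte-stable
reruns); matrix TSV round-trips use `repr` and are bit-exact. Correlations
need ≥ 3 complete pairs and non-zero variance, otherwise the record is
skipped with a warning. A signature equal to the whole gene universe is
rejected (empty out-set for ssGSEA, degenerate normalisation for
singscore). ssGSEA warns when the gene universe is under twice the
signature size. Concordance of a cohort with no significant dataset is
reported missing rather than 0 or 1.

## Known limitations

* Synthetic placeholders mean out-of-the-box scores on real data are not
  biologically meaningful until real gene sets are supplied.
* No alias/ID mapping beyond upper-casing; probe annotation must be
  provided as an explicit two-column map.
* The FAO default (unit-weight mean z-score) is a stand-in for the
  published coefficient equation; supply coefficients for fidelity.
* Survival analysis on external tumor cohorts is out of scope.
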