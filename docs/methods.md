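# Methods

This note documents the models, defaults and numerical choices behind
`metaboqtl`, and what the synthetic-data tests do and do not establish
about real data.

## Phenotype model and normalization

Metabolite peak areas are treated as lognormal. The normalization chain per
metabolite is: natural log (zeros first set to missing, because a zero
means no peak was integrated, not a measured zero), z-scaling,
ordinary-least-squares residualization on age, sex, batch indicator
variables and ancestry PCs 1–10 supplied in the covariate table, then a
rank-based inverse normal transform (INT) of the residuals. The INT uses
Blom offsets, Φ⁻¹((r − 3/8)/(n + 1/4)), with average ranks for ties —
the common choice in GWAS pipelines. Covariates are adjusted again in the
association model (double adjustment); this mirrors standard practice and
is harmless because the residuals are orthogonal to the covariates.

Ancestry PCs are consumed from the covariate file as given; estimating them
from genotypes is out of scope.

## Pooled-QC drift correction and filtering

Instrument sensitivity drifts over an injection sequence. Pooled plasma QC
samples are interspersed every `qc_interval` injections; each study sample
is scaled per feature by `reference / nearest-QC value`, where the
reference is the per-feature median over all QC injections and "nearest" is
by injection order within batch, ties to the earlier injection. QC rows
are kept unscaled so that the per-feature coefficient of variation (CV)
computed on them reflects raw measurement stability; `qc_filter` removes
features with QC CV strictly above 0.30 or missingness strictly above 0.30
of study samples. A `detrend_qc` flag computes the CV after removing a
linear injection-order trend, for runs with strong drift. CV = SD/mean
with sample SD (ddof = 1).

## Effective number of tests and thresholds

Metabolites are heavily correlated, so Bonferroni over raw feature counts
is too conservative. M_eff is the smallest number of principal components
of the column-standardized (median-imputed) metabolite matrix whose
cumulative explained variance reaches 95%. The discovery threshold is
α/M_eff with α = 5×10⁻⁸; display rounding to one significant figure is
presentation only, all comparisons use the exact quotient. PCA runs on the
post-normalization phenotypes (a flag-free design choice; pre-residual
values would give a similar but not identical count).

## Association scan

The default model is per-metabolite, per-variant OLS of the normalized
phenotype on dosage, age, sex and PCs 1–10, with two-sided p from the t
distribution at residual degrees of freedom (exact at small n). Variants
with minor allele count < 5 among analyzed samples are excluded; dosage
missingness is handled per-variant complete-case. When the dosage matrix
and phenotype are complete, the scan uses the Frisch–Waugh–Lovell
decomposition — residualize phenotype and dosages on the covariates once
(via a QR factorization), then vectorized simple regressions with
full-model degrees of freedom — which reproduces the full OLS beta/SE/p
exactly (asserted against `statsmodels` in the tests) at a fraction of the
cost.

With a genetic relationship matrix K, the covariance is modeled as
σ²(h²K + (1−h²)I) per metabolite: K is eigendecomposed once, h² estimated
by bounded profile maximum likelihood on the rotated data, and each variant
tested by weighted least squares in the rotated basis. With K = I this
collapses to OLS exactly. The GRM builder uses the standard
allele-frequency-standardized cross-product over common variants.

## Locus definition

Each significant hit seeds the 1-based inclusive interval
[pos − 500 kb + 1, pos + 500 kb] (a "1 Mb region" names the total width; a
flag widens to ±1 Mb). Per metabolite and chromosome, hits are processed in
ascending p; overlapping intervals are absorbed into the growing region and
merging repeats until no overlaps remain, making the result independent of
input row order. Sentinel = lowest p, ties broken by genomic position then
allele order. Regions whose sentinels have dosage-correlation r² ≥ 0.8
(inclusive) are combined transitively via union–find; apparent
cross-chromosome LD is logged but never combined. LD is computed in the
discovery genotypes (composite LD, i.e. Pearson correlation of dosages).

## Meta-analysis and validation

Fixed-effect inverse-variance weighting: β = Σwᵢβᵢ/Σwᵢ, SE = (Σwᵢ)^(−1/2),
wᵢ = SEᵢ⁻², two-sided normal p. Cochran's Q and I² are reported for
information only. Validation requires meta p < 0.05 and direction
consistency; the strict default demands every available cohort's sign to
match discovery (a flag relaxes this to the combined sign). A Bonferroni
tier additionally requires p < 0.05/n_tested. Missing cohorts simply drop
out of the combination.

## Feature deconvolution

Features are clustered on a graph with an edge when retention times differ
by ≤ 0.25 min and the pairwise-complete Spearman correlation over at least
20 samples exceeds 0.80; clusters are connected components (single
linkage — the minimal closure of a pairwise criterion; a stricter clique
policy would split chains and is deliberately not the default). The
20-sample overlap floor exists because rank correlations below that are
too unstable to gate on.

Primary-ion selection tries every member as a putative [M+H]+ and checks
whether other members match it plus a tabulated offset within 10 ppm
(defaults: [M+Na]+ +21.98194, [M+K]+ +37.95588, [M+H−H2O]+ −18.01056, and
the [2M+H]+ multimer relation 2·m/z − 1.00728). The interpretation
explaining the most members wins; with no offset match, the highest mean
intensity wins. Unknown members of a cluster with exactly one known
identity inherit it (annotation category 2); conflicting known identities
block propagation and are flagged. Tolerances are in ppm rather than Da to
match instrument mass accuracy.

## MS/MS processing

Scans match a feature when the precursor is within ±0.2 Da and the
retention time within ±0.1 min of the feature apex. Consensus building
groups fragments across replicate scans by a 5 ppm chain rule on the
sorted m/z list, takes intensity-weighted mean m/z and the mean intensity
over contributing scans, drops fragment groups present in fewer than half
the scans ("inconsistently detected"; the 0.5 fraction is a configurable
operationalization), and removes any fragment within 30 ppm of m/z 173.46
— a well-known electronic-noise artifact in low-abundance Orbitrap
spectra. Consensus is idempotent on its own output.

Spectral similarity is a greedy one-to-one cosine: candidate fragment
pairs within 10 ppm are accepted in decreasing order of intensity product,
each fragment used once; intensities enter as square roots by default (the
community norm for electrospray spectra, damping dominant-peak effects),
with a flag for plain intensities. The score is symmetric, ≤ 1 and
invariant to global intensity scaling; it agrees with `matchms`'s
CosineGreedy as an independent cross-check. Networks keep edges with score
strictly above 0.7; spectra acquired at different collision energies remain
separate nodes. The GNPS modified cosine (precursor-shift matching) is not
implemented, so published network scores computed with it may differ
slightly from this plain cosine.

## Annotation integration

Evidence categories, strongest first: (1) authentic-standard match,
(2) co-clustered standard-validated compound, (3) spectral-library match,
(4) in-house backbone MS/MS + RT match, (5) external structure/formula
prediction, (6) m/z database match. Categories 1–2 map to MSI level 1,
3 to level 2, 4 to level 3; 5–6 predate no MSI level. When several
categories apply, the strongest wins and supplies the identity — a strict
priority order mirroring the MSI confidence ladder; the number of
supporting sources is reported so users can impose their own
"high-confidence" cut. Pathway concordance intersects the predicted
identity (case-insensitive) with the candidate gene's mapped metabolite
set from a user-supplied two-column table; class-level matches are
accepted when only class information exists.

## Synthetic cohorts: what they emulate, and what they don't

The generator draws biallelic genotypes at Hardy–Weinberg equilibrium from
a configurable allele-frequency mixture (which can include
rare-in-one-population entries), places variants on one chromosome at
fixed spacing, and builds log-scale metabolite phenotypes as
baseline + Σβ·dosage + covariate effects + Gaussian noise. A planted β is
the per-allele effect in SD units of the normalized metabolite: where an
effect is planted, the residual SD is set to √(1 − β²·Var(dosage)) so the
phenotype's genetic-plus-noise variance is ~1 and the post-normalization
slope equals β — this is what makes "the scan recovers β within 2 SE" a
well-posed oracle. Metabolite noise is otherwise lognormal with
configurable SD (assumed, not claimed as the noise law of real
instruments).

Adduct satellites are the primary intensity × relative abundance ×
lognormal noise, at the primary RT plus a per-feature jitter capped at
0.02 min (well inside the 0.25 min clustering tolerance, so clusterability
is guaranteed while the tolerance is still exercised) and m/z shifted by
the adduct offset. Drift multiplies intensities by 1 + slope·injection
(default slope 2×10⁻⁴, i.e. a few percent over a run — typical pooled-QC
drift); pooled-QC rows are interspersed every 20 injections. Missingness
is MCAR at the configured rate on study cells only, with a left-censoring
variant behind a flag; MCAR suffices to exercise the 30% filter even
though real missingness is intensity-dependent. MS/MS scans get uniform
fragment m/z, ≤ ±2 ppm replicate jitter (inside the 5 ppm aggregation
tolerance), shared fragments (m/z and intensity) between designated
related compounds, and the 173.46 noise fragment in a configurable
fraction of scans.

One seed determines everything; each stage draws from a sub-stream derived
from (seed, stage key), so adding a stage never shifts earlier draws.

Deliberately not emulated: linkage disequilibrium blocks and admixture,
chromatographic peak shapes, isotope patterns, intensity-dependent
missingness by default, and batch structure beyond a single batch with one
indicator. Passing tests therefore demonstrate the statistical machinery
(estimator correctness, calibration, thresholds, deconvolution logic) —
not robustness to correlated variants, peak-integration artifacts or
multi-batch effects.

## Problem sizes used in the checks

The calibration suite uses 500 variants × 20 metabolites at n = 500
(10,000 null tests); effect recovery uses 200 replicates at n = 1000,
MAF 0.3, β = 0.5; end-to-end localization uses 60 replicates at β = 0.8
over 40 variants; deconvolution uses 30 primaries × 2 satellites at
n = 300; the effective-tests oracle uses 100 i.i.d. metabolites at
n = 100,000. These sizes give Monte-Carlo error comfortably inside the
asserted bounds while keeping the default test run fast.

## Known limitations

- The mixed model fits a single variance component by profile ML (not
  REML with multiple components) and requires complete dosages per variant.
- Interval merging is exact but quadratic in regions per metabolite —
  fine at study scale, not engineered for 30M variants.
- Cosine scoring is the plain greedy cosine; modified-cosine analog
  matching across precursor shifts is a documented non-goal.
- Adduct inference considers the tabulated offset list and [2M+H]+ only;
  isotopologues and negative-mode chemistry are out of scope.
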