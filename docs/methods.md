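# Methods

This note documents the models, rules and numerical choices behind
`hmolink`, and what the synthetic-data tests do and do not establish about
real cohorts.

## Genotype model and QC

Genotypes are minor-allele dosages in {0, 1, 2, missing}. The minor allele
is always re-derived from the cohort under analysis (ties resolve to the
VCF ALT allele), so annotation MAFs in the variant panel are metadata, not
orientation. QC runs in the plink tool order — sample missingness, then
variant missingness over retained samples, then MAF recomputed on
post-sample-filter data — with removal strictly above the 5% thresholds
(a sample at exactly 5% missing is kept) and below MAF 0.01. The MAF
returned by `compute_maf` is folded (`min(f, 1−f)`), so a variant whose
rarer allele flips after sample removal still reports a value ≤ 0.5.

## Status rules and milk groups

Secretor status is lost when any secretor-rule SNP (rs601338, rs1047781,
rs200157007) is homozygous for its minor allele; Lewis status analogously
over rs3745635, rs28362459, rs3894326, rs812936. Heterozygotes keep the
positive status. Rule SNPs absent from the input matrix are treated as
homozygous major with a logged warning — the two secretor-rule SNPs other
than rs601338, for example, carry no minor-allele homozygotes in European
cohorts, and many genotyping panels omit them. A *missing* genotype at a
rule SNP yields `unknown` rather than an imputed call, unless another rule
SNP already forces the negative status. Milk group is the deterministic
cross of the two statuses (1 = Se+Le+, 2 = Se−Le+, 3 = Se+Le−, 4 = Se−Le−).

The phenotypic (milk-based) classification calls Se+ when 2′FL **or**
LNFP-I is quantifiable at its LoQ, and Le+ when LNFP-II is quantifiable.
The OR over the two α-1,2-fucosylated markers is a package choice; the
field convention is presence/absence without an explicit operator. The
LNFP-II LoQ is not a published value; it defaults to the generic panel LoQ
(10 mg/L) and is configurable per analyte.

## HMO panel, censoring and statistics

The 24-analyte panel partitions into 6 core + 13 fucosylated + 5 sialylated
analytes; the galactosyllactoses 3′GL and 6′GL are summed with the core
class by convention although they are not strictly core structures. The
hexasaccharide reported under two compositional spellings in the source
material is carried under the single canonical name Hex4HexNAc2. Published
assay limits are the 2′FL LoQ (20 mg/L) and the 2′FL/LNFP-I LoDs (3.9 and
2 mg/L); all other limits default to 10 / 2 mg/L as documented assumptions.
Values below LoD are stored as 0 mg/L (`below_lod`); values between LoD and
LoQ keep their measured value with a `below_loq` flag.

Left-censored values are substituted before statistics (default LoQ/2;
zero and LoQ/√2 available). Log transforms are natural logs; exact zeros
are floored at 1 mg/L *per entry* — an additive offset on every value would
distort fitted time trends, so only the zeros are touched.

Mann-Whitney comparisons use exact enumeration for min(n) ≤ 8 without ties
and the tie-corrected normal approximation otherwise (scipy backend; the
test suite checks both against full enumeration). Correlations are Pearson
on log concentrations with BH adjustment over the strict upper triangle and
a display mask at adjusted p < 0.001; constant columns report missing.

## Multiscale-bootstrap clustering

Analytes are clustered by complete linkage on 1 − r, with columns sorted
lexicographically so dendrogram ties break by analyte name. The resampling
unit is the mother (rows), not the correlation entries: correlations are
recomputed per replicate. Bootstrap probabilities are collected at ten
scales (ratios 0.5–1.4 of n, 1000 replicates each by default) and the
approximately unbiased p-value comes from weighted least squares of
Φ⁻¹(1 − BP) on (σ, 1/σ), σ = √(n/n′), with binomial delta-method weights;
AU = 1 − Φ(v − c). BP values are clipped to (1/2B, 1 − 1/2B) for the probit
fit; a node at BP ≈ 1 on every scale gets AU = 1 directly, and the root is
AU = 1 by convention. Clusters are reported where AU ≥ 0.95.

## Lactation dynamics

Median (τ = 0.5) regression of log concentration on month minimises
Σ|y − a − bx| exactly via the standard LP formulation (HiGHS); the optimum
interpolates at least two data points, which the tests exploit as a
brute-force oracle. The time covariate is the month value {3, 6, 12}; the
printed per-analyte coefficients are treated as slopes on that axis (the
alternative ordinal coding is a config choice — recovery tests use the same
coding for generation and fitting, so they are coding-invariant). Inference
uses the sign-score rank test: under H₀ b = b₀ the centred-regressor sum of
residual signs is asymptotically normal; the confidence interval inverts
this test on a slope grid of resolution 10⁻³, and the reported interval is
clamped to contain the LP point estimate (the discrete test can reject at
the optimum itself in heavily tied data). Strata with fewer than 3
observations or one represented month are skipped with a warning; repeated
measures are treated as independent (no subject-level random effects).
Rows are flagged significant at BH q < 0.1.

## sPLS selection and the milk-group MLP

Each sPLS component soft-thresholds the dominant singular pair of the
column-centred cross-covariance XᵀY so that a fixed number of SNPs keeps
nonzero loading (default 8 per component, 2 components), deflating both
blocks on the component score between components. With the keep-count equal
to the SNP count the loadings reduce to dense PLS-SVD weights (tested to
10⁻⁸). The default keep-count is calibrated so that the selection on the
deterministic reference-scale fixture has exactly 14 members, the reference
analysis's first-selection size; because SNPs in strong LD receive equal
loadings, whole blocks enter or leave the selection together.

The classifier is a single-hidden-layer softmax network over the selected
dosages. Milk group is a *threshold* function of dosage (homozygous minor
vs carrier), and the rarer groups contribute only a handful of training
genotype patterns, so the defaults favour smooth generalisation over sheer
capacity: 16 ReLU hidden units trained full-batch with L-BFGS under L2
decay α = 0.01. Eight units interpolate the training data but misplace
thresholds on unseen rare-group patterns (held-out medians ≈ 0.96); the
16-unit regularised network reaches held-out medians 0.987–0.993 across
independent seed ranges at n = 500. The split is stratified 70/30 with
singleton classes kept in training. Variable importance is Garson's
weight-product measure, importanceᵢ = Σₕ Σₒ |w_ih · w_ho| normalised to sum
to one; it is invariant to hidden-unit relabelling and splits importance
evenly across duplicated (perfect-LD) inputs.

## The polygenic 2′FL score

Selection is bidirectional stepwise search over Gaussian GLMs (identity
link on natural-log 2′FL, i.e. OLS) from the intercept-only model,
minimising AIC by default; BIC is available and is the criterion under
which selection is consistent (pure-noise responses keep the empty model —
with AIC and several candidates, chance inclusions are expected, which is a
property of AIC itself, not of the implementation). Perfectly collinear
columns are dropped up front, keeping the earlier-ordered one. The fit is
restricted to secretor mothers, whose rs601338 dosage is 0 or 1.

The score is the **signed allele sum** Σ sign(βₛ)·dosageₛ: a literal allele
sum cannot be negative, yet the high/moderate categorisation requires
negative scores, so the sign of each coefficient is attached to its allele
count; a β-weighted variant is available via `score_mode`. The score of an
all-major-homozygote is exactly 0; positive scores predict high, zero or
negative scores moderate 2′FL. Score→concentration prediction is OLS of log
2′FL on the score with adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2) reported
on held-out data; repeated K-fold cross-validation defaults to 20 × 10 at
package scale (the reference protocol's 200 × 40 is a config choice away).

## Synthetic cohort generator

The generator defines the study conditions the analyses are validated
under.

**Genotypes.** Diploid dosages at the 20-variant FUT2/FUT3 panel MAFs.
Within-gene LD comes from shared haplotype pools: each haplotype draws one
latent uniform U and carries the minor allele of SNP i iff U < MAFᵢ, which
nests the rarer allele inside the commoner one and realises the maximum
attainable pairwise r² = p(1−q)/(q(1−p)). Because that maximum falls below
0.8 for strongly unequal MAFs, blocks are auto-formed per gene by greedy
MAF-compatibility grouping at the target r² (default 0.8); SNPs that cannot
join any block are drawn independently, and user-forced infeasible blocks
fail with a diagnostic. Equal-MAF SNPs within a block are perfectly
correlated — the idealisation of the near-complete LD seen at these loci.

**HMO profiles.** Per sample, analyte and month, log concentration =
group log-median + slope·(month − 3) + heterozygote shift + N(0, σ).
Baseline month-3 medians are representative literature-scale values (the
reference study prints none); milk-group modifiers raise FUT3-dependent
analytes 3-fold in non-secretor milk (substrate not consumed by FUT2) and
leave 3FL a 15% residual in Lewis-negative milk. Absence gates override the
log-linear model: FUT2-dependent analytes (2′FL, LNFP-I, LDFT, LNDFH-I,
DFLNHa, A-tetra) are below LoD for genetic non-secretors; LNFP-II, LNnDFH,
LNFP-III and LNnFP-V below LoD for Lewis negatives; A-tetra is nonzero only
for secretors of blood group A (blood group A ~ Bernoulli(0.4), an assumed
cohort frequency — only the gate itself is asserted). Heterozygous carriers
of an inactivating allele have their dependent analytes attenuated by
2^(−dosage_effect) (default 0.5 → ×0.71, "intermediate levels");
dosage_effect = 0 disables the shift. Per-analyte slopes default to the
printed per-(analyte, group) coefficients with the pooled class slope as
fallback; a uniform-class-slope mode makes class sums decay exactly at the
class trend, which the recovery protocols use. Residual σ defaults to 0.5
on the log scale. Ground-truth labels are derived from the generated
genotypes through the rule classifier itself, so genetic truth and the rule
calls agree by construction; optional discordance injection overwrites a
configurable handful of samples' key analytes to mimic the
genotype/phenotype mismatches real cohorts show, and is off by default.

**Fixture.** `make_fixture_cohort()` builds a deterministic 152-sample
cohort: 18 rs601338 minor-allele homozygotes and 72 heterozygotes (108
minor alleles, MAF 108/304 = 0.3553), 7 rs812936 and 2 rs28362459
homozygotes on disjoint samples, no other rule-SNP homozygotes, and every
other variant filled to its panel MAF as closely as integer allele counts
allow (Hardy-Weinberg-rounded homozygote counts). The source material
reports both 9 and 8 Lewis negatives in different passages; the fixture
follows the 7 + 2 = 9 construction. HMO profiles are generated from the
fixture genotypes under a fixed internal seed with visit sizes 152/122/28
at months 3/6/12.

**What the generator does not emulate:** read-level noise and genotype
error, haplotype phase, population structure and relatedness, maternal
covariates (parity, diet, BMI), assay batch effects, within-mother
longitudinal correlation of HMO residuals, and the unexplained
genotype/phenotype discordances beyond the injected counts. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated generative model, not robustness to these real-data features.

## Evaluation protocols and problem sizes

The acceptance protocols (`hmolink.protocols`) fix the scales used
throughout: coefficient recovery of the score GLM on 50 simulated secretor
cohorts of n = 2000 (noise σ = 0.2, the five score SNPs drawn independently
at panel MAFs); MLP accuracy as the median over 10 cohorts of n = 500;
class-trend recovery over 20 cohorts of n = 1000 per month and per-analyte
trend recovery over 20 cohorts with 500 milk-group-1 mothers per month
(noise σ = 0.3). Trend-recovery runs disable LoD/LoQ censoring: at the
printed 6′SL slope, month-12 concentrations fall below any realistic LoD,
and censoring would bias the slope — the protocols measure the regression,
not the censoring policy. These sizes keep the full evaluation around two
minutes on one core.

## Known limitations

* The rank-score confidence interval uses the sign-test variant of the
  quantile rank-score test; with very few distinct x values and heavy ties
  it is conservative.
* Stepwise selection under AIC admits occasional noise variables by design;
  coefficient-recovery summaries average over seeds where the SNP was
  selected.
* Compound heterozygosity (two inactivating heterozygous variants in trans)
  is not modelled or called; the rule classifier will label such samples
  Lewis/secretor positive, as genotype-only rules must.
* The pipeline treats repeated milk samples from one mother as independent
  observations in dynamics fits, following the reference protocol.
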