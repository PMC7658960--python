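# hmolink

**From FUT2/FUT3 genotypes to human-milk-oligosaccharide phenotypes.**

Human milk oligosaccharides (HMOs) are the third most abundant solid
component of breast milk, and their composition is strongly shaped by two
maternal fucosyltransferase genes: *FUT2* (secretor locus, α-1,2-fucose) and
*FUT3* (Lewis locus, α-1,3/4-fucose). Inactivating polymorphisms define four
*milk groups* — 1 = Se+Le+, 2 = Se−Le+, 3 = Se+Le−, 4 = Se−Le− — each with a
characteristic HMO profile. `hmolink` is a tested analysis pipeline for
cohorts of genotyped, HMO-profiled lactating mothers:

* **QC** of genotype matrices (plink-style sample-missingness,
  variant-missingness and MAF filters at 0.05 / 0.05 / 0.01);
* **Secretor/Lewis/milk-group classification** from rule SNPs
  (Se− iff any of rs601338, rs1047781, rs200157007 is homozygous minor;
  Le− analogously over rs3745635, rs28362459, rs3894326, rs812936), plus a
  phenotypic milk-group call from 2′FL / LNFP-I / LNFP-II presence and a
  genotype-vs-phenotype concordance report;
* **Panel statistics** over 24 analytes (core / fucosylated / sialylated
  class sums, left-censoring substitution, Mann-Whitney group comparisons at
  p < 10⁻⁴, Pearson correlations with Benjamini-Hochberg FDR) and
  **multiscale-bootstrap clustering** (complete linkage on 1 − r,
  approximately-unbiased p-values by probit-curve extrapolation);
* **Lactation dynamics**: exact median (τ = 0.5, linear-programming)
  regression of log concentration on month (3/6/12), rank-score confidence
  intervals, BH q-values;
* **Milk-group prediction**: sparse-PLS selection of SNPs against the HMO
  matrix, a single-hidden-layer MLP classifier, and Garson weight-product
  variable importance;
* **A polygenic 2′FL score**: bidirectional stepwise GLM on log 2′FL of
  secretor mothers, the signed allele-sum score
  `S = Σ sign(β_s)·dosage_s`, score → concentration regression with
  held-out adjusted R², and high (S > 0) / moderate (S ≤ 0) categorisation;
* **A calibrated synthetic-cohort generator** (Hardy-Weinberg genotypes with
  within-gene LD blocks, milk-group-conditional lognormal HMO profiles with
  LoD/LoQ censoring, per-analyte lactation trends, a five-SNP generative
  model for 2′FL) plus a deterministic 152-sample fixture reproducing the
  reference cohort's printed genotype counts.

## Worked example

```python
import numpy as np
from hmolink import (CohortSimParams, simulate_cohort, call_statuses,
                     SPLSSelector, train_milkgroup_mlp)
from hmolink.stats import log_concentration_matrix

cohort = simulate_cohort(CohortSimParams(n_samples=500, seed=103))
calls = call_statuses(cohort.genotypes)
print(sum(c.secretor == "Se-" for c in calls))   # 55 non-secretor mothers

logm = log_concentration_matrix(cohort.hmo, month=3)
X = cohort.genotypes.dosages.loc[logm.index]
y = cohort.truth.set_index("sample_id").loc[logm.index, "milk_group"]
sel = SPLSSelector().fit(X, logm)                # sparse-PLS SNP selection
mlp = train_milkgroup_mlp(sel.transform(X), y.to_numpy(), seed=103)
print(sel.n_selected_, round(mlp.test_accuracy_, 3))   # 10 0.987
```

The simulated 500-mother cohort contains 55 genetic non-secretors
(rs601338 A/A); sparse PLS keeps 10 SNPs whose dosages covary with the HMO
panel, and the milk-group MLP classifies 98.7% of held-out mothers
correctly — milk group is a deterministic function of the rule SNPs, so
accuracy is limited only by rare genotype patterns unseen in training.

The same pipeline runs from the shell:

```bash
hmolink simulate --seed 103 --outdir out/       # simulate + full analysis
hmolink all --genotypes cohort.vcf --hmo hmo.csv --outdir out/
```

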