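# ldlmed

Does small dense LDL (sdLDL) carry part of the association between
LDL-cholesterol and whole-blood gene expression?  `ldlmed` implements the
computational chain needed to ask that question of a bulk RNA-seq cohort:

1. **Tertile-extremes differential expression** — per-gene negative-binomial
   GLMs contrasting the upper vs lower tertile of a lipid phenotype
   (LDL-C or sdLDL), adjusted for age, sex and education, with
   likelihood-ratio tests and Benjamini–Hochberg FDR control.
2. **A three-condition mediation screen** — a gene's LDL-C association is
   called *mediated by sdLDL* when (i) the LDL-C contrast is FDR-significant,
   (ii) the sdLDL contrast is FDR-significant, the two log fold changes are
   sign-concordant, and (iii) the LDL-C logFC attenuates once sdLDL enters
   the model as a covariate.  The **proportion mediated** is
   `PM = 100 · (1 − logFC_adjusted / logFC_base)`, clamped to [0, 100].
3. **Sex-stratified mediation** — the screen re-run inside the female and male
   strata (tertiles and TMM factors recomputed per stratum, sex dropped from
   the covariates) and a four-way classification: mediated in *both*,
   *females only*, *males only*, or *neither*.
4. **Hypergeometric gene-set enrichment** of the mediated gene list against a
   user-supplied GMT collection.

Because cohort lipid + expression data of this kind are typically
access-restricted, the package ships a **calibrated synthetic cohort
generator**: truncated-Gaussian LDL-C and sdLDL with a configurable Pearson
correlation (default 0.40, calibrated exactly despite the truncation at
zero), demographic covariates, and NB read counts whose log-mean carries
planted direct and sdLDL-mediated LDL-C effects with known ground truth.
Every downstream stage is validated by parameter-recovery simulation against
that truth.

The analysis stages are scikit-learn-style estimators (`TMMNormalizer`,
`LowExpressionFilter`, `TertileDE`, `MediationScreen`,
`SexStratifiedMediation`, `HypergeometricEnrichment`) with plain-function
equivalents, plus a `ldlmed` command-line interface.

## Worked example

```python
from ldlmed import (SimulationConfig, simulate_cohort,
                    run_mediation_pipeline, stratified_mediation,
                    filter_low_expression)

ph, counts, truth = simulate_cohort(SimulationConfig(n_samples=300, n_genes=300, seed=7))
records, summary = run_mediation_pipeline(counts, ph)
print(summary)
```

prints the stage accounting of the screen:

```
{'n_genes_tested': 300, 'n_significant_ldl': 34, 'n_significant_sdldl': 30,
 'n_overlap': 30, 'n_concordant': 30, 'n_mediated': 30}
```

34 genes associate with LDL-C and 30 with sdLDL at FDR ≤ 0.05; all 30 genes
significant in both contrasts are sign-concordant, and all 30 pass the
attenuation condition.  The strongest mediated genes show near-complete
mediation — their adjusted logFC collapses toward zero:

```
         logfc_ldl  logfc_sdldl  logfc_ldl_adjusted  proportion_mediated
G00296       0.428        1.192              -0.091                100.0
G00298      -0.546       -1.741               0.059                100.0
G00289       0.776        1.858              -0.053                100.0
```

(these genes were planted with a purely indirect LDL-C effect, so a true PM
of 100% is recovered).  Re-running the screen within each sex,

```python
filtered = filter_low_expression(counts)
table, sex_summary = stratified_mediation(filtered, ph, records.index[records.mediated])
print(sex_summary)   # {'both': 27, 'female_only': 1, 'male_only': 2, 'neither': 0}
```

classifies 27 of the 30 mediated genes as mediated in both sexes — the
expected outcome here, since this cohort was simulated with sex-homogeneous
effects.

The same pipeline runs from the shell:

```bash
ldlmed simulate --n-samples 400 --n-genes 2000 --seed 1 --outdir run/
ldlmed mediate --counts run/counts.tsv --phenotypes run/phenotypes.csv --out run/mediation.tsv
ldlmed enrich --genes run/mediated.txt --universe run/universe.txt --gmt pathways.gmt
```

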