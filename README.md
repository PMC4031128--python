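# microsel

Compositional feature selection for case-control microbiome cohorts, plus the
supporting diversity and prevalence statistics.

The core pipeline treats an OTU count table as compositional data: counts are
closed to proportions with an additive pseudocount, transformed with the
centered log-ratio (clr), filtered to the most variable features, and fed to
a sparse Partial Least Squares Discriminant Analysis (sparse PLS-DA) whose
sparsity (`eta`) and number of latent components (`K`) are tuned by
stratified cross-validation. Feature significance is assessed by resampling:
a class-stratified bootstrap of the model coefficients is compared against a
permutation null, and a feature's pseudo p-value is one minus the fraction
of its bootstrap draws lying at or beyond the null's two-sided tail
thresholds. Selected features and sample scores are exported as biplot
coordinates.

Alongside the selection pipeline the package provides Shannon/observed-OTU
alpha diversity with rarefaction (subsampling without replacement), a
pooled-variance two-sample t-test, Bray-Curtis distances with ANOSIM, binomial
prevalence estimates with 95% Wald confidence intervals, and a synthetic
cohort generator with known discriminative taxa for end-to-end testing.

## Command-line usage

```bash
# generate a synthetic two-class cohort (OTU table + mapping + truth TSVs)
microsel simulate --out-dir cohort --n-pos 36 --n-neg 15 --n-otus 200 \
    --n-disc 10 --effect 1.5 --seed 1

# run the full selection pipeline
microsel select --table cohort/otu_table.tsv --mapping cohort/mapping.tsv \
    --class-column Helminth --n-boot 1000 --n-perm 1000 --alpha 0.05 \
    --seed 1 --out-dir results_select

# diversity statistics (alpha, rarefaction, Bray-Curtis + ANOSIM, t-test)
microsel diversity --table cohort/otu_table.tsv --mapping cohort/mapping.tsv \
    --seed 1 --out-dir results_div

# binomial prevalence with a 95% Wald CI
microsel prevalence --x 36 --n 51
```

Input formats are the classic tab-delimited OTU table (header `#OTU ID`,
samples as columns, optional trailing `taxonomy` column) and the tab-delimited
mapping file (header `#SampleID`). All outputs are TSV; run logs record the
package version, a config hash, and every seed, and repeat runs with the same
config are byte-identical. Exit codes: 0 ok, 1 user error, 2 internal error.

## Layout

```
src/microsel/
  io.py             table/mapping readers and writers, sample alignment
  compositional.py  closure, clr transform, variance filtering
  splsda.py         sparse PLS-DA fit, prediction, cross-validated tuning
  significance.py   bootstrap, permutation null, pseudo p-values, biplots
  diversity.py      alpha metrics, rarefaction, t-test, Bray-Curtis, ANOSIM,
                    prevalence CIs
  simulate.py       synthetic cohort generator with ground truth
  cli.py            `microsel` entry point
tests/              pytest suite (unit, property, acceptance)
scripts/acceptance.py
```
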