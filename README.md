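# gwlpheno

Quantitative analysis of cellular responses to Greatwall-kinase (GWL/MASTL)
inhibition.

GWL suppresses PP2A-B55 phosphatases during mitosis by phosphorylating
ENSA/ARPP19; inhibiting GWL de-represses PP2A-B55α, destabilises mitotic
phosphorylation and forces premature mitotic exit, with polyploidisation,
p21 induction and multinucleation as the long-term fallout. Sensitivity to
GWL inhibition varies between cell lines and tracks the balance of GWL and
B55α expression. This package implements the complete quantitative workflow
for characterising those responses, for anyone running high-content
phenotyping or drug-sensitivity studies around GWL-targeting compounds:

- **`cellfeatures`** — first-peak intensity normalisation of per-cell
  DNA/EdU/p21 features and gating into 2N / S / 4N / 8N+ classes with
  p21+ and multinucleation flags;
- **`response`** — the phenotypic drug-response statistic: Euclidean
  distance *d* between cell-cycle proportion vectors of control and
  treated populations, its dose-profile AUC, and Shapiro-gated
  t/Wilcoxon group comparisons with Cohen's d and Benjamini–Hochberg
  adjustment;
- **`similarity`** — off-target screening by phenotype: subsample cells,
  co-embed five features with UMAP, score conditions by exact
  1-Wasserstein distance to a reference condition;
- **`doseresp`** — four-parameter log-logistic (LL.4) dose-response
  fitting, `f(x) = c + (d−c)/(1 + exp(b·(ln x − ln e)))`, with
  replicate-wise ED50 mean ± SD aggregation and proliferation AUC;
- **`biomarker`** — the expression-ratio sensitivity model
  `*ED50 = gradient × GWL/B55α + intercept` (unweighted OLS), prediction,
  lowest-5% flagging, and tumour-vs-normal cohort median-shift analysis;
- **`phospho`** — differential phosphosite statistics: sum normalisation,
  log2, min−1 zero-imputation, median centring, empirical-Bayes moderated
  t-test, the p < 0.05 & FDR < 0.1 hit gate, +1-proline motif enrichment
  and multi-dataset hit intersection;
- **`synth`** — seeded generators for every input type (per-cell feature
  tables, colony curves, expression panels, phosphosite matrices,
  cohorts) with ground truth serialised next to the data;
- **`pipeline`** / CLI — configuration, orchestration and manifests.

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

Fit the sensitivity model on a synthetic 12-line panel generated from the
ratio model with 0.05 µM noise, and recover an ED50 from simulated colony
counts:

```python
from gwlpheno import synth
from gwlpheno.biomarker import fit_ratio_model, predict_ed50
from gwlpheno.doseresp import FourPL, fit_replicates, ed50_with_replicates

panel, truth = synth.gen_expression_panel(
    n_lines=12, gradient=0.399, intercept=0.406, noise_sd=0.05, seed=7)
model = fit_ratio_model(panel)
print(f"gradient  = {model.gradient:.3f} uM per ratio unit")
print(f"intercept = {model.intercept:.3f} uM")
print(f"R^2 = {model.r_squared:.2f}, p = {model.p:.2e}, n = {model.n}")

curve = FourPL(slope=2.0, lower=0.0, upper=1.0, midpoint=0.09)
doses = [0.0, 0.031, 0.0625, 0.125, 0.25, 0.5, 1.0, 2.0]
table, _ = synth.gen_dose_response(curve, doses, replicates=3,
                                   noise_cv=0.10, seed=7)
mean, sd = ed50_with_replicates(fit_replicates(table))
print(f"ED50 = {mean:.3f} +/- {sd:.3f} uM")
```

prints

```
gradient  = 0.388 uM per ratio unit
intercept = 0.392 uM
R^2 = 0.97, p = 8.05e-09, n = 12
ED50 = 0.090 +/- 0.009 uM
```

The fitted gradient and intercept sit within noise of the generative
coefficients (0.399 and 0.406 µM), with the ratio explaining 97% of the
ED50 variance on this panel; the replicate-mean ED50 lands on the
generative 0.09 µM with the spread of three independent 10%-noise fits.

The whole workflow runs end to end on synthetic data from the CLI:

```bash
gwlpheno run --seed 3 --outdir demo
```

which simulates three synthetic cell lines of graded sensitivity
(ploidy-shift midpoints 0.2, 0.5 and 1.5 µM), gates them, and writes tidy
tables under `demo/`: `response/auc.csv` ranks the lines by Euclidean-d AUC
(520.8, 478.8 and 403.9 µM·distance — the most sensitive line responds
most), `doseresp/ed50.csv` recovers their colony ED50s
(0.23 ± 0.02, 0.47 ± 0.04 and 1.43 ± 0.20 µM), and
`biomarker/ratio_model.csv`, `similarity/wasserstein.csv` and
`phospho/site_stats_*.csv` hold the remaining analyses, with a
`manifest.json` recording config hash and seed. Re-running with the same
seed reproduces every file byte-for-byte. Individual stages are available
as subcommands (`simulate`, `gate`, `respond`, `similarity`, `fitdose`,
`biomarker`, `phospho`), configured by `--config config.yaml`.

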