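# Methods

This note documents the models and procedures implemented in `gwlpheno`, the
assumptions behind them, the parameters that matter, and the numerical
choices made where the design was genuinely open.

## Scientific setting

Greatwall kinase (GWL/MASTL) keeps PP2A-B55 phosphatases switched off during
mitosis by phosphorylating ENSA/ARPP19. Chemical GWL inhibition de-represses
PP2A-B55α, destabilises mitotic phosphorylation, and drives premature mitotic
exit with downstream polyploidisation, p21 induction and multinucleation.
How hard a given cell line is hit varies, and the balance between GWL and
B55α expression is a candidate predictor of that sensitivity. The package
implements the quantitative workflow for characterising these responses:
per-cell cell-cycle phenotyping, a scalar drug-response statistic, a
phenotypic-similarity screen for off-target effects, dose-response (ED50)
estimation, the expression-ratio sensitivity model, and differential
phosphoproteomics statistics — with seeded generators for every input type
so each stage is verifiable against known ground truth.

## Per-cell phenotyping (`cellfeatures`)

**Normalisation.** Integrated DNA, mean EdU and mean p21 intensities arrive
in arbitrary units. Each is divided by the location of the *first peak* of
the corresponding distribution in an untreated reference population of the
same line, estimated as the lowest local maximum of a Gaussian KDE
(Silverman bandwidth) whose height is at least 10% of the global maximum —
the floor ignores noise bumps; the lowest-mode rule makes the G1 (2N) mode of
the DNA distribution map to 1 genome equivalent and the negative-population
mode of EdU/p21 map to 1. Cell areas are divided by the reference median.
The procedure is exactly invariant to global multiplicative gain, which the
synthetic generator deliberately exercises with gains far from 1. For
aneuploid (e.g. near-triploid) lines the convention is relative ploidy:
"2N" means the first peak, whatever the absolute karyotype.

**Gating.** EdU positivity takes precedence: an EdU+ cell is S-phase
regardless of DNA content (a replicating tetraploid is still replicating —
this precedence is a design decision, as the alternative is not
specifiable from distributions alone). Remaining cells split by normalised
DNA content at 1.5 and 3.0 genome equivalents (the midpoints between the
expected 1/2 and 2/4 peak positions on the linear scale) into 2N, 4N, 8N+.
EdU+ and p21+ thresholds default to 3x the normalised first peak. All
gates are configuration-exposed because no canonical values exist; the
defaults give ≥95% agreement with generator truth at 10% peak CV, which is
what the tests pin.

## Drug-response statistic (`response`)

Population response to a dose is summarised as the Euclidean distance *d*
between the (2N, S, 4N, 8N+) proportion vectors (percent scale, so
*d* ∈ [0, 100√2]) of control and treated populations; a dose profile of *d*
is reduced to its trapezoidal AUC over the tested grid (µM × distance).
The AUC is computed on the actually tested doses, not an interpolated grid.
Group comparisons elsewhere in the workflow use a Shapiro–Wilk gate at
α = 0.05: unpaired two-tailed t-test when both samples pass, otherwise the
unpaired two-tailed Wilcoxon rank-sum test (the unpaired design makes the
rank-sum, not the signed-rank, variant the coherent choice). Effect sizes
are Cohen's d with pooled (n−1) SD; families of p-values are adjusted with
Benjamini–Hochberg.

## Phenotypic similarity (`similarity`)

To compare whole phenotypes rather than class proportions, 500 cells per
condition (the screening convention; configurable) are subsampled, five
features (DNA, EdU, p21, area, nuclear count) are log1p-transformed where
right-skewed and jointly z-scored, and a single UMAP (15 neighbours,
min-dist 0.1, fixed seed) is fitted on the pooled cells of all conditions.
Joint fitting is essential: per-condition embeddings would have
incomparable coordinates. Each condition is scored by the 1-Wasserstein
distance of its 2D cloud to the reference condition. For equal-size uniform
empirical measures exact W1 is an assignment problem, solved with the
Hungarian algorithm (`scipy.optimize.linear_sum_assignment`); unequal
clouds are equalised by seeded subsampling. A sliced approximation
(averaged 1D transport over random directions) is available behind a flag
for large clouds; it lower-bounds the 2D value and is itself a metric, but
is not used by default. The distance of two disjoint random halves of the
reference cloud is reported as the finite-sample noise floor. Whether to
transport in 2D jointly or per-axis was open; exact 2D OT was chosen as
the faithful reading of "distance between the projections".

## Dose-response fitting (`doseresp`)

Four-parameter log-logistic (LL.4) curves
`f(x) = c + (d − c) / (1 + exp(b·(ln x − ln e)))` with slope *b*, lower *c*,
upper *d* and midpoint *e* (the EC50/ED50). Dose 0 is handled by the
asymptote limit rather than a log-offset. Positive slope means response
falls with dose; dose→effect transfer curves in the generators therefore
use negative slope. Fitting is unweighted least squares
(`scipy.optimize.least_squares`, tight tolerances) over (b, c, d, ln e),
started from the best of a coarse midpoint × slope grid, with the midpoint
bounded in [min positive dose / 10, max dose × 10]. Asymptotes are
unconstrained by default (whether published fits constrained them is
unknowable; bounds are accepted as options). Standard errors come from the
Gauss–Newton curvature at the optimum (delta method for the midpoint).

Replicate handling follows the independent-experiment convention: one fit
per replicate series, then the arithmetic mean ± sample SD of midpoints.
Two classes of fit are excluded from aggregation, with a warning:

- **non-converged** — optimiser failure, or a midpoint pinned to its
  bounding box (a flat, noise-dominated series lets the midpoint run away);
- **non-estimable** — a midpoint outside [min positive dose, max dose].
  A midpoint the dose grid does not bracket is an unsupported
  extrapolation; the standard report is "ED50 > max dose", not a number.
  At 10% noise CV roughly 3% of single-replicate fits fall in this class;
  unfiltered they dominate the mean while leaving the median untouched.

`normalize_to_max` and `proliferation_auc` implement the max-scaling and
count-AUC conventions for proliferation readouts.

## Expression-ratio sensitivity model (`biomarker`)

The predictive model is simple OLS of experimental ED50 (µM) on the scalar
ratio GWL/B55α:

    *ED50 = gradient × GWL/B55α + intercept

with unweighted fitting and the two-tailed t-test on the Pearson r
(R² = r² for a single predictor). The scalar-ratio predictor — not a
two-covariate regression — is the published model form; expression inputs
are either GAPDH-normalised, max-scaled densitometry (each analyte's top
sample = 1) or untransformed TPM/FPKM values. Mean-per-line expression is
assumed when replicates exist. Predictions with B55α = 0 are flagged, not
produced, and predictions are not truncated at a floor. Sample flagging
takes the ⌈fraction·n⌉ lowest predictions (default 5%), stable-ordered on
ties; the rule is invariant to monotone transforms of the predictions.

Cohort analysis computes per-group tumour-minus-normal median shifts per
gene, with unpaired two-tailed Wilcoxon rank-sum tests (exact below 25 per
arm, normal approximation above) and BH adjustment across all determined
tests; groups without normal samples are reported "nd", never tested.

## Phosphoproteomics statistics (`phospho`)

The processing order for a sites × samples XIC intensity matrix is fixed
as: per-sample sum normalisation → log2 → zero-imputation as (that
sample's minimum log2 value − 1) → per-sample median centring. The order
is forced by the imputation rule itself, which references the log2 sample
minimum; "centring" was ambiguous between per-sample and per-feature, and
per-sample was chosen (it composes with the per-sample normalisation into
a column-wise location/scale correction and keeps the matrix invariant to
per-sample rescaling, which is property-tested).

The differential test is an empirical-Bayes moderated t: per-site pooled
two-group variances s² with df = n₁+n₂−2 are shrunk towards a prior,
s̃² = (d₀s₀² + df·s²)/(d₀ + df), and the moderated statistic is referred to
a t distribution with df + d₀ degrees of freedom. The prior (d₀, s₀²) is
estimated by the method of moments on log s² (digamma/trigamma matching,
Newton inversion of the trigamma); d₀ = ∞ degenerates to the pooled-prior
SE and d₀ = 0 recovers the ordinary t-test exactly, both of which are
tested, the latter also against an independent implementation. Hits
require p < 0.05 AND BH-FDR < 0.1, signed by the log2 fold change
(second group minus first, groups in sorted name order).

Note the cost of min−1 imputation: a single imputed zero drags a site's
group mean and inflates its variance, so sites with missing entries lose
power (at the generator's default 5% missingness, ~a quarter of truly
changed sites are masked at spike-in effect 3). This is inherent to the
rule, not a defect of the test; calibration and power statements in the
tests therefore isolate the test on complete matrices.

Motif analysis computes per-class residue frequencies over ±7-residue
windows ('X' padding excluded from denominators) and a two-sided Fisher
exact test of proline at +1 in each hit class against the not-significant
background — the minimal Cdk1-consensus signature expected to dominate
sites destabilised by PP2A-B55α de-repression. Hit-set intersections
report every exclusive Venn region and the shared fraction
|common| / |union|.

## Synthetic data (`synth`)

The generators emulate the statistical structure the analyses assume, with
all randomness through explicit integer seeds (`numpy` Generator; no
global state) and ground truth serialised next to every dataset.

- **Cell populations**: class sampled from dose-adjusted probabilities — a
  4PL transfer curve moves a dose-dependent fraction of {2N, S} mass into
  {4N, 8N+} proportionally to their baseline weights, so expected class
  fractions (and hence the expected Euclidean-d profile) have a closed
  form. DNA intensity is lognormal with medians gain×{1, 2, 4} for
  2N/4N/8N+ and CV = `peak_cv` (default 10%); S cells draw DNA uniformly
  between the 2N and 4N medians with a ~10× EdU component; p21 has a ~5×
  elevated component in the p21+ fraction; areas are lognormal scaled by
  ploidy; multinucleated cells carry 2–4 nuclei. The arbitrary-unit gain
  (default 1, pipeline uses 1000) forces the normalisation stage to matter.
  Baseline class fractions default to (0.5, 0.2, 0.2, 0.1) — a proliferating
  culture with a G1 majority; no canonical per-line values exist, so these
  are free parameters, not calibrated to any published panel.
- **Dose-response curves**: 4PL(dose) × mean-one lognormal noise
  (µ = −σ²/2), so the expected value equals the curve at every dose;
  default CV 10% with 3 replicates, matching triplicate colony assays.
- **Expression panels**: scaled GWL and B55α uniform on [0.2, 1] (the
  dynamic range of max-scaled densitometry), ED50 linear in the ratio plus
  Gaussian noise (default 12 lines, gradient 0.399, intercept 0.406,
  noise 0.05 µM), truncated at a 0.01 µM floor.
- **Phosphosite matrices**: per-site log2 baselines N(20, 2), residual SDs
  from a scaled inverse-chi-square (d₀ = 4, s₀ = 0.25) — the hierarchical
  model the moderated test assumes — with ±`effect_log2` (default 3)
  shifts for spiked down/up fractions, a stated fraction of intensities
  zeroed (default 5%), and 15-mer windows whose +1 position is proline
  with probability 0.6 for down-regulated sites vs 0.2 background
  (odds ratio 6, in the range of a strong kinase-consensus bias).
- **Cohorts**: lognormal FPKM-like values (σ = 0.6) per gene and sample,
  tumour groups shifted on the log scale; groups may lack normals.

What the generators do **not** emulate: segmentation errors and
debris/doublet artefacts in feature tables, batch effects, correlated
phosphosites within proteins, missing-not-at-random intensity dropout,
and inter-gene correlation in cohorts. Passing tests therefore demonstrate
correctness of the statistical machinery under its stated model, not
robustness to every pathology of real screens.

## Pipeline (`pipeline`, CLI)

Stages run in dependency order (simulate → gate → respond/similarity;
simulate → fitdose/biomarker/phospho), each reading/writing tidy CSV under
the output directory; a failed stage halts its dependents but not
independent branches. µM is the canonical concentration unit and percent
(0–100) the canonical proportion scale. Every run writes `manifest.json`
(config hash, seed, versions, relative output paths); identical config and
seed reproduce every output byte-for-byte, which is tested. Stage seeds
are spawned from the global seed via `numpy.random.SeedSequence`, so
stages are independently reproducible.

Default problem sizes (2,000 cells per condition, three synthetic lines,
1,500 phosphosites × 3 datasets, 50-simulation recovery runs) were chosen
to make every statistical check well-powered while a full synthetic run
stays in the minutes range on a laptop.

## Known limitations

- The first-peak estimator assumes the negative/2N mode is the *lowest*
  KDE mode above the height floor; a sub-G1 debris peak above 10% height
  would be mistaken for it (upstream QC should remove debris).
- Exact W1 scales as O(n³) in the assignment solve; beyond ~2,000 points
  per side use the sliced approximation.
- The moderated test assumes independent sites; BH control is valid under
  positive regression dependence but the test ignores protein-level
  correlation.
- ED50s outside the tested dose grid are reported as non-estimable rather
  than extrapolated; panels whose true midpoint sits at the grid edge will
  lose replicates to this rule.
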