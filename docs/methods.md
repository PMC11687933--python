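# Methods

This note documents the statistical procedures dsimmune implements, the
design choices made where conventions were genuinely open, what the
synthetic-data generator does and does not emulate, and the numerical
details that matter for reproducing results.

## Autoantibody arrays

Bead-array median fluorescence intensities (MFI) carry a strong
sample-specific background (total IgG, plasma quality, coupling
efficiency). Each sample (reaction) is therefore standardized to MAD
units, `(MFI − median_sample) / MAD_sample`, where the median and MAD run
over that sample's antigens. The MAD is the *raw* median absolute
deviation — no 1.4826 normal-consistency constant — because downstream
thresholds are percentile-based within the same scale, so the constant
would cancel nothing and only obscure threshold values. It is exposed as
`mad_constant` for anyone who wants the consistent estimator. Samples with
zero spread (constant MFI) have no defined scale and are rejected by name
rather than silently propagated.

Positivity per antigen is a *strict* exceedance of the 90th percentile of
the euploid (D21) control samples' MAD values. Percentiles use linear
interpolation (the type-7 convention, the default of most statistical
software); the convention is configurable because the positivity boundary
moves with it. Antigens called positive in fewer than 18 samples are
excluded before testing; "detected" is read as "called positive", the
conservative reading, and the count threshold is a parameter.

Enrichment is Fisher's exact test per antigen (two-sided by default, a
one-sided option exists), with Benjamini–Hochberg correction across tested
antigens and significance at q < 0.1. Odds ratios are the cross-product
with a Haldane 0.5 correction when any cell is zero, so they stay finite.
Within-T21 condition associations use the same machinery restricted to one
karyotype, skipping conditions with fewer than five cases.

A calibration caveat discovered during testing and worth knowing: because
thresholds are order statistics of the *control* group only, the control
margin of each 2×2 table is nearly deterministic while the T21 margin
floats. When antigen positivity is rare (<~10 %) the threshold sits in the
gap between the background and positive clusters and the test calibrates
correctly (verified by null simulation); when positivity is common the
threshold lands inside the positive cluster and the test becomes
anticonservative. The procedure is intended — and calibrated — for the
rare-positivity regime of autoantibody arrays.

Scalar assays: the anti-TPO index is `(sample − neg) / (pos − neg)`
control-normalized signal, positive above the 95th percentile of healthy
controls and undefined when the positive control does not exceed the
negative; the ANA call is the OD ratio against the negative control with
the ≥ 2.1 positivity rule (boundary inclusive).

## Composite interferon and cytokine scores

Features (log2(FPKM+1) expression, or log2 pg/mL analytes) are
residualized on nuisance covariates — age (years), sex, sequencing batch
or sample source — by per-feature least squares that *includes* the
karyotype/group term, so nuisance coefficients are estimated within groups
and subtracting them preserves group contrasts exactly (verified by
refit). Applying a model to samples at the stored reference covariate
values is the identity. Expression is log-transformed before adjustment
because FPKM variance grows with the mean; a caller can pass untransformed
values to reproduce a strictly literal adjusted-FPKM reading.

Z-scores come in two modes. Reference mode standardizes each feature
against the mean and SD of the adjusted euploid-control samples, so a
score of +k means k summed reference SDs above the euploid expectation;
features with zero reference variance are rejected with a report.
Internal mode standardizes across the supplied sample set itself (all
trial timepoints pooled — the pooled choice is deliberate and switchable
to baseline-only standardization). The composite score is the plain sum
of panel Z-scores, so it is additive over disjoint panels.

The ISG panel is selected from a differential-expression table: observed
fold-change ≥ 1.5 (boundary inclusive), q < 0.1, excluding *IFNAR2*,
*MX1* and *MX2*, which sit on chromosome 21 and are elevated by gene
dosage rather than IFN signalling. The panel is always derived from a
supplied DE table or passed explicitly — there is no hard-coded gene list.
The cytokine score sums Z-scores of TNF-α, IL-6, CRP and IP-10.

Group comparisons report the median difference with a Mann–Whitney U
p-value: the exact U distribution when both groups have ≤ 12 untied
observations, otherwise the normal approximation with midrank tie
correction. Paired trial comparisons use the two-sided Wilcoxon
signed-rank test, zeros dropped, exact for ≤ 15 non-zero untied
differences, with BH correction across the endpoint family. Both tests are
validated against full enumeration oracles at small n.

## Compositional immunophenotyping

Cluster relative frequencies live in (0, 1); they are modelled with a beta
likelihood in the mean–precision parametrization, Beta(μφ, (1−μ)φ), logit
link for μ, and a single constant φ (no precision covariates, matching a
single mean submodel). Before fitting, extreme outliers are fenced per
karyotype and per cluster — values more than 3×IQR beyond the quartiles
are excluded, strictly, so a value exactly on the fence survives — and
proportions are squeezed off the boundary with `(y(n−1) + 0.5)/n`.
Fencing precedes squeezing and fitting.

The fit maximizes the likelihood by quasi-Newton (BFGS) from logit-scale
least-squares starting values with a method-of-moments φ; when the line
search stalls at a stationary point the gradient norm is checked directly
and a Nelder–Mead polish is applied if needed. Standard errors come from
the inverse observed information and group p-values are two-sided Wald
tests, BH-corrected across clusters *within* a gating level (pooling
across levels is switchable). The model is fitted through statsmodels'
beta-regression implementation; an independent grid-search likelihood
maximization in the test suite confirms the optimum on small instances.

`exp(β_group)` under the logit link is an **odds**-scale fold-change. For
rare clusters this approximates the frequency ratio; for common clusters
it does not, so the results table also carries `mean_ratio`, the ratio of
fitted means at reference covariates, to prevent misreading. Display
adjustment (residualizing logit proportions on age/sex and re-centering)
exists for plotting only; inference never touches those values.

## Plasma analytes

Wells flagged below (above) the detection/fit-curve range are replaced by
the minimum (maximum) of the in-range *calculated* concentrations for that
analyte on the same plate — not the nominal assay limits — and duplicate
wells are averaged after replacement. Zero or negative calculated
concentrations are treated as below range so log2 stays defined. Plates
with no in-range values for an analyte are dropped with a report, and
analytes with more than 10 % (strict) of values out of range are flagged.
Imputed values can never leave the plate's in-range envelope (tested as an
invariant). Min/max imputation attenuates effect estimates for heavily
censored analytes — the low-abundance analyte in the default synthetic
panel shows this — which is a property of the procedure, not a bug; the
flag is what marks those analytes as unreliable.

Differential abundance fits, per analyte, a linear mixed model of log2
concentration: karyotype (or clinical subgroup) + age + sex as fixed
effects and sample source as a random intercept, by REML. Fixed-effect
p-values use the normal (Wald) approximation — at cohort-scale n the
difference from Satterthwaite degrees of freedom is negligible. With a
single source the model falls back to OLS with a warning; at a zero
variance-component boundary estimate, where the mixed information matrix
can be singular, inference likewise falls back to the OLS limit of the
same family. BH correction runs across analytes at q < 0.1. The
age-vs-karyotype decomposition pairs the mixed-model karyotype effect
with a within-T21 linear age slope, BH-corrects each family separately,
and classifies analytes as "T21 only", "age only", "both" or "ns".

## Trial endpoints

Changes from baseline are per-participant differences `value(week) −
value(0)`; participants missing either visit are reported, never silently
dropped. "Decreased" is strict (< 0): ties count against the treatment.
ULN response reports, for participants strictly above the upper limit of
normal at baseline (60 U/mL anti-TPO, 4 IU/mL anti-TG by default), who
decreased at each requested week, who decreased at *all* requested weeks
(every visit required), and who crossed below the ULN at any on-treatment
visit. The safety rule passes when at most two serious adverse events are
definitely attributable to treatment; week-40 extension data are carried
but excluded from 16-week endpoints by default, and endpoint q-value
display can be suppressed to mirror interim-analysis reporting rules.

## The synthetic generator

The generator produces cohorts with the dependence structure the analyses
assume, under one root seed; each table draws from its own fixed
`SeedSequence` substream, so adding or regenerating a table never
perturbs the others, and identical configs give bit-identical bundles.

Default conditions mirror the autoantibody-array arm of a T21 cohort
study: 120 T21 and 60 euploid participants, ages ~1–57, AITD prevalence
53 % in T21, immune-skin-condition prevalence 43 %, celiac 10 %. Antigens
are log-normal backgrounds plus a per-sample background offset; positive
samples gain +3 log-MFI. Eight antigens carry true enrichment (40 % vs
5 % positivity), twenty-two are null at 12 %. Analytes are log2-normal
with T21 fold-changes of 0.3–0.9 log2 units on the cytokine-score
components and related markers, an age slope on CRP, plate and source
effects, two replicate wells, and hard detection limits recorded as flags
plus missing values (never clipped numbers) so the imputation path is
always exercised; plate assignment is randomized so plate effects cannot
alias the karyotype contrast. Sixteen ISGs span true fold-changes of
1.5–3×, three chromosome-21 genes are elevated but excluded by rule, and
ten null genes calibrate the panel threshold. Compositions are
logistic-normal (softmax of shifted log-baselines) with odds-scale T21
effects on B cells, basophils and eosinophils. The trial follows 10
participants at weeks 0/2/8/16 with negative treatment effects on IFN
score, cytokine score and thyroid autoantibody titers; baselines put
roughly 70 % above the anti-TPO ULN and 30 % above the anti-TG ULN, and
two configured immune-trigger spikes (week 8 and week 16, affecting the
scores but not the titers) emulate vaccination/infection visits.

What the generator does **not** emulate: bead-level array artifacts,
standard-curve fitting, cytometry event data or clustering, RNA-seq
counts (expression is generated at the FPKM level and differential
expression is a simple Welch test on log2 values), real age trajectories
beyond linear slopes, or correlations between data modalities within a
participant beyond the shared covariates. Passing tests therefore show
that the *procedures* are correct and calibrated under their assumed
models — not that those models capture every property of real cohort
data.

## Verification strategy and problem sizes

Exact tests are compared with independent enumeration oracles: Fisher p
against hypergeometric tail enumeration on every 2×2 table with total
n ≤ 40; Mann–Whitney and Wilcoxon against full labeling/sign enumeration
at n ≤ 10; BH against a direct step-up on lists ≤ 20. Null calibration
uses 200 cohort replicates per test family (antigens at 12 % positivity
with 120/60 samples; six null clusters at 100/100; eight null analytes at
50/50), checking per-feature rejection at α = 0.05 against exact binomial
99 % bounds (upper bound only for Fisher, which is discrete and
conservative) and that the mean BH q < 0.1 rejection fraction stays at or
below nominal. Parameter recovery runs at n = 500 (beta regression,
β_group = 0.5, φ = 50, tolerance ±0.1), n = 400 (mixed model, 1.0 log2
units, ±0.15), n = 300 (cluster log-odds ln 2 → fold-change in
[1.7, 2.3]) and n = 100/100 (composite-score separation, one-sided
Mann–Whitney p < 0.01). These sizes were chosen to match the regimes the
procedures are designed for while keeping the full suite runnable in a
couple of minutes on one CPU.
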