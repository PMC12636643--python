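# Methods

This note documents the models and procedures the package implements, the
defaults and why, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Harmonization

**Loading scaling.** Each sample's observed intensities are divided by
their sum and multiplied by the maximum pre-scaling column sum, so every
sample carries equal total signal. Missing cells (raw zeros, masked by
`zeros_to_missing`) are excluded from the sums and left untouched.

**TAMPOR.** Within each TMT batch, each protein's intensities are divided
by the protein's median over the batch's denominator samples (all batch
samples by default; a designated reference set, e.g. pooled internal
standards, in `designated_samples` mode). The ratios are log2-transformed
and cleaned by two-way median polish — alternately subtracting protein
(row) and sample (column) medians — until the largest absolute median
falls below `tol = 1e-8` or `max_iter = 250` iterations (values chosen to
reach float-precision medians quickly; convergence is logged). A protein
with a missing or zero denominator median in some batch has its values in
that batch set missing rather than poisoning the ratio.

Properties worth knowing:

- Multiplying *all* samples of a batch by a scalar is removed exactly (it
  cancels in the ratio), and the test suite asserts this at 1e-8.
- Rescaling a *single* sample is removed almost entirely but not exactly:
  the sample shifts its own batch's denominator median wherever it is the
  pivotal order statistic, and the median-polish residual itself is not
  unique (medians over even counts are interval-valued, so the fixed
  point reached depends on the input path). The suite asserts the
  residual effect is < 0.1 of a 3.0 log2-unit injection, with median
  < 0.01.
- Quantification filters: proteins quantified in **at least** 50% of
  samples enter the statistical analyses (boundary inclusive), while the
  machine-learning input keeps proteins observed in **strictly more
  than** 95% of samples. The asymmetry is deliberate and mirrors the two
  different inclusion rules the analyses state.

**Bootstrap covariate regression.** Per protein, OLS coefficients of log2
abundance on the design (intercept + dummy-coded covariates, batch by
default) are estimated on `n_boot = 100` bootstrap resamples of samples;
the corrected value subtracts each covariate times the *median*
coefficient across bootstraps. The median makes the estimate robust to
resamples with unlucky leverage; 100 resamples put the Monte-Carlo error
of a median coefficient well below the residual noise at the cohort sizes
used here. Proteins with fewer observed samples than coefficients are
left uncorrected and logged. The intercept is never subtracted, so the
correction is invariant to constant shifts of a covariate up to a
per-protein offset.

**KNN imputation** (ML input only). Orientation is sample-wise: a
sample's missing protein is the mean of its k = 5 nearest samples
(nan-Euclidean distance over shared observed proteins, donors restricted
to samples observed at that protein; delegated to
`sklearn.impute.KNNImputer`). k = 5 is the conventional proteomics
default; the suite checks KNN beats per-protein mean imputation on
correlated data.

## Trajectories

Outcome series (months from baseline) are filtered per outcome: clinical
and volumetric outcomes need ≥ 3 visits spanning ≥ 24 months; tau- and
FDG-PET SUVR need ≥ 2 visits spanning ≥ 12 months. Slopes come from a
linear mixed model with participant-specific intercepts and slopes fit by
REML (statsmodels `MixedLM`, L-BFGS); the per-subject slope is the fixed
slope plus the subject's BLUP. If the fit is singular or non-convergent
(common in noiseless toys and small cohorts where a variance component
hits zero), the implementation falls back to per-subject OLS slopes and
flags the table's `method` column — the pipeline stays total and tests
can condition on the flag. Slopes beyond 4 SD of the cohort mean are
removed in a single pass (mean/SD not recomputed after removal). The
fast/slow progressor split is *strictly greater than the median* after
orienting slopes so larger = clinically worse (+1 for ADAS-Cog11, CDR-SB,
tau SUVR; −1 for hippocampal volume and FDG SUVR); all-equal slopes give
a degenerate all-slow split, logged.

AT status uses the CSF Aβ42/pTau181 ratio with cutoff 39.20 and the
published assignment direction — ratio **above** the cutoff is AT+ — even
though that is the reverse of the usual biochemical reading of this
ratio; a `positive_above` flag exposes the alternative rather than
silently "fixing" it. Conversion groups: the MCI cohort uses a 36-month
window (inclusive) — converter if first dementia diagnosis ≤ 36 months,
stable if MCI at every visit with follow-up beyond 36 months, otherwise
excluded; the amyloid and asymptomatic cohorts have no window.

## Differential abundance and enrichment

`dap_linear` is per-protein OLS on the trait (binary conversion status is
coded 0/1, making the model the pooled two-sample t test, which the suite
verifies against the closed form) with BH-FDR across proteins; no
covariates by default, with an optional covariate argument for
sensitivity analyses. Time-to-event regression uses years with 0 at the
event and negative values before it.

Module enrichment uses the mean member p-value as the statistic and a
null of same-sized draws *without replacement* from the tested background
(with-replacement is available). z = (μ_perm − p̄_obs)/σ_perm, so positive
z means enrichment for small p; σ_perm uses the sample (ddof = 1)
standard deviation. p_perm = (#{null ≤ observed} + 1)/(B + 1), never
zero. When C(n, m) ≤ 10,000 the null is enumerated exhaustively instead
of sampled. B = 10,000 by default. A caveat the synthetic data makes
visible: members of a real co-expression module are correlated, which
widens the truth's null relative to the independent-draw permutation
null, so |z| around 2–3 can occur for null modules; the BH step across
modules is the guard.

## Panels

**Stability selection.** Each of `n_boot = 100` bootstraps resamples
samples with replacement stratified by class, standardizes features, and
fits an L1 logistic regression with C chosen from an 8-point log-spaced
path by 5-fold CV log-loss under the 1-SE rule (strongest penalty within
one standard error of the best), then records the nonzero support.
Features selected in ≥ 90% of bootstraps form the panel.

**Evaluation.** The default is *fixed-panel* mode — select once on all
data, then score the fixed panel across `n_runs = 100` stratified
train/test splits (test fraction 0.2; 0.3 is the documented choice for
small tau-PET cohorts) — with a random forest tuned per run by grid
search (default grid: trees ∈ {100, 300, 500}, depth ∈ {3, 5, ∞}) with
5-fold CV on the training part only. Summary: median test AUC and the
2.5–97.5 percentile interval over runs. *Nested* mode re-selects the
panel inside each training split; the fixed−nested median-AUC gap is the
selection optimism, and the suite asserts nested ≤ fixed + 0.05. AUC is
the Mann–Whitney probability with ties counted ½; the Youden threshold
maximizes TPR − FPR with ties broken toward higher sensitivity.

**Attribution.** A model-agnostic Shapley estimator: features are
switched from background-row values to the test row's values along
feature orderings and the marginal score changes are averaged over
orderings × background rows. The telescoping sum makes local accuracy
*exact*: base value (mean background score) + attributions = model score,
asserted at 1e-6. With ≤ 6 features all orderings are enumerated (exact
Shapley values); otherwise 32 sampled orderings against ≤ 32 background
rows (Monte-Carlo error ~ O(1/√(perms·background)); the suite checks
sampled vs exact agreement at 0.05 on interaction models).

**Synchronized comparison.** Observed statistic: difference of median
AUCs of two predictor blocks evaluated on *identical* splits. Null: the
participant-to-feature-row assignment of both blocks is permuted with the
same random permutation (labels and splits regenerated per permutation),
and p = (#{|Δ_b| ≥ |Δ_obs|} + 1)/(B + 1), two-sided, B = 100 by default.
The published description of the permutation scheme ("shuffled the
assignment of peptides and biomarkers for each participant") is
ambiguous; this joint row permutation is our reading, documented rather
than claimed equivalent. The estimator is pluggable; the calibration test
uses logistic regression with 3 runs and B = 49 over 200 repetitions so
the 200-repetition uniformity check fits in minutes — the permutation
machinery being calibrated is identical regardless of estimator.

## Event-based staging

Single-subtype, one z-threshold per biomarker: at stage k the first k
biomarkers of the ordering are abnormal (mean `z_event`, default 2 — a
conventional abnormality threshold) and the rest normal (mean 0), with
per-biomarker Gaussian noise σ (estimated from the stable reference group
in practice); subjects are uniform mixtures over the N+1 stages,
including stage 0. Input z-scores are standardized against the stable
group and oriented by the differential-abundance coefficient signs so
every event is an increase. Fitting: `n_restarts = 25` greedy ascents
(best single-element relocation until no gain) from random permutations,
then Metropolis MCMC over pairwise swaps (`mcmc_iters = 10,000`;
acceptance rate logged — near zero on well-separated data simply means
the mode is sharp). Positional probabilities are MCMC visit frequencies;
stage posteriors use the MAP ordering with ties broken toward the lower
stage. The multi-threshold piecewise-linear event variant is an extension
point, not implemented. Likelihoods are computed in log space with
`logsumexp`, so near-noiseless data never produce −∞ totals.

## Synthetic data

The generator emulates the statistical structure the analyses assume, at
configurable scale: log2 intensity = protein baseline + per-batch offset
(N(0, 1) by default) + per-sample loading + module latent factor
(loading 0.5 — induces realistic within-module correlation) + group
effect (±1 log2 unit on the differential proteins, which fill whole
modules first so enrichment has planted positives) + N(0, σ) noise;
exponentiated, with MCAR plus below-quantile (MNAR) missingness encoded
as zeros. Outcomes follow the random-intercept/random-slope model
(defaults: β₁ = 0.2 units/month, slope SD 0.1, noise SD 1, visits at 0,
12, 25 months). Converter status is Bernoulli (default 0.3) with
conversion times uniform on [6, 84] months — the real studies report mean
conversion times near 4–5 years but not a distributional form, so
uniform-over-follow-up is a pragmatic default, not an inference. Staging
data are exact stage mixtures with uniform stages.

What it does *not* emulate: peptide-level structure, reporter-ion
interference, batch × protein interaction effects beyond the scalar
offset, non-Gaussian outcome noise, informative dropout, or correlated
conversion hazards. Passing tests therefore demonstrate correctness of
the algorithms and calibration under the stated generative model, not
performance on real cohorts.

## Problem sizes and runtime choices

Test and acceptance workloads use the cohort scales stated in the suite
(e.g. 200 proteins × 300 samples × 10 batches for harmonization; 2,000
proteins for calibration; 600 samples for the Gaussian-shift AUC oracle;
N = 6 biomarkers × 300 subjects for staging). The AUC-oracle evaluation
grid is {100 trees} × {depth 3, ∞} with 5-fold CV: CV reliably selects
the depth-limited forest, whose ranking approximates the monotone Bayes
rule on a single Gaussian feature, whereas unlimited depth overfits 1-D
inputs and degrades AUC — letting CV make that choice is the point of the
tuning step. The default pipeline config restricts panel candidates to
the strongest 60 DAPs before stability selection; this is configurable
and matches how panels are built from a pre-ranked protein list.

## Known limitations

- The permutation-enrichment null assumes exchangeable member sets;
  correlated modules widen the true null (see above).
- BLUP slope recovery is bounded by the visit design: with three visits
  over 25 months and noise SD 1, the correlation ceiling with true slopes
  is ≈ 0.92.
- `compare_predictor_sets` p-values are discrete at resolution 1/(B+1).
- The event-based model assumes a single subtype and monotone,
  one-threshold events; heterogeneous cascades violate it by design.
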