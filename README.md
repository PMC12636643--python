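# csfprognostics

Tools for prognostic modelling from cerebrospinal-fluid (CSF) proteomics in
Alzheimer's disease cohorts. Multiplexed (TMT) CSF proteomes carry signal
about who will convert — from amyloid-negative to amyloid-positive, from
asymptomatic to symptomatic, from MCI to dementia — and how fast cognition
and imaging markers will decline. Turning raw multi-batch intensity
matrices into those statements takes a chain of careful steps, each of
which this package implements as a tested, seeded, importable unit:

1. **Harmonization** — per-sample loading scaling, zeros-as-missing, and
   TAMPOR (*tunable approach for median polish of ratio*): intensities are
   expressed as ratios to the median of selected samples within each TMT
   batch, log2-transformed, and cleaned by iterative two-way median polish
   until every row and column median is ≈ 0. Per-batch multiplicative
   effects cancel *exactly* in the ratio step. Residual technical structure
   is removed by non-parametric bootstrap regression (subtract covariate ×
   median bootstrap OLS coefficient, per protein).
2. **Trajectory phenotyping** — per-subject rates of change from the
   linear mixed model *y<sub>ij</sub> = (β₀+b₀ᵢ) + (β₁+b₁ᵢ)t<sub>ij</sub> + ε<sub>ij</sub>*
   (subject slope = β₁ + BLUP(b₁ᵢ)), with outcome-specific inclusion rules,
   4-SD trimming, median-split fast/slow progressor labels, AT± status from
   the CSF Aβ42/pTau181 ratio (cutoff 39.20), and windowed conversion groups.
3. **Differential abundance** — per-protein OLS of log2 abundance on a
   binary conversion group or a continuous slope, t tests,
   Benjamini–Hochberg FDR; Pearson-correlation ranking against outcome
   slopes; group-level regression of abundance on time-to-event.
4. **Module enrichment** — permutation Z statistic: a module's mean member
   p-value against the distribution of mean p-values of same-sized random
   protein sets, *z = (μ<sub>perm</sub> − p̄<sub>obs</sub>)/σ<sub>perm</sub>*, exact (b+1)/(B+1)
   permutation p, exhaustive enumeration on small instances, BH-FDR over modules.
5. **Predictive panels** — bootstrap-stability LASSO (features with
   nonzero L1-logistic coefficients in ≥ 90% of 100 stratified bootstraps,
   penalty tuned by internal CV with the 1-SE rule), evaluated by
   random-forest classifiers over repeated stratified 80/20 splits (grid
   search on training folds only), summarized as median AUC with a
   2.5–97.5 percentile interval, Youden-index operating thresholds, exact
   additive (Shapley) feature attributions, and a **synchronized
   permutation test** comparing predictor sets on identical splits.
6. **Event-based staging** — a single-subtype event-based model:
   progression is an unknown ordering of biomarker "events"; subjects are
   uniform mixtures over stages; the ordering is fit by greedy ascent plus
   Metropolis MCMC, yielding positional probabilities and per-subject
   stage posteriors.

Because the cohorts such analyses are built on cannot be redistributed,
the package ships a first-class **synthetic cohort generator**
(`csfprognostics.synthetic`) that plants every quantity the pipeline is
supposed to recover — batch offsets, differential proteins organized into
co-expressed modules, per-subject slopes, conversion times, event
orderings and stages — so every stage is testable against ground truth.

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/04_differential_and_enrichment.py` simulates 200 subjects
× 200 proteins with 30 planted differential proteins concentrated in
modules M1–M2, harmonizes, tests, and prints:

```
proteins tested: 199; P<0.05: 39 (22 increased, 17 decreased); q<0.05: 30
planted differential proteins: 30
module_id  n_members_tested       z  p_perm      q  significant
       M1                20  6.2019  0.0001 0.0004         True
       M2                20  2.6757  0.0032 0.0064         True
       M3                20 -0.7895  0.7821 0.9970        False
       M4                20 -2.8079  0.9970 0.9970        False
```

The fully-planted module M1 and half-planted M2 clear the 5% permutation
FDR; the null modules do not. Similarly,
`python examples/06_event_based_staging.py` recovers the planted 6-event
ordering exactly (Kendall τ = 1.00, stage Spearman ρ = 0.993), and
`python examples/05_panel_selection_and_evaluation.py` selects exactly the
two planted features (frequencies 1.00 vs ≤ 0.58 for noise) and reports a
median AUC of 0.893 (95% interval 0.831–0.959) over 50 permuted splits.

The full workflow also runs from one YAML config:

```bash
prognostics run --config cfg.yaml       # or: python examples/07_full_pipeline.py
```

Each run writes TSV artifacts plus a manifest of per-stage seeds and
SHA-256 digests; two runs with the same config produce bit-identical
manifests.

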