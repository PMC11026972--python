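# Methods

## Scope and model

The pipeline treats country-year observations as exchangeable rows: a
regression model maps the 31 normalized inputs of a row to its 5
cause-specific high temperature-related disease (HTD) burdens, and the
total burden is always the sum of the five causes — it is never predicted
directly, so the cause/total accounting identity holds by construction.
Counterfactual policy simulation then perturbs only the 12 intervention
columns of the panel and re-predicts: the fitted model is used as a
response surface, not as a causal graph. Mediators (emissions, temperature,
air pollution) stay at their observed values unless they are themselves the
scheduled intervention, so what the simulation captures is each measure's
*direct* association with burden conditional on the other inputs. This is
the central assumption of the approach and its main epistemic limit.

## The variable catalog

The catalog fixes the role structure — 11 influence factors, 8 key
variables, 12 interventions, 5 intermediate outcomes, 1 final outcome —
and the intervention taxonomy (6 mitigation measures across the
agricultural, energy and land-use sectors; 6 adaptation measures across
ecosystem resilience, infrastructure & community and health system
capacity). The identities of the influence and key variables are documented
placeholders chosen to match the influence-pathway narrative (sectoral GHG
emissions, temperature, urbanization, latitude, altitude, population
density, obesity, age structure, education, ...); real-data users can
rename them freely, only the role counts are enforced.

Two per-intervention attributes drive the simulation:

- **benefit direction** (±1): the direction anticipated to reduce burden.
  Defaults: decrease fertilizer use and air pollution; increase everything
  else. Note that "increase energy intensity as beneficial" follows the
  source framing rather than the usual efficiency convention; the sign is a
  one-line override (`catalog.with_overrides`).
- **disease mask**: the causes an intervention may affect. Pneumococcal
  vaccines and sanitation are restricted to infectious respiratory disease,
  road infrastructure to injuries; air pollution keeps all five causes
  (its pathway edges cover four, but its burden associations plausibly
  extend to injuries, and the wider mask is the more permissive default).
  Masks shrink the valid package space for cause-specific searches:
  2^m − 1 packages for m mask-valid interventions, 4095 for the total.

## The influence pathway

The default directed acyclic graph encodes: mitigation measures → their
sector's GHG emissions → temperature (together with urbanization,
population density, latitude, altitude); temperature → all five causes and
→ air pollution; air pollution → four causes; demographic and geographic
modifiers → specific causes; vaccines and sanitation → infectious
respiratory; road infrastructure → injuries; health care delivery, health
financing and education → all five causes; the five causes → total. The
mitigation-to-sector edges are included so that every intervention has a
directed path to at least one burden, which both the generator and the
graph predictor require to express mitigation effects at all.

## Preprocessing rules

- **Exclusion**: a country lacking the outcome entirely is dropped; a
  country whose missing fraction exceeds the threshold (default 0.15) on
  *any* input variable is dropped — the strictest reading of a
  per-indicator threshold. Exclusion is therefore monotone in the
  threshold.
- **Imputation**: interior gaps (observed values on both sides, any run
  length) are linearly interpolated in year — exact for series linear in
  year; boundary gaps take the country's observed mean (region mean by
  flag). The split is deterministic and covers every case: interpolation
  is undefined without two flanks, means need no flanks.
- **Normalization**: min-max to [0, 1] per variable over the full
  preprocessed panel (a fit-on-train-only mode exists for leakage-sensitive
  work; with the defaults the difference is a few range quantiles).
  Degenerate (constant) columns map to 0 and are flagged. The final
  outcome is never normalized. Application data outside the fitted range
  is clipped, keeping model inputs in the training domain.
- **Split**: 70/30 by row (each country-year an observation), seeded;
  by-country splitting is available when between-country generalization is
  the question.

## The model zoo

Seven of the eight candidates are standard scikit-learn / xgboost
regressors with CPU-sized defaults (documented in `models.py`); SVR and
Adaboost fit one model per cause behind a single multi-output facade. The
eighth is a graph neural network written in numpy:

- node features = the row's normalized values, with the cause and total
  nodes masked to zero (no target leakage);
- 2 rounds of edge-directed message passing, hidden width 32, tanh
  aggregation; readout heads at the five cause nodes;
- full-batch Adam (lr 0.01, ≤1000 epochs), early stopping on a 15%
  validation fold, and a deterministic restart if an initialization fails
  to beat the mean predictor (a rare optimization failure mode).

Because messages travel only along directed edges, a variable with no
directed path to a cause provably cannot influence that cause's
prediction; the suite tests this invariance directly.

Metrics: RMSE, MAE, MAPE, RMSPE, R², computed per cause and macro-averaged
across the five causes (a pooled mode exists; the source publication does
not state its pooling). Rows with zero actuals are excluded from the
relative errors and counted. Screening ranks by RMSE, ties broken by MAE
then name; a failing model is recorded and skipped.

## Intervention engine and optimizer

The annual intensity is interpreted as a fraction of the normalized [0, 1]
range, applied additively and cumulatively — year t of the window shifts a
member by direction × intensity × (t − start + 1), so 4%/yr over 2015–2019
is a 20% shift at 2019 — and clipped to [0, 1] because the predictors were
trained on that domain. A raw-relative mode (v·(1 ± intensity·k)) exists
behind a flag. Counterfactual panels are tagged and refuse a second
schedule application.

The optimizer evaluates every valid package (exhaustive search, so the
winner is globally optimal by construction), with ties broken toward the
smaller, lexicographically earlier package via the enumeration order.
Regional burdens are unweighted sums of the countries' inverse-normalized,
zero-floored cause predictions in 2019 (burden units are absolute, so the
sum is the faithful aggregate; means and population weights are options).
One cached sweep over the 4095 counterfactuals serves the whole 7 × 6
grid, the per-cardinality best-reduction curve, and all leave-one-out
re-evaluations.

Contribution decomposition uses the leave-one-out rule with B(∅) equal to
the unmodified baseline (the natural empty-set convention for singleton
packages). Negative raw contributions — possible when the model has
interactions — are retained, flagged with a warning, and still included in
the normalization.

## The synthetic generator

The generator is the stand-in for the study's unreleased multi-source
panel. Exogenous variables follow a per-country latent level (normal across
countries) plus an AR(1) year deviation (ρ = 0.7), giving realistic
within-country persistence and supporting the interpolation tests;
geography is time-constant. Endogenous variables are evaluated in
topological order as intercept + Σ coefficient·parent + noise; burdens are
floored at zero and the total is the exact sum of the causes. Intercepts
are solved from designed mean levels so burdens stay comfortably positive.

The structural graph augments the analysis pathway with direct
intervention → cause edges (one per disease-mask entry, signed so the
beneficial direction reduces burden). These proximal effects make the
intervention signal identifiable to a reduced-form predictor — the engine's
counterfactuals hold mediators fixed, so purely mediated effects would be
invisible to it by design — while the mediated chains through emissions and
temperature remain on top. Designed full-schedule effect sizes (2–12 raw
burden units per affected cause, distinct per intervention so the true
contribution ranking is unambiguous) and node noise scales are set so the
effects are detectable at the default scale (93 countries × 10 years)
without dominating the temperature signal; emission-node noise is large
enough that mitigation measures are not collinear with their sector's
emissions. The optional `linear_saturation` form passes each cause's
linear predictor through a centered tanh (strength 2), a monotone
diminishing-returns response that a linear model cannot capture — used to
exercise the nonlinear screening comparison.

Ground truth is computed by direct structural re-evaluation of the 2019
counterfactual (full propagation, reusing the realized noise draws), per
region and for the all-country aggregate. What recovery tests therefore
show is that the pipeline finds the truly beneficial package and ranks
contributions consistently *when the data-generating process matches the
model family and effects are additive*; they do not validate the causal
interpretation on real observational data, where confounding, measurement
error and clustered missingness are not emulated.

Missingness injection draws Binomial(n_cells, rate) gap counts and places
them uniformly over eligible cells — interior gaps away from series edges,
boundary gaps at the first/last year — which exercises both imputation
branches cleanly; real missingness is block-structured and informative,
which this deliberately is not.

## Problem sizes and runtimes

The default study conditions are 93 countries × 10 years. A full package
sweep (4095 counterfactual predictions of the 93 countries' 2019 burdens)
takes a few seconds with the cached sweep; the whole pipeline, including
GNN training, runs in minutes on one CPU. The test suite uses 14–28
country panels for unit tests and the full 93-country conditions for the
recovery and screening checks (10 generator seeds each). The acceptance
script repeats the recovery study over ten seeds at full scale.

## Known limitations

- The counterfactual simulation reads direct conditional associations off
  a predictive model; it is not a causal identification strategy.
- Placeholder variable identities; real applications must supply their own
  catalog names and units (roles and counts are fixed).
- Contributions are leave-one-out, not Shapley values: with strong
  interactions the shares depend on the package context, and negative
  shares are possible.
- The exhaustive search scales as 2^m; it is exact for m = 12 but not
  meant for much larger intervention sets.
- Regional results are unweighted sums over the panel's countries; they
  are only as representative as the panel's country coverage.
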