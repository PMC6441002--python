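# Methods

This note documents the models and numerical choices behind the package,
what the synthetic generators do and do not emulate, and the known limits
of both.

## Web descriptors

**Inclusion filter.** Webs with fewer than 25 taxa or 50 links are
excluded before any analysis (both boundaries inclusive); poorly resolved
webs bias most structural metrics. Thresholds are arguments everywhere
they appear.

**Connectance.** C = L/S² with self-loops (cannibalism) counted in L.
Self-loops are, however, removed before the trophic-level, role and
omnivory computations: a pure cannibal would otherwise be its own prey at
an undefined level, and a self-loop should not make a taxon "consumed"
for the top-taxon test. Isolated taxa count as basal so the three role
fractions always partition the web.

**Trophic level.** Prey-averaged: TL_i = 1 + mean TL of i's prey, basal
taxa fixed at 1, i.e. the linear system (I − Q)TL = 1 with Q_ij = 1/n_i.
The system is solved directly; if the matrix's condition estimate exceeds
1e12 the solver falls back to damped fixed-point iteration (damping 0.5,
up to 10,000 sweeps, convergence when the sweep-to-sweep change falls
below 1e−12); a residual above 1e−8 in either route is an error naming
the strongly connected consumer component that has no feeding pathway to
a basal taxon — such a web has no finite prey-averaged levels, and
silently dropping the offending taxa would bias S.

**Omnivory.** A taxon is an omnivore iff it has ≥ 2 prey whose trophic
levels, rounded to the nearest integer, take ≥ 2 distinct values. The
integer-rounding rule is deliberate: with continuous prey-averaged levels
almost every consumer in a rich web feeds on prey at technically distinct
levels, and the fraction saturates at 1. A continuous alternative (prey
TL range > τ, default τ = 0.5) is selectable.

**Collinearity screen.** Pearson correlations over all descriptor pairs,
flagging |r| ≥ 0.7. The analysis variable set drops p_intermediate
(complement of p_basal + p_top) and meanTL (tracks maxTL) regardless of
what the screen flags on a particular collection — the screen is a
report for the analyst, not an automatic variable selector.

## Trophospecies aggregation

Two taxa merge iff their resource sets and consumer sets are exactly
equal, after canonicalizing within-pair references (a link to the
candidate partner counts as "partner", a link to oneself as "self") so
that mutually feeding or cannibalistic near-duplicates can merge. Exact
two-sided equality is the strictest published variant of the rule; a
similarity-threshold merge is deliberately not implemented because it is
order-dependent. Groups are built by union-find over equivalent pairs
(pre-bucketed by degree signature), and the aggregated node takes the
lexicographically smallest member label. Aggregation can only shrink S
and L; connectance may move either way.

## The path-model engine

Observed variables only, recursive (acyclic) systems, covariance
structure only — no latent variables, no mean structure, no multi-group
or mixed-effects estimation, no robust/categorical estimators.

* **Standardization.** Columns are z-scored with the n−1 denominator.
  The binary aquatic indicator is standardized like any other column, the
  usual treatment of a binary covariate in a covariance SEM.
* **Estimation.** F_ML = ln|Σ(θ)| + tr(SΣ⁻¹) − ln|S| − p is minimized by
  L-BFGS-B with the exact analytic gradient
  dF = tr[Σ⁻¹(Σ − S)Σ⁻¹ dΣ], started at the equation-wise OLS solution
  with exogenous moments taken from S. For recursive models that start
  *is* the global optimum (the model factorizes as a linear-Gaussian
  network), so the optimizer usually certifies rather than searches;
  convergence requires gradient sup-norm < 1e−8 and residual variances
  are bounded below at 1e−10. Sample covariances must be positive
  definite (smallest eigenvalue ≥ 1e−10).
* **Fit statistics.** χ² = (N−1)·F_ML (Wishart convention; N·F_ML via a
  switch — the choice rescales χ² but never reorders ΔAIC). Baseline for
  CFI is the closed-form independence model Σ_b = diag(S). RMSEA and
  AGFI take their conventional values 0 and 1 at df = 0, with a flag.
  logL is the covariance-structure multivariate-normal likelihood and
  AIC = −2logL + 2t; because means are not modeled, absolute AICs are
  comparable only within the pipeline, while ΔAIC obeys
  ΔAIC = Δχ²·N/(N−1) − 2Δdf for nested models on the same data.
* **Effects.** direct = A, total = (I − A)⁻¹ − I, indirect = total −
  direct; the identity total = direct + indirect is exact, and the matrix
  form equals exhaustive path enumeration (tested to 1e−10).
* **Uncertainty.** Nonparametric bootstrap (default B = 1000, explicit
  seed required): resample rows, re-standardize, refit; SE = SD across
  replicates, Wald z against a normal reference, plus percentile CIs.
  Information-matrix SEs are not offered because indirect effects are
  products of coefficients. More than 10% failed replicates aborts.
* **Model comparison.** AIC ascending with ΔAIC from the best. Fits must
  share the sample; variable sets may differ only in declared abiotic
  covariates. An AIC comparison across variable sets charges each extra
  variable its marginal likelihood — an extra covariate pays its way only
  where it is tightly coupled to the rest of the system, which is the
  intended behaviour of the candidate ranking.

## Candidate models

Seven endogenous descriptors in the fixed causal order
S → p_basal → p_top → L → omnivory → C → maxTL, each regressed on all
earlier descriptors and the variant's abiotic variables, except that the
three paths aquatic → {omnivory, C, maxTL} are omitted (ecosystem type is
allowed to act on the biotic block, not directly on derived network
structure). This is the unique "fully recursive minus a named path set"
structure that yields df = 3 for the temperature, latitude and none
variants and df = 4 for both simultaneously. In "both", temperature is
endogenous with the single equation temperature ~ latitude, and latitude
and aquatic are exogenous with free covariance. Any other structure can
be supplied as a model-spec file ("outcome ~ p1 + p2" lines).

Latitude enters as absolute latitude: the temperature gradient is
symmetric about the equator, and a signed latitude would break the linear
latitude → temperature equation for a mixed-hemisphere collection.
Missing temperatures are handled by listwise deletion with a logged
count, not imputed.

## Synthetic data

Two generators with different jobs:

* **Linear world** (`simulate_sem_data`, `simulate_study_matrix`): exact
  draws from a specified recursive linear-Gaussian system.
  `unit_variance_theta` sets residual variances so all implied variances
  are 1, putting the generating coefficients on the standardized scale a
  fit to z-scored data estimates. The packaged temperature-only world
  uses moderate standardized paths (±0.3/±0.5, latitude → temperature
  −0.8, latitude touching structure only through temperature). This is
  the world for estimator validation: parameter recovery (n = 5000 within
  0.05; mean bias at n = 65 within 0.03 over 500 replicates), 95%
  percentile-CI coverage in [0.90, 0.98], χ² rejection of the true model
  at α = 0.05 within [0.02, 0.09], ML = OLS agreement to 1e−6.
* **Web collections** (`generate_web_collection`): 65 niche-model webs.
  Latitude ~ U(0, 70)°; temperature = 27 − 0.42·latitude + N(0, 3²) °C
  (the familiar global lapse); aquatic ~ Bernoulli(0.7) with an aquatic
  class drawn among freshwater/marine/estuarine; target
  S = 64 − 10·z(temperature) rounded and floored at 25, and target
  C = 0.105 + 0.012·z(temperature) clipped to [0.03, 0.45] — matching the
  study scale of ~64 species and ~427 links per web and encoding
  "warmer webs are smaller and denser". Each web is drawn from the niche
  model (niche value U(0,1); feeding-range width Beta(1, (1−2C)/(2C))
  times the niche value; centre U(r/2, n); the smallest-niche taxon gets
  range 0) with rejection until the web has a basal taxon, no isolated
  taxa and a solvable trophic-level system, as all empirical webs in this
  class do.

Only (S, C) are coupled to the covariates; role fractions, omnivory and
trophic levels *emerge* from the niche model. Passing tests on these
collections therefore show that the pipeline detects the abiotic signal
and ranks the true driver first; they do not show that all seven
empirical descriptors follow a linear system — no generator could impose
that, and on real data the linearity is an approximation the fit indices
must judge. A side effect of the tight size map is near-collinearity of
temperature with S in synthetic collections, which inflates offsetting
direct/indirect components on downstream descriptors; their totals remain
well behaved.

## Problem sizes and determinism

Validation runs use 100-web property samples (S ≤ 50), 500 replicates for
calibration/coverage at n = 65 with B = 200 bootstrap draws, and 200
collections for the model-selection rate; these sizes give Monte-Carlo
error comfortably inside each acceptance band. Every stochastic routine
takes an explicit seed (numpy `default_rng`); identical inputs and seed
reproduce reports byte for byte.

## Known limitations

* Covariance-only AIC: absolute values are not comparable with
  mean-structure SEM software; rankings are.
* The χ² test relies on the asymptotic distribution; at n = 65 the
  empirical size is measured (≈ 0.07), not exact.
* The integer-rounded omnivory rule is one operationalization among
  several in the literature; the continuous rule is provided but defaults
  are opinionated.
* Trophospecies equality is exact; webs digitized with noisy diets will
  aggregate little.
* The generator does not emulate research-group compilation biases,
  spatial autocorrelation, or temperature seasonality.
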