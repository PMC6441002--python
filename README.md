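# foodwebsem

Do temperature and latitude shape the structure of food webs, and if so,
directly or through knock-on effects? `foodwebsem` is an analysis pipeline
for that question: it computes structural descriptors of directed food
webs, aggregates taxa into trophospecies to control for uneven taxonomic
resolution, and fits competing path models (observed-variable structural
equation models) that link abiotic drivers — mean annual temperature,
latitude, aquatic vs terrestrial ecosystem — to web structure, decomposing
every standardized effect into its direct and indirect parts and ranking
the candidate causal structures by AIC. It is aimed at ecologists doing
food-web macroecology and at anyone who wants a small, fully tested,
from-scratch recursive-SEM engine in Python.

## The model

A food web is a directed graph with links pointing consumer → resource.
Per web the pipeline computes: species count *S*; link count *L*; directed
connectance *C = L/S²* (cannibalism counted); the proportions of basal,
intermediate and top taxa; the fraction of omnivores (taxa feeding on prey
at more than one trophic level); and the prey-averaged trophic level

  TL_i = 1 + (1/n_i) Σ_{j ∈ prey(i)} TL_j,  TL = 1 for basal taxa,

solved as the linear system (I − Q)·TL = 1 with Q_ij = 1/n_i.

The web-level descriptors and covariates are z-scored and fed to four
candidate path models — temperature, latitude, both (with latitude driving
temperature), or neither as abiotic drivers, the aquatic indicator always
included. Each candidate is a recursive system whose implied covariance is

  Σ(θ) = (I − A)⁻¹ Ψ (I − A)⁻ᵀ,

estimated by minimizing the ML discrepancy
F_ML = ln|Σ| + tr(S Σ⁻¹) − ln|S| − p, with χ² = (N−1)·F_ML, the standard
fit indices (CFI, RMSEA, SRMR, GFI/AGFI), and AIC for ranking. Effects
decompose exactly: direct = A, total = (I − A)⁻¹ − I (the sum over all
directed paths of products of coefficients), indirect = total − direct;
significance comes from a nonparametric row-resampling bootstrap.

Because no public accession bundles the empirical web compilation, the
package ships a first-class synthetic generator: niche-model webs whose
size and connectance follow a latitude/temperature gradient, plus an exact
linear-Gaussian simulator used to validate the estimator (parameter
recovery, χ² calibration, interval coverage).

## Worked example

```sh
python analysis/01_simulate_collection.py --seed 1   # scratch/collection/
python analysis/02_compute_metrics.py                # results/metrics.csv
python analysis/03_fit_candidates.py                 # results/comparison.csv
python analysis/04_effect_decomposition.py --seed 1  # results/effects_*.csv
```

The third step prints the candidate ranking (here on the default synthetic
collection, 65 webs averaging 64 species and 424 links):

```
      model  chi2  df  p_value   CFI  RMSEA  SRMR  AGFI      AIC    dAIC
temperature 3.383   3    0.336 0.999  0.045 0.015 0.830  954.689   0.000
       both 4.972   4    0.290 0.999  0.062 0.022 0.797 1005.664  50.975
       none 3.681   3    0.298 0.998  0.060 0.016 0.835 1221.862 267.173
   latitude 3.977   3    0.264 0.998  0.071 0.020 0.802 1271.850 317.160
```

Every candidate fits (p > 0.25, CFI ≈ 1, SRMR ≤ 0.02) but the
temperature-only model is the most parsimonious (ΔAIC ≥ 51 to the next),
which is exactly the structure the generator encodes: web size and
connectance respond to temperature, and latitude matters only through it.
The fourth step then decomposes the temperature effects, e.g.

```
temperature -> S         direct -1.00*  indirect -0.00   total -1.00*
temperature -> C         direct -1.57   indirect +2.20*  total +0.63*
```

read as: warming directly reduces species richness, while its positive
total effect on connectance is carried indirectly through the biotic chain
(fewer species and links mechanically raise L/S²). Asterisks mark effects
whose bootstrap 95% interval excludes zero.

The same pipeline runs on real data: put one edge list per web
(consumer, resource columns; adjacency matrices also supported) in a
directory with a `metadata.csv` (web_id, latitude, longitude,
temperature_C, ecosystem) and use the `foodwebsem study` CLI or the
analysis scripts with `--webs/--meta`.

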