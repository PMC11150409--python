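# Methods

This note documents the models and procedures implemented in `necromap`,
the synthetic landscape they are exercised on, the defaults that matter,
and the limits of what the desk-scale tests demonstrate.

## The problem

Topsoil microbial necromass carbon (MNC, mg C per g dry soil) is estimated
from amino-sugar biomarkers and mapped across a heterogeneous grassland
landscape from environmental covariates. The analysis asks two questions:
(i) do the relative abundances of microbial *eco-clusters* — groups of
dominant phylotypes sharing a habitat preference — improve MNC prediction
beyond the abiotic environment alone, and (ii) how does predicted MNC
change under a warmer climate when soil properties are held fixed?

## Necromass chemistry

MNC is derived from glucosamine (GluN) and muramic acid (MurA):
`fungal C = (GluN/179.17 − 2·MurA/251.23)·179.17·9` and
`bacterial C = 45·MurA`, with 179.17 and 251.23 g/mol the molar masses and
9 / 45 the standard conversion factors; the constants live in
`ConversionCoefficients` so alternates can be supplied. On strongly
bacteria-dominated samples the fungal term can go negative; it is clamped
to zero and flagged (`clamped`) rather than propagated. Galactosamine and
mannosamine are carried through I/O but play no role in the conversion.

Functional-gene qPCR uses the relative quantity `10^((31 − Ct)/(10/3))`
(valid Ct in (0, 45]); a gene is positive in a sample only when all three
technical replicates amplified, and the reported quantity is the mean of
the three per-replicate relative quantities — not the quantity of the mean
Ct, which would differ because the transform is nonlinear.

## Eco-cluster inference

* **Dominant phylotypes**: top `ceil(0.10·P)` by mean relative abundance
  across samples AND present (abundance > 0) in strictly more than half the
  samples. Ranking by mean abundance (rather than prevalence-weighted
  alternatives) is the simplest defensible reading of "top 10% by
  abundance"; both fractions are parameters.
* **Habitat screening**: per phylotype, a 500-tree random-forest regression
  of abundance on all environmental variables jointly; "variance
  explained" is the out-of-bag R² × 100 floored at 0, kept at ≥ 30%. The
  top-importance variable is recorded as the driver with the sign of its
  Spearman association. Screening jointly (not per variable) reflects that
  habitat preference is a property of the whole environmental response.
* **Clustering**: pairwise semi-partial Spearman correlation between
  phylotype profiles, with the spatial coordinates (lon, lat) rank-partialled
  out of the *second* variable only (the semi-partial convention); the
  nonsymmetric matrix is symmetrized by averaging. Distance 1 − ρ feeds
  average-linkage agglomerative clustering; the cut maximizes mean
  silhouette over k = 2..12 by default, or k can be pinned. Partialling
  space out of one slot removes shared spatial trend without double-counting
  it; the conditioning set is configurable.
* **Naming**: members vote with their (driver, direction) preference;
  groups are ranked by member count, then mean variance explained, then
  alphabetically, and up to two groups supported by ≥ 25% of members are
  concatenated as `H<var>`/`L<var>` with `&` (elevation abbreviates to
  `ele`). Duplicate names get numeric suffixes.

## Rule-based abundance mapping

Cluster relative abundance is mapped from the environment with a committee
of five M5/Cubist-style rule models. Each member fits a depth-≤3 regression
tree with cost-complexity pruning at `ccp_alpha = 0.15·var(target)` — a
split must buy a substantial error reduction, so a noise target collapses
to the mean — then builds a leaf linear model by greedy forward selection
under the complexity-penalized error `mean|res|·(n+v+1)/(n−v−1)`, requiring
each added variable to cut the penalized error by ≥ 5% (a guard against the
winner's curse of scanning ~20 candidates). Members 2..5 train on
Quinlan-adjusted targets `2y − previous prediction`; predictions are
committee means, clipped to [0, 1] for abundances. Fit quality is the
relative error `mean|residual| / mean|y − mean(y)|` (training data); 1 is a
mean-only baseline, models ≥ 1 are flagged as failing, and a constant
target is defined to have relative error 1. Attribute usage reports, per
variable, the percentage of training cases whose rule path conditions on it
and the percentage whose leaf model includes it.

## Stacked-autoencoder regression

For input dimension *d* the encoder has widths (*d*−1, *d*−2, *d*−1): two
compression layers and one release layer, one neuron removed or restored
per layer; the regression head is one 32-unit hidden layer and a linear
output. Inputs are z-scored with parameters stored at fit time; the target
stays in mg/g. Hidden units use the scaled tanh `3·tanh(x/3)` — effectively
linear over the standardized input range but bounded — which lets
reconstruction pretraining converge smoothly where a unit-scale tanh
saturates. Training is plain NumPy (the networks are tiny):

* **Pretraining** — each layer is trained greedily as a one-hidden-layer
  autoencoder (linear decoder) reconstructing its own input: full-batch
  Adam, learning rate 0.02 cosine-decayed to 0 over 800 epochs; per-epoch
  reconstruction MSEs are logged and are non-increasing in practice.
* **Fine-tuning** — encoder + head trained end to end on squared error,
  full-batch Adam at 0.01 for up to 800 epochs with early stopping
  (patience 80) on a seeded 15% validation split; best-validation weights
  are restored. Fine-tuning refuses n < 20.

The head reads the release layer (*d*−1 units). Every stage is
deterministic given the seed. Feature ranking uses a 500-tree random forest
with permutation importance (10 repeats); the top `ceil(0.70·n)` candidates
are selected; CE = selection, WE = selection minus cluster-abundance
variables. Validation: ten-fold CV with balanced folds (sizes differ ≤ 1),
model retrained per fold, metrics pooled over out-of-fold predictions; and
a 25% hold-out stratified by grassland class. The metric suite is the OLS
slope of observed on predicted, Pearson r, R² = 1 − SSres/SStot, RMSE, MSE
and MAE; RMSE² ≡ MSE by construction.

## Warming projection

The scenario replaces only the climate columns (MAT shifted, MAP scaled,
aridity index AI recomputed — see below); soil properties stay at current
values. Cluster abundances are re-predicted by the rule models under both
climates and fed with the selected environmental variables into the trained
CE model; the per-site D-value is projected − current MNC. Summaries (mean,
median of current/projected/D) are reported per class and for the whole
grassland, which is the exact union of the classes so counts add up.
Per-cluster abundance shifts use the Mann–Whitney U test (midrank ties):
exact enumeration when n₁+n₂ ≤ 12 without ties, otherwise the normal
approximation with tie and continuity corrections (via scipy). The default
significance threshold is α = 0.05 with no multiple-testing correction
(matching per-cluster testing conventions); α = 0.001 and a
Benjamini–Hochberg option are available. Clusters whose rule models never
condition on MAT/MAP/AI can optionally be frozen across scenarios.

## The synthetic landscape

The generator emulates a plateau grassland survey with planted truth:

* **Sites**: n (default 80; 96 with `class_split = 0.48` reproduces a
  46-meadow / 50-steppe design) split into meadow (wetter, warmer, greener,
  further east) and steppe classes. Each covariate is class-conditional
  Gaussian plus a loading on a shared standardized-longitude factor — a
  low-rank stand-in for the east–west gradient. Texture is Dirichlet so
  sand + silt + clay = 100 exactly. AI = MAP/PET with the proxy
  PET = 600 + 40·MAT (mm/yr, floored at 100), so AI responds to warming;
  whether AI is recomputed or held under a scenario is a config switch
  (default: recomputed).
* **Phylotypes** (default 100): members of a planted cluster share a
  log-linear response (effect size 1.5 per standardized driver; member
  noise SD 0.4) plus a dominance boost (base ~ N(2.0, 0.3) vs N(0, 0.8)
  for background) so they pass the abundance filter; 25% of background
  entries are zeroed to emulate patchy occupancy; rows are renormalized to
  sum to 1. The default plants a wet-cold cluster (high MAP, low MAT) and a
  high-elevation cluster, five members each.
* **Amino sugars**: target MNC = 6 + 30·(wet-cold abundance) − 6·(elevation
  cluster abundance) + 12·NDVI + 0.05·silt + N(0, 1) mg/g, chosen to give a
  plausible topsoil range (≈ 4–40 mg/g, mean ≈ 17). The deterministic part
  must stay non-negative or generation aborts; noise is clamped at 0. The
  total is split fungal:bacterial at a fixed 3:1 and inverted through the
  conversion, so the chemistry round-trips exactly at zero noise. GalN and
  ManN are lognormal nuisance columns uncorrelated with MNC.
* **Scenario**: default ΔMAT = +2.2 °C, ΔMAP = +6%, the magnitude of a
  2050s high-emission pathway over a cold highland.

In this synthetic world the planted warming effect on MNC is *negative*:
warming shrinks the wet-cold cluster (weight +30) while the elevation
cluster is climate-inert, so projected MNC declines. The projection tests
therefore check *sign consistency* between the planted effect and the
projected mean D-value, not a particular direction.

### What the generator does not emulate

Real surveys add spatial autocorrelation beyond a single longitude factor,
compositional measurement error and sequencing depth variation, taxonomic
structure, nonlinear and interactive environmental responses, and
literature-derived observations with heterogeneous protocols. Passing the
desk-scale tests shows the pipeline recovers planted structure and
propagates it correctly — not that the same skill would be achieved on
field data.

## Numerical choices and degenerate inputs

Tie-breaks are deterministic throughout (abundance ranking and naming fall
back to alphabetical order; silhouette ties pick the smaller k). A constant
phylotype screens at 0% variance explained; constant observations make the
metric suite undefined (error); a constant regression target is rejected by
the importance ranker. Fold sizes from a seeded permutation + `array_split`
differ by at most one. JSON reports have sorted keys and no timestamps, so
reruns of the same config are byte-identical.

## Problem sizes

Default study sizes — 80 sites, 100 phylotypes, two planted clusters,
ten-fold CV, five-seed repetitions for stochastic properties — were chosen
so each stage's statistical behavior (screen false-pass rate, clustering
recovery, CE-vs-WE ordering, test power) is measurable while the whole
suite stays desk-scale.

## Known limitations

* The SAE is effectively a quasi-linear encoder with a shallow nonlinear
  head at these data sizes; its advantage over simpler regressors is not
  the claim under test (the CE-vs-WE contrast is).
* The rule models report training-data relative error, as is conventional
  for rule learners; it is optimistic relative to out-of-sample error.
* Semi-partial Spearman with a one-sided conditioning set is asymmetric;
  symmetrization by averaging is a pragmatic choice.
* Regional class counts and means are computed on the synthetic point set;
  no kriging or raster upscaling is performed.
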