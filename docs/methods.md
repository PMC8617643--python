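# Methods

## Study design encoded by the package

Two treatments (`minusAM`, `plusAM`) are followed over seven phenology days
(14, 21, 24, 29, 38, 45, 52 DAS); leaf metabolomes are sampled on five of
them (14, 24, 29, 45, 52). The phenophase order is
1L → 2LI → 3LI → SI → ST → SBI → FI → FD; from 21 DAS on, the inoculated
plants are exactly one phenophase ahead of the controls at every matched
day. `mycometab.stages.StageDesign` encodes this map and the rest of the
package treats it as ground truth for matching groups by stage versus by
day.

## Synthetic data generator

The generator produces the study design with planted structure on the log2
scale:

x_ij = μ_j + a_j · f_c(j)(stage_eff(treatment_i, das_i)) + β_j·[+AM] + ε_ij

* **Baselines** μ_j ~ N(8, 1.5²) log2 units of internal-standard-relative
  peak area.
* **Class trajectories** f_c over the 8-stage order: sugars rise linearly,
  amino and carboxylic acids fall, fatty acids rise at half amplitude,
  phosphates are flat (their planted signal is the treatment fold alone, so
  the fold is identifiable at any stage pairing); the mixed "other" pool
  follows the same monotone pattern with per-feature weights a_j ~ U(−1, 1)
  (individually varied rising and falling trends, zero class mean). Named
  classes get a_j ~ U(0.5, 1.5). Default full range 3.5 log2 units.
* **Sugar lag**: sugar features of +AM samples evaluate the trajectory one
  stage earlier (clamped at 1L), so a mycorrhized plant reaches each
  phenophase before completing its sugar accumulation.
* **Phosphate elevation**: β = log2(2.0) for Pi and log2(5.6) for
  glycerophosphoglycerol; the other three phosphate features carry no
  treatment effect (only two of the five tracked phosphates respond, by
  design).
* **Replicate noise** ε ~ N(0, 0.2²) log2 units (~15% CV).
* **Artifacts**: per-sample loading factors L_i ~ LogNormal(0, 0.2) removed
  exactly by the spiked internal standard; technical dropouts hitting the
  low half of each feature's values at twice the nominal rate (overall
  missingness = `dropout_rate`, default 2%); gross spikes multiplying the
  raw area by U(5, 20) at rate 0.5%; structural absences wiping whole
  (feature, replicate-group) cells at rate 1%. Each artifact has its own
  ground-truth mask.

The noise level and trajectory amplitude were calibrated once so that the
planted structure yields validation statistics of the magnitude typical of
real consecutive-stage leaf-metabolome contrasts (Q²Y ≈ 0.8–0.98,
R²Y ≈ 0.95–0.99) and then frozen. One known compromise: the predictive
component of our contrasts carries ~0.3–0.55 of X variance, somewhat above
the ~0.2–0.4 of real leaf data, because the generator plants less
response-orthogonal structure than a real metabolome has.

What the generator does *not* emulate: chromatographic drift and batch
effects, heteroscedastic (intensity-dependent) noise, nonlinear or
non-monotone trajectories, secondary-metabolite bursts, and realistic
correlation noise between classes. Passing recovery tests therefore
demonstrates that the pipeline detects the planted effect classes at
realistic noise, not that it would be equally calibrated on any real
dataset.

## Preprocessing

Order: internal standard → sample median → Dixon → log2 → KNN imputation →
autoscaling. Imputation runs before scaling (scaling needs complete
columns). Choices:

* **Dixon's test**: two-sided r10 (Q) statistic with the standard critical
  values for n = 3..30 at α = 0.05/0.01; replicate groups are
  (treatment, DAS); at most one exclusion per feature-group; ranges below
  1e−9 relative are treated as ties (otherwise floating-point dust in
  zero-noise data triggers exclusions). At n = 3 and α = 0.05 the critical
  ratio is 0.970, so spikes below roughly 8× on low-abundance features are
  not flaggable — measured recall on the default U(5, 20) spike mix is
  ~0.8, with near-complete recall above 8×.
* **KNN imputation**: a missing cell is technical (imputed) only if the
  feature is observed in another replicate of the same group; neighbours
  are the k = min(10, J−1) nearest *features* by Euclidean distance over
  jointly observed samples, and the imputed value is the mean of their
  values in that sample. Cells missing in all replicates of their group are
  structural absences and get the feature's half-minimum (log2 minimum − 1),
  the usual limit-of-detection convention.
* **Median normalization** is multiplicative (pre-log), matching the
  processing order; **autoscaling** uses the population SD and drops
  zero-variance features with a warning.

The pipeline output is invariant to per-sample loading factors and to
rescaling all raw areas by a constant (exact algebraic identities, tested).

## Latent-variable models

NIPALS PLS(2) with X/Y deflation; OPLS restricted to a single response
column (two-class dummy or one continuous response), with
orthogonal-signal-correction components stripped before the single
predictive component. Orthogonal scores are exactly uncorrelated with the
response by construction. Component signs anchor the dominant response
loading positive (a positive X-loading means "higher in the positive
class"/"accumulates with the response"); PCA uses the
largest-magnitude-loading-positive convention.

* **Q²Y**: 1 − PRESS/SS over seeded venetian-blind folds, 7 by default
  (clamped to n, i.e. leave-one-out for 3 vs 3 contrasts), stratified by
  class for discriminant models.
* **Permutation p**: Y rows permuted jointly with the stratification
  labels, p = (1 + #{permuted ≥ observed})/(n_perm + 1); 199 permutations
  by default. With 3 vs 3 samples label permutations have only 20 distinct
  values, so the achievable floor for p(R²Y) is about 0.1 — reported as-is.
* **Orthogonal component selection**: add components while Q²Y improves by
  more than 0.01, cap 3.
* **VIP** over predictive components only; mean(VIP²) = 1 identically.

## Stage-vs-age contrast

Three observation classes — (t₁, dasₐ, stage X), (t₁, das_b, stage Y),
(t₂, dasₐ, stage Y) — one pair matched by day, one by phenophase. A
two-component PLS-DA is fitted, the development-associated component is the
one separating the stage-X from the stage-Y centroids most, and the verdict
compares same-stage vs same-age centroid distances on it. Centroids are
computed from **leave-one-out predicted scores** (each fold Procrustes-
aligned to the full-model weight basis): with 3 samples per class and 320
features the in-sample scores of any discriminant model separate any
labelling, so only held-out scores can distinguish stage-driven from
day-driven signal. This is the one place the package deliberately replaces
in-sample geometry with cross-validated geometry.

## Enrichment

Preranked GSEA-style running sum: hits advance by |stat|^w / N_R (w = 1 by
default), misses retreat by 1/(N − n_set); ES is the extremum, the leading
edge the members before (positive ES) or after (negative ES) it. Ties in
the ranking break deterministically by feature id. The null is random
same-size feature sets (1999 by default); p is sign-matched,
NES = ES / mean(|null ES| of the same sign), BH across sets. Set curation
intersects with the universe, joins class-only features to the sets of
their dominant class, and drops sets outside [3, 60] members.

## Networks and trajectories

Stage-mean profiles (5 time points) feed Pearson correlations with
two-sided t-approximation p-values (df = 3 at five points, so p ≤ 0.01
demands |r| ≳ 0.96 — the point set and α are configurable and this tension
is inherent to the design). Edges at p ≤ α; diameter and average shortest
path on the largest connected component; strong links at |r| ≥ 0.7.
Because the generator plants class-level trajectories, synthetic networks
are denser (diameter ~7, mean path ~1.5) than real leaf networks — topology
statistics are reported descriptively, and the scale-free claim is not
asserted as a test. Trajectory distances are Euclidean between
(treatment, stage) centroids in the full globally-standardized feature
space; non-additivity of a nested transition is (Σ nested)/(direct) − 1,
non-negative by the triangle inequality, infinite when the endpoints
coincide.

## Pipeline determinism and problem sizes

Every random step derives its generator from the run seed and a fixed
stream index; reruns of the same config produce byte-identical report
bundles (tested). Default problem sizes — 30 samples × 320 features, 11
contrasts, 199 model permutations, 1999 enrichment permutations, 500-tree
forests — complete in about a minute; the recovery benchmarks use 20–50
seeds per claim with 199–499 enrichment permutations, sizes chosen to keep
Monte-Carlo error well inside the tested margins.

## Known limitations

* OPLS supports one response column; multi-class questions go through
  PLS-DA.
* The permutation floor at 3 vs 3 replicates (~0.1) means per-stage
  contrast significance is coarser than the headline statistics of larger
  designs; the package reports the honest value.
* Dixon at n = 3 cannot flag mild (<8×) spikes; they survive into the
  log-scale data and are absorbed by the replicate average.
* The B/b vesicle-abundance indices of root-fragment scoring are not
  implemented: the available description duplicates the arbuscule indices,
  and guessing weights would be worse than omitting them.
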