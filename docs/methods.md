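# Methods

This note documents the models and procedures `nichephylo` implements, the
choices made where the methodology left room, and what the synthetic-data
validation does and does not establish.

## Data model

All analyses run on a planar km grid.  An `EnvStack` holds co-registered
environmental layers (values standardized per layer when generated
synthetically), a shared cell size, origin, and one nodata mask.
Occurrences are planar points; geographic lon/lat input is converted once
by a cylindrical equal-area projection (exact in area, which is the only
property the buffer and overlap computations rely on; shape distortion at
high latitudes is irrelevant to the low-latitude systems this targets).
Chronograms are ultrametric trees with ages in Ma (checked at
construction, relative tolerance 1e-6), optionally carrying a posterior
sample of trees over the same tips.

## Synthetic generators

The generators exist to provide inputs with *known* ground truth:

- **Climate-like layers** are Gaussian random fields: white noise smoothed
  with a Gaussian kernel of scale `corr_length_km`, standardized, with
  pairwise inter-layer correlation induced by mixing a shared field into
  each layer (`layer = √ρ·shared + √(1−ρ)·private`).  This reproduces the
  two properties of real bioclim stacks that matter downstream — spatial
  autocorrelation and inter-variable correlation — and nothing else: no
  trends, no coastlines, no units.  Negative ρ is only defined for two
  layers (three or more fields cannot be pairwise negatively correlated at
  arbitrary strength).
- **Occurrences** are drawn per cell with probability proportional to a
  Gaussian suitability exp(−½ Σ_l ((env_l − opt_l)/breadth_l)²), points at
  cell centers, deduplicated.  Real herbarium data add collection bias,
  georeferencing error and spatial clustering that this sampler does not
  emulate; passing calibration tests therefore shows the *statistics* are
  correct under their own assumptions, not that field data meet them.
- **Clades** evolve tip niche optima by Brownian motion along the
  chronogram (per-branch increments N(0, σ²·t), default rate 0.2 per Ma on
  standardized layer scales — enough to spread congeneric optima across
  roughly one landscape SD at 8 Ma depth), then sample occurrences per tip
  with a shared breadth.  Posterior tree samples are emulated by
  multiplicative lognormal jitter of node ages (σ = 0.1), clipped to keep
  children younger than parents; topology is never perturbed.
- **The study fixture** transcribes the two-genus, 27-species system: the
  11 sister-pair table (MRCA ages, % geographic overlap, smaller-range
  species), a monophyletic Madagascar clade excluded from pair
  enumeration, one hard polytomy for the unresolved three-species group,
  and a 14.9 Ma crown.  Deeper node ages are not published as numbers, so
  the fixture interpolates them; they are synthetic and carry no analysis
  weight (pair-level ages always come from the pair table).  The three
  pairwise comparisons of the trio are the ones the study's table lists;
  the polytomy node sits at the oldest of their printed ages (2.4 Ma).

## Geographic ranges

Discs are approximated by 64-vertex polygons (inscribed-polygon area
deficit ≈ (2π/64)²/6 ≈ 0.16%, inside the 0.2% tolerance used throughout)
and fused with a polygonal union.  Overlap is normalized by the smaller
range, so a narrow endemic nested inside a widespread congener scores near
100% even though the two never co-occur locally — a known property of the
statistic, not a bug.  Default radius 20 km; 2 and 10 km are conventional
alternatives.

## Maximum-entropy niche model

The model is the Gibbs distribution p(cell) ∝ exp(λ·f(cell)) with min–max
scaled linear and quadratic features per layer (values clipped to [0, 1]
off the background).  The feature family is deliberately restricted:
linear + quadratic keeps the objective convex and small while allowing
unimodal response curves; hinge/threshold/product features are out of
scope.  The fit minimizes

    −mean_pres[λ·f] + log Σ_support exp(λ·f) + Σ_j β_j|λ_j|,

with β_j = reg·sd_j(background)/√m and support = background sample ∪
presence cells.  Regularization default 1.0, max 500 iterations,
convergence tolerance 1e-6.

Optimization is proximal gradient (ISTA) with Armijo backtracking rather
than coordinate-wise updates: backtracking makes the full regularized
objective provably non-increasing per step (an invariant the tests
assert), and the convex objective has the same minimizers either way.  The
fitted objective is cross-checked against an independent generic convex
solver (L-BFGS-B on the split λ = u − v formulation) to 1e-4.

Background cells default to a uniform sample of up to 10,000 unmasked
cells.  Replicates bootstrap the training partition (75/25 split) and
average the raw surfaces; per-cell SD grids and AUC SDs are only produced
at ≥ 8 presences — below that a single train/test partition leaves nothing
to estimate spread from.  Training gain is mean log p(presence) −
log(1/N_cells), clamped at 0.  No logistic calibration is attempted: every
downstream overlap statistic uses the normalized raw surface, which any
monotone output transform leaves unchanged.

Species with fewer than 5 unique localities are not modelled at all;
their surface in every overlap test is uniform over their buffered
geographic range (`range_fallback_surface`).  The threshold follows the
observed practice of the motivating study, where 6- and 7-locality species
were still modelled but the 4-locality one was replaced by its range.

## Overlap randomization tests

The identity test pools both species' localities in a canonical sorted
order (so the null sample is invariant to which species is called A),
re-partitions into the original sample sizes without replacement, refits
both models per pseudoreplicate, and uses the one-tailed-low estimator.
Observed surfaces are single fits on each species' full locality set (not
replicate averages), so observed and null models are built identically and
the comparison is exchangeable under the null.  The p-value is
p = (1 + #{null ≤ observed})/(n_reps + 1) — rejection means the niches are
*less* similar than re-partitions of the same points, i.e. not equivalent.
The (1+k)/(1+n) form avoids zero p-values; at the default 100
pseudoreplicates the smallest attainable p is 1/101 ≈ 0.0099.

The background test draws n_sister cells uniformly (without replacement)
from inside the sister's buffered range per pseudoreplicate, fits a model,
and records overlap with the focal surface.  Decisions are two-tailed at
the null's 2.5/97.5 percentiles; "more"/"less" label the side, stars come
from the two-tailed pseudo-p, and the test is run in both directions per
pair (4 results per pair across D and I).  Pseudoreplicate count defaults
to 100 for both tests.

Star coding everywhere: * p < 0.05, ** p < 0.01, *** p < 0.001, NS
otherwise.

## PCA and Mann-Whitney comparisons

Each sister pair gets one PCA on the pooled, standardized localities of
both species (correlation-matrix PCA — bioclim-style variables mix units),
and a two-sided Mann-Whitney U test per component (PC1–PC3).  The exact
permutation null is enumerated for pooled n ≤ 20 (tie-safe); larger
samples use the tie-corrected normal approximation.  ANOVA-family tests
are deliberately not offered; climatic variables routinely violate their
assumptions.

## Phylogenetic signal

The linear-parsimony cost is computed by Sankoff dynamic programming over
the finite candidate-state set given by the tip values (an optimal L1
reconstruction always exists on that set, so the DP is exact, polytomies
included); branch lengths are ignored, as in any retention-index analogue.
QVI = (Obs − Min)/(Max − Min) with Min = trait range and Max = Σ|x_i −
median(x)|; constant traits are defined to 0.  Linear (not squared-change)
parsimony is essential: the range is the linear-parsimony minimum, which
is what keeps QVI inside [0, 1].

The posterior test averages QVI over up to 1000 posterior trees; each null
replicate shuffles tip values on one randomly drawn posterior tree
(shuffling per draw, seeded).  A variable shows signal when its observed
mean falls below the null's 1% quantile — the threshold is a parameter,
since reasonable conventions differ.

Blomberg's K uses the BM tip covariance V (shared root-to-MRCA path
lengths), the GLS phylogenetic mean â = (1ᵀV⁻¹x)/(1ᵀV⁻¹1), MSE₀/MSE as
printed in the definition, and the tree-specific expected ratio
(tr V − n/(1ᵀV⁻¹1))/(n − 1).  On an equal-branch star tree V = cI and
K = 1 identically.  Significance: tip shuffles, p = (1 + #{K_shuffled ≥
K_obs})/(n_rand + 1), default 999 shuffles.

## Age-range correlation

For every internal node, the mean overlap between tips of different
daughter clades (all cross-child pairs at polytomies) is paired with the
node age; OLS of overlap on age gives the intercept and slope.  The
default between-clade summary is the unweighted mean; the nested
0.5-per-extra-node weighting of the original formulation is available
behind a flag.  The Monte-Carlo null permutes tip identities of the
overlap matrix (joint row/column permutation) and recomputes the fit;
f(greater) is the fraction of null coefficients *strictly* greater than
observed (ties excluded, so a fully tied null reports 0), reported as a
frequency rather than converted to a two-sided p.  Species present in the
tree but absent from the matrix are pruned with a warning.

## Validation problem sizes

The calibration and power studies run on deliberately small instances,
chosen so the whole suite re-runs quickly while leaving each check
statistically meaningful:

- identity/background calibration: 20×20-cell, 2-layer landscapes (5 km
  cells), 30 (identity) or 25 (background) occurrence draws per species,
  100 pseudoreplicates, 50 trials per condition;
- maxent-vs-oracle: 225-cell grids with 4 features;
- Blomberg's K: one 32-tip tree, 200 BM simulations for the mean, 50
  trials × 999 shuffles for power and type-I error;
- ARC recovery: 12-tip trees, overlap decaying as exp(−0.3·divergence)
  plus symmetric noise (SD 0.03), 200 permutations, 50 trials;
- end-to-end determinism: two 11-species clades on a 20×20 grid, every
  stage with reduced replicate counts.

These sizes are configuration values, not limits; `RunConfig` scales every
count.

## Known limitations

- The maxent variant is not bit-compatible with the reference Maxent
  software (no hinge features, no logistic calibration, no clamping/MESS
  handling); agreement is at the level of the shared convex objective.
- The occurrence sampler has no spatial sampling bias, so calibration
  results do not speak to bias-driven artifacts in real collections.
- The background test's verdicts depend on how the background is drawn
  (here: the buffered range); finer or coarser backgrounds can change
  outcomes, a sensitivity inherent to the method.
- QVI's tip-randomization power is limited on small (≤ 16-tip) trees;
  non-significance there is weak evidence of absence.
- The study fixture's deep node ages are interpolations for tree-shape
  completeness only.
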