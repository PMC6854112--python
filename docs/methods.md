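# Methods

This note documents the statistical model, the numerical choices, and the
design decisions behind `maxentsdm`, together with what the synthetic-data
generator does and does not emulate.

## Model

Presence-background data consist of n₁ presence locations and N uninformed
background locations described by explanatory variables (EVs). The target
of estimation is the relative occurrence intensity over the landscape. The
maximum-entropy estimate — the occurrence density that is maximally
uniform subject to matching the predictor means at presences — is a Gibbs
density, and its parameters coincide with the strong-weight limit of a
weighted logistic regression (infinitely weighted logistic regression,
IWLR). `maxentsdm` fits exactly that: presences enter with label 1 and
weight 1; the background, **with all presences appended** (the background
should represent every condition in the study area, including where the
species was found), enters with label 0 and weight `bg_weight`.

Predictions are expressed as probability ratio output,

    PRO_i = N · exp(α + Σ_k β_k x_ik),

with x the derived-variable (DV) matrix, β the fitted slopes, and α a
normalizing constant — not a free parameter — recomputed after fitting so
that Σ_background exp(α + Σβx) = 1. Hence mean PRO over the training
background is exactly 1, and PRO = 1 reads as "the suitability of an
average training location". For presence-absence data the identical DV
designs are fitted by ordinary logistic regression (`algorithm="LR"`),
with the intercept retained and probabilities returned.

### Deviance bookkeeping

Goodness of fit is the fraction of null deviance explained,
D² = 1 − deviance/null deviance, where both deviances come from the same
weighted binomial likelihood used in fitting (the saturated log-likelihood
is zero for 0/1 responses, so deviance = −2ℓ). The null deviance uses the
intercept-only model under identical weights. D² is tiny in absolute terms
for presence-background models (the weighted null deviance is large); it
is used comparatively, along nested chains.

### Variable transformation

Seven types, each allowing a unimodal or truncated-unimodal response:

| tag | raw form | parameters |
|-----|----------|------------|
| L | x | training min/max |
| M | zero-skewness transform | family (log/exp/identity), constant c |
| D | \|x − optimum\|^γ, γ ∈ {0.5, 1, 2} | optimum from the smoothed FOP curve |
| HF | max(0, x − k) | knot k |
| HR | max(0, k − x) | knot k |
| T | 1[x > k] | knot k |
| B | 1[x = level] | level label (categorical EVs) |

Every DV is linearly rescaled so the training column spans [0, 1]
(T/B take values in {0, 1}); projection values outside the training range
map outside [0, 1] — clamping is a projection-time option, not a
transform-time one. Each DV stores its parameterized transformation, so a
serialized catalogue plus model is self-contained and re-appliable to new
data. DV names embed the metadata (`slope_D2`, `slope_HF4`, `soil_B3`).

**Zero-skewness (M).** Right-skewed EVs use log(c + x) with c > −min(x);
left-skewed EVs use exp(c·(x − max(x))) with c > 0 (the shift is a
positive rescaling of exp(c·x), so it cannot change skewness but prevents
overflow). c is found by bracket expansion and Brent's method on the
sample skewness of the transformed values (tolerance driven to machine
precision; the acceptance check requires |skewness| < 1e−6 at n = 500).
When no root brackets — e.g. the sample is already symmetric — the
transformation falls back to the identity (linear rescale) with a warning.

**Hinge/threshold preselection.** Candidate knots are 20 points evenly
spaced strictly inside the training range (the count is a package default,
exposed as `n_knots`). Each candidate is fitted alone against the response
and its D² recorded; only candidates at local maxima of the D²-versus-knot
sequence are retained (endpoints count when greater than their single
neighbour). This keeps multiple genuine response inflections without a
magic top-k.

**Deviation optimum.** The optimum is the argmax of the smoothed FOP curve
(below). To prevent the optimum from being an edge-extrapolation artifact
of the local fit, the argmax is restricted to bins holding at least half
the mean occupancy of nonempty bins (never fewer than 2 rows); if the FOP
optimum is undefined the EV median is used with a warning.

### Frequency of observed presence (FOP)

FOP is the share of presence records among all records per interval
(continuous) or level (categorical). Defaults: equal-width bins,
n_bins = min(100, rows/10) bounded below by 5; a local quadratic fit to
(bin centre, FOP), weighted by bin totals with tricube distance weights
over a window spanning half the range (`smoother_span=0.5`). Both defaults
are exploratory choices and are config-exposed. The data density (bin
occupancy share) is reported and plotted alongside.

### Subset selection

Forward stepwise selection with a nested-model F-test,

    F = ((D²_full − D²_ref)/df_e) / ((1 − D²_full)/df_u),
    df_e = m_full − m_ref,   df_u = n − m_full − 2,

with p from the F(df_e, df_u) upper tail and n the number of background
rows used in fitting (presences included) for maxent models, or the
number of observations for LR. The −2 in df_u is the convention of the
reference audit tables (one for the intercept/normalizer beyond the m
DVs). Within a round, candidates are ranked by p ascending, then F
descending, then input order (a deterministic, auditable tie-break); the
best candidate is accepted iff p < alpha (default 0.01 at both stages).

Stage one selects DVs separately within each EV; EVs with no significant
DV are dropped and never revisited. Stage two selects whole per-EV DV
sets as indivisible units contributing their DV count as df_e. A
`formula_start` list forces EVs into the base model unconditionally. With
`interaction=True`, after main effects terminate, products of DV pairs
between selected EVs (rescaled to [0, 1], named `ev1:ev2_dv1.dv2`) are
tested as further units. Rejected candidates are not revisited within a
stage. Because each test demands deviance orthogonal to the current model,
two highly correlated EVs are never both retained, which is why no
collinearity prescreening is built in.

### Evaluation

AUC uses the rank (Mann-Whitney) tie convention; the trapezoidal area of
the ROC curve over all distinct thresholds equals U/(n₁n₀) to machine
precision. Presence-only AUC (background as negatives) is always flagged
with a warning — it is not comparable to presence-absence AUC. Spatial
block cross-validation splits the presences at the median longitude into
two halves differing by at most one record, then each half at its own
median latitude (order swappable via `lon_first`); background locations
fall into the same four rectangles. The complexity grid reruns the entire
pipeline per alpha and fold and scores the held-out fold.

## Synthetic data generator

The generator emulates the *shape* of presence-background datasets:
background EVs drawn iid from stated distributions (normal, uniform,
lognormal, categorical levels), and presences drawn by conditional
thinning of candidates from the same law with acceptance probability
proportional to exp(η), where η sums per-EV responses (linear, Gaussian-
bump unimodal, threshold, hinge, categorical offsets) on the log-intensity
scale. Generation is a pure function of spec + seed. It does **not**
emulate spatial autocorrelation of EVs, sampling bias, or detection error
— coordinates, when generated, are independent uniforms — so passing tests
demonstrate statistical correctness of the machinery under the stated
sampling model, not robustness to the biases of real survey data.

Because the fit deliberately appends presences to the background, its
estimand is mildly attenuated relative to the generator coefficient when
presences are a non-negligible background fraction; for a Gaussian EV with
a linear log-intensity the estimand solves a one-line mean-matching fixed
point, which the test suite uses as its oracle. The LR/presence-absence
path has no augmentation and recovers coefficients unbiasedly.

## Default study sizes

The quantitative checks run at sizes chosen to make Monte-Carlo noise
negligible relative to the tolerances while staying desk-scale: F-test
oracle on 1,000 random cases; zero-skewness at n = 500; AUC agreement at
n = 300; predictor recovery and type-I control over 20 replicates of
2,000 background + 200 presence records with 8 candidate EVs (at least 20
presences per candidate — the regime in which forward selection is
well-behaved), transformation types {L, M, D} matching the generator's
linear/unimodal responses; block partitioning of 114 records (sizes
29/29/28/28); parameter recovery at 10,000 background records.

## Numerical choices and degenerate inputs

- IRLS/Newton with step-halving on the exact weighted binomial
  log-likelihood; convergence at max-norm gradient < 1e−8, cap 100
  iterations (non-convergence warns and reports the gradient norm;
  perfect separation therefore surfaces as a warning, with coefficients
  at the iteration cap).
- `bg_weight` defaults to 100. Slope estimates are already at the
  infinite-weight limit there for well-conditioned designs (the 100 vs
  1,000 shift is below 1e−3 max-norm); nearly aliased DV pairs (e.g. L
  and M of near-symmetric data) or heavy-tailed EVs make individual
  coefficients ill-determined, though fitted predictions remain stable.
- A categorical EV whose every indicator is selected is aliased with the
  intercept; coefficients are then non-unique (minimum-norm solution) but
  predictions are unaffected.
- Constant EVs are skipped with a warning; EVs with fewer than 3 distinct
  values get no M or spline DVs; single-level categoricals get no DVs.
- Raster cell membership is half-open and lower-left anchored
  ([x0, x0+cellsize) × [y0, y0+cellsize)), so boundary points are assigned
  deterministically. Background cell sampling is seeded, uniform without
  replacement over cells valid in every raster. The ASCII grid writer uses
  shortest round-trip float formatting, so write→read is value-identical.
- Response coding: 1 presence, 0 absence, NaN background. EV rows with
  missing raster values are dropped at import with a logged count; losing
  every presence is fatal.
- Marginal-effect curves hold other continuous EVs at their training mean
  and categorical EVs at their modal level (config-exposed reference
  point); single-effect curves refit the EV's own selected DVs rather than
  slicing coefficients out of the full model, avoiding confounded
  normalizers.

## Known limitations

- No sampling-bias correction or spatial-autocorrelation treatment; these
  must be handled upstream of the model.
- No regularization path; selection strictness (alpha) is the only
  complexity control, tunable by the block-CV grid.
- Coefficient standard errors are not reported (the weighted likelihood
  is not a proper likelihood for inference on individual coefficients;
  model comparison runs through the F-test machinery instead).
- The block partitioner implements the 4-fold latitude/longitude scheme
  only.
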