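# Methods

This note documents the models, the synthetic data they are validated on,
and the numerical and design choices made where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

The unit of analysis is a per-subject structural connectivity matrix:
symmetric, nonnegative, zero-diagonal, over a parcellation whose parcels
carry a hemisphere (L/R, balanced) and one of seven functional communities
(visual, somatomotor, dorsal attention, ventral attention, limbic,
frontoparietal, default mode). Hemispheres are analyzed separately;
inter-hemispheric edges are discarded at the hemisphere split. Edge
vectors are the row-major upper triangle (i < j) of each within-hemisphere
submatrix — p parcels per hemisphere give p(p−1)/2 edges (4950 at the
200-parcel default). The layout decision matters only for bookkeeping: the
vectorize/devectorize round trip is exact and tested.

Whether the original analysis fed the full matrix or a triangle, and
whether inter-hemispheric edges entered at all, is not derivable from the
layer sizes; the non-redundant within-hemisphere triangle is this
package's choice.

## Confound residualization

Each edge is residualized by OLS on [intercept, age, sex, site dummies],
fit on all subjects pooled across groups — per-group fitting would leak
group signal into the confound estimates. Collinear design columns (e.g.
a constant sex column, or site dummies after subsetting to one site) are
dropped with a warning. Residuals are exactly orthogonal to the retained
design columns; a planted group shift survives residualization because
group membership is deliberately not in the design.

## Autoencoder

Fully connected tanh encoder/decoder; the decoder mirrors the encoder
sizes in reverse, with independent weights per layer (weight sharing
across layers of different sizes is not meaningful). Defaults follow the
full-scale analysis: hidden sizes 7700/5500/2930/900, bottleneck 200,
input dropout 0.3, learning rate 8e-5, 500 epochs, averaged SGD. All
fields are overridable, and every experiment here uses proportionally
small layers (e.g. [64] or [64, 32] hidden, bottleneck 8–16) on small
parcellations — the problem sizes used by the tests and the validation
script are desk-scale choices, stated with each experiment.

Numerical choices:

- **Loss** is the per-sample feature-mean squared error, averaged over the
  batch; training is full-batch by default (cohorts are small),
  mini-batches are configurable.
- **Optimizer**: plain gradient steps with Polyak–Ruppert tail averaging
  (averaging starts at a configurable fraction of the epoch budget,
  default 0.5). Epoch losses are evaluated with dropout off, using the
  averaged weights once averaging is active.
- **Initialization**: symmetric uniform scaled by 1/sqrt(fan-in), seeded.
- **Model selection**: the epoch minimizing validation loss (earliest on
  ties); "minimum loss in training and validation" is ambiguous, and
  validation-loss selection is the standard overfitting guard.
- **Input scaling**: the decoder's tanh output is bounded in (−1, 1), so
  each edge is min–max rescaled so the training range spans [−1, 1]; the
  scaler is frozen on training data and applied to validation/test
  (values may leave the interval there; the encoder input is
  unconstrained). Constant edges map to 0.
- **Non-finite losses** abort training with the epoch index.

Two things are deliberately **shared between the two groups within a split
repeat**: the per-edge scaler (fit on the union of both groups' training
subjects) and the weight initialization. Both are comparability
requirements discovered by simulation: a per-group min–max scaler absorbs
exactly the group mean differences the pipeline is meant to detect, and
independent initializations make the two groups' attribution fields differ
everywhere for reasons unrelated to the data. With shared init the models
diverge only through their group's training data.

Splits are disjoint and exhaustive per group (explicit counts must sum to
the group size, mirroring the 45/20/15 and 33/16/12 partitions of 80 and
61 subjects; fractional splits default to 55/25/20 with the rounding
remainder in training). All randomness derives from numpy `SeedSequence`
spawning, so every model is reproducible from the master seed.

## Integrated gradients

Attribution of edge i toward the bottleneck code, from baseline m (default
all-zero — the "zero-information" input; attributions do depend on this
choice, and other baselines are configurable):

IG_i(x) = (x_i − m_i) · (1/M) Σ_{k=1..M} ∂f(m + (k/M)(x − m))/∂x_i

- Right-endpoint Riemann rule, exactly as the defining sum; M defaults to
  300. The rule is exact for linear targets at any M; for tanh encoders
  the completeness residual |Σ IG_i − (f(x) − f(m))| is the convergence
  diagnostic and shrinks roughly as 1/M.
- **Scalarization**: IG is defined per output neuron; attributing to the
  latent code collectively requires a scalar target. Default is the sum of
  bottleneck activations, which preserves the completeness axiom against a
  single scalar. Per-unit Jacobian attributions (aggregate e.g. by sum of
  absolute values) are available.
- Attribution always uses the selected weights in evaluation mode
  (dropout off), so gradients are deterministic.
- Per-subject attributions are computed under every split repeat's model
  for the subject's group and averaged across repeats. Averaging matters:
  the part of the attribution field that is idiosyncratic to one trained
  model is roughly independent across repeats and shrinks with averaging,
  while data-driven structure persists.
- Z-normalization is per edge across subjects pooled over both groups
  (per-group normalization would remove the group differences under
  study). Zero-variance edges are set to 0 with a warning.

## Group statistics

Pooled-variance two-sample t per edge (Welch available), two-tailed
permutation p-values from random label reassignment with permutations
shared across edges, add-one estimator p = (1 + #{|t*| ≥ |t|})/(B + 1),
and Benjamini–Hochberg FDR across all edges of both hemispheres jointly
(the correction family is not derivable from the source analysis; pooling
is the conservative reading). Two-tailed tests because attribution
differences have no a-priori sign.

One resolution constraint is worth knowing: with B permutations the
smallest attainable p is 1/(B+1), and BH at level q with m edges and k
true positives rejects nothing unless 1/(B+1) ≤ kq/m. At m ≈ 1100 edges
and k ≈ 20 planted edges, B = 1000 sits exactly at the boundary; the
planted-block experiment therefore uses B = 2000.

Block summaries over the 28 unordered community pairs support three
rules: signed mean t (default, matching "summarized the t-statistics"),
mean |t|, and significant-edge count. Because the sign of an attribution
difference is tied to the arbitrary sign of the encoder's gradient at that
edge, signed means can cancel within a block; the count rule is the robust
localization statistic and is what the planted-block recovery experiment
uses. Blocks with no significant edges are flagged, never silently zero.

## Behavior CCA

Classical CCA via SVD of the whitened cross-covariance (economy SVDs of
the centered views; canonical correlations are the singular values of
Ux'Uy). This construction gives exactly non-increasing correlations,
within-view orthogonal variates, and affine invariance — properties the
test suite asserts at machine precision; an independent NIPALS
implementation (scikit-learn's) serves as a numerical cross-check in the
tests, not as the implementation.

- **Dimensionality**: edges far outnumber subjects, so X is reduced by
  PCA to min(n/2, 50) components before CCA (configurable); canonical
  weights are back-projected to edge space for explained-variance
  summaries.
- **Component selection**: five-fold cross-validation. Per fold, fit on
  training rows, project held-out rows, correlate held-out u with v per
  component; p-values by permuting held-out rows of one view (1000
  permutations, add-one, two-tailed — parametric tests are inappropriate
  at fold sizes of tens); BH-FDR across components within a fold; a
  component is selected when significant in a majority of folds.
- **Explained variance** uses population (divide-by-n) variances; as a
  variance ratio EV is invariant to that convention, but the worked
  examples are reproducible only once a convention is fixed. Cross-view
  prediction is used for the EV profile (Y from the X-side scores u, X
  from the Y-side scores v, restricted to the selected components), so EV
  measures behavior-linked variance; per-edge EV is averaged within each
  community block.
- Feature modes (attributions, raw connectivity, latent bottleneck
  vectors) run through identical machinery; subjects without behavior
  scores are dropped with a logged count (the score-availability filter,
  not a site-name filter).

## Synthetic cohort generator

The generator emulates the structure, not the calibrated distributions,
of a two-site-style case-control cohort:

- **Edges**: baseline log-weight scale 3.0 plus a rank-r factor model
  (shared subject scores across hemispheres, per-hemisphere loadings;
  signal SD 0.5 by default) plus N(0, 0.2) noise, mapped through a sharp
  softplus (β = 4) for nonnegativity. At this operating point the softplus
  is the identity to ~1e-5, so planted mean shifts survive essentially
  exactly — the Monte-Carlo recovery test verifies the planted delta to
  ±0.05. The low-rank structure is what makes the data compressible, i.e.
  gives the autoencoder something to learn.
- **Phenotype**: age uniform on 8–18 years, sex binary, site a 3-level
  categorical — matching the demographic ranges of the motivating cohort
  without copying any data. Confounds act additively and linearly on
  edges (scalar scale per covariate times a per-edge random direction),
  so OLS residualization can remove them exactly.
- **Group effects**: per-block mean shifts added to the autism-like
  group's edges in declared community blocks, identically in both
  hemispheres; the ground-truth object records the exact per-edge mask.
- **Behavior**: four ADOS-like scores. Either an explicit linear map
  (scores = loadings·features + noise) or planted canonical structure: a
  random orthonormal direction per target correlation ρ, scaled so
  corr(score, projection) = ρ given the noise SD. In the noiseless limit
  the planted correlation is 1 along any nonzero loading direction.

What the generator does **not** emulate: realistic edge-weight marginals
after log transformation (unknown for the motivating data), spatial
autocorrelation of parcels, site-by-covariance interactions, missingness,
or motion artifacts. Passing recovery tests therefore demonstrates the
statistical machinery is correct and calibrated under its own assumptions,
not that effect sizes transfer to real cohorts.

## Validation experiments and problem sizes

`latentconn.experiments` (driven by `scripts/acceptance.py` and the
end-to-end test module) fixes these desk-scale study conditions:

- IG linearity at d = 50; completeness on a [32]-hidden encoder over 105
  edges at M = 50/300/3000.
- Permutation calibration: 2000 null edges, 30 vs 30, 1000 permutations.
- FDR: 2000 edges, 10% shifted by 1.5 SD, 20 seeded repeats.
- Planted-block chain: 68-parcel scheme, 100/100 subjects, delta 0.5 in
  the default-mode block, 5 split repeats, IG M = 50, B = 2000
  permutations, count-rule summary, 20 simulated cohorts.
- Capacity: noiseless rank-5 edges (105 edges, n = 200), [64, 32]-hidden
  bottleneck-8 model trained 4000 full-batch epochs at rate 0.25, against
  a 5-component PCA oracle fit on the same training rows.
- CCA: ρ = 0.8 at n = 300 (30 features); two planted components at
  n = 500; 20 independent null runs for the zero-selection rate.

## Known limitations

- Full-scale layer sizes (7700-unit layers) are supported but slow in
  pure numpy; the package targets method validation and moderate cohorts,
  not GPU-scale training.
- The ASGD implementation is tail averaging over epochs, not a
  per-iterate decaying schedule.
- Only the zero baseline for IG is validated; the attribution literature
  and the source analysis both note baseline sensitivity.
- CCA p-values are conditional on the PCA reduction rank; very low ranks
  can hide true canonical structure.
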