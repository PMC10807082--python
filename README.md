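# latentconn

Feature-representation learning for structural brain connectomes:
autoencoder compression of connectivity, integrated-gradient attribution of
edges to the latent code, permutation-based group comparison, and
cross-validated canonical correlation analysis (CCA) against symptom
scores — with a synthetic cohort generator so every stage is testable
against known ground truth.

## Who this is for

Researchers analyzing case-control diffusion-MRI connectome cohorts (e.g.
autism vs neurotypical controls) who want an interpretable low-dimensional
representation of structural connectivity instead of edge-by-edge mass
univariate testing. The pipeline starts from per-subject parcellated
connectivity matrices (log-transformed streamline weights over a
parcellation such as a 200-parcel scheme with the seven canonical
functional communities); image preprocessing and tractography are out of
scope.

## The method

1. **Confound removal.** Each within-hemisphere edge is residualized on
   age, sex and site by OLS, pooled across groups.
2. **Autoencoder.** Per group and hemisphere, a fully connected tanh
   autoencoder compresses the edge vector `x` through a bottleneck:

       z = E(x) = tanh(W x + b)        (per encoder layer)
       y = D(z) = tanh(W z + b)        (decoder mirrors the encoder)
       L(x, y) = Σ |x − y|² / n        (per-sample MSE)

   Training uses averaged stochastic gradient descent with dropout on the
   input layer; the epoch with minimum validation loss is selected, and
   test performance is the per-subject Pearson correlation between input
   and reconstruction. Splits are repeated (100 times at full scale) to
   reduce subject-selection bias.
3. **Integrated gradients.** The contribution of edge *i* to the latent
   code, from a zero baseline `m`, via the Riemann approximation

       IGᵢ(x) = (xᵢ − mᵢ) · (1/M) Σₖ ∂f(m + (k/M)(x − m)) / ∂xᵢ

   with `f` the scalarized bottleneck (sum over units). Attributions are
   averaged over split repeats and z-normalized per edge.
4. **Group statistics.** Edgewise two-sample t-tests with a label
   permutation null, Benjamini–Hochberg FDR, and summaries over the 28
   community blocks (signed mean t, mean |t|, or significant-edge count).
5. **Behavior CCA.** Attributions (or raw connectivity, or latent vectors)
   vs four ADOS scores; the number of canonical components is chosen by
   five-fold cross-validation with FDR-corrected held-out correlations,
   and explained variance EV = (Var{x} − Var{x − x̂}) / Var{x} is profiled
   per score and per community block.

The synthetic generator plants known group effects in chosen community
blocks, linear age/sex/site confounds, low-rank latent structure and a
configured canonical correlation with behavior scores, so recovery of each
planted quantity can be asserted.

## Worked example

```python
from latentconn.pipeline import PipelineConfig, run_pipeline
from latentconn.synthetic import SyntheticConfig
from latentconn.autoencoder import EncoderSpec
from latentconn.attribution import IGConfig
from latentconn.cca import CCAConfig

config = PipelineConfig(
    synthetic=SyntheticConfig(
        n_autism=80, n_control=80, n_parcels=48, latent_rank=5,
        effect_blocks=[("default_mode", "default_mode", 0.5)],
    ),
    encoder=EncoderSpec(hidden_sizes=[48], bottleneck=12, input_dropout=0.1,
                        learning_rate=0.1, max_epochs=150),
    ig=IGConfig(steps=50),
    cca=CCAConfig(n_perm=500),
    n_perm=2000, n_repeats=5, seed=11, outdir="demo_run",
)
outdir, state = run_pipeline(config)
```

This simulates a 160-subject cohort with a +0.5 edge-weight shift planted
in the default-mode block of the autism-like group, then runs every stage.
Key outputs (from this exact run):

- `reconstruction.json` — test reconstruction, mean ± SD Pearson r per
  group: autism 0.192 ± 0.083, control 0.208 ± 0.063 (noisy synthetic
  edges; the compressible low-rank part is what the model can recover).
- `groupdiff_attributions.tsv` — 17 of 1 104 edges significant after
  permutation tests + FDR.
- `block_count_attributions.tsv` — significant-edge count per community
  block. The planted default-mode–default-mode block holds 12 of the 17
  significant edges; no other block holds more than 2, so the planted
  effect is correctly localized.
- `cca_mode_comparison.tsv` — held-out canonical correlations per feature
  mode. Behavior was planted on raw edges with canonical correlation 0.8;
  five-fold selection keeps 1 component, with mean held-out r = 0.66 for
  the connectivity mode and 0.47 for attributions.

The same pipeline is exposed on the command line:

```bash
latentconn run-all --config config.yaml --seed 11 --outdir demo_run
latentconn sweep --config config.yaml --grid grid.yaml   # hyperparameter sensitivity
```

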