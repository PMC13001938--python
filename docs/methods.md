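# Methods

`microstress` implements a generative machine-learning pipeline for
predicting oil contamination from microbial community composition in
oil-amended microcosm experiments, together with a synthetic-cohort
generator used to exercise and validate the pipeline end to end.

## The pipeline

The input is a flat sample table: one row per microcosm sample with
five environmental features — encoded location, incubation time
(weeks × 10), encoded oil type, incubation temperature (°C), calendar
month (× 10) — a block of per-taxon 16S counts (`Bac_1 .. Bac_T`,
T ≈ 503), and a bottle identifier naming the physical microcosm the
sample came from.

1. **Categorical codecs.** Oil treatment labels are written as binary
   pairs — no oil (0,0), crude (0,1), diesel (1,0); (1,1) is illegal —
   and compressed to a single scalar by a 2-8-4-1-4-8-2 autoencoder
   (ReLU bottleneck, sigmoid outputs). Latitude/longitude pairs are
   compressed by a 2-16-8-4-1-4-8-16-2 autoencoder (sigmoid
   bottleneck, linear outputs); coordinates are min–max scaled to
   [0, 1] before training because raw degrees over a narrow regional
   range train poorly against a linear output layer. Both codecs use
   Adam on MSE at batch size 16. Decoding a raw sigmoid pair back to a
   label rounds each coordinate at 0.5 and falls back to the nearest
   legal code by Euclidean distance (ties broken no_oil → crude →
   diesel), so label decoding is total on [0,1]².
2. **Taxa selection.** A random-forest regressor (2,500 trees, max
   depth 25, MSE splits) maps the full count block to the encoded oil
   type; taxa are ranked by normalized mean decrease in impurity, ties
   broken by ascending taxon index for determinism. Seeded permutation
   importance is available as a cross-check. PCA and t-SNE 2-D
   embeddings are provided for the conventional ordination comparison.
3. **Augmentation (ADNN).** A 5→32→64→128→64→32→N network (central
   layer Gaussian-activated, f(x) = exp(−x²); linear output) learns
   env → top-N taxa abundances on all samples (3,000 epochs, batch 32).
   Synthetic inputs add zero-mean Gaussian noise with sd 0.01·σᵢ (σᵢ =
   sample sd of input column i) to the full real input matrix, once
   per round, four rounds by default: 404 real samples yield 1,616
   synthetic inputs and, with the network's predictions attached, a
   2,020-row augmented training set. Noise is applied in raw feature
   units (σᵢ is defined there); the network standardizes internally
   and de-standardizes at its outputs, clipping predicted abundances
   at 0. If the augmentation fit is poor (training R² < 0.75) the
   package emits a reliability warning — synthetic rows inherit the
   generator's biases.
4. **VAE stress sets.** A variational autoencoder (encoder trunk
   256-128-64 ReLU, 3-D Gaussian latent with μ and log σ² heads,
   mirrored decoder, linear output) is fit to the (5+N)-dimensional
   augmented set with loss = per-sample reconstruction squared error
   + KL(N(μ,σ²) ‖ N(0,I)), Adam, 3,000 epochs, batch 32, β = 1 with no
   annealing. Features are z-scored inside the model. *Stress sets*
   decode one latent draw per training row from its posterior
   N(μᵢ, σᵢ²) — samples similar to, but not identical to, the
   originals (drawing from the N(0, I₃) prior instead is available for
   global latent-space probing, at the cost of blended, less coherent
   samples between latent clusters). Stress sets probe the predictor's
   internal consistency; they are never treated as independent
   validation data. The summed (per-sample) reconstruction term
   matters: weighting reconstruction as a per-feature mean collapses
   the posterior onto the prior and the decoder onto a constant.
5. **Prediction.** A (4+N)→32→64→128→64→32→1 regression network (all
   ReLU; batch normalization on the fifth hidden layer when enabled)
   predicts the encoded oil scalar from the four non-oil environmental
   features plus the N selected taxa (1,500 epochs, batch 16). The
   target is continuous regression — R² is the metric throughout — and
   predictions decode to labels through the oil codec. Inputs and
   target are z-scored internally; R² is affine-invariant so reported
   values are unchanged.
6. **Evaluation.** `feature_sweep` reruns the chain per feature count
   k and reports the four stage R² values (internal-fit regime:
   training uses all samples). `bottle_holdout` runs repeated random
   grouped splits (default 22 at an 80/20 bottle ratio; at 172 bottles
   the held-out count alternates 34/35): ranking, augmentation
   statistics, the ADNN and the predictor are refit per split on
   training-split samples only, and R² is computed on untouched
   held-out samples. Stress-test targets take the generated `oil_enc`
   column snapped to the nearest legal encoded-oil value — oil type is
   categorical underneath, so a generated target between codes is
   attributed to its nearest class.

Every stage trains with Adam on MSE, logs its training R² at a
100-epoch cadence, and returns the best-R² checkpoint. All training
loops run on a small numpy engine written for this package (dense
layers, the four activations, batch normalization, Adam, seeded
initialization and shuffling); training is bit-reproducible given the
stage seed, and a master seed fans out to per-stage seeds through a
splittable seed sequence.

### Numerical choices

- ReLU-bottleneck autoencoders can land on dead optima (the bottleneck
  scalar collapses). Codec training restarts from deterministically
  derived seeds (at most 5 times) when the fit is poor, keeping the
  whole procedure a pure function of its seed.
- Codec convergence: early stop when full-data MSE < 1e-7, default
  budget 2,000 epochs (4,000 for the location codec, which sees very
  few distinct points per epoch).
- Multi-output R² is pooled in raw units:
  1 − Σ_cols Σ_rows (y−ŷ)² / Σ_cols Σ_rows (y−ȳ_col)², equivalently a
  variance-weighted pooling of standardized columns; zero-variance
  columns are excluded. High-abundance taxa therefore dominate the
  augmentation R², which is the behaviour of the raw-unit definition.
- BN layers use batch statistics in training and exponential running
  moments (momentum 0.9) at inference, so predictions are independent
  of inference batch size.
- The VAE monitors *deterministic* reconstruction (z = μ) for
  checkpointing; posterior collapse (μ→0, σ→1, negative reconstruction
  R²) warns rather than fails. A mild per-epoch learning-rate decay
  (0.999) stabilizes the late epochs.
- The sigmoid is computed in the stable piecewise form (exp only of
  −|x|).

## The synthetic cohort generator

The generator emulates the structure of a multi-campaign Great Lakes
microcosm study: 172 bottles across 4 sites, 0–7 weeks of incubation,
three oil treatments assigned in balance, ~2.35 samples per bottle
(expected total ≈ 404), and 503 taxa of which 10 are planted
oil-responsive. Responsive taxa have their negative-binomial mean
multiplied by `2^(log2fc · ramp(week))` under the matching treatment,
where `ramp` rises linearly to 1 at week 3 — hydrocarbon-degrader
blooms grow in over the first weeks of incubation and saturate.
Default effect size is 2⁴ = 16-fold, cycling taxa through crude-only /
diesel-only / both-oil response patterns.

Key distributional choices, all configurable:

- **Campaign structure.** Month and incubation temperature are
  site-level attributes (each site sampled in one campaign with one
  lab setting), so location, month and temperature are collinear at
  the site level. This mirrors the provenance of multi-experiment
  cohorts, whose printed tables show constant temperature within a
  campaign, and gives the five environmental features a low intrinsic
  dimension (site ⊕ week ⊕ treatment) — the regime in which a
  3-D-latent VAE is a sensible model.
- **Counts.** Negative binomial (default overdispersion α = 0.05,
  var = μ + αμ²) under abundance-dependent structural dropout
  π = exp(−μ/μ₀), with μ₀ calibrated by bisection so the expected
  overall zero fraction equals the configured `sparsity` (default
  0.7). Dropout concentrated on low-abundance taxa reflects how
  sparsity arises in real 16S data: rare organisms fall below the
  detection limit while blooming degraders are reliably observed.
  A flat per-cell zero process would instead make even dominant taxa
  intermittently unobservable and cap any env→taxa regression far
  below the fitted regime this method operates in.
- **Bottle effects.** Each bottle carries a shared log₂-normal random
  effect (sd 0.15) multiplying all taxa means, plus *taxon-specific*
  bottle effects (sd 0.5 per taxon per bottle) — the between-bottle
  community variability that environmental covariates cannot explain
  and that motivates grouped hold-out. The taxon-level term is what
  makes the augmentation network's fit degrade as more (and less
  informative) taxa are selected, and what keeps held-out R² modest.
  Raising the shared term (e.g. to ≥ 1) produces the regime where
  bottle-level splits score clearly worse than sample-level splits.
- **Encodings.** The generator writes stand-in encoded values
  (per-site location scalars; oil encoding {no_oil: 0, crude: 45.11,
  diesel: 146.27}) rather than training codecs; any three distinct
  oil values are equivalent downstream since ranking and R² are
  affine-invariant in the target.

What the generator does **not** emulate: phylogenetic correlation
between taxa, compositional (fixed-depth) constraints, sequencing
error, temporal autocorrelation within a bottle beyond the shared
random effect, and any real taxonomy. Passing tests on this cohort
demonstrates that the pipeline's machinery behaves as designed under a
known, recoverable signal — not that real communities are this clean,
nor that held-out performance on real data would be high.

## Problem sizes used in tests

Training costs are kept proportionate by running reduced schedules
where the full ones add nothing to the property under test: module
tests use cohorts of 40–172 bottles with 30–503 taxa and stage budgets
of 50–400 epochs; the pipeline-shape checks run the augmentation
network for 800 epochs, the VAE for 600 and the predictor for 600
(each stage is past its R² plateau well before these budgets);
the grouped hold-out check runs all 22 splits of the full 172-bottle
cohort with 100-tree forests, two noise rounds and short stage
schedules (the split-level guarantees being the point there); ranking
recovery uses 300-tree forests, whose top-of-ranking behaviour matches
the 2,500-tree default. Library defaults everywhere remain the full
schedule.

## Known limitations

- The stress-test R² shares training provenance with the predictor (both
  see ADNN-augmented data); it measures internal consistency, not
  generalization — the grouped hold-out exists precisely because the
  internal-fit numbers are optimistic.
- Augmentation noise (0.01·σᵢ) perturbs inputs only; outputs are the
  network's deterministic predictions, so synthetic rows cannot add
  response variability the augmentation network has not learned.
- MDI importances are biased toward high-cardinality/high-variance
  features; the permutation cross-check mitigates but does not remove
  this.
- The single-neuron codec bottleneck imposes a total order on
  categories and coordinates; with more than a handful of distinct
  sites the location codec's reconstruction degrades.
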