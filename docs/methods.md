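# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `patternfit`. It is written for a reader who wants to
understand *why* the package computes what it computes, and what passing
its test suite does and does not demonstrate.

## The scientific problem

Biological patterns — fish skin stripes, bacterial colony outlines,
dendritic growth — can be reproduced by many mathematical models whose
likelihoods are intractable, so neither model choice nor parameter values
can be read off an observed snapshot directly. The package implements a
two-stage, simulation-based approach:

1. **Model selection by retrieval.** Pattern images from a library of
   simulators are embedded into a shared latent space; for a target
   image, the most similar library patterns (cosine similarity) suggest
   which generative mechanisms are *capable* of producing it. This is
   deliberately retrieval, not classification: several mechanisms can
   generate near-identical patterns, and the output is a ranked list of
   candidates with a MAP@k affinity matrix quantifying the overlap.
2. **Parameter estimation by simulation-decoupled neural posterior
   estimation (SD-NPE).** For one chosen model (the two-species Turing
   system), a probabilistic regressor maps an image's reduced feature
   vector to a bivariate-normal "per-sample posterior" over the free
   parameters. N snapshot posteriors are combined on a parameter lattice
   using

       log p(w | x_1..x_N) = Σ_i log p_i(w) − (N−1) log p̂(w) + const

   where the prior p̂ is approximated by the cell-wise average of the
   per-sample posteriors over the whole training set (Monte Carlo
   integration). Training happens once; inference needs no further
   simulation.

## The Turing model and its stability analytics

The reaction-diffusion system is

    ∂u/∂t = f_u u − f_v v + q u² − u³ + D_u ∇²u
    ∂v/∂t = g_u u − g_v v               + D_v ∇²v

with estimation-protocol constants f_u = 0.51, g_u = 0.81, q = 0,
D_u = 0.1, D_v = 1.0 and free parameters (f_v, g_v) ∈ [0.6, 1.0]².
Linearizing about (0,0) gives the dispersion relation λ(k) — the growth
rate of a perturbation of wavenumber k — as the dominant eigenvalue of
J − k² diag(D_u, D_v) with J = [[f_u, −f_v], [g_u, −g_v]].

Two closed-form features summarize λ(k):

* the fastest-growing wavenumber

      k_max² = [(D_u+D_v)·√(f_v g_u) − √(D_u D_v)·(f_u+g_v)]
               / [√(D_u D_v)·(D_v−D_u)],

  derived from dλ/d(k²) = 0 (the derivation in `stability.py` is
  validated against a golden-section argmax of λ to relative error
  < 1e−3 over the whole parameter box). Substituting the protocol
  constants and factoring out the coefficient of the D_u(f_u+g_v) term
  gives the two-parameter form k_max = C·√(0.31·√f_v − 0.1·(0.51+g_v))
  with prefactor C = √(1/(D_u(D_v−D_u))) = 3.33;
* the band-width feature D_k = ln((A+B)/(A−B)) with
  A = D_v f_u − D_u g_v and B = √(A² − 4 D_u D_v (f_v g_u − f_u g_v)),
  which equals ln(k_right²/k_left²) for the band edges where λ crosses
  zero. Large D_k correlates with labyrinthine rather than straight
  stripes.

The numeric dispersion relation (direct eigenvalue computation) is the
ground truth everywhere; the closed forms are tested against bisection
band edges and the numeric argmax, not the other way round.

## Simulators (the synthetic-data generators)

All lattice models use a square grid with unit spacing and periodic
boundaries (chosen to keep pattern spectra free of edge artifacts).
Simulators emit raw fields; `imaging.normalize_field` min-max scales to
[0, 1] (constant fields map to 0.5).

* **Turing**: explicit Euler, dx = 1, dt = 0.1, default 20,000 steps with
  early exit when the relative L2 change of u per 1,000 steps is below
  1e−5; initial condition is seeded uniform noise U(−0.01, 0.01) around
  the homogeneous state. A semi-implicit spectral (IMEX) integrator —
  diffusion exact per Fourier mode, reaction explicit — is provided for
  batch dataset generation; at dt = 0.25 its dominant wavenumber agrees
  with the explicit scheme and theory (checked in the acceptance suite).
* **Gray-Scott**: standard feed/kill kinetics, trivial state (u,v)=(1,0),
  central perturbed patch; one simulation yields snapshots at the
  geometric schedule t ∈ {500, 1000, 2000, 4000, 8000, 16000} steps so a
  single run contributes several morphologically distinct images.
* **Kernel-based Turing (KT)**: synchronous update u ← clip(u + dt·(K∗u))
  with a radially symmetric disk kernel, positive inside the activation
  radius and negative out to the inhibition radius.
* **Eden / DLA**: stochastic growth on the lattice from a central seed;
  Eden occupies one uniformly chosen perimeter site per event (occupied
  cells = events + 1 exactly); DLA walkers launch at cluster radius + 5,
  stick on first 4-neighbour contact, and are discarded beyond 3× the
  launch radius (textbook settings). Hitting the grid edge raises a
  truncation warning that dataset builders record.
* **Edwards-Wilkinson**: h ← h + dt·ν∇²h + noise, stability ν·dt ≤ 1/4.
* **L-system**: bracketed turtle rewriting (symbols F + − [ ]); the path
  is auto-scaled into the raster with a 4-pixel margin because extent
  grows unpredictably with iteration count.
* **Phase field**: Kobayashi-type anisotropic solidification (phase +
  temperature fields); dataset replicates vary only the initial-noise
  seed.
* **Cahn-Hilliard** (out-of-library probe): semi-implicit spectral
  integration; the k = 0 mode is untouched by the update, so the spatial
  mean is conserved to machine precision.

The reference composition of the selection library (228 Turing, 288 KT,
486 Gray-Scott, 99 Edwards-Wilkinson, 182 Eden, 300 DLA, 133 L-system,
83 phase field; total 1,799) is the default manifest; the per-model
parameter samplers are this package's own choices (recorded per row in
the manifest, so counts — not specific pixels — are the dataset
contract). Every row carries its rng seed and parameter record; images
regenerate byte-for-byte from the manifest.

## Feature extraction

The reference encoder is the frozen CLIP ViT-B/32 image tower used
zero-shot (512-d embeddings, grayscale replicated to three channels). It
is an optional adapter: when the `open_clip` stack is absent the package
raises an explicit "encoder unavailable" error. The default, fully
offline encoder (`spectral_fallback`) concatenates a 64-bin radially
averaged log power spectrum (computed on an FFT zero-padded to 128 so
the bins stay resolved for small rasters; rotation-invariant), a 16-bin
gradient-orientation energy histogram, a 32-bin intensity histogram and
8 radial-spectrum moments (peak wavenumber, power- and
log-power-weighted mean/spread, skewness, peak sharpness, total power —
the sub-bin statistics that carry the dominant spatial scale and band
width), projects to 512 dimensions with a fixed seeded Gaussian
projection, and L2-normalizes. The dense projection deliberately mirrors
the CLIP-like situation downstream models face: information spread
redundantly over many coordinates rather than axis-aligned. The fallback
is *not* a CLIP substitute semantically — it is a deterministic,
classical pattern descriptor that makes every pipeline stage testable
offline; conclusions that depend on CLIP's zero-shot semantics
(e.g. organism photographs) are out of its scope.

Images are blurred (Gaussian, σ = 1.5 px, reflective padding) before
embedding. The blur exists to suppress the binary-vs-smooth boundary
sharpness cue that would otherwise separate growth models from PDE
models; the strength is configurable.

## Model selection

Cosine similarity in the latent space ranks library rows for a target
image (ties broken by manifest order). For external targets of unknown
spatial scale, eleven center crops at ratios 0.50–1.00 in steps of 0.05
are each encoded; the crop whose best match scores highest is adopted.
Retrieval structure across models is summarized by MAP@k with k = 50
(mitigating class imbalance); a query that is itself a library row is
excluded from its own candidate list, and average precision is
normalized by the number of positives inside the top k (the alternative
normalization by k is available behind a flag).

## Dimensionality reduction

The 512→2 reducer is an MLP (512-256-128-128-64-64-32-32-16-2, ReLU,
batch normalization on hidden layers 1–2, dropout 0.2 on hidden layers
1, 2 and 4) trained with a triplet margin loss (margin 0.1, Euclidean
distance) under a modified contrastive scheme for regression labels: the
parameter box is split into a 10×10 grid and same-cell samples are
positives. Triplets are mined per batch (size 32) by multi-similarity
mining (ε = 0.2) in the current reduced space; any triplet whose
anchor-negative cosine similarity in the *input* latent space exceeds
its anchor-positive similarity is excluded — different parameters can
produce genuinely indistinguishable patterns and such triplets are
uninformative (ties are kept, since only a strictly more similar
negative indicates a look-alike). Optimization is Adam (lr 0.001, weight
decay 0.001), at most 100 epochs, early-stopped when validation MAP@R
(R = number of same-label samples) has not improved for 20 epochs; the
best checkpoint is returned. Because no deep-learning framework is a
dependency, the MLP (forward, backward, batch-norm and dropout
semantics, Adam) is implemented in numpy and verified against
finite-difference gradients in the test suite.

A seeded UMAP projection and an identity pass-through serve as the two
comparison arms of the generalization-error benchmark.

## SD-NPE

The probabilistic regressor is natural-gradient boosting with a
bivariate-normal head: θ = (μ₁, μ₂, log L₁₁, log L₂₂, L₂₁) parameterizes
the mean and Cholesky factor, each boosting stage fits one
depth-3 regression tree (Friedman-MSE criterion) per θ-component to the
Fisher-preconditioned gradient of the negative log-likelihood, followed
by a line search over the fitted direction and shrinkage by the learning
rate 0.087; 150 stages; initial θ is the marginal MLE of the labels.
Covariances are SPD by construction; externally supplied covariances are
repaired by eigenvalue flooring at 1e−10 with a logged warning.

The parameter lattice is 100×100 cells of size 0.005. Those spans
(0.5 per axis) exceed the 0.4 span of the parameter box; the lattice is
centered on the box, i.e. it covers [0.55, 1.05]², so that posteriors
near the box edge are not clipped. Posterior integration works entirely
in the log domain with densities floored at 1e−300 (the (N−1)-fold prior
division underflows otherwise), then renormalizes so that
Σ density · cell_area = 1. The generalization error (negative mean log
posterior density at the true parameters) interpolates the density
bilinearly between cell centers to avoid cell-boundary artifacts.

### Linear-regression validation

The supplementary validation compares the full SD-NPE pipeline against
exact conjugate Bayesian linear regression. The package's design (the
original specifics are not printed): covariates x ~ U(−1, 1),
observation noise σ = 0.1, weight prior N(0, 0.5²I); the **simple**
condition observes y = a·x + b + ε (both weights identifiable), the
**redundant** condition observes y = (a+b)·x + ε (only the sum is
identifiable, producing a ridge posterior). Each observation (x, y) is
one sample fed to the regressor; the analytic posterior is discretized
on a 100×100 lattice over [−1.25, 1.25]² and compared by KL divergence
of cell masses, KL(analytic ‖ SD-NPE).

## Scaled study conditions of the benchmark

The estimation benchmark (`patternfit.bench`) runs the full pipeline at
reduced size: 2,000 Turing images (1,800 train / 200 validation for
reducer early stopping, labels uniform on the box), simulated on a 48²
grid with the IMEX integrator (dt = 0.25, horizon t = 300, by which the
dominant wavenumber matches theory within a few percent), encoded with
the offline spectral encoder; 40 synthetic truths with 20 snapshot
images each. The full-scale protocol uses 9,700 training images at 128² with
the CLIP encoder; the reduced sizes keep the whole suite tractable on a
single CPU and are the package's own scaled protocol.

What passing these benchmarks shows: the pipeline's arithmetic (mining,
training, prior approximation, posterior integration) is correct and the
method's qualitative behavior (parameter information recoverable from
snapshots; reduction helping the regressor) reproduces at reduced scale.
What it does not show: performance on real organism photographs, CLIP
zero-shot semantics, or full-scale absolute error values.

## Known limitations

* The mean-field product powers the per-sample conditional N times; any
  systematic error of the fitted conditional (bias of the predicted mean,
  under-dispersion of the predicted covariance) is amplified ×N rather
  than averaged away, because all N snapshots share the same truth. With
  few training samples and a nearly deterministic encoder the integrated
  posterior is therefore overconfident; this is a property of the method
  itself (most visible when parameters are redundant and the conditional
  is ridge-shaped) and the main reason HPD coverage at the scaled study
  conditions falls short of nominal.
* The Gaussian output family cannot represent curved or multimodal
  conditionals; a normalizing-flow head is the natural upgrade.
* The offline encoder is texture-statistical; it cannot stand in for
  CLIP on natural images.
* NGBoost-style training scales cubically with the number of predicted
  parameters; two parameters are the tested path.
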