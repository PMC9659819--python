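# Methods

## The problem

Unstained cells are nearly transparent: they barely change the intensity of
light passing through them, but they delay it, imprinting a phase shift
proportional to their optical thickness. A conventional microscope records
only intensity, so the phase — which carries the cell's shape, edges and
internal structure — is lost. Digital holography recovers it numerically:
given the measured field amplitude on two planes (the object plane and an
imaging/Fourier plane), an iterative algorithm reconstructs the phase that
connects them. The package implements the Gerchberg–Saxton (GS) family of
such algorithms and a comparison harness for four variants of increasing
constraint, the fourth being an initial-phase-optimised ("improved") variant.
The motivating application is flagging abnormal red blood cells — rendered
conspicuous by their strong phase dome and membrane bleb — inside the
cluttered background of a urine-sediment image.

## Wave propagation model

A monochromatic scalar field `U(x, y, 0)` sampled at pitch `Δ` is propagated
a signed distance `z` with the angular-spectrum transfer function obtained by
inserting the plane-wave decomposition into the Helmholtz equation:

    H(f_x, f_y) = exp( j 2π (z/λ) √(1 − (λ f_x)² − (λ f_y)²) )
    U(·, z) = IFFT{ H · FFT{U(·, 0)} }

Numerical choices:

* **Evanescent cutoff.** Where `(λf_x)² + (λf_y)² > 1` the square root turns
  imaginary; those components decay exponentially and, for `z < 0`, would
  grow without bound. The kernel is set to exactly 0 there. On the remaining
  (propagating) support the kernel has unit modulus, so propagation is
  unitary and back-propagation is its exact inverse.
* **Transform convention.** All FFTs are unitary (`norm="ortho"`), so
  Parseval's identity — and therefore energy conservation — holds without
  scale bookkeeping. Frequencies use the `numpy.fft.fftfreq` layout, which
  matches `fft2` bit-exactly.
* **Default optics for demos** (all operations take them explicitly):
  λ = 632.8 nm (He–Ne), pitch 4.65 µm (a common CCD), z = 20 mm. No result
  in the package depends on these defaults.

Validation uses two independent oracles on a 16×16 grid with a contained,
band-limited Gaussian input: (i) a brute-force Riemann sum of the Fresnel
diffraction integral, evaluated at the critical distance `z = NΔ²/λ` where
the convolution kernel is adequately sampled (agreement ≈ 1e-5 relative);
(ii) the closed-form paraxial Gaussian-beam law `u ∝ (q₀/q) e^{ikz}
e^{ikr²/2q}`, `q(z) = z − i z_R` (agreement < 0.5%).

## The GS iteration and the four models

With `A = |f|` the known input-plane amplitude and `T = |g|` the known
imaging-plane amplitude, one iteration is the classic pair of amplitude
projections

    g_k = FFT{f_k};  g'_k = T·e^{j·arg g_k};  f'_k = IFFT{g'_k};
    f_{k+1} = A·e^{j·arg f'_k}

Amplitude replacement at a zero-modulus pixel uses phase 0 (any phase is
admissible; 0 is reproducible). Because each half-step is a projection onto
an amplitude constraint set, the imaging-plane mismatch `‖|g_k| − T‖` is
non-increasing — the property the convergence tests assert with 1e-12
absolute slack on its RMS form.

The model variants:

| model | initial phase | input amplitude | output |
|---|---|---|---|
| 1 | uniform on [−π, π) | as given | imaging-plane amplitude (the reconstruction of interest) |
| 2 | uniform on [−π, π) | as given | phase, raw radians |
| 3 | restricted to [−π, π] | grey levels scaled into [0, 1] | phase mapped [−π, π] → [0, 1] |
| 4 | min–max normalised, × β | as model 3 | as model 3 |

Model 1 shares Model 2's iteration; it differs only in which plane's
reconstruction is reported. Model 3's mapping is applied at initialisation
and output only, never inside the loop. The grey-level scaling for Models
3–4 divides 8-bit-style data into [0, 1] and leaves data already on [0, 1]
untouched — it is not a min–max stretch, which would distort a measured
amplitude and make it inconsistent with the recorded hologram. β defaults to
π, so the optimised start spans half the principal range; a small,
non-negative start matters because a weak phase object's true phase is
mostly near zero, and GS is a local method: starting in the right basin
avoids the speckled stagnation that a fully random start frequently
produces.

**Randomness.** The only stochastic element is the initial phase, drawn
i.i.d. uniform on [−π, π) from NumPy's PCG64; a `GSConfig` (model,
iterations, β, seed, stopping threshold) determines the entire run
bit-for-bit.

**Early stopping.** Optionally (off by default), the run stops once the
modulus of the normalised complex correlation between the field entering a
Fourier round trip (`f_k`) and the field leaving it (`f'_k`) reaches a
threshold. This correlation tends to 1 as the iteration converges, so it is
a usable stopping rule; correlation against the *initial* random field would
not converge to 1, which is why the reference is the current iterate. The
correlation is invariant to global complex scaling, and its self-correlation
is exactly 1.0 in floating point (ratio-of-energies form).

**Trace.** Per iteration the run records (a) the RMSE of that iteration's
phase against the *final* iteration's phase — the self-referential
convergence indicator, whose last entry is exactly 0 and whose base-10 log
uses a −inf sentinel at 0; (b) the round-trip correlation; (c) the
imaging-plane amplitude RMSE. Computing (a) needs the final phase first, so
the deterministic iteration is replayed once instead of holding every
snapshot in memory. Phase differences are taken in the run's own output
convention (mapped [0, 1] or raw radians), recorded in the trace.

## Preprocessing

RGB images are reduced with ITU-R BT.601 luma weights (0.299/0.587/0.114),
resampled to the square target (default 256×256) by local-mean (area)
averaging — chosen over interpolating kernels because it cannot overshoot
the input range or alias high-frequency clutter — and min–max normalised to
[0, 1]. A centred crop is available but off by default. The pipeline is
idempotent. Constant images are degenerate for min–max normalisation;
the convention (here and for phase normalisation) is an all-zeros result
plus a `DegenerateInputWarning`.

## The synthetic phantom

The generator emulates a urine-sediment micrograph as a field of phase
objects on a 256×256 canvas: three large faint epithelial cells (raised-
cosine phase dome, peak 0.3 rad, yellow tint), one red blood cell (dome peak
1.5 rad — a typical erythrocyte optical thickness at visible wavelengths —
red tint, radius ≈ 4.5% of the canvas) carrying a membrane bleb (an
overlapping disk at 45% of the cell radius, dome peak 80% of the cell's),
and dark amplitude-only speckle covering ≈ 1% of the background. Objects are
placed by rejection sampling without overlap (red cells first, so the
detection target always finds room; a `PlacementError` is raised when a
configuration cannot fit). Scenes are bit-identical per seed and ship with
disjoint boolean masks per object class; the ground-truth phase is zero
outside the masks and attains its maximum, exactly
`phase_amplitude_rbc`, at the red cell's centre pixel.

What the phantom does **not** emulate: detector noise, partial coherence,
off-axis reference fringes, stain variability, realistic cell morphology.
Passing tests therefore demonstrate the algorithmic properties of the
retrieval (convergence, determinism, the benefit of the optimised start, RBC
localisation against clutter), not performance on real micrographs.

## The phantom retrieval experiment

`simulate_hologram` builds the true object field `A·e^{jφ_true}` and records
`T = |FFT{·}|` — an ideal, noise-free imaging-plane measurement. The
amplitude pair is exactly consistent, so the true phase is a fixed point of
the iteration and recovery error measures algorithmic stagnation, not data
noise. Scoring:

* **Gauge fixing.** A two-amplitude retrieval determines the phase only up
  to a global offset (`f·e^{jθ₀}` satisfies the same constraints), so any
  ground-truth score computed on the raw estimate measures that arbitrary
  offset, not the reconstruction: Model 4's confined start lands at a
  consistent offset near β/2 while Model 2's is uniform over the circle,
  which would turn the comparison into a statistic about offsets. Both
  scores below therefore first reference the estimate to the circular mean
  of its background phase — exactly how a quantitative phase image is read
  against the surrounding medium, and the standard gauge alignment in
  phase-retrieval benchmarking.
* **RMSE to truth** is then computed on the unit [0, 1] scale for every
  model (raw-radian estimates are wrapped and mapped first), so mapped and
  unmapped models are compared on one scale rather than letting the [0, 1]
  models win by a factor of 2π of scale alone. The plain, un-referenced
  comparison remains available as `metrics.phase_rmse_to_truth`.
* **Peak localisation** takes the peak of the background-referenced
  `|phase|` after a 3×3 local mean, so a single wrap-boundary speckle pixel
  (|phase| ≈ π at a point) cannot pose as the energy peak. The
  `phase_energy_map` / `phase_energy_peak` operations themselves stay
  literal (height = `|phase|`, peak = arg-max) for plotting and API use.

At the study conditions (bundled 256×256 phantom, 200 iterations, seeds
0–10) the β-optimised Model 4 beats plain-GS Model 2 on median truth RMSE
(≈ 0.0144 vs ≈ 0.0152 on the unit scale) and localises the red cell in
every seed; Model 3 — whose distinctive steps reduce to no-ops on
unit-range input, making its trajectory identical to Model 2's — localises
it in the large majority of seeds, occasionally stagnating on a clutter
speckle near the cell. The median gap is modest: on noise-free, exactly
consistent phantom data plain GS also converges well by 200 iterations, so
the ordering holds for most but not every batch of 11 retrieval seeds (the
advantage of the optimised start is larger at low iteration counts and its
runs are far more repeatable). These numbers are recomputed, never stored,
by the test suite and `scripts/acceptance.py`.

## Problem sizes

Convergence and determinism tests run on 32–64 px phantoms at up to 200
iterations; the model-comparison study runs the full 256×256 phantom at 200
iterations over 11 seeds per model; the propagation oracles use a 16×16
grid, where the brute-force O(N⁴) Fresnel sum is exact enough and cheap.
These sizes are the package's chosen defaults for its bundled study; every
routine accepts larger grids and iteration counts (the CLI grid reproduces
the 20/200/2000-iteration sweep).

## Known limitations

* Plain GS (Models 1–3) stagnates from unlucky random starts; the package
  reports this honestly rather than restarting. No hybrid input–output or
  relaxation schemes are included.
* The correlation stopping rule watches round-trip self-consistency; it can
  fire at a stagnation point as well as at the true solution.
* Phases are compared without unwrapping; objects thicker than π radians
  would alias in both the phantom and the scoring.
* The angular-spectrum hard cutoff discards genuinely evanescent content;
  fields sampled below λ/2 pitch lose those components on the first hop.
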