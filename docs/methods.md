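# Methods

This note documents the models, numerical choices and limitations of the
`myodyn` pipeline: what each stage assumes, which parameters matter, what
the synthetic generators do and do not emulate, and where the design was
genuinely open.

## Strain from phase-contrast velocities

The dynamic input is a cine of three-directional voxel velocities over one
stimulation cycle (period T = contraction + release, default
750 + 750 = 1500 ms), already decoded from phase to cm/s (Venc, default
15 cm/s, maps a phase of π to the encoded velocity; inputs may be raw
phase volumes, auto-detected by value range and decoded as
v = phase/π · Venc).

**Temporal integration.** Displacement is accumulated with the trapezoidal
rule forward from u(0) = 0 and backward from u(T) = 0, treating the cycle
as periodic (v(T) := v(0)), and the two estimates are blended linearly in
time. The linear blend has two exact algebraic properties: the endpoints
are pinned (u(0) = u(T) = 0, enforcing the physiological periodicity of an
evoked twitch), and any spatially/temporally constant velocity offset —
the signature of eddy-current phase errors — integrates to exactly zero
displacement, because (1 − t/T)·ct + (t/T)·c(t − T) ≡ 0. The trapezoidal
(centered) quadrature is chosen over a one-sided Riemann sum because it is
the adjoint-consistent partner of the central-difference derivative: the
pair gives an O(Δt²) round trip (measured ≈1.3% of peak displacement at
32 frames on the reference phantom, shrinking with frame count), whereas a
one-sided sum carries an O(Δt) half-sample lag of ~10% at 32 frames.

Assumption: displacements stay small enough (a few mm here) that gradients
may be taken on the fixed reference grid (Lagrangian small-displacement
approximation) without tracking voxels through the motion.

**Spatial differentiation.** The displacement gradient ∇u is computed with
a separable 3-D Savitzky–Golay derivative filter: the SG first-derivative
kernel along the derivative axis and the SG smoothing kernel along the two
orthogonal axes (shared window of 5 voxels and polynomial order 2 by
default). SG kernels reproduce polynomials up to the fit order exactly, so
affine and quadratic displacement fields are differentiated exactly at
interior voxels; the local least-squares averaging is what makes the
derivative robust to velocity noise. Mirror padding handles volume edges,
and a ⌈window/2⌉ boundary band is excluded from ROI statistics because
derivative kernels are biased there.

**Strain tensor and principal strains.** The default convention is the
finite-strain Green–Lagrange tensor E = ½(∇u + ∇uᵀ + ∇uᵀ∇u), exactly zero
for rigid rotations — a property the infinitesimal tensor lacks (a 10°
rotation already produces a spurious ε of ~1.5×10⁻²). The infinitesimal
convention is retained as an option because at the strain magnitudes seen
here (0.1–0.35) the two differ by only a few percent and some prior
analyses use the small-strain form. Eigenvalues are obtained per voxel
with a symmetric eigensolver and sorted descending; the biomarker map is
the *first positive eigenvalue* max(λ₁, 0), the maximal local lengthening.
Voxels where λ₁ ≤ 0 are clamped to zero but flagged, since "largest
positive eigenvalue" is undefined when the voxel only shortens; non-finite
tensors invalidate the voxel.

**ROI averaging.** The λ₁ map is averaged over each labelled muscle
restricted to the axial span between the two stimulation-electrode
centers — the segment of muscle the stimulation actually recruits — with
invalid and edge-band voxels excluded and the voxel count reported per
frame.

## Contraction dynamics

The ROI curve is split at its maximum (ties to the earlier frame;
a maximum at either end flags the corresponding phase as degenerate) and
each phase is fitted with a four-parameter logistic
s(t) = b + A/(1 + exp(∓k(t − t₀))) by bounded least squares (A ≥ 0,
k ∈ (0, 1] ms⁻¹, t₀ within the fitted window ± 25%). Initialization uses
b = min, A = range, t₀ = half-maximum crossing and k = 4·max|Δs/Δt|/A (the
logistic's maximum slope is Ak/4), plus four seeded jittered restarts —
short noisy segments have local minima. A fit "converges" when the
optimizer succeeds and the residual RMS is below 20% of the fitted
amplitude; anything else leaves the metrics missing rather than silently
wrong.

The steepness k is the only fitted parameter with pure time⁻¹ units and is
reported both per second and per frame (they differ by the frame
interval). Published rate magnitudes in this field are not always explicit
about their time base — values of a few 10⁻² for a 750 ms ramp are
plausible per frame but not per second — so both scales are carried
through and neither is treated as an exact external reference. "Strain" is
reported as the fitted plateau b + A of the buildup fit, with the raw
curve maximum alongside, because which of the two a given study tabulates
is usually unstated.

## EPG relaxometry

The 17-echo multi-echo spin-echo protocol (TE 10.9–185.3 ms, TR 4100 ms)
is simulated with the extended phase graph recursion over configuration
states (F±k, Zk): relaxation over each half echo spacing, one
configuration-order shift per half spacing, refocusing rotation, echo read
from F₀. T1 is fixed per compartment (water 1400 ms, fat 365 ms); the TR
saturation factor (1 − e^(−TR/T1)) scales each compartment. With ideal
180° refocusing the recursion collapses to exp(−TE/T2) (machine-precision
identity, used as a test anchor); reduced flip angles generate stimulated
echoes that slow the apparent decay, which is why a plain exponential fit
is biased and dictionary matching against the EPG model is used instead.

**Slice profile.** Excitation and refocusing pulses are modelled as
Hann-windowed sincs with a time–bandwidth product of 2; the small-tip
Fourier profile is sampled at 51 equidistant positions across the
half-slice, giving per-bin flip-angle scales (monotone from center, ~0.62
at the nominal edge) with uniform weights. A tbw of 2 keeps a single main
lobe — a smooth, monotone profile — which is the simplest defensible shape
when the true pulse is unknown; echoes are the magnitude of the weighted
complex sum over bins.

**Dictionary.** Signals are simulated on a grid of wT2 ∈ [10, 80] ms step
0.2 ms × ff ∈ [0, 1] step 0.005 (70,551 entries), each unit-normalized:
matching maximizes the normalized inner product, making the estimate
exactly invariant to the unknown proton density. Rows are ordered by
(wT2, ff) so exact ties resolve deterministically toward lower values. The
grid is finer than the ~1 ms / ~1% group differences the biomarkers are
expected to resolve. Fat T2 is calibrated per subject by a 1-D grid search
(100–250 ms, 1 ms) of the pure-fat model against the mean normalized
subcutaneous-fat signal (≥10 voxels required; configuration default
155 ms otherwise). Because subcutis is ~90% fat rather than pure fat, the
calibration sits slightly below the true fat T2; the bias is stable across
subjects and absorbed by the dictionary.

On magnitude data the Rician noise floor inflates the weakest late echoes;
the matcher reads that flattening as extra fat and, because ff and wT2
trade off strongly along the likelihood ridge (empirical correlation
≈ −0.84), biases wT2 low by ~1 ms at SNR 50. `match_dictionary` therefore
accepts an optional noise level and applies the second-moment correction
√max(m² − 2σ², 0) before matching, which removes the bias (E[m²] = A² +
2σ² for Rician magnitudes); the default remains the uncorrected inner
product. Note the intrinsic precision limit: with proton density, ff and
wT2 all free, the Cramér–Rao bound at SNR 50 (first-echo referenced)
already implies a per-voxel wT2 spread of ~2 ms, so accuracy claims at
this SNR are about bias, not per-voxel scatter.

## Dixon fat–water separation

The 6-echo gradient-echo stack (TE 1.7–9.2 ms, 3 T) is fitted per voxel
with S(TE) = (W + F·c(TE))·e^(i2πψTE), where c(TE) is the 6-peak fat
spectral phasor (shifts −3.80 … +0.60 ppm relative to water; amplitudes
from the standard in-vivo calibration, shipped as editable YAML package
data). The fit uses variable projection: for each candidate fieldmap ψ the
complex (W, F) are the closed-form linear solution, and ψ is selected on a
grid (±300 Hz, 2 Hz) then refined continuously. Water–fat swaps are the
failure mode of fieldmap estimation, so ψ is regularized by region
growing: voxels are visited in descending signal magnitude from the
strongest seed, and each picks the residual local minimum closest to the
mean ψ of its visited neighbours. ff = |F|/(|W| + |F|), clipped to [0, 1].
Magnitude-only input falls back to a magnitude fit with a warning — near
ff = 0.5 the water and fat roles are then inherently ambiguous. This
estimator is a generic multi-peak least-squares implementation; its
validation surface is synthetic recovery (noise-free bias < 10⁻² in ff,
< 1 Hz in ψ), not equivalence with any specific published reconstruction.
No R2* term is included, consistent with the short echo range.

## Cohort statistics

Distributions of muscle biomarkers are skewed, so groups are summarized as
median and IQR (linear-interpolation quartiles, the default convention of
the usual statistical environments; configurable). Group discrimination
uses standardized logistic regression — group (patient = 1) on the
variable z-scored over all subjects pooled (n−1 SD) — so exp(slope) is the
odds ratio per SD and is invariant to affine rescaling of the variable.
The 95% CI is the profile-likelihood interval (deviance threshold
χ²₀.₉₅,₁ = 3.84, intercept profiled out by Newton iteration, endpoints by
bracketed root finding): at small n with quasi-separation the profile can
stay below the threshold out to arbitrarily large slopes, in which case
that endpoint is undefined and reported as missing — the behaviour that
produces "NA" upper bounds in small-cohort tables. A Wald fallback exists
but is always flagged. Complete separation is detected directly from the
data ordering and flagged; the slope is capped for reporting. Empirical
null coverage of the profile CI at n = 24 is ~93–95% over 500 replicates.
Missing values are handled complete-case per variable with counts
reported. Spearman correlations (average ranks on ties) relate the dynamic
variables to FF and wT2, pooled over all subjects and muscles; per-muscle
stratification is a caller choice.

## Synthetic generators

The phantom is a nested-cylinder calf — leg outline, subcutaneous fat rim,
and three muscle compartments (soleus posterior, medial/lateral
gastrocnemius anterior) — with electrode centers at 25%/75% of the
superior–inferior extent. The deformation is affine per muscle,
u(x, t) = g(t)·A·(x − c), with symmetric amplitude tensor A and a temporal
envelope g built as the product of a rising and a falling logistic
(default steepness 15 s⁻¹ each, transitions centered in the contraction
and release phases), ramp-corrected to make g(0) = g(T) = 0 exact and
rescaled to peak at 1. Because g belongs to the same family the dynamics
stage fits, rate recovery is exact in the noise-free case — by
construction a *self-consistency* check, not evidence about curves of a
different shape. Displacement is tapered to zero over a 3-voxel cosine rim
inside each muscle so the field is continuous; the closed-form strain
E(t) = ½((I + gA)ᵀ(I + gA) − I) holds only on the untapered interior,
which is where ground-truth assertions are made. Default conditions
emulate the acquisition being modelled: 750 + 750 ms cycle, Venc 15 cm/s,
peak principal strains in 0.1–0.35, muscle wT2 ≈ 35 ms, FF 3–5% with a
few patients carrying focal FF > 10%, Gaussian noise on velocity
components and Rician noise on echo magnitudes (the standard models for
phase-derived and magnitude MR data).

Subject tables draw each variable from a log-normal parameterized by
target median and IQR per muscle and group, defaulting to the observed
cohort summaries of the emulated study (14 HC / 10 patients); the
`effects` argument replaces the patient/HC contrast with a relative median
shift (all-zero ⇒ exact null). MVF is constant within subject; a seeded
subset of patients receives one muscle with FF drawn from 10.5–25%.

What the generators do *not* emulate: focal activation heterogeneity
within a muscle (the deformation is spatially uniform per muscle plus
taper), through-plane fascicle architecture, partial-volume mixtures at
muscle boundaries, eddy-current fields beyond a constant offset, phase
wrapping (only flagged), B1 transmit inhomogeneity beyond the slice
profile, k-space sampling/compressed-sensing artifacts, and physiological
inter-cycle variability. Passing tests therefore demonstrate correctness
of the numerics and estimators under the stated noise models, not
robustness to every artifact of in-vivo data.

## Problem sizes and determinism

Default validation sizes were chosen so the full suite runs comfortably on
a laptop-class single core: phantom grids of 32×32×48 voxels (2.3×2.3×2.5
mm), 16–64 frames per cycle, 200-replicate Monte Carlo recovery runs, a
70k-entry dictionary with 10⁴-voxel matching, and 500-replicate coverage
simulations. All stochastic paths take explicit integer seeds and are
bit-reproducible; library threading does not affect results.

## Known limitations

- Strain is computed on the reference grid without tissue tracking; at
  displacements beyond a few voxels a registration-based Lagrangian
  approach would be needed.
- Whole-muscle ROI means mix the taper/boundary region with the interior,
  biasing the peak strain low relative to the interior truth (by ~20% on
  the default phantom); electrode-span restriction mitigates but does not
  remove this.
- The sigmoid rate is identifiable only when the transition is resolved by
  several frames; at 16 frames per cycle the Monte Carlo spread of k
  roughly doubles.
- Dictionary matching reports grid values; sub-grid interpolation is
  deliberately avoided to keep the estimator's tie-breaking exact and
  deterministic.
- The Dixon magnitude-only fallback cannot distinguish water-dominant from
  fat-dominant voxels near ff = 0.5.
- Profile-likelihood CIs assume the logistic model; with n ≈ 24 the
  undefined-endpoint behaviour under quasi-separation is expected and
  reported, not an error.
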