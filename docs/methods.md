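# Methods

This note documents the models implemented in `fatqsm`, the defaults and
their rationale, what the synthetic phantom does and does not emulate, and
the numerical choices that affect results.

## Signal model and units

The voxel signal of a water/fat mixture in a multi-echo gradient-echo
acquisition is

    S(t) = (ρ_W + ρ_F Σ_p α_p e^{i 2π f_p t}) e^{i(φ0 + 2π f_B t)} e^{−R2* t},

with relative lipid amplitudes normalized to Σ α_p = 1 and peak offsets
f_p = δ_p · f0 · 10⁻⁶ (δ_p in ppm relative to water, negative for the
aliphatic peaks). The default lipid spectrum is the standard six-peak
liver/oil triglyceride model (dominant methylene at −3.40 ppm); every stage
accepts an arbitrary spectrum, and the test suite deliberately uses small
synthetic spectra so no result depends on the default's exact numbers.

Field maps are carried internally in **ppb of B0**; Hz is a view through
the scanner frequency (f0 = 123.195 MHz, so 100 ppb ↔ 12.3195 Hz). This
keeps the dipole inversion unitless (field and χ share ppb) and avoids
repeated γ/2π conversions.

The dipole kernel is the Lorentz-corrected k-space form
D(k) = 1/3 − (k·b̂0)²/|k|², with D(0) := 0: the k = 0 coefficient of the
field is physically undetermined, and the absolute zero point is fixed at
the end by referencing to the background agar, as a scanner study would.
Forward fields are computed on a grid zero-padded ×2 to suppress periodic
wrap-around, and the output is demeaned (again: the mean belongs to the
referencing step). Against the closed-form field of a uniformly magnetized
sphere the forward model is accurate to ~1% relative RMSE outside a
one-voxel shell, with interior mean < 2 ppb at Δχ = 1000 ppb on a 128³
grid.

## The digital phantom

The generator reproduces the layout and composition of a spherical agar
phantom: a 14 cm outer sphere (background, χ ≡ 0 by convention) holding
nine 3 cm inclusions — fat only at 4/10/20 vol%, agent only
(Fe₃O₄ 0.13/0.19/0.26 mM or MnCl₂ 2.5/3.5/4.5 mM), and agent + 20% fat.
Inclusion centers default to a 3×3 mid-plane grid at 31 mm spacing, which
keeps ≥ 10 mm clearance to the outer boundary (at the nominal 35 mm spacing
the corner inclusions would come within ~6 mm of the boundary).

Ground-truth assignment:

* χ = 1088 ppb/mM · C_Fe + 4.83 ppb/% · PDFF (relative to agar; the
  intercept of the χ-vs-PDFF line cancels when referencing to fat-free
  agar). The manganese slope (180 ppb/mM) is a literature-based molar
  susceptibility, and the manganese variant's relaxation lookup contains
  plausibility values, not measurements — the manganese phantom is a
  synthetic stand-in and no quantitative claim rests on it.
* R1/R2/R2* come from a per-inclusion lookup of measured VOI means rather
  than a microstructure model. This is deliberate: recovery tests then
  compare estimates against exactly what was simulated, with no modelling
  slack in between.
* PDFF ground truth is the nominal volume fraction.

Echo series are generated voxel-wise from the signal model with f_B taken
from the forward dipole field of the ground-truth χ (plus an optional shim
field), φ0 = 0 by default (a smooth φ0 can be injected), and complex white
Gaussian noise with per-channel σ = (mean background magnitude at TE1)/SNR;
the default SNR is 100. Inversion-recovery series use the ideal
two-compartment form |1 − 2e^{−TI·R1}| (TR = 10 s ≫ T1 justifies dropping
saturation terms), spin-echo series e^{−TE·R2}.

What the twin does **not** emulate: coil sensitivities and combination,
k-space acquisition/reconstruction effects (partial volume arises only from
rasterization), air inclusions (optional), motion, gradient
nonlinearities, stimulated echoes in the SE train, and any
microstructure-driven relationship between composition and relaxation.
Passing recovery tests therefore validate the *processing chain* under the
stated noise model, not robustness to real-scanner artifacts.

Default problem sizes: 96³ at 2 mm for the end-to-end study and water-fat
experiments, 64³ at 3 mm for multi-orientation experiments, chosen so each
inclusion spans ≥ 10 voxels across while a complete seeded study remains a
few minutes of desk-scale compute.

## Water–fat separation (fat-corrected field mapping)

For fixed (f_B, R2*) the signal model is linear in the complex amplitudes
(ρ_W, ρ_F), so they are projected out (VARPRO). The per-voxel residual
profile over a discrete f_B grid (default ±250 Hz, 1 Hz step; R2*
inner-minimized over a 0–400 s⁻¹ coarse grid) is computed in closed form
through the echo cross-product identity
s^H P(f_B) s = Σ_jk P0_jk conj(s_j) s_k e^{i2πf_B(t_j−t_k)}, which turns
the full scan into one matrix product per R2* candidate.

The field map is then chosen by minimizing Σ residual + μ Σ |f_B − f_B,nb|
over the 6-neighborhood with iterated conditional modes (ICM, checkerboard
sweeps) — a deterministic substitute for graph-cut jump moves on the same
objective. Two implementation details matter:

* ICM arbitrates only between each voxel's **residual local minima** (the
  true solution, the water-fat swap roughly one fat-peak frequency away,
  and aliasing replicas). This is ~100× faster than sweeping all labels
  and prevents the L1 penalty from dragging labels off the data optimum at
  genuine field edges. The L1 penalty itself is median-seeking, so linear
  field ramps pass through unchanged.
* μ defaults to 0.1 × (median per-voxel residual span) / (grid
  half-width), i.e. a full-grid-width disagreement with a neighbor costs a
  tenth of a typical voxel's residual span. This is strong enough to
  remove isolated swaps (which sit ~420 Hz away) and weak enough not to
  distort real gradients.

After label selection, f_B is refined off-grid by parabolic interpolation
of the residual profile, R2* on a 10 s⁻¹ grid plus parabolic vertex, and
the complex amplitudes are refit per voxel. Parabolic refinement was chosen
over a per-voxel bounded NLLS polish: it is deterministic, vectorizes over
the volume, and on noiseless phantoms leaves < 0.02 Hz field error —
self-consistency of the refit parameters with the input data is limited to
~10⁻⁴ relative by the interpolation, which is far below the noise floor of
any simulated experiment here.

PDFF from the joint complex fit uses the phase-aligned ratio
Re(ρ_F conj(ρ_W+ρ_F))/|ρ_W+ρ_F|², clipped to [0, 100]%. Water and fat
share the voxel phase, so this projection is unbiased in fat-free voxels,
whereas |ρ_F|/(|ρ_W|+|ρ_F|) carries a Rayleigh noise floor that biases
fat-free, high-R2* voxels up by > 1 percentage point at SNR 100. The plain
magnitude formula remains in `compute_pdff_pct` for magnitude-only input.

## Relaxometry

* **R1**: |a(1 − b e^{−TI·R1})| with the inversion efficiency b free,
  polarity restored by trying every sign-flip split point and keeping the
  lowest residual. Three parameters, because magnitude IR data cannot
  distinguish a perfect from an imperfect inversion without paying a bias.
* **R2**: ordinary least squares on the log signal; non-positive samples
  dropped with a warning; negative decay estimates clipped to 0 and
  flagged.
* **R2*/PDFF from magnitude only**: nonlinear least squares of the analytic
  modulus |ρ_W + ρ_F Σα_p e^{i2πf_p t}| e^{−R2*t} (φ0 and f_B drop out of
  the magnitude); multi-start over PDFF ∈ {5, 50, 95}% resolves the
  magnitude-domain water/fat ambiguity, ties go to the lower PDFF
  (water-dominant prior, appropriate below ~22% fat).
* **Spectrum T2 correction**: per-peak log-linear fit of the STEAM TE
  series, extrapolation to TE = 0, renormalization.

## QSM chain

**Unwrapping** is least-squares (Poisson) unwrapping: the divergence of the
wrapped phase gradients is inverted with a DCT (Neumann boundaries), the
undetermined constant is aligned by the circular mean, and a congruence
step restores output ≡ input (mod 2π). Per-echo 2π offsets are anchored so
the median phase inside the mask falls in (−π, π].

**Echo combination** (fat-uncorrected path) fits a weighted line of phase
vs 2π·TE per voxel with an intercept for φ0. Weights default to ∝ TE.
This choice is load-bearing: with TE·magnitude² weights, fast-decaying
iron+fat voxels weight the early echoes where the residual fat-phase
oscillation aliases into a *positive* frequency bias, which would make the
uncorrected susceptibility look spuriously high; TE weights reproduce the
physically expected direction (fat biases the apparent frequency, and hence
the uncorrected χ, low — fat correction raises χ).

**Background removal** is V-SHARP: each voxel is high-pass filtered with
the largest spherical-mean-value kernel fully inside the mask (radii 1–10
voxel units, interpreted on the acquisition-resolution convention of ≤
~8 mm kernels), the combined map is deconvolved with the (δ − SMV)
operator of the largest radius, and the mask is eroded by the smallest
radius. The deconvolution is regularized at the 0.02 mm⁻¹ high-pass
cutoff by **capping the inverse-filter gain** at its value at the cutoff
rather than zeroing everything below it: hard truncation at 0.02 mm⁻¹
removes roughly a third of a 3 cm inclusion's VOI-mean susceptibility
(5 cm wavelength content is genuine signal for these objects), while the
gain cap bounds noise amplification identically and leaves harmonic
(external-source) fields suppressed to < 1% RMS. SMV kernels are built in
image space with a linear anti-aliased edge and exact DC normalization.

**Single-orientation inversion** is thresholded k-space division (TKD),
χ(k) = B(k)/D(k) where |D| ≥ δ and sign(D)·B(k)/δ otherwise, δ = 0.2.
TKD is deterministic and parameter-light; its known cone-clamping
underestimation is ~20% for a uniform sphere at this δ and is asserted as
such in the tests rather than hidden.

**Multi-orientation inversion** comes in two variants. The per-k least
squares χ(k) = ΣD_iB_i/ΣD_i² (zeroed where ΣD_i² < 0.01) is exact on
fully observed, periodically consistent fields for the five-orientation
scheme (neutral plus ±60° tilts in the y-z and x-z planes — these kernels
share no zeros, unlike three exactly orthogonal orientations, whose cones
all contain the grid's body-diagonal rays). On real (mask-limited) data,
however, sources near the object boundary lose their external dipole lobes
and the division biases them low (~5% on the phantom's corner inclusions).
The masked variant solves min Σ‖M(d_i ⊗ χ − b_i)‖² with χ supported on
the mask, by conjugate gradients on zero-padded convolutions; it evaluates
the misfit only where field data exist and recovers boundary-near sources
essentially exactly. The per-k form is the pipeline default (it mirrors
the conventional chain); the masked form is the estimator of choice when
inclusion-level accuracy matters.

Multi-orientation inputs are simulated in a fixed object frame with a
rotated B0 direction, which is equivalent to physically tilting the object
and removes any need for image registration.

**Referencing** subtracts the mean over the background-agar label, making
all maps relative to agar; it is idempotent and absorbs every undetermined
k = 0 / mean ambiguity accumulated upstream.

## Calibration analysis

The calibration model carries the χ-vs-iron lines (slope 1088 ppb/mM,
intercept 9.15 ppb fat-free; slope 1082 ppb/mM, intercept 86.08 ppb with
20% fat) and the χ-vs-PDFF line (4.83 ppb/%, −6.49 ppb). The
fat-compensated estimator uses the rounded fat-free intercept 9.2 ppb, the
value quoted alongside that estimator, so its worked numbers (0.093 mM at
20% fat, 0.026 mM at 35% fat for a 200 ppb shift) reproduce exactly at
3-decimal rounding; both intercept values are retained in the model.
Reported tables round to 3 decimals for mM and 1 decimal for ppb and s⁻¹.

## Known limitations

* TKD underestimates compact sources (~20% for spheres at δ = 0.2); no
  iteratively regularized single-orientation method is provided.
* The per-k multi-orientation division underestimates boundary-near
  sources on masked data; use the masked CG variant when that matters.
* PDFF clipping at 0 re-introduces a small (< 0.3 pp at SNR 100) positive
  bias in exactly-fat-free regions.
* The noise model is additive complex Gaussian with spatially uniform σ;
  no Rician magnitude statistics are modelled for the IR/SE series beyond
  additive noise.
* Simulated inclusions are rasterized binary objects; partial-volume
  mixtures of fat/water/iron within a voxel are not modelled.
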