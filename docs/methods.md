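# Methods

## Signal models

All times are milliseconds throughout. The spin-echo magnitude signal is
modelled as `SI ≈ PD · (1 − e^(−TR/T1)) · e^(−TE/T2)`. Each mapping mode
fits the two-parameter limit of this product:

* **T1 (saturation recovery).** TE is held short and fixed; the fitted
  model is `A · (1 − e^(−TR/T1))` with `A = PD · e^(−TE/T2)`. No joint
  three-parameter PD/T2 fit is attempted — with a single fixed TE the
  extra factor is unidentifiable and is absorbed into the amplitude.
* **T2 (monoexponential decay).** TR is held long and fixed; the fitted
  model is `A · e^(−TE/T2)` with `A = PD · (1 − e^(−TR/T1)) ≈ PD`.

The proton gyromagnetic constant is stored as γ/2π = 42.57747892 MHz/T,
so `larmor_frequency(1.5)` = 63.86621838 MHz and twice that at 3 T.

The default T1 protocol is the 23-point TR ladder 40, 50, 60, 78, 80,
100, 120, 140, 200, 240, 300, 400, 500, 600, 700, 800, 1000, 1500,
2000, 3000, 5000, 10000, 15000 ms at TE = 20 ms: dense where the
recovery bends, with TR_max at least 5× the longest expected T1 so the
plateau is sampled. The default T2 protocol is 20 geometrically spaced
echoes from 10 to 500 ms at TR = 15 000 ms; both are configurable.

## Pixel-wise fitting

Each retained pixel is fitted by bounded trust-region least squares
(`scipy.optimize.least_squares`, analytic Jacobian, ftol = xtol = gtol =
1e-8, ≤ 200 function evaluations) with T ∈ [1, 20000] ms and
A ∈ [0, 10·max(SI)]. The fit is seeded from the characteristic-point
rule: the time at which the curve crosses 63.212% of the plateau
estimate (mean of the two largest-time samples) for recovery, or falls
to 36.788% of the first sample for decay, located by linear
interpolation. In decay mode the first sample time t₀ is subtracted from
the crossing (the level is relative to y(t₀), so the crossing sits at
t₀ + T); with ≥ 10 noiseless samples spanning [0.1T, 5T] the seed alone
lands within 5% of T. When the curve never crosses the level, the seed
falls back to half the largest sampled time and the bounds do the rest.

Degenerate vectors (all-zero, constant, or non-finite) are excluded with
a `DEGENERATE` status rather than fitted: R² = 1 − SSE/SST is undefined
at SST = 0, and is stored as computed otherwise — negative values are
legitimate for a nonlinear model and are only clipped for display.
Histograms default to 256 bins over [0, 5000] ms (T1) or [0, 1000] ms
(T2) and count only mask-retained, successfully fitted pixels, so
aerated space contributes nothing; the ungated variant exists for
before/after comparison.

## Per-scan classifier

The gate is a K–10–1 feed-forward network: tanh (bipolar) hidden units
and a logistic (unipolar) output, both with slope β = 1. β is kept at 1
because the input normalisation already fixes the scale: all intensity
vectors are divided by the series-wide maximum (stored with the model),
without which raw clinical intensities (~10³) would saturate the
sigmoids. Weights start from small zero-mean Gaussians (1/√fan-in);
training is full-batch gradient descent with momentum (rate 0.5,
momentum 0.9) on binary cross-entropy, stopping when the loss change
drops below 1e-6 or at 500 epochs. For a 200-vector training set this
converges in a few tens of epochs; anything fancier would be
over-engineering at this size, and any optimiser that separates the two
ROI classes is acceptable. Training is deterministic given the seed.

The decision threshold is 0.5 — the midpoint of the sigmoid's (0, 1)
range — with exact 0.5 conservatively treated as noise. No validation
split is held out by default (N = 200); the real quality check is mask
agreement against ground truth on synthetic scenes. Models never
transfer across protocols with a different number of acquisitions (the
input dimension is K).

**ROI guidance.** Train the object class on the weakest-signal sample in
the field of view — the slowest-recovering tube for T1 work, the
shortest-T2 region for T2 work. Every other sample then lies *between*
the training classes and classification is interpolation; training on
the brightest sample instead leaves weak samples beyond the learned
boundary on the noise side (observed as a whole tube rejected on
synthetic scenes).

## Synthetic phantom

The generator emulates a bench phantom: disk-shaped tubes (a pixel
belongs to a tube if its centre lies inside the disk) with per-tube T1,
T2 and amplitude, on a background whose signal is exactly zero before
noise. The default scene is five tubes of radius 12 on a 128×128 grid —
T1 = 150/350/800/1600/3000 ms (each step ≥ 20% and the longest equal to
TR_max/5), T2 = 60/110/200/400/1500 ms, amplitudes 1300…700 — emulating
a concentration ladder plus distilled water, with visibly different
maximum intensities. Default noise is Rician (σ = 20, SNR ≈ 50 against
the mid amplitude): each signal s becomes √((s+n₁)² + n₂²) with
n₁, n₂ ~ N(0, σ²), so signal-free pixels follow a Rayleigh distribution
with mean σ√(π/2). A Gaussian option exists for linear-regime tests and
clips at zero, since stored magnitudes cannot be negative. Rendering is
bit-reproducible from the spec's seed.

Problem sizes in the test suite are chosen to exercise every claim at
meaningful statistics: closed-loop recovery and segmentation use the
full 128×128 default scene; fit-heavy comparisons use a 64×64 three-tube
variant of the same design.

**What the generator does not emulate — and what that implies.** Real
aerated regions contain more than i.i.d. Rician noise: ghosting that
tracks object signal along the phase-encode direction, partial-volume
edges, and inter-acquisition receiver-gain drift. Those structured
contaminants are what drive real air-pixel "fits" to absurdly long T1
(thousands of ms). Under pure Rayleigh noise this cannot happen: the
long-T1 branch of the recovery model is a ramp through zero, while
Rayleigh data sit on a positive floor, so air fits provably collapse
into the short-T1 / near-zero-R² basin (verified empirically against a
global profile search over T1; no air fit above ~300 ms in thousands of
draws). On synthetic scenes the spurious long-T1 entries that gating
removes therefore arise from noise-stretched fits of weak long-T1
pixels at low SNR rather than from air itself. Passing tests demonstrate
the gating mechanics and fit accuracy; they do not certify behaviour
against structured real-scanner artifacts.

## DICOM handling

Series are directories of single-frame magnitude DICOM files carrying
RepetitionTime (0018,0080) and EchoTime (0018,0081); the stack is sorted
by the varied time regardless of on-disk order, rescale slope/intercept
are applied, the held-constant time is verified constant to 0.01 ms, and
duplicate varied times (re-acquisitions) are averaged with a warning.
Multi-frame files are rejected — the analysis is single-slice by design.
Fixtures are written as 16-bit unsigned integers: integer data in range
round-trip bit-exactly (slope 1), anything else maps onto [0, 65535]
with quantization bounded by half a stored unit. Coordinates are 0-based
[row, col] with row 0 at the top, and ROIs are half-open squares.

## Pipeline accounting

The run report counts pixels, not seconds: ungated work equals the image
size, gated work equals the mask sum, and their ratio is set entirely by
the object-to-air area ratio of the scene. Wall-clock stage durations go
to the log for curiosity only — they depend on the host and say nothing
portable. Reports, maps and trained models are byte-reproducible given
the same configuration and seed.

## Known limitations

* Single-component exponentials only; no multi-exponential or
  inversion-recovery/CPMG sequence models.
* Unweighted ordinary least squares; no Rician noise-floor bias
  correction (visible as a small negative T1 bias on dim, slow tubes at
  low SNR), no B1/B0 inhomogeneity handling.
* Inter-acquisition gain changes are neither simulated nor corrected;
  intensities are read as stored, so vendor auto-gain switching between
  acquisitions would bias real-data fits.
* The classifier is per-scan by construction; there is deliberately no
  model reuse across scans.
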