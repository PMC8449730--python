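# Methods

`cerevess` segments bright tubular vessels in 3-D time-of-flight MR
angiography (TOF-MRA) volumes.  The method combines three classical
ingredients — multiscale Hessian vessel enhancement, a finite Gaussian
mixture model of the brain intensity histogram, and a Markov-random-field
label prior — wired so that the only data-driven scalar connecting them is
the vessel volume fraction.  This note records the model, the parameters
that matter, the synthetic data the tests run on, and the design choices
made where the design was genuinely open.

## Vessel enhancement

At scale σ the image Hessian is computed by separable convolution with
sampled Gaussian-derivative kernels and normalized by σ² (γ = 2), so tube
responses are comparable across scales.  The sampled kernels are
moment-corrected — the smoothing kernel sums to exactly 1, the derivative
kernels annihilate constants and differentiate ramps/quadratics exactly —
which keeps the analytic identities (constant image → zero Hessian,
f = x² → component 2σ²) true to machine precision rather than to kernel
discretization error.  Kernels are truncated at 4σ with reflect boundary
handling; σ is interpreted in voxel units (anisotropic spacing is carried
through I/O but not resampled — a documented limitation).

Per voxel, eigenvalues are sorted by magnitude |λ1| ≤ |λ2| ≤ |λ3|.  For
bright vessels the two large eigenvalues are negative inside a tube, so
they are negated into a positive working convention (a `bright_vessels`
flag skips this).  A low-contrast floor replaces λ3 by

    λe = λ3        if λ3 > ε·M,
    λe = ε·M       if 0 < λ3 ≤ ε·M,       M = max over voxels of λ3 at this scale,
    λe = 0         otherwise,

with ε defaulting to 0.5 (the midpoint of its valid range; no principled
value is available) and M taken inside the brain mask when one is
supplied.  The tube response is

    T = 0                                 if λ2 ≤ 0 or λe ≤ 0,
    T = 1                                 if λ2 ≥ λe/2 > 0,
    T = λ2²(λe − λ2)·[3/(λ2 + λe)]³       otherwise,

which is continuous with value exactly 1 at the seam λ2 = λe/2 and bounded
in [0, 1].  A `response_form="literal"` switch substitutes |λ2| + |λ3| for
the denominator for comparison runs.  The multiscale map is the voxel-wise
maximum over a geometric grid of scales (default 5 scales from 0.5 to 4.0
voxels, covering tube diameters of roughly 1–8 voxels).

Two structural properties of this response family are worth knowing:

* it has **no blobness term** (λ1 never enters), so an isolated bright
  ball saturates to T = 1 exactly like a tube.  Plates are suppressed
  hard (λ2 ≈ 0).  The test suite asserts both behaviors explicitly;
* on the centerline of a clean tube T saturates to 1 at *every* scale, so
  scale selectivity lives in the normalized λ3, which peaks at the scale
  matched to the tube's effective cross-section width (≈ r/2 for a
  parabolic profile).

Constant volumes are short-circuited to T ≡ 0: with no structure, M is
pure floating-point roundoff and would otherwise trip the saturated case.

## Vessel volume fraction and threshold

A K-component Gaussian mixture (default K = 3: dark background/CSF,
parenchyma, vessel) is fitted by EM to the raw brain-masked intensity
histogram.  The fit is deterministic given the sample.  Initialization
encodes the two priors that justify calling this a vessel-aware EM:
vessels are *bright* and vessels are *rare* — the K−1 background
components start at evenly spaced percentiles with equal weights, the last
component starts at the 99.9th percentile with weight 0.1.  Starting all
components inside the bulk of the histogram reliably loses the small
bright class to the background (measured on the reference phantom: the
top component converges to a broad remnant with weight 0.03–0.4 instead
of ≈ 0.005).  Convergence is declared at relative log-likelihood change
below 1e-6 (max 500 iterations); components whose responsibility mass
falls below 1e-6 are pruned with a logged warning.  The vessel class is
the largest-mean component and the vessel volume fraction W is its
mixing weight.

Given W and the S masked enhancement values f_p, the threshold Q is the
m-th largest value with m = round(W·S) (half-up, clamped to [1, S]); with
distinct values exactly m voxels satisfy f_p ≥ Q.  The sigmoid transform
S(T) = 1/(1 + (Q/T)²) then maps the enhancement to a probability-like
score that crosses 0.5 exactly at T = Q, so thresholding the transform at
0.5 is identical to T ≥ Q and introduces no new parameter.

## MRF refinement

Labels x ∈ {0,1} are refined under the two-term energy

    E(x) = Σ_p −log p(I_p | x_p) + β Σ_{p~q} [x_p ≠ x_q],

where p(I | vessel) is the vessel component density and p(I | background)
the re-normalized mixture of the remaining components, both evaluated on
the raw intensities the mixture was fitted to.  The pair sum counts each
neighboring pair once; the default neighborhood is 6-connected (26
available) and β defaults to 1.0.  Optimization is iterated conditional
modes: deterministic raster-order single-site updates until a sweep
changes nothing (energy non-increasing per sweep; β = 0 reduces to
voxel-wise maximum likelihood regardless of initialization; re-running on
the output is a no-op).  The inner sweep is JIT-compiled when numba is
importable; a pure-Python sweep with identical semantics is the fallback
and reference.

## Pipeline

`segment()` chains: Gaussian denoising (default σ = 0.8 voxel) of the
copy used for *geometric* analysis → brain mask (Otsu + largest component
+ hole fill by default; file or none) → multiscale enhancement on the
denoised volume → mixture fit on the **raw** masked intensities → fraction
threshold on the masked enhancement → sigmoid transform → initial labels
(transform ≥ 0.5) → ICM refinement driven by the raw-intensity likelihood
→ optional removal of small connected components (off by default).  The
run report records every intermediate statistic (W, Q, achieved fraction,
energy trace, sweep count) plus a configuration hash; input + config fully
determine the output.

The denoising/raw split is deliberate.  Sub-voxel noise texture produces
large fine-scale Hessian responses, and because M itself is then
noise-driven, the saturated case T = 1 fires on a few percent of
background voxels; denoising the geometric branch suppresses this.  The
mixture, by contrast, must see the raw histogram: the class structure of
an independently drawn background is destroyed by any spatial averaging
(a smoothed mixture of classes collapses toward a single Gaussian around
the grand mean).  Running the MRF on raw intensities keeps the data term
honest on vessel-free volumes — bright noise is spatially incoherent, so
the Potts term erases it and no structure survives beyond the forced
fraction.  The measured alternative (MRF on the denoised volume) scores a
higher Dice on tube phantoms but hallucinates coherent pseudo-structure on
vessel-free volumes and was rejected.

## Synthetic phantoms

`make_phantom` renders tubes (straight, helical, or bifurcating dense
polylines, sampling step ≤ 0.25 voxel) with lumen intensity
peak·(1 − (d/r)^e), truth mask = all voxels within the (possibly
tapering) radius, overlap resolved by maximum, background drawn
independently per voxel from a Gaussian mixture, plus Gaussian (default)
or Rician noise.  Identical spec + seed is bit-identical.

The reference study conditions, fixed once and used by the tests and the
acceptance script: 64³ grid (44³ for replicate studies), one straight
axis-aligned tube of radius 3 voxels, peak intensity 300, flow-profile
exponent 4, background (0.40, 60, 12) + (0.60, 140, 12), and
SNR = peak/noise_sd = 10 (noise sd 30).  The exponent models the blunted,
saturation-flattened profile of TOF inflow — near-uniform lumen signal
with the laminar falloff concentrated at the wall — rather than the pure
parabolic velocity profile (e = 2), whose zero wall signal no saturated
TOF acquisition shows.

What the phantom does **not** emulate: spatially coherent tissue regions
(the background is white, i.e. classes are drawn independently per
voxel), point-spread partial-volume blur, skull/CSF anatomy, flow
pulsatility, and intensity inhomogeneity.  Passing tests therefore
demonstrate the estimator mechanics (fraction recovery, threshold
calibration, energy descent, metric arithmetic) and end-to-end behavior
under a harsh noise model — not clinical-grade accuracy on patient data.

A consequence worth stating plainly: the truth mask is geometric, but
with any profile exponent the outermost lumen shell is darker than
parenchyma (≈ 25 % of the cross-section at e = 4).  Those voxels are
invisible to the raw-intensity data term, which bounds end-to-end
sensitivity near 0.75 and Dice near 0.82–0.84 under the reference
conditions regardless of the smoothness weight.  The pipeline tests
assert the behaviors that are achievable (refinement never hurting across
noise replicates, precision ≈ 0.95, the vessel-free contract); the
packaged acceptance check for Dice ≥ 0.85 documents the measured value.

## Clinical scales

Berg Balance Scale: 14 items, each 0–4, total 0–56.  Fugl-Meyer motor
assessment: 33 upper-limb + 17 lower-limb items, each 0–2, subtotals
66/34, total 100.  Functional Independence Measure: 13 motor + 5
cognitive items, each 1–7, subtotals 91/35, total 18–126, mapped to eight
ordered dependence bands (126; 108–125; 90–107; 72–89; 54–71; 36–53;
19–35; 18).  The 1–7 item range and 13/5 split are inferred from the
published extrema (18 items, min 18, max 126, subscale maxima 91/35); only
counts and ranges are enforced — the instruments' item-level clinical
wording is not reproduced.  Input is strict: one CSV row per assessment,
labeled item columns, no imputation.

## Numerical choices and degenerate inputs

* EM: spreads floored at 1e-6 of the data range; a sample with zero
  variance or fewer than 10·K points is rejected.
* Threshold: all-equal enhancement values are rejected (threshold
  undefined); ties at Q keep every tied voxel, so the achieved fraction
  can exceed W when the enhancement map has plateaus (T = 1 saturation).
* ICM tie-break: equal local energies resolve to background, making β = 0
  deterministic.
* Eigen-decomposition uses LAPACK (`eigvalsh`) with a stable magnitude
  sort; non-finite inputs raise instead of propagating.
* round() in m = round(W·S) is half-up, clamped to at least 1.

## Problem sizes

Test and acceptance runs use 64³ volumes for the single end-to-end run,
44³ for the 20-replicate refinement study, 28³ for optimizer-guarantee
checks, n = 100 000 samples × 20 replicates for EM recovery, and 100
random samples (≤ 1000 values) for the threshold oracle — sizes at which
every suite completes in a few minutes on one CPU while keeping the
estimators in their asymptotic regime.
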