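# Methods

## Signal model and scope

One Talbot–Lau acquisition yields three co-registered channels of the same
scene: attenuation (AC), differential phase (DPC, a derivative-like
refraction signal) and dark-field (DFC, small-angle scattering from
structure below the system resolution). The package fuses exactly three
same-shape channels; the interferometric retrieval itself (phase stepping,
visibility) is out of scope — inputs are assumed already retrieved and
normalised to dimensionless [0, 1] intensities.

## Step 1 — adaptive Wiener filter

Local mean `m` and population variance `σ²` are computed over an odd
`X×Y` window (default 5×5) with symmetric (mirror) boundary padding, which
avoids dark rims at the frame edge. The shrinkage gain `(σ² − v²)/σ²` is
floored at zero — without the floor the filter would invert contrast
wherever `σ² < v²` — and where `σ² = 0` the output is the local mean (which
there equals the input). When no noise variance is supplied, `v²` is the
mean of all local variances: the only self-consistent closure given that a
separate noise estimate is generally unavailable for retrieved
interferometry channels. Passing `v² = 0` makes the filter the identity.

## Step 2 — the transform

The non-subsampled contourlet decomposition is realised as a
frequency-domain partition of unity:

* **Pyramid**: nested Meyer-style radial windows `φ_j(r)`, equal to 1 for
  `r ≤ π/2^j` and decaying to 0 at `π/2^{j-1}` through a raised-cosine
  (`cos²`) taper. Scale j's ring is `φ_{j-1} − φ_j` (j = 1 is the finest
  scale; `φ_0 ≡ 1`); the final low-pass is `φ_J`.
* **Directional bank**: each ring is multiplied by `2^{l_j}` angular `cos²`
  bumps in the wedge coordinate `θ/(π/2^{l_j})`, where θ is the frequency
  orientation taken modulo π (wedge pairs symmetric through the origin, so
  filters are real). Integer translates of the bump tile unity, so the
  wedges of one ring sum exactly to the ring.

Because all windows sum to exactly 1 and filtering is circular (FFT), the
synthesis operator is the plain sum of all bands: perfect reconstruction,
shift invariance and linearity hold to machine precision (measured round-trip
error ~1e-15, far inside the 1e-6 the pipeline relies on). This is a design
choice over discrete maxflat à-trous filter cascades, which realise the same
band structure but only approximate these identities; no specific filter
pair is intrinsic to the fusion rules, which consume band coefficients and
their saliences only. The cost is that band energy is localised in frequency
rather than by compactly supported spatial kernels — irrelevant for
coefficient selection driven by per-pixel salience. Requested depth J
requires `min(M, N) ≥ 2^{J+2}`; violations name the maximum feasible depth.

## Step 2 — SCM salience and coefficient selection

Stimulus preparation maps each sub-band to `|coefficient|`, max-normalised
per band (high-pass coefficients are signed; magnitude is what signals
activity; an all-zero band yields zero drive). The SCM iterates

    U ← f·U + S·(1 + β·(W ⊛ Y)),  Y ← [U > Θ],  Θ ← g·Θ + h·Y

with `f = 0.8, g = 0.7, h = 20, k = 200` and the eight-neighbour kernel
`W = [[.1091,.1409,.1091],[.1409,0,.1409],[.1091,.1409,.1091]]` (zero
centre: no self-linking). The spike condition is published as a steep
logistic of `U − Θ` exceeding ½, which is algebraically `U > Θ`; the
comparison is implemented directly (exact, cheaper, no overflow). The
linking strength β is not part of the published parameter set; the default
β = 0.3 is the typical value in SCM/PCNN fusion practice and is exposed in
the configuration. Initial conditions are `U = Y = 0`, `Θ = 1`: a zero
initial threshold would make every positively driven neuron fire
synchronously at the first step, destroying the salience ordering, while
`Θ₀ = 1` keeps zero-stimulus neurons silent forever. The neighbourhood
convolution uses zero padding — border neurons have fewer neighbours. The
ignition matrix is the total spike count over k iterations (the "time
matrix" reading of firing activity as perceived stimulus intensity);
first-spike-time is the documented alternative and was not chosen because
totals are better resolved at moderate k.

Low-pass selection compares `a·T_AC` against `(1−a)·T_DPC` and
`(1−a)·T_DFC` and takes the winner's coefficient; ties resolve by the
priority AC > DPC > DFC, consistent with the rule's purpose of biasing the
fused image toward the attenuation appearance. The high-pass rule's three
prose cases overlap at their boundaries; they are made a total partition by
a fixed decision order: (1) exactly one channel significantly exceeds both
others → take it; (2) two channels each significantly exceed the third →
average them (the three pair conditions are mutually exclusive once no
single channel dominates, because pair membership requires opposite-sign
significant differences); (3) otherwise blend with `(b, c, d)`. All seven
outcomes are convex combinations of the three coefficients. Band matching
across channels is positional — all channels share one filter bank.

## Step 3 — enhancement

CLAHE runs on a 5×5 tile grid (tile kernel = ceil(shape/5)) with clip limit
0.00125 and 500 histogram bins, with bilinear blending between tiles; the
implementation is scikit-image's `equalize_adapthist`. A constant image is
returned unchanged (its histogram is degenerate). Sharpening subtracts
`C·∇²I` with the 4-neighbour second-difference Laplacian (replicate
boundary); `C` is the 256-level-entropy argmax over the grid 0:0.05:5,
divided by the guard α = 3. The grid is a package choice — the entropy
argmax is insensitive to its resolution at 0.05 — and is configurable. The
tone curve is the logistic `1/(1 + exp(λ₁(λ₂ − v)))` (the published form
with a minus sign in the denominator is negative or singular on [0, 1] and
is read as a sign typo), followed by a min-max rescale to [0, 1]; whether to
rescale after the sigmoid is the package's choice, made so every stage maps
[0, 1] into [0, 1]. Enhancement is a function of the fused image alone and
can add no information from the source channels.

## Metrics

All histogram quantities (H, MI, FMI, FF) quantise [0, 1] onto 256 uniform
levels (the 8-bit convention) and use base-2 logarithms, so `MI(A, A) = H(A)`
holds exactly. FMI's feature image is the max-normalised Sobel gradient
magnitude. SSIM uses 11×11 Gaussian windows (σ = 1.5), `k₁ = 0.01,
k₂ = 0.03, L = 1`, population covariances, valid-window pooling; it is
implemented in-package so the windowed statistic matches the defining
equation exactly. FSIM combines phase congruency (a 4-scale, 4-orientation
log-Gabor quadrature bank; PC = pooled orientation energy over total
amplitude, without a noise threshold — self-similarity is exactly 1 by
construction) with Scharr gradient magnitude on a 0–255 scale, constants
`T₁ = 0.85, T₂ = 160, α = β = 1`. Edge strength follows the
Sobel-based edge-preservation model with sigmoid constants
(0.9994, −15, 0.5) for relative strength and (0.9879, −22, 0.8) for
orientation agreement, pooled with the inputs' gradient magnitudes as
weights; as normalised it lies in [0, 1]. The PSD is the periodogram
`|F|²/(MN)` pooled into integer-radius annuli up to the Nyquist ring
(mean power per annulus); normalisation and binning are package choices,
and comparisons use curve ordering, which is invariant to them. Note the
finite-sample bias of a 256×256-bin joint histogram: MI between independent
256×256 images measures ≈ 0.8 bits, the chi-square bias
`(K−1)²/(2N ln 2)`, not zero.

## Phantom generator

The phantom emulates the structure of small-animal extremity data: smooth
Gaussian-profile elliptical bodies (AC); DPC as the row-direction first
derivative of the anatomy, min-max rescaled, plus band-limited "trabecular"
noise (difference of Gaussians, σ 1→3 px) painted only inside the main
body's interior (`dpc_only_mask`); DFC as a 0.08 background plus
high-amplitude fine-grain texture (DoG, σ 0.5→1.5 px) only on the main
body's elliptical rim (`dfc_only_mask`, the "bone cortex"). Default
amplitudes 0.35/0.4 give the exclusive features a clear margin over the
default per-channel noise (σ = 0.01, 0.02, 0.02 — attenuation retrieval is
the least noisy channel in practice). Noise is additive Gaussian, matching
the Wiener stage's additive-noise model, not Poisson. The generator does
**not** emulate source-spectrum hardening, visibility loss, phase-wrapping
artifacts or correlated retrieval noise; green tests demonstrate correct
mechanics of the scheme on data with the stated statistics, not performance
on any particular experimental dataset.

## Problem sizes and numerics

The evaluation-scale choices of the package: feature-transfer checks run on
the default 256×256 phantom; the multi-seed comparison against the
averaging baseline uses five 128×128 phantoms with a central 64×64 ROI —
sizes at which every SCM run (65 bands × 3 channels × 200 iterations) stays
cheap while the texture scales remain well resolved. Phantom shapes below
32×32 are rejected (texture scales undefined). Degenerate inputs: constant
images normalise to zeros with a logged warning; zero bands give zero SCM
stimulus; a constant image passes through CLAHE, sharpening and SD/H/SF as
the exact fixed point or zero.

## Known limitations

* The NSCT here is a tight partition-of-unity frame, not the classical
  maxflat filter cascade; band coefficients differ from MATLAB-toolbox
  outputs even though structure, redundancy and all transform identities
  match.
* β and the SCM initial conditions are not pinned by the published
  parameter set; results depend mildly on both, and both are configurable.
* ES as normalised cannot exceed 1; published tables for this family of
  measures sometimes report values above 1 from unnormalised variants.
* Metrics on enhanced outputs mix the fusion's merit with the enhancement's;
  the pipeline exposes `skip_enhance` so either can be scored in isolation.
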