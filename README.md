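# xgifuse

Tri-contrast image fusion for X-ray grating (Talbot–Lau) interferometry.

A single grating-interferometry acquisition retrieves three co-registered
2-D images with complementary contrast mechanisms: **AC** (attenuation, the
conventional radiographic signal), **DPC** (differential phase — refraction,
sensitive to electron-density gradients) and **DFC** (dark-field — small-angle
scattering from sub-resolution structure such as bone trabeculae and cortex).
Reading three images at once burdens interpretation; `xgifuse` combines them
into one image that keeps the familiar attenuation appearance while importing
the edge and scattering detail that only the phase and dark-field channels see.
No registration is needed anywhere: the three channels come out of the
retrieval temporally and spatially aligned.

## The scheme

Three steps, each independently toggleable:

1. **Adaptive Wiener denoising** of each channel with a 5×5 window:
   `out = m + max(σ² − v², 0)/σ² · (I − m)`, where `m`, `σ²` are the local
   window moments and the noise variance `v²` defaults to the mean of all
   local variances.

2. **NSCT–SCM fusion.** Each channel is decomposed by a non-subsampled
   contourlet transform (NSCT): an undecimated pyramid over J octave scales
   followed by an undecimated directional filter bank with `2^{l_j}`
   orientation wedges per scale (default levels `(4,4,4,4)` → 64 directional
   bands + 1 low-pass, all input-sized; redundancy `R = Σ_j 2^{l_j}`).
   Every sub-band drives a **spiking cortical model** (SCM) — a simplified
   Eckhorn-type neural network

   ```
   U ← f·U + S·(1 + β·(W ⊛ Y)),   Y ← [U > Θ],   Θ ← g·Θ + h·Y
   ```

   whose per-pixel firing totals over k = 200 iterations ("ignition
   matrices" T) score local salience. Coefficients are then mixed pixelwise:
   the low-pass band by winner-take-all on `a·T_AC` vs `(1−a)·T_DPC` vs
   `(1−a)·T_DFC` (a = 0.55 biases the fused image toward the attenuation
   look), and each high-pass band by a seven-case significance rule with
   threshold `T_th = 1`: take the single channel whose ignition significantly
   exceeds both others, average a pair that jointly dominates the third, or
   otherwise blend all three with weights `(b, c, d) = (0.41, 0.29, 0.30)`.
   The fused coefficients are inverted back to an image.

3. **Enhancement**: CLAHE (5×5 tiles, clip limit 0.00125, 500 bins),
   entropy-guided adaptive unsharp sharpening (gain = entropy-argmax / 3),
   and a logistic tone curve `1/(1 + exp(λ₁(λ₂ − v)))` with
   `λ₁ = 4.8, λ₂ = 0.49`, rescaled to [0, 1].

The package also ships the nine-figure evaluation suite used to score
fusion quality — edge strength (ES), spatial frequency (SF), standard
deviation (SD), entropy (H), feature mutual information (FMI), feature
similarity (FSIM), fusion factor (FF), structural similarity (SSIM) and the
radially averaged power spectral density (PSD) — plus a seeded synthetic
tri-contrast phantom generator with known channel-exclusive features, and
two simple comparison fusers (per-pixel mean; NSCT with max-|coefficient|
high bands).

## Worked example

```python
import numpy as np
from xgifuse import PhantomSpec, generate_phantom, run_pipeline
from xgifuse.baseline import mean_fuse
from xgifuse.metrics import report

truth = generate_phantom(PhantomSpec(shape=(128, 128), seed=0))
fused = run_pipeline(truth.tri)          # denoise -> NSCT-SCM fuse -> enhance
baseline = mean_fuse(truth.tri)

roi = (32, 32, 96, 96)
print("NSCT-SCM:");             print(report(truth.tri, fused, roi).format_table())
print("per-pixel mean baseline:"); print(report(truth.tri, baseline, roi).format_table())
```

prints

```
NSCT-SCM:
ES    0.3011
H     7.2747
SD    0.2602
SF    0.1332
FMI   5.4459
FF    8.3043
SSIM  0.2659
FSIM  0.7416
per-pixel mean baseline:
ES    0.1445
H     6.8483
SD    0.1350
SF    0.0415
FMI   6.7074
FF    7.0936
SSIM  0.4213
FSIM  0.8120
```

The fused image carries substantially more information (H: 7.27 vs 6.85
bits) and contrast (SD: 0.26 vs 0.14) inside the region of interest than
plain averaging, and roughly twice the edge transfer (ES) and spatial
frequency — the averaging baseline scores higher on the pure similarity
figures (SSIM/FSIM/FMI) simply because an average is, by construction,
similar to each of its inputs. Intensities are dimensionless [0, 1] floats;
H, FMI and FF are in bits over a 256-level quantisation.

The same pipeline is available from the shell:

```sh
xgifuse phantom --shape 256 256 --seed 0 -o work/
xgifuse fuse --ac work/ac.tif --dpc work/dpc.tif --dfc work/dfc.tif -o work/fused.tif
xgifuse metrics --ac work/ac.tif --dpc work/dpc.tif --dfc work/dfc.tif \
    --fused work/fused.tif --roi 64 64 192 192 -o work/report.json
```

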