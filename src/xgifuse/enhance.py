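"""Post-fusion enhancement: CLAHE, adaptive sharpening, sigmoid gamma.

The stage operates on the fused image alone — it stretches contrast and
accentuates detail but cannot add information from the source channels.
Three sub-steps, in order:

1. Contrast-limited adaptive histogram equalisation (CLAHE) on a tile
   grid with bilinear blending between tiles and a clip limit that caps
   noise amplification.
2. Adaptive unsharp sharpening: subtract C times the 4-neighbour
   discrete Laplacian, where C is chosen by maximising the entropy of
   the sharpened candidate over a grid and then divided by a guard
   constant alpha (default 3) against over-sharpening.
3. Gamma correction by a logistic tone curve
   1 / (1 + exp(lambda1 * (lambda2 - v))), followed by a min-max rescale
   back to [0, 1].

Every sub-step maps [0, 1] images to [0, 1] images of the same shape.
"""

from __future__ import annotations

import numpy as np
from skimage import exposure

from .config import EnhanceParams
from .errors import ValidationError
from .image_io import validate_image
from .metrics import entropy


def _check_unit_range(image, name):
    if image.min() < 0.0 or image.max() > 1.0:
        raise ValidationError(f"{name} expects intensities in [0,1]")


def clahe(image: np.ndarray, params: EnhanceParams | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation on a tile grid."""
    params = (params or EnhanceParams()).validate()
    image = validate_image(image)
    _check_unit_range(image, "clahe")
    tr, tc = params.clahe_tiles
    M, N = image.shape
    if tr > M or tc > N:
        raise ValidationError(f"tile grid {params.clahe_tiles} larger than image {image.shape}")
    if image.max() == image.min():
        return image.copy()  # flat histogram is invariant
    kernel = (int(np.ceil(M / tr)), int(np.ceil(N / tc)))
    out = exposure.equalize_adapthist(
        image, kernel_size=kernel, clip_limit=params.clahe_clip, nbins=params.clahe_bins
    )
    return np.clip(out, 0.0, 1.0)


def laplacian(image: np.ndarray) -> np.ndarray:
    """4-neighbour second-difference Laplacian with replicate boundary."""
    p = np.pad(image, 1, mode="edge")
    return (p[2:, 1:-1] + p[:-2, 1:-1] + p[1:-1, 2:] + p[1:-1, :-2]
            - 4.0 * p[1:-1, 1:-1])


def adaptive_sharpen(image: np.ndarray, params: EnhanceParams | None = None,
                     return_C: bool = False):
    """Entropy-guided unsharp sharpening.

    Sweeps the gain C over ``params.sharpen_C_grid``; the candidate
    clip(I - C * lap(I), 0, 1) with maximum 256-level entropy defines
    C_max, and the applied gain is C_max / alpha.
    """
    params = (params or EnhanceParams()).validate()
    image = validate_image(image)
    _check_unit_range(image, "adaptive_sharpen")
    lo, hi, step = params.sharpen_C_grid
    grid = np.arange(lo, hi + 0.5 * step, step)
    if grid.size == 0:
        raise ValidationError("empty sharpening gain grid")
    lap = laplacian(image)
    entropies = [entropy(np.clip(image - C * lap, 0.0, 1.0)) for C in grid]
    C_max = float(grid[int(np.argmax(entropies))])
    C_final = C_max / params.sharpen_alpha
    out = np.clip(image - C_final * lap, 0.0, 1.0)
    return (out, C_final) if return_C else out


def gamma_sigmoid(image: np.ndarray, lambda1: float = 4.8, lambda2: float = 0.49) -> np.ndarray:
    """Logistic tone curve, then min-max rescale to [0, 1].

    The curve 1/(1 + exp(lambda1*(lambda2 - v))) is strictly increasing
    for lambda1 > 0 and takes the value 1/2 exactly at v = lambda2.
    """
    image = validate_image(image)
    _check_unit_range(image, "gamma_sigmoid")
    mapped = 1.0 / (1.0 + np.exp(lambda1 * (lambda2 - image)))
    lo, hi = mapped.min(), mapped.max()
    if hi == lo:
        return np.zeros_like(mapped)
    return (mapped - lo) / (hi - lo)


def enhance(image: np.ndarray, params: EnhanceParams | None = None, manifest=None) -> np.ndarray:
    """Full Step-3 chain: CLAHE -> adaptive sharpening -> sigmoid gamma."""
    params = (params or EnhanceParams()).validate()
    out = clahe(image, params)
    if manifest is not None:
        manifest.record("clahe", tiles=list(params.clahe_tiles),
                        clip=params.clahe_clip, bins=params.clahe_bins)
    out, C_final = adaptive_sharpen(out, params, return_C=True)
    if manifest is not None:
        manifest.record("adaptive_sharpen", C_final=C_final, alpha=params.sharpen_alpha)
    out = gamma_sigmoid(out, params.lambda1, params.lambda2)
    if manifest is not None:
        manifest.record("gamma_sigmoid", lambda1=params.lambda1, lambda2=params.lambda2)
    return out
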