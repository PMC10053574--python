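"""Adaptive Wiener denoising (pipeline Step 1).

Per pixel, the filter estimates the local mean m and local variance
sigma^2 over an X x Y window and shrinks the deviation from the mean by
the noise-adaptive gain (sigma^2 - v^2) / sigma^2:

    out = m + max(sigma^2 - v^2, 0) / sigma^2 * (I - m)

where v^2 is the noise variance.  When not supplied, v^2 is the mean of
all local variances — the standard "average noise variance" estimate.
The gain is floored at zero (the raw expression would invert contrast
where sigma^2 < v^2); where sigma^2 = 0 the output is the local mean.
Local moments use symmetric (mirror) boundary padding, which avoids dark
rims at the image border.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .image_io import validate_image


def local_moments(image: np.ndarray, window: tuple) -> tuple:
    """Local mean and population variance over an X x Y window
    (symmetric boundary padding).  Variance is floored at 0 to absorb
    floating-point cancellation."""
    size = tuple(int(w) for w in window)
    m = ndimage.uniform_filter(image, size=size, mode="reflect")
    m2 = ndimage.uniform_filter(image * image, size=size, mode="reflect")
    var = np.maximum(m2 - m * m, 0.0)
    return m, var


def wiener_filter(image: np.ndarray, window: tuple = (5, 5),
                  noise_variance: float | None = None) -> np.ndarray:
    """Adaptive Wiener filter of one channel; output clipped to [0, 1]."""
    image = validate_image(image)
    X, Y = (int(w) for w in window)
    if X % 2 == 0 or Y % 2 == 0 or X < 3 or Y < 3:
        raise ValidationError(f"window dims must be odd and >= 3, got {(X, Y)}")
    if X > image.shape[0] or Y > image.shape[1]:
        raise ValidationError(f"window {(X, Y)} does not fit image of shape {image.shape}")
    if noise_variance is not None and noise_variance < 0:
        raise ValidationError("noise variance must be >= 0")

    m, var = local_moments(image, (X, Y))
    v2 = float(np.mean(var)) if noise_variance is None else float(noise_variance)
    if v2 == 0.0:
        # zero-noise limit: unit gain everywhere sigma^2 > 0 and
        # output = m = I where sigma^2 = 0, i.e. the identity
        return np.clip(image, 0.0, 1.0)
    gain = np.zeros_like(var)
    np.divide(np.maximum(var - v2, 0.0), var, out=gain, where=var > 0)
    out = m + gain * (image - m)
    # where the window is constant the pixel equals the local mean already
    out = np.where(var > 0, out, m)
    return np.clip(out, 0.0, 1.0)
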