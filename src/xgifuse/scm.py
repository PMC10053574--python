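"""Spiking cortical model (SCM) ignition matrices.

The SCM is a simplified Eckhorn-type neural network: one neuron per
pixel, driven by an external stimulus S and modulated by the spikes of
its eight neighbours.  Per iteration n:

    U <- f*U + S * (1 + beta * (W (*) Y))      membrane potential
    Y <- 1 where U > Theta else 0              spike
    Theta <- g*Theta + h*Y                     dynamic threshold

with leak constants 0 < f, g < 1 and refractory recharge h > 0.  The
published form gates the spike through a steep logistic of (U - Theta)
exceeding 1/2, which is algebraically the comparison U > Theta; the
comparison is implemented directly.  The ignition matrix is the total
spike count per pixel over k iterations — a monotone salience measure of
the local stimulus ("time matrix" reading): strongly driven neurons fire
earlier and more often.

Initial conditions are U = 0, Y = 0 and Theta = theta_init (default 1):
a unit initial threshold prevents the spurious synchronous all-fire
first step that a zero threshold would cause under any positive
stimulus, while keeping zero-stimulus neurons silent forever.

The neighbourhood term uses zero padding: border neurons simply have
fewer neighbours.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import SCMParams
from .errors import ValidationError


def prepare_stimulus(band: np.ndarray) -> np.ndarray:
    """Map a (possibly signed) sub-band to a nonnegative drive in [0, 1].

    High-frequency contourlet coefficients are signed; their magnitude
    is what signals local activity, so the stimulus is |coefficient|
    max-normalised per band.  An all-zero band yields a zero stimulus.
    """
    mag = np.abs(np.asarray(band, dtype=np.float64))
    peak = mag.max()
    return mag / peak if peak > 0 else mag


def scm_ignition(stimulus: np.ndarray, params: SCMParams | None = None) -> np.ndarray:
    """Run the SCM for ``params.iterations`` steps; return spike totals.

    ``stimulus`` must be finite and lie in [0, 1] (use
    :func:`prepare_stimulus` on raw sub-bands).  Returns an integer
    array with values in [0, k].  The model has no randomness: identical
    inputs give identical counts.
    """
    params = (params or SCMParams()).validate()
    S = np.asarray(stimulus, dtype=np.float64)
    if S.ndim != 2:
        raise ValidationError(f"stimulus must be 2-D, got shape {S.shape}")
    if not np.all(np.isfinite(S)):
        raise ValidationError("stimulus contains non-finite values")
    if S.min() < 0:
        raise ValidationError("stimulus must be nonnegative (take magnitudes upstream)")
    if S.max() > 1.0:
        raise ValidationError("stimulus must lie in [0, 1] (max-normalise upstream)")

    W = params.W
    f, g, h, beta = params.f, params.g, params.h, params.beta
    U = np.zeros_like(S)
    Y = np.zeros_like(S)
    Theta = np.full_like(S, params.theta_init)
    counts = np.zeros(S.shape, dtype=np.int64)

    link = np.empty_like(S)
    any_spike = False
    for _ in range(params.iterations):
        if beta != 0.0 and any_spike:
            ndimage.convolve(Y, W, output=link, mode="constant", cval=0.0)
            U = f * U + S * (1.0 + beta * link)
        else:
            U = f * U + S
        fired = U > Theta
        any_spike = bool(fired.any())
        Y = fired.astype(np.float64)
        Theta = g * Theta + h * Y
        counts += fired
    return counts
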