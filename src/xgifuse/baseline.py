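"""Minimal comparison fusers for the evaluation harness.

Two deliberately simple arms against which the NSCT-SCM scheme is
scored: per-pixel averaging, and a generic transform-domain rule (NSCT
with max-|coefficient| high bands and mean low band).
"""

from __future__ import annotations

import numpy as np

from .image_io import TriContrastSet
from .nsct import NSCTCoefficients, nsct_forward, nsct_inverse


def mean_fuse(tri: TriContrastSet) -> np.ndarray:
    """Per-pixel arithmetic mean of the three channels."""
    return (tri.ac + tri.dpc + tri.dfc) / 3.0


def max_abs_highpass_fuse(tri: TriContrastSet, levels=(4, 4, 4, 4)) -> np.ndarray:
    """NSCT baseline: per-pixel max-|coefficient| highs, mean lows."""
    dec = [nsct_forward(ch, levels) for ch in tri.channels()]
    low = (dec[0].lowpass + dec[1].lowpass + dec[2].lowpass) / 3.0
    high = []
    for j in range(len(dec[0].levels)):
        scale = []
        for m in range(len(dec[0].highpass[j])):
            stack = np.stack([d.highpass[j][m] for d in dec])
            idx = np.argmax(np.abs(stack), axis=0)
            scale.append(np.take_along_axis(stack, idx[None], axis=0)[0])
        high.append(scale)
    return nsct_inverse(NSCTCoefficients(lowpass=low, highpass=high, levels=dec[0].levels))
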