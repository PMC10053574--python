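"""Non-subsampled contourlet decomposition and exact inverse.

The transform is the undecimated two-stage cascade of the contourlet
family: a non-subsampled pyramid splits the image into one low-pass band
and J octave high-pass bands, and a non-subsampled directional filter
bank splits each high-pass band into 2^{l_j} angular wedge bands.  No
band is subsampled, so every band has the input's shape and the
redundancy is R = sum_j 2^{l_j}.

Filters are realised in the Fourier domain as a smooth partition of
unity: Meyer-style raised-cosine radial windows define the pyramid
(scale j passes the octave [pi/2^j, pi/2^{j-1}]), and raised-cosine
angular windows on the orientation theta mod pi define the directional
wedges.  Because all windows sum to exactly one, synthesis is the plain
sum of the bands, so perfect reconstruction holds to floating-point
precision; because filtering is circular (periodic extension), the
transform commutes exactly with circular shifts and is exactly linear.
All windows are symmetric under frequency negation, so real inputs give
real bands.

Scale ordering convention: index j = 1 (the first entry of ``levels``
and of ``highpass``) is the finest scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import ValidationError
from .image_io import validate_image


@dataclass
class NSCTCoefficients:
    """One low-pass band plus per-scale lists of directional bands."""

    lowpass: np.ndarray
    highpass: list  # highpass[j-1] is the list of 2^{l_j} bands of scale j
    levels: tuple

    def __post_init__(self):
        self.levels = tuple(int(l) for l in self.levels)
        shape = self.lowpass.shape
        if len(self.highpass) != len(self.levels):
            raise ValidationError("one list of directional bands per scale is required")
        for j, (l_j, bands) in enumerate(zip(self.levels, self.highpass), start=1):
            if len(bands) != 2 ** l_j:
                raise ValidationError(
                    f"scale {j} must carry 2^{l_j} = {2 ** l_j} directional bands, got {len(bands)}"
                )
            for band in bands:
                if band.shape != shape:
                    raise ValidationError(
                        f"band shape {band.shape} differs from lowpass shape {shape}"
                    )

    @property
    def n_highpass(self) -> int:
        return sum(len(bands) for bands in self.highpass)

    @property
    def redundancy(self) -> int:
        """R = sum_j 2^{l_j}, the band count of the undecimated transform."""
        return sum(2 ** l for l in self.levels)

    def all_bands(self):
        """Iterate (scale_index, direction_index, band); lowpass excluded."""
        for j, bands in enumerate(self.highpass):
            for m, band in enumerate(bands):
                yield j, m, band


def max_feasible_scales(shape: tuple) -> int:
    """Largest pyramid depth J such that min(shape) >= 2^{J+2}."""
    return max(int(np.floor(np.log2(min(shape)))) - 2, 0)


def _raised_cosine(x: np.ndarray) -> np.ndarray:
    """Smooth ramp: 1 for x <= 0, 0 for x >= 1, cos^2 taper between."""
    y = np.clip(x, 0.0, 1.0)
    return np.cos(0.5 * np.pi * y) ** 2


@lru_cache(maxsize=8)
def _frequency_windows(shape: tuple, levels: tuple):
    """Build the partition-of-unity windows for one (shape, levels) pair.

    Returns (lowpass_window, [[directional windows of scale j], ...]),
    all real arrays on the unshifted FFT grid, summing to one.
    """
    M, N = shape
    wy = 2.0 * np.pi * np.fft.fftfreq(M)[:, None]
    wx = 2.0 * np.pi * np.fft.fftfreq(N)[None, :]
    r = np.hypot(wy, wx)
    theta = np.mod(np.arctan2(wy, wx), np.pi)  # orientation, period pi

    J = len(levels)
    # nested radial low-pass windows: phi_j = 1 for r <= pi/2^j,
    # tapering to 0 at r = pi/2^{j-1}
    phis = []
    for j in range(1, J + 1):
        hi = np.pi / 2 ** (j - 1)
        lo = np.pi / 2 ** j
        phis.append(_raised_cosine((r - lo) / (hi - lo)))

    directional = []
    prev = np.ones(shape)
    for j, l_j in enumerate(levels):
        band = prev - phis[j]  # octave ring of scale j (j=0 is finest)
        n_dir = 2 ** l_j
        delta = np.pi / n_dir
        u = theta / delta  # wedge coordinate in [0, n_dir)
        wedges = []
        for m in range(n_dir):
            # cos^2 bump centred on wedge m+1/2, wrapped with period n_dir;
            # integer translates of the bump tile unity exactly
            d = np.mod(u - (m + 0.5) + n_dir / 2.0, n_dir) - n_dir / 2.0
            bump = np.where(np.abs(d) < 1.0, np.cos(0.5 * np.pi * d) ** 2, 0.0)
            wedges.append(band * bump)
        directional.append(wedges)
        prev = phis[j]
    return phis[-1], directional


def _validate_levels(shape, levels):
    levels = tuple(int(l) for l in levels)
    if not levels or any(l < 1 for l in levels):
        raise ValidationError("levels must be a non-empty vector of integers >= 1")
    J = len(levels)
    if min(shape) < 2 ** (J + 2):
        raise ValidationError(
            f"image of shape {shape} is too small for {J} pyramid scales; "
            f"maximum feasible depth is J = {max_feasible_scales(shape)}"
        )
    return levels


def nsct_forward(image: np.ndarray, levels) -> NSCTCoefficients:
    """Decompose ``image`` into 1 low-pass + sum_j 2^{l_j} directional bands."""
    image = validate_image(image)
    levels = _validate_levels(image.shape, levels)
    low_win, dir_wins = _frequency_windows(image.shape, levels)
    F = np.fft.fft2(image)
    lowpass = np.fft.ifft2(low_win * F).real
    highpass = [
        [np.fft.ifft2(w * F).real for w in wedges] for wedges in dir_wins
    ]
    return NSCTCoefficients(lowpass=lowpass, highpass=highpass, levels=levels)


def nsct_inverse(coeffs: NSCTCoefficients) -> np.ndarray:
    """Exact synthesis: the bands form a partition of unity, so summing
    them reconstructs the input to floating-point precision."""
    out = coeffs.lowpass.copy()
    for _, _, band in coeffs.all_bands():
        out += band
    return out
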