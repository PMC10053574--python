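"""Synthetic tri-contrast phantoms with known channel-exclusive features.

Real grating-interferometry data of the kind the fusion scheme targets
(small-animal extremities) have three hallmarks the generator emulates:

* the attenuation channel (AC) is dominated by smooth absorbing bodies —
  bone and bulk soft tissue — with little fine texture;
* the differential-phase channel (DPC) is a derivative-like signal
  (refraction deflects the beam where the electron density changes), so
  it highlights edges, and it additionally carries fine "trabecular"
  texture inside the bone that no other channel sees;
* the dark-field channel (DFC) responds to sub-resolution small-angle
  scattering, so the cortical rim of the bone lights up strongly against
  a low background, again invisible elsewhere.

The generator builds a shared anatomy of Gaussian-profile elliptical
bodies, derives DPC as the directional first derivative of AC plus
band-limited texture painted only inside ``dpc_only_mask`` (the
trabecular interior), and paints high-amplitude fine-grain texture only
inside ``dfc_only_mask`` (the cortical rim).  Zero-mean Gaussian noise
is added per channel, then values are clipped to [0, 1].  Identical
seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .image_io import TriContrastSet, normalize

MIN_PHANTOM_DIM = 32  # texture scales are undefined below this


@dataclass
class PhantomSpec:
    shape: tuple = (256, 256)
    n_bodies: int = 4
    dpc_texture_amplitude: float = 0.35
    dfc_texture_amplitude: float = 0.4
    noise_sigma_per_channel: tuple = (0.01, 0.02, 0.02)
    seed: int = 0

    def validate(self) -> "PhantomSpec":
        M, N = self.shape
        if M < MIN_PHANTOM_DIM or N < MIN_PHANTOM_DIM:
            raise ValidationError(
                f"phantom shape must be at least {MIN_PHANTOM_DIM}x{MIN_PHANTOM_DIM}, got {self.shape}"
            )
        if self.n_bodies < 1:
            raise ValidationError("n_bodies must be >= 1")
        if self.dpc_texture_amplitude < 0 or self.dfc_texture_amplitude < 0:
            raise ValidationError("texture amplitudes must be >= 0")
        if any(s < 0 for s in self.noise_sigma_per_channel):
            raise ValidationError("noise sigmas must be >= 0")
        return self


@dataclass
class PhantomTruth:
    """Noisy set, noise-free set, and the channel-exclusive feature masks."""

    tri: TriContrastSet
    clean: TriContrastSet
    dpc_only_mask: np.ndarray = field(repr=False)
    dfc_only_mask: np.ndarray = field(repr=False)


def _elliptical_bodies(shape, n_bodies, rng):
    """Sum of smooth Gaussian-profile ellipses; returns (field, main-body distance map)."""
    M, N = shape
    ii, jj = np.mgrid[0:M, 0:N].astype(np.float64)
    acc = np.zeros(shape)
    main_q = None
    for b in range(n_bodies):
        # first body is the large central "bone"; the rest are satellites
        if b == 0:
            ci, cj = M * 0.5, N * 0.5
            ri, rj = M * 0.22, N * 0.14
            amp = 0.9
        else:
            ci = rng.uniform(0.2, 0.8) * M
            cj = rng.uniform(0.2, 0.8) * N
            ri = rng.uniform(0.06, 0.14) * M
            rj = rng.uniform(0.06, 0.14) * N
            amp = rng.uniform(0.3, 0.6)
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (ii - ci) * ct + (jj - cj) * st
        v = -(ii - ci) * st + (jj - cj) * ct
        q = (u / ri) ** 2 + (v / rj) ** 2  # squared elliptical radius
        acc += amp * np.exp(-0.5 * q)
        if b == 0:
            main_q = q
    return acc, main_q


def _bandpass_texture(shape, rng, low_sigma, high_sigma):
    """Zero-mean band-limited noise, unit peak amplitude."""
    noise = rng.standard_normal(shape)
    band = ndimage.gaussian_filter(noise, low_sigma) - ndimage.gaussian_filter(noise, high_sigma)
    peak = np.abs(band).max()
    return band / peak if peak > 0 else band


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate one seeded tri-contrast phantom with ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    M, N = spec.shape

    bodies, main_q = _elliptical_bodies(spec.shape, spec.n_bodies, rng)
    ac_clean = np.clip(bodies, 0.0, 1.0)

    # channel-exclusive regions on the main body: trabecular interior for
    # DPC, cortical rim for DFC; disjoint by construction (q bands)
    dpc_only_mask = main_q <= 0.55
    dfc_only_mask = (main_q > 0.7) & (main_q <= 1.3)

    # DPC: directional first derivative of the anatomy (refraction is the
    # gradient of the phase shift), rescaled to [0,1]
    d_rows = np.gradient(ac_clean, axis=0)
    dpc_clean = normalize(d_rows)
    trabecular = _bandpass_texture(spec.shape, rng, low_sigma=1.0, high_sigma=3.0)
    dpc_clean = dpc_clean + spec.dpc_texture_amplitude * trabecular * dpc_only_mask
    dpc_clean = np.clip(dpc_clean, 0.0, 1.0)

    # DFC: low background, bright fine-grain scattering texture on the rim
    dfc_clean = np.full(spec.shape, 0.08)
    grain = _bandpass_texture(spec.shape, rng, low_sigma=0.5, high_sigma=1.5)
    dfc_clean = dfc_clean + spec.dfc_texture_amplitude * (0.75 + 0.25 * grain) * dfc_only_mask
    dfc_clean = np.clip(dfc_clean, 0.0, 1.0)

    clean = TriContrastSet(ac_clean, dpc_clean, dfc_clean)

    sig_ac, sig_dpc, sig_dfc = spec.noise_sigma_per_channel
    if sig_ac == sig_dpc == sig_dfc == 0.0:
        noisy = TriContrastSet(ac_clean.copy(), dpc_clean.copy(), dfc_clean.copy())
    else:
        noisy = TriContrastSet(
            np.clip(ac_clean + sig_ac * rng.standard_normal((M, N)), 0.0, 1.0),
            np.clip(dpc_clean + sig_dpc * rng.standard_normal((M, N)), 0.0, 1.0),
            np.clip(dfc_clean + sig_dfc * rng.standard_normal((M, N)), 0.0, 1.0),
        )

    return PhantomTruth(tri=noisy, clean=clean, dpc_only_mask=dpc_only_mask, dfc_only_mask=dfc_only_mask)
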