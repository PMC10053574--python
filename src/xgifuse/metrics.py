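"""Fusion quality metrics for three-input fusion.

Nine figures of merit, computed either on the full frame or on a
rectangular region of interest (ROI):

==========  =========================================================
ES          edge-preservation strength transferred from the inputs
SF          spatial frequency (RMS of first differences)
SD          standard deviation (population, image contrast)
H           Shannon entropy over a 256-level quantisation, in bits
FMI         feature mutual information (gradient-magnitude features)
FSIM        feature similarity (phase congruency x gradient magnitude)
FF          fusion factor: summed channel-vs-fused mutual information
SSIM        structural similarity, 11x11 Gaussian windows
PSD         radially averaged power spectral density curve
==========  =========================================================

Scalar metrics that compare the fused image against the three source
channels (ES, FMI, FSIM, FF, SSIM) use all four images; SF, SD, H and
PSD are single-image statistics of the fused result.

Histogram-based quantities (H, MI, FMI) quantise [0, 1] intensities
onto 256 uniform levels — the 8-bit convention.  Logarithms are base 2
throughout, so entropies and mutual informations are in bits and the
identity MI(A, A) = H(A) holds exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage, signal

from .errors import ValidationError
from .image_io import TriContrastSet, validate_image

_EPS = 1e-12

# ---------------------------------------------------------------------------
# single-image statistics


def spatial_frequency(image: np.ndarray) -> float:
    """SF = sqrt(RF^2 + CF^2); RF/CF are RMS first differences along
    rows/columns, normalised by the full pixel count M*N."""
    Z = validate_image(image)
    M, N = Z.shape
    rf2 = np.sum((Z[:, 1:] - Z[:, :-1]) ** 2) / (M * N)
    cf2 = np.sum((Z[1:, :] - Z[:-1, :]) ** 2) / (M * N)
    return float(np.sqrt(rf2 + cf2))


def standard_deviation(image: np.ndarray) -> float:
    """Population standard deviation — the contrast measure."""
    Z = validate_image(image)
    if Z.max() == Z.min():
        return 0.0  # exact for constants (mean round-off otherwise leaks in)
    return float(np.sqrt(np.mean((Z - Z.mean()) ** 2)))


def quantize(image: np.ndarray, levels: int = 256) -> np.ndarray:
    """Uniform quantisation of [0, 1] intensities onto integer levels."""
    q = np.floor(np.asarray(image, dtype=np.float64) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def entropy(image: np.ndarray, levels: int = 256) -> float:
    """Shannon entropy in bits over a uniform ``levels``-bin histogram."""
    q = quantize(image, levels)
    counts = np.bincount(q.ravel(), minlength=levels)
    p = counts / counts.sum()
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


# ---------------------------------------------------------------------------
# mutual information family


def mutual_information(a: np.ndarray, b: np.ndarray, levels: int = 256) -> float:
    """MI in bits from the ``levels`` x ``levels`` joint histogram."""
    a = validate_image(a)
    b = validate_image(b)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    qa = quantize(a, levels).ravel()
    qb = quantize(b, levels).ravel()
    joint = np.bincount(qa * levels + qb, minlength=levels * levels).astype(np.float64)
    joint = joint.reshape(levels, levels) / joint.sum()
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    denom = np.outer(pa, pb)
    return float(np.sum(joint[nz] * np.log2(joint[nz] / denom[nz])))


def fusion_factor(tri: TriContrastSet, fused: np.ndarray, levels: int = 256) -> float:
    """FF = MI(AC, F) + MI(DPC, F) + MI(DFC, F)."""
    return float(sum(mutual_information(ch, fused, levels) for ch in tri.channels()))


def _gradient_feature(image: np.ndarray) -> np.ndarray:
    """Sobel gradient-magnitude feature, max-normalised to [0, 1]."""
    g = _sobel_magnitude(image)
    peak = g.max()
    return g / peak if peak > 0 else g


def feature_mutual_information(tri: TriContrastSet, fused: np.ndarray, levels: int = 256) -> float:
    """FMI: mutual information between gradient-magnitude feature images,
    summed over the three channel-vs-fused pairs."""
    feat_f = _gradient_feature(fused)
    return float(sum(
        mutual_information(_gradient_feature(ch), feat_f, levels)
        for ch in tri.channels()
    ))


# ---------------------------------------------------------------------------
# SSIM


def _gaussian_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2.0 * sigma ** 2))
    w = np.outer(g, g)
    return w / w.sum()


def ssim(a: np.ndarray, b: np.ndarray, *, win_size: int = 11, sigma: float = 1.5,
         k1: float = 0.01, k2: float = 0.03, L: float = 1.0) -> float:
    """Mean structural similarity over sliding Gaussian-weighted windows.

    The per-window statistic uses the weighted local means, population
    variances and cross-covariance; windows are taken fully inside the
    image (no padding) and averaged.
    """
    a = validate_image(a)
    b = validate_image(b)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    if min(a.shape) < 16:
        raise ValidationError("images must be at least 16x16 for windowed SSIM")
    w = _gaussian_window(win_size, sigma)
    mu_a = signal.convolve2d(a, w, mode="valid")
    mu_b = signal.convolve2d(b, w, mode="valid")
    e_aa = signal.convolve2d(a * a, w, mode="valid")
    e_bb = signal.convolve2d(b * b, w, mode="valid")
    e_ab = signal.convolve2d(a * b, w, mode="valid")
    var_a = e_aa - mu_a ** 2
    var_b = e_bb - mu_b ** 2
    cov = e_ab - mu_a * mu_b
    c1 = (k1 * L) ** 2
    c2 = (k2 * L) ** 2
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)
    return float(np.mean(num / den))


def overall_ssim(tri: TriContrastSet, fused: np.ndarray) -> float:
    """Mean of the three channel-vs-fused SSIM values."""
    return float(np.mean([ssim(ch, fused) for ch in tri.channels()]))


# ---------------------------------------------------------------------------
# FSIM: phase congruency x gradient magnitude


def _log_gabor_responses(F: np.ndarray, shape, nscale=4, norient=4,
                         min_wavelength=6.0, mult=2.0, sigma_onf=0.55,
                         d_theta_sigma=1.2):
    """Complex log-Gabor responses per (orientation, scale) of a
    pre-computed FFT ``F``."""
    M, N = shape
    fy = np.fft.fftfreq(M)[:, None]
    fx = np.fft.fftfreq(N)[None, :]
    r = np.hypot(fy, fx)
    r[0, 0] = 1.0  # avoid log(0); the filter is zeroed at DC anyway
    theta = np.arctan2(-fy, fx)
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    theta_sigma = np.pi / norient / d_theta_sigma
    log_sig2 = 2.0 * np.log(sigma_onf) ** 2

    responses = []
    for o in range(norient):
        angle = o * np.pi / norient
        ds = sin_t * np.cos(angle) - cos_t * np.sin(angle)
        dc = cos_t * np.cos(angle) + sin_t * np.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta ** 2) / (2 * theta_sigma ** 2))
        per_scale = []
        for s in range(nscale):
            f0 = 1.0 / (min_wavelength * mult ** s)
            radial = np.exp(-(np.log(r / f0) ** 2) / log_sig2)
            radial[0, 0] = 0.0
            per_scale.append(np.fft.ifft2(F * radial * spread))
        responses.append(per_scale)
    return responses


def phase_congruency(image: np.ndarray) -> np.ndarray:
    """Phase congruency map in [0, 1] from a log-Gabor quadrature bank.

    PC = sum_o |sum_s e_{so}| / (sum_o sum_s |e_{so}| + eps): local
    energy pooled over orientations, normalised by total amplitude —
    maximal where all scales agree in phase (edges, lines), regardless
    of contrast.
    """
    image = validate_image(image)
    F = np.fft.fft2(image)
    responses = _log_gabor_responses(F, image.shape)
    energy = np.zeros(image.shape)
    amplitude = np.zeros(image.shape)
    for per_scale in responses:
        sum_e = np.zeros(image.shape, dtype=complex)
        for e in per_scale:
            sum_e += e
            amplitude += np.abs(e)
        energy += np.abs(sum_e)
    return energy / (amplitude + _EPS)


_SCHARR_X = np.array([[3.0, 0.0, -3.0], [10.0, 0.0, -10.0], [3.0, 0.0, -3.0]]) / 16.0


def _scharr_magnitude(image: np.ndarray) -> np.ndarray:
    gx = ndimage.convolve(image, _SCHARR_X, mode="reflect")
    gy = ndimage.convolve(image, _SCHARR_X.T, mode="reflect")
    return np.hypot(gx, gy)


def fsim(a: np.ndarray, b: np.ndarray, *, T1: float = 0.85, T2: float = 160.0,
         alpha: float = 1.0, beta: float = 1.0) -> float:
    """Feature similarity index from phase congruency and gradient magnitude.

    The pointwise similarity S = S_PC^alpha * S_GM^beta is pooled with
    max(PC_a, PC_b) weights.  T2 is on the 0-255 gradient scale, so
    images are rescaled to 0-255 for the gradient term.
    """
    a = validate_image(a)
    b = validate_image(b)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    if min(a.shape) < 16:
        raise ValidationError("images must be at least 16x16 for FSIM")
    pc_a = phase_congruency(a)
    pc_b = phase_congruency(b)
    gm_a = _scharr_magnitude(a * 255.0)
    gm_b = _scharr_magnitude(b * 255.0)
    s_pc = (2 * pc_a * pc_b + T1) / (pc_a ** 2 + pc_b ** 2 + T1)
    s_gm = (2 * gm_a * gm_b + T2) / (gm_a ** 2 + gm_b ** 2 + T2)
    s = (s_pc ** alpha) * (s_gm ** beta)
    pc_max = np.maximum(pc_a, pc_b)
    return float(np.sum(s * pc_max) / (np.sum(pc_max) + _EPS))


def overall_fsim(tri: TriContrastSet, fused: np.ndarray) -> float:
    """Mean of the three channel-vs-fused FSIM values."""
    return float(np.mean([fsim(ch, fused) for ch in tri.channels()]))


# ---------------------------------------------------------------------------
# edge strength (edge-preservation transfer)

_SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])

# sigmoid constants of the edge-preservation model: (gain, steepness, midpoint)
_ES_STRENGTH = (0.9994, -15.0, 0.5)
_ES_ORIENT = (0.9879, -22.0, 0.8)


def _sobel_fields(image: np.ndarray):
    gx = ndimage.convolve(image, _SOBEL_X, mode="reflect")
    gy = ndimage.convolve(image, _SOBEL_X.T, mode="reflect")
    mag = np.hypot(gx, gy)
    orient = np.mod(np.arctan2(gy, gx), np.pi)  # orientation, period pi
    return mag, orient


def _sobel_magnitude(image: np.ndarray) -> np.ndarray:
    return _sobel_fields(image)[0]


def _edge_preservation(g_x, a_x, g_f, a_f):
    """Per-pixel preservation Q in [0, 1] of one input against the fused."""
    denom = np.maximum(g_x, g_f)
    with np.errstate(invalid="ignore", divide="ignore"):
        G = np.where(denom > 0, np.minimum(g_x, g_f) / np.where(denom > 0, denom, 1.0), 1.0)
    d = np.abs(a_x - a_f)
    d = np.minimum(d, np.pi - d)
    A = 1.0 - d / (np.pi / 2.0)
    Gg, Kg, Sg = _ES_STRENGTH
    Ga, Ka, Sa = _ES_ORIENT
    q_g = Gg / (1.0 + np.exp(Kg * (G - Sg)))
    q_a = Ga / (1.0 + np.exp(Ka * (A - Sa)))
    return q_g * q_a


def edge_strength(tri: TriContrastSet, fused: np.ndarray) -> float:
    """Relative amount of edge information transferred into the fusion.

    Per-pixel edge-preservation values Q_{X,F} (a sigmoid model of the
    relative Sobel strength and orientation agreement) are pooled with
    the inputs' own edge magnitudes as weights.  The value lies in
    [0, 1]; it peaks when every input's edges reappear unchanged in the
    fused image and vanishes when none do.
    """
    fused = validate_image(fused)
    if fused.shape != tri.shape:
        raise ValidationError(f"shape mismatch: {fused.shape} vs {tri.shape}")
    g_f, a_f = _sobel_fields(fused)
    num = np.zeros(fused.shape)
    den = np.zeros(fused.shape)
    for ch in tri.channels():
        g_x, a_x = _sobel_fields(ch)
        q = _edge_preservation(g_x, a_x, g_f, a_f)
        num += q * g_x
        den += g_x
    total = den.sum()
    if total == 0:
        return 0.0
    return float(num.sum() / total)


# ---------------------------------------------------------------------------
# power spectral density


def periodogram(image: np.ndarray) -> np.ndarray:
    """2-D periodogram |F|^2 / (M*N); Parseval: its sum equals sum(I^2)."""
    Z = validate_image(image)
    F = np.fft.fft2(Z)
    return (np.abs(F) ** 2) / Z.size


def psd_curve(image: np.ndarray):
    """Radially averaged power spectral density.

    Periodogram bins are pooled into integer-radius annuli of the
    wavenumber grid, from the DC bin up to the Nyquist ring
    min(M, N) // 2; each bin holds the mean power of its annulus.
    Returns an array of (radius, power) rows.
    """
    P = periodogram(image)
    M, N = P.shape
    ky = np.fft.fftfreq(M) * M
    kx = np.fft.fftfreq(N) * N
    radius = np.rint(np.hypot(ky[:, None], kx[None, :])).astype(np.int64)
    kmax = min(M, N) // 2
    sums = np.bincount(radius.ravel(), weights=P.ravel(), minlength=kmax + 1)
    counts = np.bincount(radius.ravel(), minlength=kmax + 1)
    k = np.arange(kmax + 1)
    power = sums[: kmax + 1] / np.maximum(counts[: kmax + 1], 1)
    return np.column_stack([k, power])


# ---------------------------------------------------------------------------
# report


@dataclass
class MetricReport:
    es: float
    sf: float
    sd: float
    entropy: float
    fmi: float
    fsim: float
    ff: float
    ssim: float
    psd: list = field(repr=False)
    roi: tuple | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def format_table(self) -> str:
        rows = [("ES", self.es), ("H", self.entropy), ("SD", self.sd),
                ("SF", self.sf), ("FMI", self.fmi), ("FF", self.ff),
                ("SSIM", self.ssim), ("FSIM", self.fsim)]
        width = max(len(n) for n, _ in rows)
        lines = [f"{name:<{width}}  {value:.4f}" for name, value in rows]
        return "\n".join(lines)


def crop_roi(image: np.ndarray, roi: tuple) -> np.ndarray:
    r0, c0, r1, c1 = roi
    M, N = image.shape
    if not (0 <= r0 < r1 <= M and 0 <= c0 < c1 <= N):
        raise ValidationError(f"ROI {roi} invalid or empty for image of shape {image.shape}")
    return image[r0:r1, c0:c1]


def report(tri: TriContrastSet, fused: np.ndarray, roi: tuple | None = None) -> MetricReport:
    """Compute every metric, optionally on an ROI crop of all images."""
    fused = validate_image(fused)
    if fused.shape != tri.shape:
        raise ValidationError(f"shape mismatch: {fused.shape} vs {tri.shape}")
    if roi is not None:
        tri = tri.map(lambda im: crop_roi(im, roi))
        fused = crop_roi(fused, roi)
    return MetricReport(
        es=edge_strength(tri, fused),
        sf=spatial_frequency(fused),
        sd=standard_deviation(fused),
        entropy=entropy(fused),
        fmi=feature_mutual_information(tri, fused),
        fsim=overall_fsim(tri, fused),
        ff=fusion_factor(tri, fused),
        ssim=overall_ssim(tri, fused),
        psd=psd_curve(fused).tolist(),
        roi=roi,
    )
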