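"""Independent scalar/brute-force reference implementations.

Everything here is written as plain double loops straight from the
defining formulas, deliberately independent of the vectorised package
code it is used to check.
"""

import math

import numpy as np


# ---------------------------------------------------------------------------
# spiking cortical model: scalar reference iteration


def scm_scalar(stimulus, f, g, h, beta, W, k, theta_init=1.0):
    """Non-vectorised SCM reference; returns integer spike totals."""
    S = np.asarray(stimulus, dtype=float)
    M, N = S.shape
    W = np.asarray(W, dtype=float)
    U = np.zeros((M, N))
    Y = np.zeros((M, N))
    Theta = np.full((M, N), float(theta_init))
    counts = np.zeros((M, N), dtype=np.int64)
    for _ in range(k):
        U_new = np.zeros((M, N))
        for i in range(M):
            for j in range(N):
                link = 0.0
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ki, kj = i + di, j + dj
                        if 0 <= ki < M and 0 <= kj < N:
                            # correlation with the flipped kernel = convolution
                            link += W[1 - di, 1 - dj] * Y[ki, kj]
                U_new[i, j] = f * U[i, j] + S[i, j] * (1.0 + beta * link)
        U = U_new
        Y_new = np.zeros((M, N))
        for i in range(M):
            for j in range(N):
                if U[i, j] > Theta[i, j]:
                    Y_new[i, j] = 1.0
                    counts[i, j] += 1
        Y = Y_new
        Theta = g * Theta + h * Y
    return counts


# ---------------------------------------------------------------------------
# fusion rules: scalar case enumeration


def fuse_lowpass_scalar(l_ac, l_dpc, l_dfc, t_ac, t_dpc, t_dfc, a):
    """One-pixel low-frequency rule: strictly greatest weighted score,
    ties by priority AC > DPC > DFC."""
    s_ac, s_dpc, s_dfc = a * t_ac, (1 - a) * t_dpc, (1 - a) * t_dfc
    if s_ac >= s_dpc and s_ac >= s_dfc:
        return l_ac
    if s_dpc >= s_dfc:
        return l_dpc
    return l_dfc


def fuse_highpass_scalar(h_ac, h_dpc, h_dfc, t_ac, t_dpc, t_dfc, b, c, d, tth):
    """One-pixel seven-case high-frequency rule."""
    def sig(x, z):
        return (x - z) > tth

    dom_ac = sig(t_ac, t_dpc) and sig(t_ac, t_dfc)
    dom_dpc = sig(t_dpc, t_ac) and sig(t_dpc, t_dfc)
    dom_dfc = sig(t_dfc, t_ac) and sig(t_dfc, t_dpc)
    if dom_ac:
        return h_ac
    if dom_dpc:
        return h_dpc
    if dom_dfc:
        return h_dfc
    if sig(t_ac, t_dfc) and sig(t_dpc, t_dfc):
        return 0.5 * (h_ac + h_dpc)
    if sig(t_ac, t_dpc) and sig(t_dfc, t_dpc):
        return 0.5 * (h_ac + h_dfc)
    if sig(t_dpc, t_ac) and sig(t_dfc, t_ac):
        return 0.5 * (h_dpc + h_dfc)
    return b * h_ac + c * h_dpc + d * h_dfc


# ---------------------------------------------------------------------------
# metric oracles: direct double-loop evaluations


def sf_scalar(Z):
    M, N = Z.shape
    rf = 0.0
    for i in range(M):
        for j in range(1, N):
            rf += (Z[i, j] - Z[i, j - 1]) ** 2
    cf = 0.0
    for i in range(1, M):
        for j in range(N):
            cf += (Z[i, j] - Z[i - 1, j]) ** 2
    return math.sqrt(rf / (M * N) + cf / (M * N))


def sd_scalar(Z):
    M, N = Z.shape
    mu = sum(Z[i, j] for i in range(M) for j in range(N)) / (M * N)
    var = sum((Z[i, j] - mu) ** 2 for i in range(M) for j in range(N)) / (M * N)
    return math.sqrt(var)


def _quant(Z, levels):
    q = np.floor(Z * levels).astype(int)
    return np.clip(q, 0, levels - 1)


def entropy_scalar(Z, levels=256):
    q = _quant(Z, levels)
    counts = {}
    for v in q.ravel():
        counts[v] = counts.get(v, 0) + 1
    n = q.size
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def mi_scalar(A, B, levels=256):
    qa = _quant(A, levels).ravel()
    qb = _quant(B, levels).ravel()
    n = qa.size
    joint = {}
    pa = {}
    pb = {}
    for x, y in zip(qa, qb):
        joint[(x, y)] = joint.get((x, y), 0) + 1
        pa[x] = pa.get(x, 0) + 1
        pb[y] = pb.get(y, 0) + 1
    mi = 0.0
    for (x, y), cnt in joint.items():
        p = cnt / n
        mi += p * math.log2(p / ((pa[x] / n) * (pb[y] / n)))
    return mi


def ssim_scalar(A, B, win=11, sigma=1.5, k1=0.01, k2=0.03, L=1.0):
    """Double-loop over all fully-interior windows, Eq.-style statistic."""
    ax = np.arange(win) - (win - 1) / 2.0
    gk = np.exp(-(ax ** 2) / (2 * sigma ** 2))
    w = np.outer(gk, gk)
    w /= w.sum()
    M, N = A.shape
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
    vals = []
    for i in range(M - win + 1):
        for j in range(N - win + 1):
            wa = A[i:i + win, j:j + win]
            wb = B[i:i + win, j:j + win]
            mu_a = (w * wa).sum()
            mu_b = (w * wb).sum()
            va = (w * wa * wa).sum() - mu_a ** 2
            vb = (w * wb * wb).sum() - mu_b ** 2
            cov = (w * wa * wb).sum() - mu_a * mu_b
            vals.append(((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                        / ((mu_a ** 2 + mu_b ** 2 + c1) * (va + vb + c2)))
    return float(np.mean(vals))


def _sobel_scalar(Z):
    """Sobel magnitude/orientation with edge replication at borders."""
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
    M, N = Z.shape
    P = np.pad(Z, 1, mode="edge")
    mag = np.zeros((M, N))
    ori = np.zeros((M, N))
    for i in range(M):
        for j in range(N):
            gx = gy = 0.0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    # ndimage.convolve applies the flipped kernel
                    gx += kx[1 - di, 1 - dj] * P[i + 1 + di, j + 1 + dj]
                    gy += kx.T[1 - di, 1 - dj] * P[i + 1 + di, j + 1 + dj]
            mag[i, j] = math.hypot(gx, gy)
            ori[i, j] = math.atan2(gy, gx) % math.pi
    return mag, ori


def edge_strength_scalar(channels, F):
    """Per-pixel double-loop Sobel edge-preservation pooling."""
    gf, af = _sobel_scalar(F)
    M, N = F.shape
    num = den = 0.0
    for X in channels:
        gx, ax = _sobel_scalar(X)
        for i in range(M):
            for j in range(N):
                lo, hi = min(gx[i, j], gf[i, j]), max(gx[i, j], gf[i, j])
                G = lo / hi if hi > 0 else 1.0
                d = abs(ax[i, j] - af[i, j])
                d = min(d, math.pi - d)
                A = 1.0 - d / (math.pi / 2.0)
                qg = 0.9994 / (1.0 + math.exp(-15.0 * (G - 0.5)))
                qa = 0.9879 / (1.0 + math.exp(-22.0 * (A - 0.8)))
                num += qg * qa * gx[i, j]
                den += gx[i, j]
    return num / den if den > 0 else 0.0


def psd_scalar(Z):
    """Radial PSD via an explicit double-loop DFT (small images only)."""
    M, N = Z.shape
    F = np.zeros((M, N), dtype=complex)
    for u in range(M):
        for v in range(N):
            s = 0.0 + 0.0j
            for i in range(M):
                for j in range(N):
                    s += Z[i, j] * np.exp(-2j * np.pi * (u * i / M + v * j / N))
            F[u, v] = s
    P = np.abs(F) ** 2 / (M * N)
    ky = np.fft.fftfreq(M) * M
    kx = np.fft.fftfreq(N) * N
    kmax = min(M, N) // 2
    sums = np.zeros(kmax + 1)
    counts = np.zeros(kmax + 1)
    for u in range(M):
        for v in range(N):
            r = int(round(math.hypot(ky[u], kx[v])))
            if r <= kmax:
                sums[r] += P[u, v]
                counts[r] += 1
    return np.column_stack([np.arange(kmax + 1), sums / np.maximum(counts, 1)])
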