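"""NSCT-SCM band mixing: the core coefficient-selection fusion rules.

Each denoised channel is decomposed by the NSCT; every sub-band of every
channel is fed (as a magnitude-normalised stimulus) to the spiking
cortical model, whose per-pixel firing totals ("ignition matrices")
score local salience.  Coefficients are then selected or blended
pixelwise:

* Low-frequency band — winner-take-all on weighted ignition scores
  a*T_AC vs (1-a)*T_DPC vs (1-a)*T_DFC.  The weight a biases the fused
  low-pass toward the attenuation channel so the result reads like a
  conventional radiograph; a closer to 1 means closer to AC.

* High-frequency bands — a significance-threshold rule with seven
  outcomes.  Channel X "significantly exceeds" channel Z when
  T_X - T_Z > T_th.  If exactly one channel significantly exceeds both
  others, its coefficient is taken; if two channels each significantly
  exceed the remaining one, the two are averaged; otherwise all three
  are blended with weights (b, c, d), b + c + d = 1.  Every outcome is a
  convex combination of the three input coefficients.

The fused coefficient set is inverted back to the image domain.  No
rescaling is applied here — the enhancement stage owns the output range.
"""

from __future__ import annotations

import numpy as np

from .config import FusionConfig
from .errors import ValidationError
from .image_io import TriContrastSet
from .nsct import NSCTCoefficients, nsct_forward, nsct_inverse
from .scm import prepare_stimulus, scm_ignition

_WEIGHT_SUM_TOL = 1e-9


def _check_shapes(*arrays):
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValidationError(f"band/ignition shapes differ: {sorted(shapes)}")


def fuse_lowpass(L_ac, L_dpc, L_dfc, T_ac, T_dpc, T_dfc, a: float) -> np.ndarray:
    """Winner-take-all low-frequency rule.

    Pixelwise scores are a*T_AC, (1-a)*T_DPC, (1-a)*T_DFC; the channel
    with the strictly greatest score wins, ties resolved by the priority
    AC > DPC > DFC (the attenuation bias is the point of the rule).
    """
    if not (0.0 < a < 1.0):
        raise ValidationError(f"low-frequency weight a must lie in (0,1), got {a}")
    _check_shapes(L_ac, L_dpc, L_dfc, T_ac, T_dpc, T_dfc)
    s_ac = a * np.asarray(T_ac, dtype=np.float64)
    s_dpc = (1.0 - a) * np.asarray(T_dpc, dtype=np.float64)
    s_dfc = (1.0 - a) * np.asarray(T_dfc, dtype=np.float64)
    pick_ac = (s_ac >= s_dpc) & (s_ac >= s_dfc)
    pick_dpc = ~pick_ac & (s_dpc >= s_dfc)
    out = np.where(pick_ac, L_ac, np.where(pick_dpc, L_dpc, L_dfc))
    return out


def fuse_highpass(H_ac, H_dpc, H_dfc, T_ac, T_dpc, T_dfc,
                  weights_bcd, Tth: float) -> np.ndarray:
    """Seven-case high-frequency rule driven by ignition significance.

    Decision order (total and unambiguous for every ignition triple):
    first "exactly one channel significantly exceeds both others" (take
    it), then "two channels each significantly exceed the remaining one"
    (average the pair; the pair conditions are mutually exclusive), else
    the weighted three-channel blend.
    """
    b, c, d = weights_bcd
    if abs(b + c + d - 1.0) > _WEIGHT_SUM_TOL:
        raise ValidationError(f"high-frequency weights must sum to 1, got {b + c + d!r}")
    if Tth < 0:
        raise ValidationError("significance threshold Tth must be >= 0")
    _check_shapes(H_ac, H_dpc, H_dfc, T_ac, T_dpc, T_dfc)

    T_ac = np.asarray(T_ac, dtype=np.float64)
    T_dpc = np.asarray(T_dpc, dtype=np.float64)
    T_dfc = np.asarray(T_dfc, dtype=np.float64)

    def sig(x, z):  # "x significantly larger than z"
        return (x - z) > Tth

    dom_ac = sig(T_ac, T_dpc) & sig(T_ac, T_dfc)
    dom_dpc = sig(T_dpc, T_ac) & sig(T_dpc, T_dfc)
    dom_dfc = sig(T_dfc, T_ac) & sig(T_dfc, T_dpc)
    # pair P = {X, Y} where both significantly exceed the third channel;
    # evaluated only where no single channel dominates both others
    no_dom = ~(dom_ac | dom_dpc | dom_dfc)
    pair_ac_dpc = no_dom & sig(T_ac, T_dfc) & sig(T_dpc, T_dfc)
    pair_ac_dfc = no_dom & sig(T_ac, T_dpc) & sig(T_dfc, T_dpc)
    pair_dpc_dfc = no_dom & sig(T_dpc, T_ac) & sig(T_dfc, T_ac)

    blend = b * H_ac + c * H_dpc + d * H_dfc
    out = np.select(
        [dom_ac, dom_dpc, dom_dfc, pair_ac_dpc, pair_ac_dfc, pair_dpc_dfc],
        [
            H_ac, H_dpc, H_dfc,
            0.5 * (H_ac + H_dpc),
            0.5 * (H_ac + H_dfc),
            0.5 * (H_dpc + H_dfc),
        ],
        default=np.nan,
    )
    # remaining pixels: no channel stands out -> three-channel blend
    rest = ~(dom_ac | dom_dpc | dom_dfc | pair_ac_dpc | pair_ac_dfc | pair_dpc_dfc)
    out = np.where(rest, blend, out)
    return out


def band_ignitions(coeffs: NSCTCoefficients, scm_params) -> NSCTCoefficients:
    """Ignition matrix of every band of one channel's decomposition.

    Returned in the same container type so band matching across channels
    stays positional (all channels share the same filter bank).
    """
    low_T = scm_ignition(prepare_stimulus(coeffs.lowpass), scm_params)
    high_T = [
        [scm_ignition(prepare_stimulus(band), scm_params) for band in bands]
        for bands in coeffs.highpass
    ]
    return NSCTCoefficients(lowpass=low_T, highpass=high_T, levels=coeffs.levels)


def fuse_tricontrast(tri: TriContrastSet, config: FusionConfig | None = None,
                     manifest=None) -> np.ndarray:
    """Fuse a denoised AC/DPC/DFC triple into one image (no enhancement)."""
    config = (config or FusionConfig()).validate()
    levels = config.nsct_levels

    dec = {name: nsct_forward(chan, levels)
           for name, chan in zip(("ac", "dpc", "dfc"), tri.channels())}
    if manifest is not None:
        manifest.record("nsct_forward", levels=list(levels),
                        n_highpass=dec["ac"].n_highpass)

    ign = {name: band_ignitions(dec[name], config.scm) for name in dec}
    if manifest is not None:
        manifest.record("scm_ignition", iterations=config.scm.iterations)

    fused_low = fuse_lowpass(
        dec["ac"].lowpass, dec["dpc"].lowpass, dec["dfc"].lowpass,
        ign["ac"].lowpass, ign["dpc"].lowpass, ign["dfc"].lowpass,
        config.low_weight_a,
    )
    fused_high = []
    for j in range(len(levels)):
        scale_bands = []
        for m in range(2 ** levels[j]):
            scale_bands.append(fuse_highpass(
                dec["ac"].highpass[j][m], dec["dpc"].highpass[j][m], dec["dfc"].highpass[j][m],
                ign["ac"].highpass[j][m], ign["dpc"].highpass[j][m], ign["dfc"].highpass[j][m],
                config.high_weights_bcd, config.high_threshold_Tth,
            ))
        fused_high.append(scale_bands)

    fused = nsct_inverse(NSCTCoefficients(lowpass=fused_low, highpass=fused_high, levels=levels))
    if manifest is not None:
        manifest.record("band_mixing", a=config.low_weight_a,
                        bcd=list(config.high_weights_bcd), Tth=config.high_threshold_Tth)
    return fused
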