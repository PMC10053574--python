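"""Pipeline configuration.

All tunable parameters of the three-step fusion scheme live in one
:class:`FusionConfig` so a run is fully described by a single YAML
document plus a seed.  Defaults follow the published parameterisation of
the scheme: 5x5 Wiener window; NSCT decomposition levels (4, 4, 4, 4);
SCM constants f=0.8, g=0.7, h=20, k=200 iterations with the eight-
neighbour synaptic kernel; low-frequency weight a=0.55; high-frequency
blend weights (b, c, d) = (0.41, 0.29, 0.30) with significance threshold
T_th=1; CLAHE on a 5x5 tile grid with clip limit 0.00125 and 500
histogram bins; sharpening guard alpha=3; sigmoid constants
lambda1=4.8, lambda2=0.49.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import ImageIOError, ValidationError

_WEIGHT_SUM_TOL = 1e-9

#: Eight-neighbour synaptic weight kernel (zero centre: no self-linking).
DEFAULT_SCM_KERNEL = (
    (0.1091, 0.1409, 0.1091),
    (0.1409, 0.0, 0.1409),
    (0.1091, 0.1409, 0.1091),
)


@dataclass
class SCMParams:
    """Constants of the spiking cortical model iteration."""

    f: float = 0.8          # membrane-potential attenuation, 0 < f < 1
    g: float = 0.7          # threshold attenuation, 0 < g < 1
    h: float = 20.0         # absolute-refractory recharge, > 0
    beta: float = 0.3       # linking strength of the neighbourhood term
    kernel: tuple = DEFAULT_SCM_KERNEL
    iterations: int = 200   # k, total iterative count
    theta_init: float = 1.0  # initial dynamic threshold

    def validate(self) -> "SCMParams":
        if not (0.0 < self.f < 1.0):
            raise ValidationError(f"SCM f must lie in (0,1), got {self.f}")
        if not (0.0 < self.g < 1.0):
            raise ValidationError(f"SCM g must lie in (0,1), got {self.g}")
        if self.h <= 0:
            raise ValidationError(f"SCM h must be positive, got {self.h}")
        if self.iterations < 1:
            raise ValidationError("SCM iteration count k must be >= 1")
        W = np.asarray(self.kernel, dtype=float)
        if W.shape != (3, 3):
            raise ValidationError(f"SCM kernel must be 3x3, got {W.shape}")
        if W[1, 1] != 0.0:
            raise ValidationError("SCM kernel centre must be 0 (no self-linking)")
        return self

    @property
    def W(self) -> np.ndarray:
        return np.asarray(self.kernel, dtype=float)


@dataclass
class EnhanceParams:
    """Constants of the CLAHE / adaptive-sharpening / sigmoid stage."""

    clahe_tiles: tuple = (5, 5)
    clahe_clip: float = 0.00125
    clahe_bins: int = 500
    sharpen_alpha: float = 3.0
    sharpen_C_grid: tuple = (0.0, 5.0, 0.05)  # (min, max, step) entropy search
    lambda1: float = 4.8
    lambda2: float = 0.49

    def validate(self) -> "EnhanceParams":
        if len(self.clahe_tiles) != 2 or min(self.clahe_tiles) < 1:
            raise ValidationError("clahe_tiles must be two positive integers")
        if not (0.0 < self.clahe_clip < 1.0):
            raise ValidationError("clahe_clip must lie in (0,1)")
        if self.clahe_bins < 2:
            raise ValidationError("clahe_bins must be >= 2")
        if self.sharpen_alpha <= 0:
            raise ValidationError("sharpen_alpha must be positive")
        lo, hi, step = self.sharpen_C_grid
        if step <= 0 or hi < lo:
            raise ValidationError("sharpen_C_grid must be (min, max, step>0) with max >= min")
        return self


@dataclass
class FusionConfig:
    """All tunable parameters of the three pipeline steps."""

    wiener_window: tuple = (5, 5)
    nsct_levels: tuple = (4, 4, 4, 4)
    scm: SCMParams = field(default_factory=SCMParams)
    low_weight_a: float = 0.55
    high_weights_bcd: tuple = (0.41, 0.29, 0.30)
    high_threshold_Tth: float = 1.0
    enhance: EnhanceParams = field(default_factory=EnhanceParams)
    seed: int = 0

    def validate(self) -> "FusionConfig":
        X, Y = self.wiener_window
        if X % 2 == 0 or Y % 2 == 0 or X < 3 or Y < 3:
            raise ValidationError(f"wiener_window dims must be odd and >= 3, got {(X, Y)}")
        if not self.nsct_levels or any(l < 1 for l in self.nsct_levels):
            raise ValidationError("nsct_levels must be a non-empty vector of integers >= 1")
        if not (0.0 < self.low_weight_a < 1.0):
            raise ValidationError(f"low_weight_a must lie in the open interval (0,1), got {self.low_weight_a}")
        b, c, d = self.high_weights_bcd
        if abs((b + c + d) - 1.0) > _WEIGHT_SUM_TOL:
            raise ValidationError(f"high_weights_bcd must sum to 1, got sum {b + c + d!r}")
        if self.high_threshold_Tth < 0:
            raise ValidationError("high_threshold_Tth must be >= 0")
        self.scm.validate()
        self.enhance.validate()
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def _apply_overrides(cfg: FusionConfig, doc: dict) -> FusionConfig:
    doc = copy.deepcopy(doc)

    def take(obj, key, value, cast=None):
        if not hasattr(obj, key):
            raise ValidationError(f"unknown configuration key: {key!r}")
        setattr(obj, key, cast(value) if cast else value)

    for key, value in doc.items():
        if key == "scm":
            if not isinstance(value, dict):
                raise ValidationError("scm section must be a mapping")
            for k, v in value.items():
                if k == "kernel":
                    v = tuple(tuple(float(x) for x in row) for row in v)
                take(cfg.scm, k, v)
        elif key == "enhance":
            if not isinstance(value, dict):
                raise ValidationError("enhance section must be a mapping")
            for k, v in value.items():
                if k in ("clahe_tiles", "sharpen_C_grid"):
                    v = tuple(v)
                take(cfg.enhance, k, v)
        elif key in ("wiener_window", "nsct_levels", "high_weights_bcd"):
            take(cfg, key, tuple(value))
        else:
            take(cfg, key, value)
    return cfg


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> FusionConfig:
    """Build a validated :class:`FusionConfig`.

    Parameters
    ----------
    path:
        Optional YAML document.  Absent file path or absent keys fall
        back to the defaults above.  Unknown keys are rejected.
    overrides:
        Optional in-memory mapping applied after the file, same schema.
    """
    cfg = FusionConfig()
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ImageIOError(f"config file not found: {p}")
        doc = yaml.safe_load(p.read_text()) or {}
        if not isinstance(doc, dict):
            raise ValidationError(f"config document must be a mapping: {p}")
        cfg = _apply_overrides(cfg, doc)
    if overrides:
        cfg = _apply_overrides(cfg, overrides)
    return cfg.validate()
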