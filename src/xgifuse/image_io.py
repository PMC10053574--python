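"""Reading, writing and normalising radiograph channels.

All internal processing operates on 2-D float64 arrays with intensities
in [0, 1] ("radiograph images").  A Talbot-Lau acquisition yields three
co-registered channels — attenuation (AC), differential phase (DPC) and
dark-field (DFC) — bundled here as a :class:`TriContrastSet`; no
registration step exists anywhere in the pipeline because the three
channels come out of the interferometric retrieval already aligned.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

from .errors import ImageIOError, ValidationError

logger = logging.getLogger("xgifuse")

MIN_DIM = 8  # smallest side supporting the 5x5 windows and filter banks

# Rec. 601 luminance weights for collapsing RGB inputs.
_LUMA = np.array([0.299, 0.587, 0.114])


def validate_image(pixels: np.ndarray, *, name: str = "image") -> np.ndarray:
    """Check the radiograph-image contract and return a float64 view."""
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < MIN_DIM or arr.shape[1] < MIN_DIM:
        raise ValidationError(f"{name} must be at least {MIN_DIM}x{MIN_DIM}, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def normalize(pixels: np.ndarray) -> np.ndarray:
    """Linear min-max rescale to [0, 1].

    A constant image maps to all zeros (the degenerate-range convention);
    an already-normalised image is reproduced exactly, so the map is
    idempotent.
    """
    arr = np.asarray(pixels, dtype=np.float64)
    lo = arr.min()
    hi = arr.max()
    if hi == lo:
        logger.warning("degenerate intensity range (constant image); normalising to zeros")
        return np.zeros_like(arr)
    if lo == 0.0 and hi == 1.0:
        return arr.copy()
    return (arr - lo) / (hi - lo)


@dataclass
class TriContrastSet:
    """The co-registered AC / DPC / DFC triple of one acquisition."""

    ac: np.ndarray
    dpc: np.ndarray
    dfc: np.ndarray

    def __post_init__(self):
        self.ac = validate_image(self.ac, name="ac")
        self.dpc = validate_image(self.dpc, name="dpc")
        self.dfc = validate_image(self.dfc, name="dfc")
        if not (self.ac.shape == self.dpc.shape == self.dfc.shape):
            raise ValidationError(
                "AC/DPC/DFC shapes must be identical, got "
                f"{self.ac.shape}, {self.dpc.shape}, {self.dfc.shape}"
            )

    @property
    def shape(self) -> tuple:
        return self.ac.shape

    def channels(self):
        return (self.ac, self.dpc, self.dfc)

    def map(self, fn) -> "TriContrastSet":
        """Apply ``fn`` to each channel, returning a new set."""
        return TriContrastSet(fn(self.ac), fn(self.dpc), fn(self.dfc))


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF or PNG channel and normalise it to [0, 1].

    8/16-bit integer and floating-point single-channel images are
    accepted; RGB inputs are collapsed by the Rec. 601 luminance
    combination with a logged warning.  The original dtype and range are
    logged for the run manifest.
    """
    p = Path(path)
    if not p.exists():
        raise ImageIOError(f"cannot read image: no such file {p}")
    try:
        if p.suffix.lower() in (".tif", ".tiff"):
            raw = tifffile.imread(p)
        else:
            raw = iio.imread(p)
    except ImageIOError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap any decoder failure
        raise ImageIOError(f"unreadable image file {p}: {exc}") from exc

    raw = np.asarray(raw)
    if raw.size == 0:
        raise ValidationError(f"zero-area image: {p}")
    if raw.ndim == 3 and raw.shape[-1] in (3, 4):
        logger.warning("RGB input %s collapsed to luminance (Rec. 601)", p)
        raw = raw[..., :3].astype(np.float64) @ _LUMA
    if raw.ndim != 2:
        raise ValidationError(f"expected a single-channel 2-D image, got shape {raw.shape}: {p}")

    logger.info(
        "read %s: shape=%s dtype=%s range=[%s, %s]",
        p, raw.shape, raw.dtype, np.min(raw), np.max(raw),
    )
    return validate_image(normalize(raw), name=str(p))


def write_image(path: str | Path, pixels: np.ndarray, *, as_float: bool = False) -> None:
    """Write a [0, 1] image as 16-bit TIFF (default) or float32 TIFF/PNG.

    16 bits preserve the dynamic range produced by the enhancement
    stage; ``as_float`` keeps full precision for intermediate dumps.
    """
    p = Path(path)
    arr = validate_image(pixels, name=str(p))
    try:
        if as_float:
            tifffile.imwrite(p, arr.astype(np.float32))
        elif p.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(p, np.round(np.clip(arr, 0, 1) * 65535).astype(np.uint16))
        else:
            iio.imwrite(p, np.round(np.clip(arr, 0, 1) * 65535).astype(np.uint16))
    except Exception as exc:  # noqa: BLE001
        raise ImageIOError(f"cannot write image {p}: {exc}") from exc


class RunManifest:
    """Structured log of one pipeline run: parameters, stages, timings."""

    def __init__(self, config_dict: dict | None = None):
        self.entries: list[dict] = []
        self.config = config_dict or {}
        self._t0 = time.monotonic()

    def record(self, stage: str, **params) -> None:
        entry = {"stage": stage, "elapsed_s": round(time.monotonic() - self._t0, 4), **params}
        self.entries.append(entry)
        logger.info("stage %s: %s", stage, params)

    def write(self, path: str | Path) -> None:
        doc = {"config": self.config, "stages": self.entries}
        Path(path).write_text(json.dumps(doc, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return str(obj)
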