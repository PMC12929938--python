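"""Trace-to-image rendering for the convolutional classifier.

Every event is drawn once on a fixed 240x240 master raster — deviation-
corrected (median recentred to the configured base level), clipped to the
200-700 pA acquisition band, with fixed y-limits equal to that band and the
x-axis spanning the whole event — and then area-average downsampled to the
requested resolution.  All resolutions therefore derive from one geometry.

The line is drawn as a vertically-connected 1-px polyline; downsampling
produces the anti-aliased grayscale profile.  Intensities are in [0, 1] with
the trace high-valued on a zero background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .errors import ConfigurationError, DataError
from .sim import EventTrace

__all__ = [
    "TraceImage",
    "SUPPORTED_RESOLUTIONS",
    "MASTER_RESOLUTION",
    "render_image",
    "render_dataset",
    "save_png",
    "load_png",
]

SUPPORTED_RESOLUTIONS = (28, 56, 70, 84, 112, 140, 240)
MASTER_RESOLUTION = 240


@dataclass
class TraceImage:
    pixels: np.ndarray  # (res, res) float in [0, 1]
    resolution: int
    event_id: str


def _master_raster(
    samples: np.ndarray,
    base_level: float,
    band: tuple[float, float],
) -> np.ndarray:
    lo, hi = band
    y = np.clip(samples, lo, hi)  # acquisition band
    y = np.clip(y - np.median(y) + base_level, lo, hi)  # deviation correction
    n = y.size
    res = MASTER_RESOLUTION
    cols = (np.arange(n) * res) // n
    rows = np.rint((hi - y) / (hi - lo) * (res - 1)).astype(int)

    canvas = np.zeros((res, res), dtype=np.float32)
    prev_last: int | None = None
    for c in range(int(cols[0]), int(cols[-1]) + 1):
        sel = rows[cols == c]
        if sel.size == 0:
            # column without samples: bridge straight across at the last level
            if prev_last is not None:
                canvas[prev_last, c] = 1.0
            continue
        r_lo, r_hi = int(sel.min()), int(sel.max())
        if prev_last is not None:  # connect to the previous column
            r_lo = min(r_lo, prev_last)
            r_hi = max(r_hi, prev_last)
        canvas[r_lo : r_hi + 1, c] = 1.0
        prev_last = int(sel[-1])
    return canvas


def render_image(
    trace: EventTrace,
    resolution: int,
    base_level: float = 450.0,
    band: tuple[float, float] = (200.0, 700.0),
) -> TraceImage:
    """Render one event at a supported resolution (deterministic)."""
    if resolution not in SUPPORTED_RESOLUTIONS:
        raise ConfigurationError(
            f"resolution {resolution} not in {SUPPORTED_RESOLUTIONS}"
        )
    if len(trace) == 0:
        raise DataError("cannot render an empty trace")
    master = _master_raster(trace.samples, base_level, band)
    if resolution == MASTER_RESOLUTION:
        pixels = master
    else:
        im = Image.fromarray((master * 255).astype(np.uint8))
        im = im.resize((resolution, resolution), Image.BOX)
        pixels = np.asarray(im, dtype=np.float32) / 255.0
    return TraceImage(pixels=pixels, resolution=resolution, event_id=trace.event_id)


def render_dataset(traces, resolution: int) -> tuple[np.ndarray, list[str]]:
    """Stack rendered images into an (n, res, res) float32 array."""
    imgs = [render_image(t, resolution) for t in traces]
    return np.stack([im.pixels for im in imgs]), [im.event_id for im in imgs]


def save_png(image: TraceImage, path) -> None:
    Image.fromarray((np.clip(image.pixels, 0, 1) * 255).astype(np.uint8)).save(path)


def load_png(path, event_id: str = "") -> TraceImage:
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.float32) / 255.0
    if arr.shape[0] != arr.shape[1]:
        raise DataError(f"expected a square image, got {arr.shape}")
    return TraceImage(pixels=arr, resolution=arr.shape[0], event_id=event_id)
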