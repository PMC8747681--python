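"""8-bit color-space conversions for seed-coat descriptors.

All four spaces used by the trait extractor (RGB, HSV, CIELAB, YCrCb) are
represented on an 8-bit scale so that every descriptor lives in [0, 255],
except hue which is stored as degrees/2 in [0, 180].  The conventions are:

* HSV: H = hue_degrees / 2, S and V scaled to [0, 255].
* CIELAB (sRGB, D65): L = 255 * L* / 100, a = a* + 128, b = b* + 128,
  clipped to [0, 255].  A pure gray (g, g, g) maps to a = b = 128.
* YCrCb: full-range ITU-R BT.601 luma/chroma,
  Y  = 0.299 R + 0.587 G + 0.114 B,
  Cr = (R - Y) * 0.713 + 128,  Cb = (B - Y) * 0.564 + 128,
  so gray (g, g, g) maps to (g, 128, 128).

Inputs are arrays of 8-bit RGB values (any shape ending in 3); outputs are
float64 on the 8-bit scale — descriptors keep full precision and are never
re-quantized.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2hsv, rgb2lab

#: Order in which the four spaces contribute trait columns.
SPACES = ("RGB", "HSV", "Lab", "YCrCb")

#: Component labels per space, in trait-name order.
COMPONENTS = {
    "RGB": ("R", "G", "B"),
    "HSV": ("H", "S", "V"),
    "Lab": ("L", "a", "b"),
    "YCrCb": ("Y", "Cr", "Cb"),
}

#: Index of the brightness-like component of each space (used for
#: deterministic tie-breaking when ranking dominant colors).
BRIGHTNESS_INDEX = {"RGB": None, "HSV": 2, "Lab": 0, "YCrCb": 0}


def _as_float_rgb(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.shape[-1] != 3:
        raise ValueError(f"expected trailing RGB axis of size 3, got shape {rgb.shape}")
    return rgb


def rgb_to_hsv8(rgb: np.ndarray) -> np.ndarray:
    """RGB [0,255] -> (H in [0,180], S in [0,255], V in [0,255])."""
    rgb = _as_float_rgb(rgb)
    hsv = rgb2hsv(rgb / 255.0)
    out = np.empty_like(hsv)
    out[..., 0] = hsv[..., 0] * 180.0
    out[..., 1] = hsv[..., 1] * 255.0
    out[..., 2] = hsv[..., 2] * 255.0
    return out


def rgb_to_lab8(rgb: np.ndarray) -> np.ndarray:
    """RGB [0,255] -> 8-bit CIELAB (L in [0,255], a/b offset by 128)."""
    rgb = _as_float_rgb(rgb)
    lab = rgb2lab(rgb / 255.0)
    out = np.empty_like(lab)
    out[..., 0] = lab[..., 0] * 255.0 / 100.0
    out[..., 1] = lab[..., 1] + 128.0
    out[..., 2] = lab[..., 2] + 128.0
    return np.clip(out, 0.0, 255.0)


def lab8_to_rgb(lab8: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_lab8`; returns float RGB on [0, 255]."""
    from skimage.color import lab2rgb

    lab8 = np.asarray(lab8, dtype=np.float64)
    lab = np.empty_like(lab8)
    lab[..., 0] = lab8[..., 0] * 100.0 / 255.0
    lab[..., 1] = lab8[..., 1] - 128.0
    lab[..., 2] = lab8[..., 2] - 128.0
    return np.clip(lab2rgb(lab), 0.0, 1.0) * 255.0


_BT601 = np.array([0.299, 0.587, 0.114])


def rgb_to_ycrcb8(rgb: np.ndarray) -> np.ndarray:
    """RGB [0,255] -> full-range BT.601 (Y, Cr, Cb), chroma centered at 128."""
    rgb = _as_float_rgb(rgb)
    y = rgb @ _BT601
    cr = (rgb[..., 0] - y) * 0.713 + 128.0
    cb = (rgb[..., 2] - y) * 0.564 + 128.0
    return np.clip(np.stack([y, cr, cb], axis=-1), 0.0, 255.0)


def convert_pixels(rgb: np.ndarray, space: str) -> np.ndarray:
    """Convert 8-bit RGB pixels to ``space`` ('RGB', 'HSV', 'Lab', 'YCrCb')."""
    if space == "RGB":
        return _as_float_rgb(rgb)
    if space == "HSV":
        return rgb_to_hsv8(rgb)
    if space == "Lab":
        return rgb_to_lab8(rgb)
    if space == "YCrCb":
        return rgb_to_ycrcb8(rgb)
    raise ValueError(f"unknown color space {space!r}")
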