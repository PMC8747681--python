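"""Per-seed descriptors: 3 size, 4 shape and 48 color traits.

Size traits come from the minimum-area bounding rectangle (length sL,
width sW) and the mask pixel count (projected area sA), scaled by the
chart-derived mm/px.  Shape indices are the four classic contour ratios:

    sCi = 4*pi*area / perimeter^2          (circularity, <= 1)
    sRo = 4*area / (pi * major_axis^2)     (roundness; major axis = max
                                            Feret diameter, so sRo <= 1)
    sRu = Ps / Pc                          (rugosity, >= 1)
    sSo = area / hull_area                 (solidity, <= 1)

Color traits are computed in four spaces (RGB, HSV, CIELAB, YCrCb; 8-bit
conventions in :mod:`grainaging.colorspaces`).  Per space there are three
3-sigma-trimmed component means (one trim pass, strict comparison,
population SD) and the three components of each of k=3 dominant colors
(k-means centroids ranked by descending pixel fraction), giving
4 * (3 + 9) = 48 color values.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import colorspaces
from .colorspaces import BRIGHTNESS_INDEX, COMPONENTS, SPACES
from .imaging import GrainContour

SIZE_TRAITS = ("sL", "sW", "sA")
SHAPE_TRAITS = ("sCi", "sRo", "sRu", "sSo")

#: Accepted alias: some sources label rugosity sRg instead of sRu.
RUGOSITY_ALIASES = ("sRu", "sRg")


def color_trait_names() -> list[str]:
    names: list[str] = []
    for space in SPACES:
        for comp in COMPONENTS[space]:
            names.append(f"{space}_m{comp}")
        for i in (1, 2, 3):
            for comp in COMPONENTS[space]:
                names.append(f"{space}_dC{comp}_{i}")
    return names


COLOR_TRAITS = tuple(color_trait_names())
ALL_TRAITS = SIZE_TRAITS + SHAPE_TRAITS + COLOR_TRAITS  # 55 names
ID_COLUMNS = ("image_id", "grain_id", "genotype", "year")
FRACTION_COLUMNS = ("f1", "f2", "f3")


def size_traits(contour: GrainContour, mm_per_px: float) -> tuple[float, float, float]:
    """(sL, sW, sA) in mm / mm^2 from rectangle sides and pixel area."""
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    if contour.area <= 0:
        raise ValueError("degenerate contour")
    return (
        contour.rect_l * mm_per_px,
        contour.rect_w * mm_per_px,
        contour.area * mm_per_px**2,
    )


def circularity(contour: GrainContour) -> float:
    if contour.perimeter <= 0:
        raise ValueError("zero perimeter")
    return 4.0 * np.pi * contour.polygon_area / contour.perimeter**2


def roundness(contour: GrainContour) -> float:
    if contour.feret_max <= 0:
        raise ValueError("degenerate contour")
    return 4.0 * contour.polygon_area / (np.pi * contour.feret_max**2)


def rugosity(contour: GrainContour) -> float:
    if contour.hull_perimeter <= 0:
        raise ValueError("degenerate contour")
    return contour.perimeter / contour.hull_perimeter


def solidity(contour: GrainContour) -> float:
    if contour.hull_area <= 0:
        raise ValueError("degenerate contour")
    return contour.polygon_area / contour.hull_area


def shape_traits(contour: GrainContour) -> dict[str, float]:
    return {
        "sCi": circularity(contour),
        "sRo": roundness(contour),
        "sRu": rugosity(contour),
        "sSo": solidity(contour),
    }


def trimmed_mean(values: np.ndarray, n_sigma: float = 3.0) -> float:
    """Two-pass mean: drop values deviating from the pass-1 mean by
    strictly more than ``n_sigma`` population SDs, then average the rest.

    Exactly one trim iteration; a zero SD discards nothing.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty pixel set")
    m = values.mean()
    sd = values.std()  # ddof=0
    if sd == 0:
        return float(m)
    keep = np.abs(values - m) <= n_sigma * sd
    return float(values[keep].mean())


def mean_color_descriptors(pixels_rgb: np.ndarray) -> dict[str, float]:
    """The 12 ``SPACE_mC`` values for one grain's RGB pixel set."""
    pixels_rgb = np.asarray(pixels_rgb, dtype=float).reshape(-1, 3)
    if pixels_rgb.size == 0:
        raise ValueError("empty pixel set")
    out: dict[str, float] = {}
    for space in SPACES:
        converted = colorspaces.convert_pixels(pixels_rgb, space)
        for j, comp in enumerate(COMPONENTS[space]):
            out[f"{space}_m{comp}"] = trimmed_mean(converted[:, j])
    return out


def _brightness(space: str, centroids: np.ndarray) -> np.ndarray:
    idx = BRIGHTNESS_INDEX[space]
    if idx is None:  # RGB: component sum
        return centroids.sum(axis=1)
    return centroids[:, idx]


def _rank_clusters(space: str, centroids: np.ndarray, fractions: np.ndarray):
    order = np.lexsort((-_brightness(space, centroids), -fractions))
    return centroids[order], fractions[order]


def dominant_colors(
    pixels: np.ndarray, space: str, k: int = 3, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """k-means dominant colors of one grain in one color space.

    Returns ``(centroids, fractions)`` with clusters ranked by descending
    pixel fraction (ties broken by descending brightness component).  If
    the grain has fewer than ``k`` distinct colors, the distinct colors are
    kept and the remaining ranks duplicate rank 1 with fraction 0, keeping
    the descriptor schema fixed.
    """
    pixels = np.asarray(pixels, dtype=float).reshape(-1, 3)
    if pixels.size == 0:
        raise ValueError("empty pixel set")
    unique = np.unique(pixels, axis=0)
    if len(unique) < k:
        counts = np.array(
            [(pixels == u).all(axis=1).sum() for u in unique], dtype=float
        )
        fractions = counts / counts.sum()
        cents, fracs = _rank_clusters(space, unique, fractions)
        pad = k - len(unique)
        cents = np.vstack([cents, np.repeat(cents[:1], pad, axis=0)])
        fracs = np.concatenate([fracs, np.zeros(pad)])
        return cents, fracs
    km = KMeans(n_clusters=k, n_init=10, random_state=seed % (2**31)).fit(pixels)
    counts = np.bincount(km.labels_, minlength=k).astype(float)
    return _rank_clusters(space, km.cluster_centers_, counts / counts.sum())


def dominant_color_descriptors(
    pixels_rgb: np.ndarray, k: int = 3, seed: int = 0
) -> tuple[dict[str, float], np.ndarray]:
    """The 36 ``SPACE_dCC_i`` values plus RGB-space cluster fractions.

    k-means runs independently per color space on that space's components;
    the reported fractions are those of the RGB-space clustering.
    """
    pixels_rgb = np.asarray(pixels_rgb, dtype=float).reshape(-1, 3)
    if pixels_rgb.size == 0:
        raise ValueError("empty pixel set")
    out: dict[str, float] = {}
    rgb_fracs = None
    for space in SPACES:
        converted = colorspaces.convert_pixels(pixels_rgb, space)
        cents, fracs = dominant_colors(converted, space, k=k, seed=seed)
        if space == "RGB":
            rgb_fracs = fracs
        for i in range(k):
            for j, comp in enumerate(COMPONENTS[space]):
                out[f"{space}_dC{comp}_{i + 1}"] = float(cents[i, j])
    return out, rgb_fracs


def grain_seed(grain_id: str) -> int:
    """Deterministic k-means seed from the grain identifier."""
    return zlib.crc32(grain_id.encode())


@dataclass
class TraitRecord:
    """Identifiers plus the 55 descriptors for one seed."""

    image_id: str
    grain_id: str
    genotype: str
    year: int
    values: dict[str, float]

    def as_row(self) -> dict:
        row = {
            "image_id": self.image_id,
            "grain_id": self.grain_id,
            "genotype": self.genotype,
            "year": self.year,
        }
        row.update(self.values)
        return row


def grain_traits(
    contour: GrainContour,
    corrected_image: np.ndarray,
    mm_per_px: float,
    image_id: str = "",
    grain_id: str = "",
    genotype: str = "",
    year: int = 0,
    k: int = 3,
) -> TraitRecord:
    """All 55 descriptors for one grain of a corrected image."""
    if contour.pixel_coords is None:
        raise ValueError("contour has no pixel coordinates (analytic polygon?)")
    rr, cc = contour.pixel_coords
    pixels = corrected_image[rr, cc].astype(float)
    sL, sW, sA = size_traits(contour, mm_per_px)
    values: dict[str, float] = {"sL": sL, "sW": sW, "sA": sA}
    values.update(shape_traits(contour))
    values.update(mean_color_descriptors(pixels))
    dom, fracs = dominant_color_descriptors(pixels, k=k, seed=grain_seed(grain_id))
    values.update(dom)
    for name, frac in zip(FRACTION_COLUMNS, fracs):
        values[name] = float(frac)
    return TraitRecord(image_id, grain_id, genotype, year, values)


def compute_trait_table(per_image: list[dict]) -> pd.DataFrame:
    """Assemble the per-seed trait table.

    ``per_image`` entries need keys ``image_id, genotype, year,
    corrected`` (uint8 image), ``contours`` (accepted GrainContours) and
    ``mm_per_px``.  Output: one row per grain, identifier columns followed
    by the 55 trait columns and the cluster-fraction columns.
    """
    rows = []
    for item in per_image:
        for j, contour in enumerate(item["contours"]):
            grain_id = f"{item['image_id']}_s{j:02d}"
            rec = grain_traits(
                contour,
                item["corrected"],
                item["mm_per_px"],
                image_id=item["image_id"],
                grain_id=grain_id,
                genotype=item["genotype"],
                year=item["year"],
            )
            rows.append(rec.as_row())
    table = pd.DataFrame(rows)
    ordered = list(ID_COLUMNS) + list(ALL_TRAITS) + list(FRACTION_COLUMNS)
    return table[ordered] if len(table) else pd.DataFrame(columns=ordered)
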