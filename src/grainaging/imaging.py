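"""Image processing: chart location, scaling, color correction,
segmentation, contour extraction and filtration.

The stages mirror a standard seed-scatter workflow: measure the chart
patches and the image scale, fit a least-squares affine RGB correction
from measured to reference patch colors, apply it, threshold the grains
(darker than the white background) with Otsu on luminance, clean the mask
morphologically, and extract one filtered contour per connected component.

Contours use a marching-squares sub-pixel boundary smoothed with a short
circular moving average; pixel-edge (staircase) perimeters would bias
circularity low by ~10%.  Convex-hull measures are computed from the same
smoothed polygon, which makes ``hull perimeter <= contour perimeter`` and
``hull area >= polygon area`` exact geometric identities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label as label_components
from skimage.morphology import disk, opening

from .chart import ChartLayout

logger = logging.getLogger(__name__)


class ChartMissingError(RuntimeError):
    """The chart fiducial was not found where the layout expects it."""


class ChartGeometryError(RuntimeError):
    """A patch region falls outside the image."""


class ColorFitError(ValueError):
    """The affine color fit is under-determined."""


@dataclass
class SeedImage:
    """An 8-bit RGB photograph plus identifiers."""

    pixels: np.ndarray
    image_id: str = ""
    genotype: str = ""
    year: int | None = None
    path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("SeedImage requires an HxWx3 array")
        if min(px.shape[:2]) < 64:
            raise ValueError("SeedImage requires H, W >= 64")
        self.pixels = px


def locate_chart(
    image: np.ndarray | SeedImage, layout: ChartLayout
) -> tuple[np.ndarray, float]:
    """Measure the chart: per-patch mean RGB and the image scale.

    The fiducial (a solid black square at the chart corner) must be dark;
    otherwise the chart is considered missing.  Patch means are taken over
    the central 50% of each painted patch.  Returns ``(measured, mm_per_px)``
    with ``measured`` of shape (n_patches, 3).
    """
    px = image.pixels if isinstance(image, SeedImage) else np.asarray(image)
    H, W = px.shape[:2]
    r0, c0, r1, c1 = layout.fiducial_bbox
    if r1 > H or c1 > W:
        raise ChartGeometryError("fiducial region outside image")
    if px[r0:r1, c0:c1].mean() > 80:
        raise ChartMissingError(
            "chart fiducial not found at the configured location"
        )
    half = max(layout.half_width // 2, 1)
    measured = np.empty((len(layout.centers), 3), dtype=float)
    for i, (r, c) in enumerate(layout.centers):
        r, c = int(r), int(c)
        if r - half < 0 or c - half < 0 or r + half >= H or c + half >= W:
            raise ChartGeometryError(f"patch {i} region outside image")
        measured[i] = px[r - half:r + half + 1, c - half:c + half + 1].reshape(-1, 3).mean(axis=0)
    return measured, layout.mm_per_px


@dataclass
class ColorTransform:
    """3x4 affine map ``corrected = M[:, :3] @ rgb + M[:, 3]``."""

    matrix: np.ndarray
    residual_rms: float = 0.0
    clipped_fraction: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 4) or not np.all(np.isfinite(m)):
            raise ValueError("ColorTransform needs a finite 3x4 matrix")
        self.matrix = m

    @classmethod
    def identity(cls) -> "ColorTransform":
        return cls(np.hstack([np.eye(3), np.zeros((3, 1))]))


def fit_color_correction(
    measured: np.ndarray, reference: np.ndarray
) -> ColorTransform:
    """Least-squares affine fit from measured to reference patch colors.

    Requires >= 4 patch pairs and a full-rank design (measured colors not
    coplanar in RGB); the residual RMS over the fitted patches is recorded
    on the returned transform.
    """
    measured = np.asarray(measured, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if measured.shape != reference.shape or measured.ndim != 2 or measured.shape[1] != 3:
        raise ColorFitError("measured/reference must both be (n, 3)")
    n = len(measured)
    if n < 4:
        raise ColorFitError(f"need >= 4 patch pairs for an affine fit, got {n}")
    X = np.hstack([measured, np.ones((n, 1))])
    if np.linalg.matrix_rank(X) < 4:
        raise ColorFitError("measured patch colors are rank-deficient")
    coef, *_ = np.linalg.lstsq(X, reference, rcond=None)
    resid = X @ coef - reference
    return ColorTransform(matrix=coef.T, residual_rms=float(np.sqrt(np.mean(resid**2))))


def apply_color_correction(
    image: np.ndarray | SeedImage, transform: ColorTransform
) -> np.ndarray:
    """Apply the affine map per pixel, round and clip to [0, 255].

    Clipping is defined behavior; the clipped-pixel fraction is stored on
    the transform and logged.
    """
    px = image.pixels if isinstance(image, SeedImage) else np.asarray(image)
    flat = px.reshape(-1, 3).astype(float)
    out = flat @ transform.matrix[:, :3].T + transform.matrix[:, 3]
    clipped = float(np.mean((out < 0.0).any(axis=1) | (out > 255.0).any(axis=1)))
    transform.clipped_fraction = clipped
    if clipped:
        logger.info("color correction clipped %.2f%% of pixels", 100 * clipped)
    return np.rint(np.clip(out, 0.0, 255.0)).astype(np.uint8).reshape(px.shape)


def segment_grains(
    image: np.ndarray,
    chart_bbox: tuple[int, int, int, int] | None = None,
    opening_radius: int = 2,
    chart_margin: int = 6,
) -> np.ndarray:
    """Binary grain mask: Otsu on luminance, inverted, opened, hole-filled.

    The chart bounding box (expanded by ``chart_margin``) is forced to
    background.  An empty mask is a valid result (blank image).
    """
    px = np.asarray(image, dtype=float)
    luma = px @ np.array([0.299, 0.587, 0.114])
    if chart_bbox is not None:
        r0, c0, r1, c1 = chart_bbox
        m = chart_margin
        region = np.ones_like(luma, dtype=bool)
        region[max(r0 - m, 0):r1 + m, max(c0 - m, 0):c1 + m] = False
        values = luma[region]
    else:
        region = np.ones_like(luma, dtype=bool)
        values = luma.ravel()
    if values.size == 0 or np.ptp(values) < 1.0:
        return np.zeros_like(region)
    thr = threshold_otsu(values)
    # guard against a unimodal (grain-free) histogram: background sits in a
    # narrow bright band, so a threshold close to the background mean with
    # almost no foreground is treated as empty
    mask = (luma < thr) & region
    if mask.mean() < 1e-5:
        return np.zeros_like(region)
    if opening_radius > 0:
        mask = opening(mask, disk(opening_radius))
    return ndimage.binary_fill_holes(mask)


def _smooth_closed(vertices: np.ndarray, window: int = 5, iterations: int = 2) -> np.ndarray:
    """Circular moving average of a closed polygon's vertices."""
    v = vertices
    if np.allclose(v[0], v[-1]):
        v = v[:-1]
    if len(v) <= window:
        return v
    kernel = np.ones(window) / window
    half = window // 2
    for _ in range(iterations):
        wrapped = np.vstack([v[-half:], v, v[:half]])
        v = np.column_stack(
            [np.convolve(wrapped[:, j], kernel, mode="valid") for j in (0, 1)]
        )
    return v


@dataclass
class GrainContour:
    """One grain's closed boundary polygon with derived measures.

    All measures are in pixel units; the trait layer converts to mm using
    the chart scale.  ``area`` is the mask pixel count for rasterized
    grains and the polygon (shoelace) area for analytic polygons;
    ``polygon_area`` is always the shoelace area of the boundary polygon.
    The shape indices use ``polygon_area`` together with ``perimeter``,
    ``hull_perimeter`` and ``hull_area`` — all derived from the same
    polygon — so solidity <= 1 and rugosity >= 1 hold exactly.
    """

    vertices: np.ndarray                 # (n, 2) closed CCW polygon, px
    area: float                          # px^2 (pixel count for masks)
    polygon_area: float                  # px^2, shoelace area of `vertices`
    perimeter: float                     # Ps, px
    hull_perimeter: float                # Pc, px
    hull_area: float                     # px^2
    feret_max: float                     # major axis, px
    rect_l: float                        # min-area rectangle long side, px
    rect_w: float                        # short side, px
    pixel_coords: tuple[np.ndarray, np.ndarray] | None = None
    label: int = 0

    @classmethod
    def from_polygon(cls, vertices: np.ndarray, label: int = 0) -> "GrainContour":
        """Analytic constructor: measures straight from the polygon."""
        poly = Polygon(np.asarray(vertices, dtype=float))
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("contour must be a simple closed polygon with area > 0")
        return cls._from_shapely(poly, poly.area, label, None)

    @classmethod
    def from_mask(
        cls,
        mask: np.ndarray,
        label: int = 0,
        offset: tuple[int, int] = (0, 0),
        smoothing_window: int = 5,
        smoothing_iterations: int = 2,
    ) -> "GrainContour":
        """Rasterized constructor: sub-pixel marching-squares boundary.

        ``area`` is the pixel count; the boundary polygon is smoothed to
        suppress the staircase bias of the raw level-set contour.
        """
        mask = np.asarray(mask, dtype=bool)
        area = float(mask.sum())
        if area == 0:
            raise ValueError("empty mask")
        padded = np.pad(mask.astype(float), 1)
        contours = find_contours(padded, 0.5)
        if not contours:
            raise ValueError("no boundary found")
        verts = max(contours, key=len) - 1.0
        verts = _smooth_closed(verts, smoothing_window, smoothing_iterations)
        poly = Polygon(verts)
        if not poly.is_valid:
            poly = poly.buffer(0)
            if poly.geom_type != "Polygon":
                poly = max(poly.geoms, key=lambda g: g.area)
        rr, cc = np.nonzero(mask)
        out = cls._from_shapely(poly, area, label,
                                (rr + offset[0], cc + offset[1]))
        return out

    @classmethod
    def _from_shapely(cls, poly: Polygon, area: float, label: int, coords):
        poly = shapely.geometry.polygon.orient(poly, sign=1.0)  # CCW
        hull = poly.convex_hull
        hull_xy = np.asarray(hull.exterior.coords)[:-1]
        # maximum Feret diameter = max pairwise distance of hull vertices
        diff = hull_xy[:, None, :] - hull_xy[None, :, :]
        feret = float(np.sqrt((diff**2).sum(-1)).max())
        rect = poly.minimum_rotated_rectangle
        rect_xy = np.asarray(rect.exterior.coords)
        if len(rect_xy) >= 4:
            s1 = float(np.hypot(*(rect_xy[1] - rect_xy[0])))
            s2 = float(np.hypot(*(rect_xy[2] - rect_xy[1])))
        else:  # degenerate (line/point)
            s1 = s2 = 0.0
        verts = np.asarray(poly.exterior.coords)[:-1]
        return cls(
            vertices=verts,
            area=float(area),
            polygon_area=float(poly.area),
            perimeter=float(poly.length),
            hull_perimeter=float(hull.length),
            hull_area=float(hull.area),
            feret_max=feret,
            rect_l=max(s1, s2),
            rect_w=min(s1, s2),
            pixel_coords=coords,
            label=label,
        )


@dataclass
class ContourFilters:
    """Acceptance rules for candidate grain components."""

    min_area_mm2: float = 4.0
    max_area_mm2: float = 80.0
    max_aspect: float = 4.0
    exclude_border: bool = True


@dataclass
class RejectedComponent:
    label: int
    reason: str
    area_mm2: float


def extract_grain_contours(
    mask: np.ndarray,
    filters: ContourFilters | None = None,
    mm_per_px: float = 1.0,
) -> tuple[list[GrainContour], list[RejectedComponent]]:
    """One contour per connected component passing the filters.

    Components touching the image border, outside the area band, or more
    elongated than ``max_aspect`` are rejected and logged with a reason.
    """
    if filters is None:
        filters = ContourFilters()
    labels = label_components(mask, connectivity=2)
    H, W = mask.shape
    accepted: list[GrainContour] = []
    rejected: list[RejectedComponent] = []
    for lbl in range(1, labels.max() + 1):
        comp = labels == lbl
        area_mm2 = comp.sum() * mm_per_px**2
        rr, cc = np.nonzero(comp)
        if filters.exclude_border and (
            rr.min() == 0 or cc.min() == 0 or rr.max() == H - 1 or cc.max() == W - 1
        ):
            rejected.append(RejectedComponent(lbl, "border", area_mm2))
            continue
        if area_mm2 < filters.min_area_mm2:
            rejected.append(RejectedComponent(lbl, "too_small", area_mm2))
            continue
        if area_mm2 > filters.max_area_mm2:
            rejected.append(RejectedComponent(lbl, "too_large", area_mm2))
            continue
        r0, r1 = rr.min(), rr.max() + 1
        c0, c1 = cc.min(), cc.max() + 1
        contour = GrainContour.from_mask(
            comp[r0:r1, c0:c1], label=lbl, offset=(r0, c0)
        )
        if contour.rect_w > 0 and contour.rect_l / contour.rect_w > filters.max_aspect:
            rejected.append(RejectedComponent(lbl, "too_elongated", area_mm2))
            continue
        accepted.append(contour)
    return accepted, rejected
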