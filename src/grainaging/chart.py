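"""Color-reference chart layout.

The synthetic scenes carry a 24-patch color chart (the familiar 6 x 4
ColorChecker-style grid) at a fixed, known position, with a solid black
fiducial square at its top-left corner so the locator can verify the chart
is actually present.  The physical patch pitch in millimetres is recorded
on the layout and, together with the rendered pitch in pixels, yields the
image scale (mm per pixel).  Real chart geometry is not reproduced exactly;
for real photographs the chart location can be supplied externally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Reference sRGB coordinates of the 24 chart patches, row-major (dark
#: skin .. black).  The widely published 8-bit targets scaled by 0.9:
#: the headroom keeps every patch below saturation under global gain
#: casts up to ~1.15, so the affine correction stays identifiable (a
#: clipped patch channel carries no recoverable information).
CLASSIC_24 = (
    (104, 74, 61), (175, 135, 117), (88, 110, 141), (78, 97, 60),
    (120, 115, 159), (93, 170, 153),
    (193, 113, 40), (72, 82, 149), (174, 81, 89), (85, 54, 97),
    (141, 169, 58), (202, 147, 41),
    (50, 55, 135), (63, 133, 66), (158, 49, 54), (208, 179, 28),
    (168, 77, 134), (7, 120, 145),
    (219, 219, 218), (180, 180, 180), (144, 144, 144), (110, 110, 109),
    (76, 76, 76), (47, 47, 47),
)

#: Row-major index of the white patch in CLASSIC_24.
WHITE_PATCH_INDEX = 18


class ChartSpecError(ValueError):
    """Chart specification is unusable (too few / duplicate patches)."""


@dataclass(frozen=True)
class ChartLayout:
    """Patch geometry + reference colors of the rendered chart.

    Coordinates are pixel positions (row, col) of patch centers.  The
    fiducial is a filled black square whose top-left corner anchors the
    chart; its bounding box is included in the chart bounding box.
    """

    centers: np.ndarray            # (n, 2) float, (row, col)
    half_width: int                # half side of the painted patch square
    reference_rgb: np.ndarray      # (n, 3) uint8
    pitch_px: int
    pitch_mm: float
    origin: tuple[int, int]        # (row, col) of chart block top-left
    n_rows: int
    n_cols: int
    fiducial_size: int = 16

    @property
    def mm_per_px(self) -> float:
        return self.pitch_mm / self.pitch_px

    @property
    def fiducial_bbox(self) -> tuple[int, int, int, int]:
        r0, c0 = self.origin
        s = self.fiducial_size
        return (r0, c0, r0 + s, c0 + s)

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(r0, c0, r1, c1) covering fiducial and all patches, half-open."""
        r0, c0 = self.origin
        r1 = int(np.max(self.centers[:, 0]) + self.half_width + 1)
        c1 = int(np.max(self.centers[:, 1]) + self.half_width + 1)
        return (r0, c0, r1, c1)


def build_chart_layout(
    patch_rgb=CLASSIC_24,
    n_rows: int = 4,
    n_cols: int = 6,
    pitch_px: int = 40,
    pitch_mm: float = 4.0,
    origin: tuple[int, int] = (12, 12),
    fiducial_size: int = 16,
) -> ChartLayout:
    """Lay out ``n_rows x n_cols`` patches in row-major order.

    At least 4 patches are required (an affine RGB correction has 12 free
    parameters, 4 color pairs determine it); duplicate grid positions or a
    grid smaller than the patch list are rejected.
    """
    patch_rgb = np.asarray(patch_rgb, dtype=np.uint8)
    n = len(patch_rgb)
    if n < 4:
        raise ChartSpecError(
            f"need >= 4 reference patches for an affine fit, got {n}"
        )
    if n_rows * n_cols < n:
        raise ChartSpecError("grid too small for the patch list")
    if pitch_px < 4:
        raise ChartSpecError("patch pitch must be >= 4 px")

    r0, c0 = origin
    # patches start below the fiducial row
    top = r0 + fiducial_size + 4
    left = c0
    centers = np.empty((n, 2), dtype=float)
    seen: set[tuple[int, int]] = set()
    for i in range(n):
        rr, cc = divmod(i, n_cols)
        if (rr, cc) in seen:
            raise ChartSpecError(f"duplicate patch position {(rr, cc)}")
        seen.add((rr, cc))
        centers[i] = (top + rr * pitch_px + pitch_px // 2,
                      left + cc * pitch_px + pitch_px // 2)
    half_width = int(0.4 * pitch_px)
    return ChartLayout(
        centers=centers,
        half_width=half_width,
        reference_rgb=patch_rgb,
        pitch_px=pitch_px,
        pitch_mm=pitch_mm,
        origin=(r0, c0),
        n_rows=n_rows,
        n_cols=n_cols,
        fiducial_size=fiducial_size,
    )


def render_chart(canvas: np.ndarray, layout: ChartLayout) -> None:
    """Paint the fiducial and patches into a float RGB canvas in place."""
    r0, c0, r1, c1 = layout.fiducial_bbox
    canvas[r0:r1, c0:c1] = 0.0
    hw = layout.half_width
    for center, rgb in zip(layout.centers, layout.reference_rgb):
        r, c = int(center[0]), int(center[1])
        canvas[r - hw:r + hw + 1, c - hw:c + hw + 1] = rgb
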