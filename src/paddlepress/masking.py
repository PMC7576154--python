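"""Body segmentation, outline smoothing and mask rasterization.

The animal appears dark on a bright field; segmentation thresholds on
image contrast, keeps the largest connected dark region above a minimum
area, and extracts a sub-pixel boundary contour. Masks rasterized onto the
velocity grid are dilated so that velocimetry vectors contaminated by the
surface are excluded from the pressure computation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import LineString, Polygon
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import (
    EmptyMaskError,
    InvalidContourError,
    NoBodyFoundError,
    SmoothingFailedError,
)
from .fields import GridGeometry


@dataclass
class BodyMask:
    """Boolean raster aligned to the velocity grid plus the physical
    contour polygon it was rasterized from."""

    raster: np.ndarray          # (ny, nx) bool, True inside the (dilated) body
    contour: np.ndarray         # (n, 2) physical coordinates, closed by convention
    dilation_cells: int = 0


def segment_body(
    image: np.ndarray,
    threshold_method: str = "otsu",
    min_area_px: int = 50,
    pixel_size: float = 1.0,
    invert: bool = False,
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Segment the body from a grayscale image in [0, 1].

    Global threshold (inter-class-variance maximizing by default), connected
    dark regions, discard regions below ``min_area_px``, return the sub-pixel
    boundary of the largest survivor as an ordered closed contour in physical
    coordinates (y up: image row 0 is the top of the frame).

    ``invert=True`` segments bright-on-dark instead.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InvalidContourError("segment_body expects a single 2D grayscale image")
    if float(img.max() - img.min()) < 1e-9:
        raise NoBodyFoundError("no body found: image has no contrast")
    if threshold_method == "otsu":
        thr = float(threshold_otsu(img))
    else:
        thr = float(threshold_method)
    binary = (img > thr) if invert else (img < thr)
    labels, _ = ndimage.label(binary)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    surviving = np.flatnonzero(sizes >= min_area_px)
    if surviving.size == 0:
        raise NoBodyFoundError(
            f"no body found: no region of >= {min_area_px} px below threshold"
        )
    target = surviving[np.argmax(sizes[surviving])]
    region = ndimage.binary_fill_holes(labels == target)
    # sub-pixel contour: contour the grayscale image at the threshold and
    # keep the closed contour enclosing the segmented region's centroid
    cy, cx = ndimage.center_of_mass(region)
    level_img = -img if invert else img
    level = -thr if invert else thr
    contour = _select_contour(level_img, level, (cy, cx))
    if contour is None:
        # fall back to the binary region boundary
        contour = _select_contour(region.astype(float), 0.5, (cy, cx))
    if contour is None:
        raise NoBodyFoundError("no closed boundary contour found for the body region")
    rows, cols = contour[:, 0], contour[:, 1]
    h = img.shape[0]
    x = origin[0] + cols * pixel_size
    y = origin[1] + (h - 1 - rows) * pixel_size
    return np.column_stack([x, y])


def _select_contour(img, level, centroid) -> np.ndarray | None:
    best = None
    for c in measure.find_contours(img, level):
        if not np.allclose(c[0], c[-1]):
            continue
        poly = Polygon(c[:-1])
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty:
            continue
        if poly.contains(shapely.points(centroid[0], centroid[1])):
            if best is None or poly.area > best[0]:
                best = (poly.area, c[:-1])
    return None if best is None else best[1]


def smooth_contour(contour: np.ndarray, window: int = 5) -> np.ndarray:
    """Circular moving average of closed-contour coordinates.

    ``window`` must be odd; window 1 is the identity. Raises if smoothing
    induces a self-intersection (try a smaller window).
    """
    pts = np.asarray(contour, dtype=float)
    if window % 2 != 1 or window < 1:
        raise InvalidContourError("smoothing window must be odd and >= 1")
    if len(pts) < window:
        raise InvalidContourError("contour has fewer points than the smoothing window")
    if window == 1:
        return pts.copy()
    half = window // 2
    idx = np.arange(len(pts))
    out = np.zeros_like(pts)
    for off in range(-half, half + 1):
        out += pts[(idx + off) % len(pts)]
    out /= window
    if not Polygon(out).is_valid:
        raise SmoothingFailedError(
            f"smoothing with window {window} produced a self-intersecting contour; "
            "try a smaller window"
        )
    return out


def rasterize_mask(
    contour: np.ndarray,
    grid: GridGeometry,
    dilation_cells: int = 1,
) -> BodyMask:
    """Node-in-polygon rasterization (boundary nodes count as inside)
    followed by binary dilation with a 3x3 structuring element applied
    ``dilation_cells`` times."""
    pts = np.asarray(contour, dtype=float)
    if len(pts) < 3:
        raise EmptyMaskError("contour has fewer than 3 points")
    poly = Polygon(pts)
    if not poly.is_valid:
        poly = poly.buffer(0)
    if poly.is_empty:
        raise EmptyMaskError("contour collapses to an empty polygon")
    X, Y = grid.mesh()
    nodes = shapely.points(X.ravel(), Y.ravel())
    inside = shapely.covers(poly, nodes).reshape(grid.shape)
    if not inside.any():
        raise EmptyMaskError("contour covers no grid node (entirely outside grid?)")
    if dilation_cells > 0:
        inside = ndimage.binary_dilation(
            inside, structure=np.ones((3, 3), dtype=bool), iterations=dilation_cells
        )
    return BodyMask(raster=inside, contour=pts, dilation_cells=dilation_cells)


def thicken_centerline(
    centerline_points: np.ndarray, half_width: float
) -> np.ndarray:
    """Closed outline of a centerline thickened to ``2*half_width``
    (rounded caps); used to build propulsor masks from digitized
    centerlines when no image is available."""
    line = LineString(np.asarray(centerline_points, dtype=float))
    outline = line.buffer(half_width)
    return np.asarray(outline.exterior.coords)[:-1]


def mask_centroid(mask: BodyMask, grid: GridGeometry) -> np.ndarray:
    X, Y = grid.mesh()
    r = mask.raster
    return np.array([X[r].mean(), Y[r].mean()])
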