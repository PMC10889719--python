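"""Slide pre-processing: biopsy ROI detection and coarse upright export.

The detection chain on each stained slide: grayscale conversion, Canny edge
detection (hysteresis thresholds 100/255 on a 0-255 intensity scale), adaptive
local thresholding (window 11, offset 2, inverted), the pixelwise OR of the
two maps, morphological closing (15 dilations then 15 erosions, 3x3 square),
and contour/component extraction.  The component whose axis-aligned bounding
rectangle has the largest area is taken as the biopsy; it is described by its
minimum-area ("rotated") rectangle and its filled concave outline.  Rotating
the slide upright by the rectangle angle provides the coarse alignment, after
which the ROI is cropped and downsampled to a working resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature, filters, transform
from shapely.geometry import MultiPoint

from trabekit.transforms import Affine2D


class EmptySlideError(ValueError):
    """No biopsy contour was found on the slide."""


@dataclass
class Slide:
    """One scanned serial section: RGB raster plus physical pixel size."""

    pixels: np.ndarray
    pixel_ratio_um: float
    slide_id: int = 0

    def __post_init__(self) -> None:
        if self.pixel_ratio_um <= 0:
            raise ValueError("pixel_ratio_um must be positive")
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[-1] != 3:
            raise ValueError("Slide pixels must be an RGB raster")

    @property
    def gray255(self) -> np.ndarray:
        px = self.pixels.astype(float)
        if px.max() <= 1.0:
            px = px * 255.0
        return px @ np.array([0.2125, 0.7154, 0.0721])


@dataclass
class RoiDetection:
    """Detected biopsy region: box, rotated rectangle and concave outline."""

    bounding_box: tuple[int, int, int, int]  # (x, y, w, h)
    rotated_rect: tuple[tuple[float, float], float, float, float]  # (center(x,y), w, h, angle_deg)
    roi_polygon_mask: np.ndarray  # filled concave contour, full-frame binary

    @property
    def angle_deg(self) -> float:
        return self.rotated_rect[3]


def _min_area_rect(points_xy: np.ndarray):
    """Minimum-area rotated rectangle of a point set.

    Returns (center(x, y), width, height, angle_deg) with width >= height and
    the angle of the width edge normalized to (-90, 90].
    """
    rect = MultiPoint(points_xy).minimum_rotated_rectangle
    if rect.geom_type != "Polygon":  # degenerate: line or point
        raise EmptySlideError("degenerate ROI (zero area)")
    corners = np.asarray(rect.exterior.coords)[:4]
    e1 = corners[1] - corners[0]
    e2 = corners[2] - corners[1]
    l1, l2 = np.linalg.norm(e1), np.linalg.norm(e2)
    if l1 >= l2:
        width, height, wvec = l1, l2, e1
    else:
        width, height, wvec = l2, l1, e2
    angle = np.degrees(np.arctan2(wvec[1], wvec[0]))
    while angle <= -90.0:
        angle += 180.0
    while angle > 90.0:
        angle -= 180.0
    center = tuple(corners[:4].mean(axis=0))
    return center, float(width), float(height), float(angle)


def detect_roi(
    slide: Slide,
    canny_low: float = 100.0,
    canny_high: float = 255.0,
    adaptive_block: int = 11,
    adaptive_offset: float = 2.0,
    adaptive_kind: str = "gaussian",
    closing_iterations: int = 15,
) -> RoiDetection:
    """Detect the biopsy ROI on a slide (deterministic operator chain).

    ``adaptive_kind`` chooses the local-threshold weighting (``gaussian`` or
    ``mean``); the Canny and adaptive maps are merged by pixelwise OR before
    the closing.  Ties in the largest-bounding-box rule break by component
    pixel count, then by the lowest (y, x) box origin.
    """
    gray = slide.gray255
    edges = feature.canny(gray, low_threshold=canny_low, high_threshold=canny_high)
    local = filters.threshold_local(
        gray, block_size=adaptive_block, method=adaptive_kind, offset=adaptive_offset
    )
    adaptive = gray < local  # inverted binary: tissue darker than background
    combined = edges | adaptive
    st = np.ones((3, 3), dtype=bool)
    closed = ndimage.binary_dilation(combined, structure=st, iterations=closing_iterations)
    # border_value=1: the canvas edge must not erode the band inward when the
    # crop margin is smaller than the closing radius
    closed = ndimage.binary_erosion(
        closed, structure=st, iterations=closing_iterations, border_value=1
    )

    labels, n = ndimage.label(closed)
    if n == 0:
        raise EmptySlideError("empty slide: no contour found")
    objects = ndimage.find_objects(labels)
    best = None
    for i, sl in enumerate(objects, start=1):
        h = sl[0].stop - sl[0].start
        w = sl[1].stop - sl[1].start
        box_area = w * h
        npix = int((labels[sl] == i).sum())
        key = (box_area, npix, -sl[0].start, -sl[1].start)
        if best is None or key > best[0]:
            best = (key, i, sl)
    _, idx, sl = best
    comp = labels == idx
    comp_filled = ndimage.binary_fill_holes(comp)

    ys, xs = np.nonzero(comp)
    pts = np.column_stack([xs, ys]).astype(float)
    center, width, height, angle = _min_area_rect(pts)
    bbox = (int(xs.min()), int(ys.min()), int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1))
    return RoiDetection(
        bounding_box=bbox,
        rotated_rect=(center, width, height, angle),
        roi_polygon_mask=comp_filled,
    )


@dataclass
class WorkingImage:
    """Coarsely aligned, downsampled export of one slide."""

    image: np.ndarray
    roi_mask: np.ndarray
    pixel_ratio_um: float
    downsample: float
    rotation_deg: float


def coarse_align_and_export(
    slide: Slide,
    roi: RoiDetection,
    target_shape: tuple[int, int] | None = None,
    downsample: float | None = None,
    pad_frac: float = 0.02,
) -> WorkingImage:
    """Rotate the slide upright, crop to the ROI, and export downsampled.

    Exactly one of ``target_shape`` (rows, cols) or ``downsample`` must be
    given; with ``downsample`` the output shape is the crop divided by that
    factor, and the output pixel ratio is the input ratio times the factor.
    Binary masks are rescaled bicubically and re-binarized at level 128.
    """
    if (target_shape is None) == (downsample is None):
        raise ValueError("give exactly one of target_shape or downsample")
    (cx, cy), rw, rh, angle = roi.rotated_rect
    if rw <= 0 or rh <= 0:
        raise ValueError("degenerate ROI (zero area)")

    img = slide.pixels.astype(float)
    if img.max() > 1.0:
        img = img / 255.0
    h, w = img.shape[:2]
    # rotate about the image centre so the rotated rectangle becomes upright
    rot = Affine2D(theta=-angle)
    upright = rot.warp(img, order=1, cval=1.0)
    mask_upright = rot.warp(roi.roi_polygon_mask.astype(float) * 255.0, order=3, cval=0.0)
    mask_upright = mask_upright >= 128.0

    # the rect centre moves with the rotation; crop the upright extents
    c_img = ((w - 1) / 2.0, (h - 1) / 2.0)
    new_c = rot.apply_points(np.array([[cx, cy]]), c_img)[0]
    pad_w, pad_h = pad_frac * rw, pad_frac * rh
    x0 = int(max(0, np.floor(new_c[0] - rw / 2 - pad_w)))
    x1 = int(min(w, np.ceil(new_c[0] + rw / 2 + pad_w)))
    y0 = int(max(0, np.floor(new_c[1] - rh / 2 - pad_h)))
    y1 = int(min(h, np.ceil(new_c[1] + rh / 2 + pad_h)))
    crop = upright[y0:y1, x0:x1]
    mask_crop = mask_upright[y0:y1, x0:x1]

    ch, cw = crop.shape[:2]
    if target_shape is not None:
        out_shape = tuple(int(v) for v in target_shape)
        factor = float(np.sqrt((ch * cw) / (out_shape[0] * out_shape[1])))
    else:
        factor = float(downsample)
        out_shape = (max(1, int(round(ch / factor))), max(1, int(round(cw / factor))))
    out = transform.resize(crop, out_shape + (3,), order=3, anti_aliasing=factor > 1)
    m = transform.resize(mask_crop.astype(float) * 255.0, out_shape, order=3, anti_aliasing=factor > 1)
    out_mask = m >= 128.0
    return WorkingImage(
        image=np.clip(out, 0.0, 1.0),
        roi_mask=out_mask,
        pixel_ratio_um=slide.pixel_ratio_um * factor,
        downsample=factor,
        rotation_deg=-angle,
    )
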