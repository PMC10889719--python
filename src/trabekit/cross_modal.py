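"""Final alignment: match histology slides to in-silico microCT slices.

The microCT volume is sliced in silico in the plane of the physical
sectioning.  For each (pre-aligned) histology slide, keypoint matching
against every CT slice yields a match-count profile along z; the count at
the true partner slice stands far above the background, and a bell curve
(Gaussian plus constant baseline) fitted to the profile localizes the peak
robustly against count noise — its mean, rounded, is the matched slice
index.  Each slide is then registered to its matched CT slice with the same
sequential affine optimizer used in pre-alignment, and the warped tissue
class masks are written into a labelled volume on the CT grid, so the
reconstruction is born registered to the microCT frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from trabekit.registration import (
    AffineBounds,
    ClassicalMatcher,
    consistent_match_count,
    estimate_similarity_from_matches,
    match_keypoints,
    optimize_affine,
)
from trabekit.transforms import Affine2D, warp_mask
from trabekit.volumes import CLASS_MISSING, LabeledVolume

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------- slicing
@dataclass(frozen=True)
class Plane:
    """Cut-plane family: unit normal (z, y, x) through the volume centre.

    ``(1, 0, 0)`` reproduces the native axial planes; oblique normals
    resample trilinearly.
    """

    normal: tuple[float, float, float] = (1.0, 0.0, 0.0)

    @property
    def unit_normal(self) -> np.ndarray:
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("plane normal must be nonzero")
        return n / norm

    @property
    def is_axis_aligned(self) -> bool:
        n = np.abs(self.unit_normal)
        return np.isclose(n.max(), 1.0)


@dataclass
class InSilicoStack:
    """Ordered grayscale slices cut from the CT volume along a plane normal."""

    slices: list[np.ndarray]
    plane: Plane
    spacing_um: float  # along the cut normal
    pixel_size_um: float  # in-plane

    def __len__(self) -> int:
        return len(self.slices)


def slice_volume(
    ct_volume: np.ndarray,
    plane: Plane | None = None,
    spacing_um: float | None = None,
    voxel_size_um: float = 11.0,
) -> InSilicoStack:
    """Cut the CT volume into planar sections along the plane normal.

    Axis-aligned cuts at native spacing return the raw voxel planes exactly;
    oblique cuts resample trilinearly onto square in-plane grids with the
    native voxel pitch.
    """
    vol = np.asarray(ct_volume, dtype=float)
    plane = plane or Plane()
    spacing_um = spacing_um if spacing_um is not None else voxel_size_um

    if plane.is_axis_aligned and abs(spacing_um - voxel_size_um) < 1e-9:
        axis = int(np.argmax(np.abs(plane.unit_normal)))
        vol_axis_first = np.moveaxis(vol, axis, 0)
        return InSilicoStack(
            slices=[vol_axis_first[k].copy() for k in range(vol_axis_first.shape[0])],
            plane=plane,
            spacing_um=voxel_size_um,
            pixel_size_um=voxel_size_um,
        )

    n = plane.unit_normal
    center = (np.array(vol.shape) - 1) / 2.0
    # in-plane orthonormal basis
    a = np.cross(n, [1.0, 0.0, 0.0])
    if np.linalg.norm(a) < 1e-8:
        a = np.cross(n, [0.0, 1.0, 0.0])
    a /= np.linalg.norm(a)
    b = np.cross(n, a)

    half_diag = float(np.linalg.norm(vol.shape)) / 2.0
    step = spacing_um / voxel_size_um
    n_half = int(np.floor(half_diag / step))
    offsets = np.arange(-n_half, n_half + 1) * step
    m = int(np.ceil(half_diag))
    ij = np.arange(-m, m + 1)
    oi, oj = np.meshgrid(ij, ij, indexing="ij")

    slices = []
    kept_any = False
    for off in offsets:
        base = center + off * n
        pts = base[:, None, None] + oi[None] * a[:, None, None] + oj[None] * b[:, None, None]
        inside = np.all(
            (pts >= -0.5) & (pts <= (np.array(vol.shape)[:, None, None] - 0.5)), axis=0
        )
        if not inside.any():
            if kept_any:
                break
            continue
        sl = ndimage.map_coordinates(vol, pts.reshape(3, -1), order=1, cval=0.0)
        slices.append(sl.reshape(oi.shape))
        kept_any = True
    if not slices:
        raise ValueError("plane does not intersect the volume")
    return InSilicoStack(
        slices=slices, plane=plane, spacing_um=spacing_um, pixel_size_um=voxel_size_um
    )


# ----------------------------------------------------------- peak profiling
@dataclass
class PeakFit:
    amplitude: float
    mu: float
    sigma: float
    baseline: float
    matched_index: int
    fallback: bool = False


@dataclass
class MatchProfile:
    """Per-CT-slice matched-keypoint counts for one histology slide."""

    counts: np.ndarray
    fit: PeakFit | None = None
    z_offset: int = 0  # index of counts[0] in the full CT stack

    @property
    def matched_index(self) -> int:
        if self.fit is None:
            raise ValueError("profile not yet fitted")
        return self.fit.matched_index + self.z_offset

    def peak_to_background(self, exclude_halfwidth: int = 3) -> float:
        """Peak count over the median background count (peak window excluded)."""
        c = np.asarray(self.counts, dtype=float)
        k = int(np.argmax(c))
        mask = np.ones(len(c), dtype=bool)
        lo, hi = max(0, k - exclude_halfwidth), min(len(c), k + exclude_halfwidth + 1)
        mask[lo:hi] = False
        bg = np.median(c[mask]) if mask.any() else 0.0
        return float(c[k] / max(bg, 1.0))


def fit_peak(counts) -> PeakFit:
    """Least-squares Gaussian-plus-baseline fit of a match-count profile.

    Initialized at (max - median, argmax, 2, median).  If the fit diverges
    (non-finite parameters or a width wider than the profile) the argmax is
    used instead and the result is flagged as a fallback.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 5:
        raise ValueError("need at least 5 slice counts to fit a peak")
    if counts.max() <= 0:
        raise ValueError("all-zero counts: no correspondence")
    z = np.arange(counts.size, dtype=float)
    k = int(np.argmax(counts))
    med = float(np.median(counts))
    p0 = (float(counts.max() - med), float(k), 2.0, med)

    def bell(zz, A, mu, sigma, b):
        return A * np.exp(-((zz - mu) ** 2) / (2.0 * sigma**2)) + b

    try:
        popt, _ = optimize.curve_fit(bell, z, counts, p0=p0, maxfev=5000)
        A, mu, sigma, b = (float(v) for v in popt)
        sigma = abs(sigma)
        ok = (
            np.isfinite([A, mu, sigma, b]).all()
            and 0 < sigma <= counts.size
            and A > 0
            and -1 <= mu <= counts.size
        )
    except (RuntimeError, optimize.OptimizeWarning, ValueError):
        ok = False
    if not ok:
        return PeakFit(
            amplitude=float(counts.max() - med),
            mu=float(k),
            sigma=float("nan"),
            baseline=med,
            matched_index=k,
            fallback=True,
        )
    idx = int(np.clip(round(mu), 0, counts.size - 1))
    return PeakFit(amplitude=A, mu=mu, sigma=sigma, baseline=b, matched_index=idx)


def ct_feature_cache(ct_stack: InSilicoStack, matcher) -> list | None:
    """Pre-extract matcher features for every CT slice (reused across slides)."""
    if not (hasattr(matcher, "extract") and hasattr(matcher, "match_features")):
        return None
    return [matcher.extract(s) for s in ct_stack.slices]


def keypoint_profile(
    histology_slide: np.ndarray,
    ct_stack: InSilicoStack,
    matcher=None,
    z_range: tuple[int, int] | None = None,
    count_mode: str = "inliers",
    ct_features: list | None = None,
) -> MatchProfile:
    """Match-count profile of one histology slide against every CT slice.

    ``count_mode="inliers"`` counts only matches consistent with a single
    similarity transform per slice (crossing match lines betray false
    matches), which keeps the off-partner background near zero;
    ``"matches"`` counts raw descriptor matches.  ``z_range`` optionally
    restricts the scan to ``[lo, hi)`` of the stack (the counts are then
    indexed from ``lo``).  All-zero counts raise a no-correspondence error.
    """
    matcher = matcher or ClassicalMatcher()
    gray = histology_slide
    if gray.ndim == 3:
        gray = gray @ np.array([0.2125, 0.7154, 0.0721])
    lo, hi = (0, len(ct_stack)) if z_range is None else z_range
    lo, hi = max(0, lo), min(len(ct_stack), hi)
    # keep at least 5 slices in view for the bell fit
    if hi - lo < 5:
        lo = max(0, hi - 5)
        hi = min(len(ct_stack), lo + 5)
    if count_mode not in ("inliers", "matches"):
        raise ValueError("count_mode must be 'inliers' or 'matches'")

    def score(mr) -> int:
        if count_mode == "matches":
            return mr.n_matches
        return consistent_match_count(mr)

    can_cache = hasattr(matcher, "extract") and hasattr(matcher, "match_features")
    counts = np.zeros(hi - lo, dtype=int)
    if can_cache:
        f_h = matcher.extract(gray)
        for i, k in enumerate(range(lo, hi)):
            f_ct = ct_features[k] if ct_features is not None else matcher.extract(ct_stack.slices[k])
            counts[i] = score(matcher.match_features(f_ct, f_h))
    else:
        for i, k in enumerate(range(lo, hi)):
            counts[i] = score(match_keypoints(ct_stack.slices[k], gray, matcher))
    if counts.max() == 0:
        raise ValueError("no correspondence: zero matches against every CT slice")
    prof = MatchProfile(counts=counts, z_offset=lo)
    prof.fit = fit_peak(counts)
    return prof


# --------------------------------------------------------------- assembly
@dataclass
class AssemblyReport:
    matched_indices: list[int]
    profiles: list[MatchProfile]
    transforms: list[Affine2D]
    collisions: list[tuple[int, int, int]] = field(default_factory=list)
    monotone_violations: list[int] = field(default_factory=list)
    skipped: list[int] = field(default_factory=list)  # slides with no correspondence


def register_and_assemble(
    slides: list[np.ndarray],
    class_masks: list[np.ndarray],
    ct_stack: InSilicoStack,
    matcher=None,
    hist_pixel_um: float | None = None,
    fill_missing: bool = False,
    enforce_monotone: bool = False,
    z_search_radius: int | None = None,
    bounds: AffineBounds | None = None,
) -> tuple[LabeledVolume, AssemblyReport]:
    """Register each slide to its matched CT slice and assemble the volume.

    One class mask per slide is required.  Masks are resampled to the CT
    in-plane pixel size (``hist_pixel_um``, default equal to CT), warped by
    the optimized transform (nearest neighbour) and written at the matched
    z.  CT planes matched by no slide are marked missing (class 255), or
    filled by nearest-plane replication with ``fill_missing``.  When two
    slides claim one CT index the higher peak wins and the loser demotes to
    its second-best index.  ``z_search_radius`` restricts each slide's scan
    to a window around the previous match (plus one spacing step), which
    keeps long stacks tractable.
    """
    if len(slides) != len(class_masks):
        raise ValueError("need exactly one class mask per slide")
    matcher = matcher or ClassicalMatcher()
    ct_px = ct_stack.pixel_size_um
    hist_pixel_um = hist_pixel_um if hist_pixel_um is not None else ct_px
    ct_shape = ct_stack.slices[0].shape

    zoom = hist_pixel_um / ct_px
    profiles: list[MatchProfile | None] = []
    matched: list[int | None] = []
    fits: list[Affine2D | None] = []
    skipped: list[int] = []
    ct_feats = ct_feature_cache(ct_stack, matcher)

    prev_match = None
    for i, (slide, mask) in enumerate(zip(slides, class_masks)):
        gray = slide
        if gray.ndim == 3:
            gray = gray @ np.array([0.2125, 0.7154, 0.0721])
        if abs(zoom - 1.0) > 1e-9:
            gray = ndimage.zoom(gray, zoom, order=1)
            mask = ndimage.zoom(mask, zoom, order=0)
        gray = _embed(gray, ct_shape, fill=float(np.median(gray)))
        mask = _embed(mask, ct_shape, fill=0)

        z_range = None
        if z_search_radius is not None and prev_match is not None:
            z_range = (prev_match - z_search_radius // 2, prev_match + z_search_radius + 1)
        try:
            prof = keypoint_profile(
                gray, ct_stack, matcher, z_range=z_range, ct_features=ct_feats
            )
        except ValueError:
            try:  # windowed scan found nothing: retry over the full stack
                prof = keypoint_profile(gray, ct_stack, matcher, ct_features=ct_feats)
            except ValueError:
                logger.warning("slide %d: no correspondence to any CT slice; skipped", i)
                skipped.append(i)
                profiles.append(None)
                matched.append(None)
                fits.append(None)
                continue
        z = prof.matched_index
        prev_match = z

        ct_slice = ct_stack.slices[z]
        mr = match_keypoints(ct_slice, gray, matcher)
        seed = estimate_similarity_from_matches(mr, gray.shape)
        local_bounds = bounds or AffineBounds()
        if seed is not None:
            glo = local_bounds.scale
            center = float(np.clip(seed.s, glo[0] + 0.02, glo[1] - 0.02))
            local_bounds = AffineBounds(8.0, 5.0, (center - 0.02, center + 0.02))
        fit = optimize_affine(
            gray, ct_slice, init=seed, bounds=local_bounds, smooth_sigma=1.0
        )

        profiles.append(prof)
        matched.append(z)
        fits.append(fit.transform)

    report = AssemblyReport(
        matched_indices=matched, profiles=profiles, transforms=fits, skipped=skipped
    )

    # collision resolution: higher peak keeps the index
    def peak_height(p: MatchProfile) -> float:
        return float(np.max(p.counts))

    claimed: dict[int, int] = {}
    final = list(matched)
    for i, z in enumerate(matched):
        if z is None:
            continue
        if z not in claimed:
            claimed[z] = i
            continue
        j = claimed[z]
        loser = i if peak_height(profiles[i]) <= peak_height(profiles[j]) else j
        winner = j if loser == i else i
        claimed[z] = winner
        c = profiles[loser].counts.copy().astype(float)
        order = np.argsort(c)[::-1] + profiles[loser].z_offset
        second = next((int(k) for k in order if int(k) not in claimed), None)
        logger.warning("slides %d and %d both matched CT slice %d; demoting %d to %s",
                       i, j, z, loser, second)
        report.collisions.append((i, j, z))
        if second is not None:
            final[loser] = second
            claimed[second] = loser

    placed = [z for z in final if z is not None]
    for a, b in zip(placed, placed[1:]):
        if b < a:
            report.monotone_violations.append(final.index(b))
    if enforce_monotone:
        running = None
        for i, z in enumerate(final):
            if z is None:
                continue
            if running is not None and z < running:
                final[i] = running
            running = final[i]
    report.matched_indices = final

    voxels = np.full((len(ct_stack),) + ct_shape, CLASS_MISSING, dtype=np.uint8)
    for i, z in enumerate(final):
        if z is None:
            continue
        mask = class_masks[i]
        if abs(zoom - 1.0) > 1e-9:
            mask = ndimage.zoom(mask, zoom, order=0)
        # pixels outside the slide footprint carry no evidence: mark missing
        mask = _embed(mask, ct_shape, fill=CLASS_MISSING)
        voxels[z] = warp_mask(mask.astype(np.uint8), fits[i], cval=CLASS_MISSING)

    placed_set = {z for z in final if z is not None}
    missing = [z for z in range(len(ct_stack)) if z not in placed_set]
    if fill_missing and missing:
        present = np.array(sorted(placed_set))
        for z in missing:
            nearest = int(present[np.argmin(np.abs(present - z))])
            voxels[z] = voxels[nearest]
        filled_missing: list[int] = []
    else:
        filled_missing = missing

    vol = LabeledVolume(
        voxels=voxels,
        spacing_um=(ct_stack.spacing_um, ct_px, ct_px),
        frame="ct",
        missing_planes=filled_missing,
    )
    return vol, report


def _embed(image: np.ndarray, shape: tuple[int, int], fill=0.0) -> np.ndarray:
    """Centre-crop or centre-pad a 2D array to ``shape``."""
    out = np.full(shape, fill, dtype=image.dtype)
    h, w = image.shape
    th, tw = shape
    # source and target windows
    sy = max(0, (h - th) // 2)
    sx = max(0, (w - tw) // 2)
    ty = max(0, (th - h) // 2)
    tx = max(0, (tw - w) // 2)
    ch = min(h, th)
    cw = min(w, tw)
    out[ty : ty + ch, tx : tx + cw] = image[sy : sy + ch, sx : sx + cw]
    return out
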