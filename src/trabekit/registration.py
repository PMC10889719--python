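"""Stack pre-alignment: keypoint matching and sequential affine optimization.

Two cooperating pieces:

* a pluggable **matcher contract** — any callable taking two grayscale images
  and returning a :class:`MatchResult` of paired keypoints.  The default
  backend is a classical oriented multi-scale corner detector with binary
  descriptors (skimage ORB) and cross-checked ratio-test matching, which
  needs no trained weights.  A transformer-based dense matcher can be plugged
  in through the same contract when its weights are available.

* a **sequential cross-entropy optimizer** that refines an in-plane
  similarity transform by coordinate descent: the optimal translation first,
  then rotation, then scale, each by bracketed 1-D search.  Separating the
  components stabilizes the search and avoids false optima of the joint
  problem.  The objective is the mean Bernoulli cross-entropy between the
  intensity-normalized fixed image and the warped moving image over their
  overlap (with an overlap-area floor to forbid degenerate escapes).

Pre-alignment walks the stack from one end, aligning each slide to whichever
already-aligned predecessor (within a window) shares the most keypoint
matches with it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from trabekit.transforms import Affine2D

logger = logging.getLogger(__name__)

_EPS = 1e-6


# ------------------------------------------------------------------ matching
@dataclass
class MatchResult:
    """Paired keypoints between two images, (x, y) coordinates."""

    keypoints_a: np.ndarray
    keypoints_b: np.ndarray
    confidences: np.ndarray
    backend: str = "classical"

    @property
    def n_matches(self) -> int:
        return len(self.keypoints_a)

    @property
    def displacements(self) -> np.ndarray:
        return self.keypoints_b - self.keypoints_a

    def parallel_fraction(self, tol_deg: float = 10.0) -> float:
        """Fraction of match vectors within ``tol_deg`` of the median direction.

        Crossing (non-parallel) match lines indicate false matches; a high
        parallel fraction is the sanity signal that a rigid-ish displacement
        dominates.  Zero-length vectors count as parallel.
        """
        d = self.displacements
        if len(d) == 0:
            return 0.0
        norms = np.linalg.norm(d, axis=1)
        moving = norms > 1e-9
        if not moving.any():
            return 1.0
        ang = np.degrees(np.arctan2(d[moving, 1], d[moving, 0]))
        med = np.median(ang)
        dev = np.abs((ang - med + 180.0) % 360.0 - 180.0)
        frac_moving = float((dev <= tol_deg).mean())
        return (frac_moving * moving.sum() + (~moving).sum()) / len(d)


class ClassicalMatcher:
    """Oriented multi-scale corner descriptors with ratio-test matching.

    Deterministic for fixed inputs and parameters; serves as the default,
    weight-free backend of the matcher contract.
    """

    name = "classical"

    def __init__(self, n_keypoints: int = 800, max_ratio: float = 0.9, fast_threshold: float = 0.02):
        self.n_keypoints = n_keypoints
        self.max_ratio = max_ratio
        self.fast_threshold = fast_threshold

    def extract(self, image):
        """Keypoints and descriptors of one image (cacheable)."""
        from skimage.feature import ORB

        orb = ORB(n_keypoints=self.n_keypoints, fast_threshold=self.fast_threshold)
        try:
            orb.detect_and_extract(np.asarray(image, dtype=float))
        except (RuntimeError, ValueError, IndexError):
            return None, None
        return orb.keypoints, orb.descriptors

    def match_features(self, feats_a, feats_b) -> MatchResult:
        from skimage.feature import match_descriptors

        ka, da = feats_a
        kb, db = feats_b
        if ka is None or kb is None or len(ka) == 0 or len(kb) == 0:
            return MatchResult(
                keypoints_a=np.empty((0, 2)),
                keypoints_b=np.empty((0, 2)),
                confidences=np.empty(0),
                backend=self.name,
            )
        matches = match_descriptors(da, db, cross_check=True, max_ratio=self.max_ratio)
        # keypoints come back (row, col); expose (x, y)
        a = ka[matches[:, 0]][:, ::-1]
        b = kb[matches[:, 1]][:, ::-1]
        return MatchResult(
            keypoints_a=a.astype(float),
            keypoints_b=b.astype(float),
            confidences=np.ones(len(a)),
            backend=self.name,
        )

    def __call__(self, image_a, image_b) -> MatchResult:
        return self.match_features(self.extract(image_a), self.extract(image_b))


def _fit_ransac_similarity(mr: MatchResult, residual_threshold: float = 2.0, seed: int = 0):
    """RANSAC similarity fit over the matched pairs; (model, n_inliers)."""
    if mr.n_matches < 3:
        return None, 0
    from skimage.measure import ransac
    from skimage.transform import SimilarityTransform

    try:
        model, inliers = ransac(
            (mr.keypoints_b, mr.keypoints_a),
            SimilarityTransform,
            min_samples=3,
            residual_threshold=residual_threshold,
            max_trials=300,
            rng=seed,
        )
    except (ValueError, ZeroDivisionError):
        return None, 0
    if model is None or inliers is None:
        return None, 0
    return model, int(inliers.sum())


def consistent_match_count(
    mr: MatchResult,
    residual_threshold: float = 2.0,
    min_inliers: int = 6,
    seed: int = 0,
) -> int:
    """Number of matches consistent with one similarity transform.

    Spurious matches between unrelated images scatter in random directions
    (they would draw crossing lines); matches on truly corresponding images
    agree on a single in-plane transform.  Counting RANSAC inliers therefore
    suppresses the background of a slice-matching profile.  Below
    ``min_inliers`` the count is reported as zero.
    """
    model, n = _fit_ransac_similarity(mr, residual_threshold, seed)
    if model is None or n < min_inliers:
        return 0
    s = float(model.scale)
    if not (0.5 < s < 2.0):
        return 0
    return n


def estimate_similarity_from_matches(
    mr: MatchResult,
    shape: tuple[int, int],
    residual_threshold: float = 2.0,
    min_inliers: int = 6,
    seed: int = 0,
) -> Affine2D | None:
    """Robust similarity estimate (RANSAC) mapping image B onto image A.

    Returns a centre-based :class:`Affine2D` suitable as an optimizer seed,
    or None when too few matches (or too few consistent inliers) support a
    model.
    """
    model, n_in = _fit_ransac_similarity(mr, residual_threshold, seed)
    if model is None or n_in < min_inliers:
        return None
    s = float(model.scale)
    if not (0.5 < s < 2.0):
        return None
    theta = float(np.degrees(model.rotation))
    # skimage maps p' = sR p + t about the origin; recentre about the image centre
    h, w = shape
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    lin = s * np.array(
        [[math.cos(math.radians(theta)), -math.sin(math.radians(theta))],
         [math.sin(math.radians(theta)), math.cos(math.radians(theta))]]
    )
    t_my = np.asarray(model.translation) + lin @ c - c
    return Affine2D(tx=float(t_my[0]), ty=float(t_my[1]), theta=theta, s=s)


def get_matcher(backend: str = "classical", **kwargs):
    """Resolve a matcher backend by name.

    Only the classical backend ships with the package; requesting an
    unavailable deep backend raises and names the fallback.
    """
    if backend == "classical":
        return ClassicalMatcher(**kwargs)
    raise ValueError(
        f"matcher backend {backend!r} is not available in this installation; "
        "use backend='classical' (weight-free fallback)"
    )


def match_keypoints(image_a, image_b, matcher=None) -> MatchResult:
    """Match keypoints between two grayscale images via the matcher contract."""
    image_a = np.asarray(image_a)
    image_b = np.asarray(image_b)
    if image_a.ndim != 2 or image_b.ndim != 2:
        raise ValueError("match_keypoints expects 2D grayscale images")
    if matcher is None:
        matcher = ClassicalMatcher()
    return matcher(image_a, image_b)


# ---------------------------------------------------------------- optimizer
@dataclass
class AffineBounds:
    """Search bounds for the sequential optimizer (about the initial guess)."""

    translation_px: float = 24.0
    rotation_deg: float = 15.0
    scale: tuple[float, float] = (0.9, 1.1)


@dataclass
class AffineFit:
    """Result of :func:`optimize_affine`: transform plus descent diagnostics."""

    transform: Affine2D
    objective: float
    stage_objectives: dict = field(default_factory=dict)


def _normalize01(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    lo, hi = img.min(), img.max()
    if hi - lo < 1e-12:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def cross_entropy_objective(
    moving01: np.ndarray,
    fixed01: np.ndarray,
    t: Affine2D,
    overlap_floor: float = 0.25,
    fixed_mask: np.ndarray | None = None,
) -> float:
    """Mean Bernoulli cross-entropy H(fixed, warp(moving)) over the overlap.

    Out-of-frame pixels are excluded, as are pixels outside ``fixed_mask``
    when given (so the objective scores tissue, not canvas background).  If
    the overlap covers less than ``overlap_floor`` of the scored region the
    objective is +inf (degenerate escape).
    """
    warped = t.warp(moving01, order=1, cval=-1.0)
    valid = warped >= 0.0
    if fixed_mask is not None:
        valid &= fixed_mask
        denom = max(int(fixed_mask.sum()), 1)
    else:
        denom = valid.size
    if valid.sum() / denom < overlap_floor:
        return float("inf")
    m = np.clip(warped[valid], _EPS, 1.0 - _EPS)
    f = fixed01[valid]
    ce = -(f * np.log(m) + (1.0 - f) * np.log(1.0 - m)).mean()
    if not np.isfinite(ce):
        raise FloatingPointError("non-finite registration objective")
    return float(ce)


def optimize_affine(
    moving: np.ndarray,
    fixed: np.ndarray,
    init: Affine2D | None = None,
    bounds: AffineBounds | None = None,
    tol: tuple[float, float, float] = (0.25, 0.05, 0.001),
    n_cycles: int = 2,
    coarse_stride_px: float = 8.0,
    smooth_sigma: float = 0.0,
    fixed_mask: np.ndarray | None = None,
) -> AffineFit:
    """Sequential similarity registration of ``moving`` onto ``fixed``.

    Coordinate descent over translation, then rotation, then scale (repeated
    ``n_cycles`` times): translation by an exhaustive coarse grid (stride
    ``coarse_stride_px``) refined by bounded golden-section searches per axis;
    rotation and scale by golden-section within their bounds.  ``tol`` gives
    the (px, deg, scale) search tolerances.  The returned objective never
    exceeds the objective at ``init``, and each stage is non-increasing.

    ``smooth_sigma`` Gaussian-smooths both images before the objective; on
    noisy inputs this removes the spurious advantage of blur-inducing warps
    (up-scaling or interpolation), which otherwise biases the scale stage.
    """
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed must share a shape")
    init = init or Affine2D()
    bounds = bounds or AffineBounds()
    from scipy import ndimage as _ndi

    if smooth_sigma > 0:
        moving = _ndi.gaussian_filter(np.asarray(moving, dtype=float), smooth_sigma)
        fixed = _ndi.gaussian_filter(np.asarray(fixed, dtype=float), smooth_sigma)
    m01 = _normalize01(moving)
    f01 = _normalize01(fixed)

    if fixed_mask is not None:
        fixed_mask = np.asarray(fixed_mask, dtype=bool)

    def obj(tx, ty, th, s):
        try:
            return cross_entropy_objective(
                m01, f01, Affine2D(tx, ty, th, s), fixed_mask=fixed_mask
            )
        except FloatingPointError:
            return float("inf")

    tx, ty, th, s = init.params
    best = obj(tx, ty, th, s)
    if not np.isfinite(best):
        raise ValueError("empty overlap (or non-finite objective) at the initial transform")
    stages = {"init": best}

    BIG = 1e9

    def golden(fun, lo, hi, xatol, x0, f0):
        """Bounded scalar minimization that never loses the incumbent."""
        if not lo < hi:
            return x0, f0
        res = optimize.minimize_scalar(
            lambda v: min(fun(v), BIG),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": xatol},
        )
        if np.isfinite(res.fun) and res.fun < f0:
            return float(res.x), float(res.fun)
        return x0, f0

    for cycle in range(n_cycles):
        # ---- translation: coarse grid then per-axis refinement
        r = bounds.translation_px if cycle == 0 else max(2.0, 2 * coarse_stride_px / (cycle + 1))
        stride = coarse_stride_px if cycle == 0 else max(1.0, coarse_stride_px / 2)
        grid = np.arange(-r, r + 1e-9, stride)
        gx_cand = grid + tx
        gy_cand = grid + ty  # freeze the grid; the incumbent moves, it must not
        for gx in gx_cand:
            for gy in gy_cand:
                v = obj(gx, gy, th, s)
                if v < best:
                    best, tx, ty = v, float(gx), float(gy)
        tx, best = golden(lambda v: obj(v, ty, th, s), tx - stride, tx + stride, tol[0], tx, best)
        ty, best = golden(lambda v: obj(tx, v, th, s), ty - stride, ty + stride, tol[0], ty, best)
        stages[f"translation_{cycle}"] = best
        # ---- rotation
        rr = bounds.rotation_deg if cycle == 0 else bounds.rotation_deg / (2 * (cycle + 1))
        th, best = golden(lambda v: obj(tx, ty, v, s), th - rr, th + rr, tol[1], th, best)
        stages[f"rotation_{cycle}"] = best
        # ---- scale
        s, best = golden(lambda v: obj(tx, ty, th, v), bounds.scale[0], bounds.scale[1], tol[2], s, best)
        stages[f"scale_{cycle}"] = best

    return AffineFit(transform=Affine2D(tx, ty, th, s), objective=best, stage_objectives=stages)


# ------------------------------------------------------------- pre-alignment
@dataclass
class PrealignResult:
    aligned: list[np.ndarray]
    transforms: list[Affine2D]
    reference_indices: list[int]
    flagged: list[int]  # slides with zero matches to every candidate


def _to_gray(image: np.ndarray) -> np.ndarray:
    if image.ndim == 3:
        return image @ np.array([0.2125, 0.7154, 0.0721])
    return np.asarray(image, dtype=float)


def _border_background(image: np.ndarray):
    """Per-channel median of the one-pixel image border (background estimate)."""
    border = np.concatenate(
        [image[0], image[-1], image[:, 0], image[:, -1]], axis=0
    )
    return np.median(border, axis=0)


def prealign_stack(
    stack: list[np.ndarray],
    matcher=None,
    direction: str = "forward",
    window: int = 5,
    bounds: AffineBounds | None = None,
    roi_masks: list[np.ndarray] | None = None,
    **opt_kwargs,
) -> PrealignResult:
    """Pre-align a slide stack by stepwise affine propagation.

    Walking the stack from one end, each slide is registered to the
    already-aligned predecessor (within the last ``window`` slides) that has
    the highest keypoint-match count with it; slides matching nothing are
    flagged and passed through with the identity transform.  ``roi_masks``
    (one per slide) restrict the intensity objective to tissue, which matters
    when slides carry uniform canvas margins.  Returns the aligned stack and
    the per-slide cumulative transforms.
    """
    if len(stack) < 2:
        raise ValueError("stack must contain at least 2 slides")
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    matcher = matcher or ClassicalMatcher()
    order = range(len(stack)) if direction == "forward" else range(len(stack) - 1, -1, -1)
    order = list(order)

    grays = [_to_gray(s) for s in stack]
    can_cache = hasattr(matcher, "extract") and hasattr(matcher, "match_features")
    feats = [matcher.extract(g) for g in grays] if can_cache else None

    def pair_match(j, i):
        if can_cache:
            return matcher.match_features(feats[j], feats[i])
        return match_keypoints(grays[j], grays[i], matcher)

    transforms: dict[int, Affine2D] = {}
    refs: dict[int, int] = {}
    flagged: list[int] = []

    first = order[0]
    transforms[first] = Affine2D()
    refs[first] = first

    for pos, i in enumerate(order[1:], start=1):
        candidates = order[max(0, pos - window) : pos]
        matches = {j: pair_match(j, i) for j in candidates}
        ranked = sorted(candidates, key=lambda j: matches[j].n_matches, reverse=True)
        if matches[ranked[0]].n_matches == 0:
            logger.warning("slide %d matched no candidate reference; passing through", i)
            flagged.append(i)
            transforms[i] = Affine2D()
            refs[i] = i
            continue
        # seed from the candidate with the most matches that yields a
        # RANSAC-consistent similarity; refine tightly around the seed
        ref, seed = ranked[0], None
        for j in ranked:
            if matches[j].n_matches == 0:
                break
            seed = estimate_similarity_from_matches(matches[j], grays[i].shape)
            if seed is not None:
                ref = j
                break
        if seed is None:
            ref = ranked[0]
            disp = np.median(
                matches[ref].keypoints_a - matches[ref].keypoints_b, axis=0
            )
            seed = Affine2D(tx=float(disp[0]), ty=float(disp[1]))
            local_bounds = bounds or AffineBounds()
        else:
            # refine tightly around the seed; in particular pin scale and
            # rotation, which the keypoint model estimates well and which the
            # intensity objective biases (warp interpolation blurs noise, and
            # smoother predictions lower the cross-entropy), a bias that
            # compounds along the chain
            glo = (bounds or AffineBounds()).scale
            center = float(np.clip(seed.s, glo[0] + 0.005, glo[1] - 0.005))
            local_bounds = AffineBounds(
                translation_px=4.0,
                rotation_deg=1.0,
                scale=(center - 0.005, center + 0.005),
            )
        opt_kwargs.setdefault("smooth_sigma", 1.0)
        fit = optimize_affine(
            grays[i],
            grays[ref],
            init=seed,
            bounds=local_bounds,
            fixed_mask=None if roi_masks is None else roi_masks[ref],
            **opt_kwargs,
        )
        # relative fit maps slide i into the *raw* frame of the reference;
        # compose with the reference's cumulative transform
        transforms[i] = transforms[ref].compose(fit.transform)
        refs[i] = ref

    n = len(stack)
    aligned = [
        transforms[i].warp(stack[i], order=1, cval=_border_background(stack[i]))
        for i in range(n)
    ]
    return PrealignResult(
        aligned=aligned,
        transforms=[transforms[i] for i in range(n)],
        reference_indices=[refs[i] for i in range(n)],
        flagged=sorted(flagged),
    )
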