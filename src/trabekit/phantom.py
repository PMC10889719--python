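"""Synthetic trabecular phantoms with full ground truth.

The generator emulates the study object end to end: a binary trabecular
network at a prescribed volume fraction (a thresholded Gaussian random field),
a noisy/blurred grayscale microCT rendering of it, and a stained serial-section
stack produced by slicing the volume, applying known per-slide affine jitter
and random slide dropout.  Because every corruption is recorded, each
downstream stage (ROI detection, pre-alignment, cross-modal matching,
segmentation, morphometry) can be tested against exact truth without any
external data.

Deterministic: a fixed seed yields byte-identical phantoms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from trabekit.transforms import Affine2D, warp_mask
from trabekit.volumes import (
    CLASS_BONE,
    CLASS_GRAFT,
    CLASS_NON_MINERALIZED,
    LabeledVolume,
)

# Fixed stain palette (RGB in [0, 1]).  These hues are a test fixture meant to
# be *distinguishable*, not a chemical model of H&E staining.
STAIN_COLORS = {
    CLASS_NON_MINERALIZED: (0.95, 0.82, 0.86),  # pale pink soft tissue
    CLASS_BONE: (0.85, 0.35, 0.45),  # eosin pink bone
    CLASS_GRAFT: (0.55, 0.35, 0.65),  # violet graft particles
}
BACKGROUND_COLOR = (1.0, 1.0, 1.0)  # glass slide


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic trabecular volume.

    ``correlation_length_um`` sets the feature scale of the random field
    (trabecular strut/spacing scale); ``target_bvtv`` is the mineralized
    volume fraction in (0, 1); ``graft_fraction`` is the fraction of
    mineralized voxels relabelled as graft, in [0, 1).
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size_um: float = 11.0
    target_bvtv: float = 0.30
    correlation_length_um: float = 60.0
    graft_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.target_bvtv < 1.0):
            raise ValueError("target_bvtv must be strictly between 0 and 1")
        if len(self.grid_shape) != 3 or any(n < 32 for n in self.grid_shape):
            raise ValueError("grid_shape must be three integers, each >= 32")
        if self.voxel_size_um <= 0 or self.correlation_length_um <= 0:
            raise ValueError("voxel size and correlation length must be positive")
        if not (0.0 <= self.graft_fraction < 1.0):
            raise ValueError("graft_fraction must be in [0, 1)")
        sigma_vox = self.correlation_length_um / self.voxel_size_um
        if sigma_vox > min(self.grid_shape):
            raise ValueError(
                "grid too small to host one correlation length: "
                f"correlation length is {sigma_vox:.1f} voxels but the smallest "
                f"grid axis is {min(self.grid_shape)}; enlarge grid_shape or "
                "reduce correlation_length_um"
            )


@dataclass(frozen=True)
class HistologySimSpec:
    """Per-slide corruption model for the simulated serial sections.

    Sections default to 5 um thickness.  Each retained slide is warped by a
    random similarity transform drawn uniformly within the jitter bounds;
    slides are independently discarded ("torn") with ``dropout_prob``.
    """

    slice_thickness_um: float = 5.0
    max_rotation_deg: float = 10.0
    max_translation_px: float = 20.0
    max_scale_dev: float = 0.03
    dropout_prob: float = 0.0
    stain_noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slice_thickness_um <= 0:
            raise ValueError("slice_thickness_um must be positive")
        for name in ("max_rotation_deg", "max_translation_px", "max_scale_dev", "stain_noise_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative")
        if not (0.0 <= self.dropout_prob < 1.0):
            raise ValueError("dropout_prob must be in [0, 1)")


@dataclass
class GroundTruth:
    """Everything needed to score a reconstruction of the simulated stack."""

    transforms: list[Affine2D]  # applied jitter, one per retained slide
    z_indices: list[int]  # source z-plane in the volume per retained slide
    class_masks: list[np.ndarray]  # per-slide class mask *after* jitter
    clean_masks: list[np.ndarray]  # per-slide class mask before jitter
    dropped_z_indices: list[int]
    mineralized_volume: np.ndarray  # binary (z, y, x)

    def save(self, path) -> None:
        path = Path(path)
        meta = {
            "transforms": [t.to_list() for t in self.transforms],
            "z_indices": [int(z) for z in self.z_indices],
            "dropped_z_indices": [int(z) for z in self.dropped_z_indices],
            "transform_format": "[tx, ty, theta_deg, scale] about image centre",
        }
        path.write_text(json.dumps(meta, indent=2))


# --------------------------------------------------------------------- volume
def generate_trabecular_volume(spec: PhantomSpec) -> tuple[LabeledVolume, np.ndarray]:
    """Generate a three-class trabecular volume and its smooth source field.

    A Gaussian random field (white noise filtered at the correlation length)
    is thresholded at the quantile that pins the mineralized fraction to
    ``target_bvtv``; a ``graft_fraction`` of mineralized voxels, selected as
    contiguous blobs of a second independent smooth field, is relabelled
    graft.

    Returns the labelled volume and the underlying smooth field (useful for
    simulating partial-volume effects).
    """
    rng = np.random.default_rng(spec.seed)
    sigma_vox = spec.correlation_length_um / spec.voxel_size_um

    fld = rng.standard_normal(spec.grid_shape)
    fld = ndimage.gaussian_filter(fld, sigma=sigma_vox, mode="reflect")
    thr = np.quantile(fld, 1.0 - spec.target_bvtv)
    mineralized = fld > thr

    frac = mineralized.mean()
    if abs(frac - spec.target_bvtv) > 0.005:
        # only possible with massive value ties; regenerate is pointless, report
        raise RuntimeError(
            f"quantile thresholding missed target BV/TV: {frac:.4f} vs {spec.target_bvtv}"
        )

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    labels[mineralized] = CLASS_BONE

    if spec.graft_fraction > 0:
        blob = rng.standard_normal(spec.grid_shape)
        blob = ndimage.gaussian_filter(blob, sigma=sigma_vox, mode="reflect")
        vals = blob[mineralized]
        cut = np.quantile(vals, 1.0 - spec.graft_fraction)
        graft = mineralized & (blob > cut)
        labels[graft] = CLASS_GRAFT

    vol = LabeledVolume(
        voxels=labels,
        spacing_um=(spec.voxel_size_um,) * 3,
        frame="phantom",
    )
    return vol, fld


def simulate_microct(
    labeled_volume: LabeledVolume,
    blur_sigma_vox: float = 1.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Render a grayscale microCT-like volume of the mineralized phase.

    Mineralized classes (bone and graft are both radiopaque) map to intensity
    1, non-mineralized to 0; Gaussian blur then additive Gaussian noise are
    applied and the result is clipped to [0, 1].
    """
    if blur_sigma_vox < 0 or noise_sd < 0:
        raise ValueError("blur sigma and noise SD must be nonnegative")
    fg = np.isin(labeled_volume.voxels, (CLASS_BONE, CLASS_GRAFT))
    img = fg.astype(float)
    if blur_sigma_vox > 0:
        img = ndimage.gaussian_filter(img, sigma=blur_sigma_vox, mode="reflect")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


# ------------------------------------------------------------------ histology
def stain_slide(class_mask: np.ndarray, noise_sd: float = 0.0, rng=None) -> np.ndarray:
    """Colour a 2D class mask with the fixed stain palette (+ optional noise)."""
    out = np.empty(class_mask.shape + (3,), dtype=float)
    for cls, color in STAIN_COLORS.items():
        out[class_mask == cls] = color
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return np.clip(out, 0.0, 1.0)


def simulate_histology_stack(
    labeled_volume: LabeledVolume,
    sim: HistologySimSpec,
) -> tuple[list[np.ndarray], GroundTruth]:
    """Slice the volume into stained, jittered serial sections.

    Each section at physical depth ``k * slice_thickness_um`` takes the class
    map at z-index ``floor(depth / voxel_size)``; it is stain-coloured, then
    warped by a random similarity transform drawn within the jitter bounds
    (recorded exactly in the ground truth).  Slides are dropped independently
    with ``dropout_prob``.
    """
    rng = np.random.default_rng(sim.seed)
    vox_z = labeled_volume.spacing_um[0]
    nz = labeled_volume.shape[0]

    depths = np.arange(0, nz * vox_z - 1e-9, sim.slice_thickness_um)
    z_indices_all = np.minimum((depths / vox_z).astype(int), nz - 1)

    slides: list[np.ndarray] = []
    truth = GroundTruth(
        transforms=[],
        z_indices=[],
        class_masks=[],
        clean_masks=[],
        dropped_z_indices=[],
        mineralized_volume=np.isin(
            labeled_volume.voxels, (CLASS_BONE, CLASS_GRAFT)
        ),
    )

    for z in z_indices_all:
        # draw jitter and dropout for every section so the random stream does
        # not depend on which slides survive
        dropped = rng.random() < sim.dropout_prob
        t = Affine2D(
            tx=float(rng.uniform(-sim.max_translation_px, sim.max_translation_px)),
            ty=float(rng.uniform(-sim.max_translation_px, sim.max_translation_px)),
            theta=float(rng.uniform(-sim.max_rotation_deg, sim.max_rotation_deg)),
            s=float(rng.uniform(1.0 - sim.max_scale_dev, 1.0 + sim.max_scale_dev)),
        )
        clean_mask = labeled_volume.voxels[int(z)].astype(np.uint8)
        if dropped:
            truth.dropped_z_indices.append(int(z))
            # burn the stain-noise draw for stream stability
            if sim.stain_noise_sd > 0:
                rng.normal(size=clean_mask.shape + (3,))
            continue
        jittered_mask = warp_mask(clean_mask, t, cval=CLASS_NON_MINERALIZED)
        rgb = stain_slide(
            jittered_mask,
            noise_sd=0.0,
        )
        if sim.stain_noise_sd > 0:
            rgb = np.clip(
                rgb + rng.normal(0.0, sim.stain_noise_sd, size=rgb.shape), 0.0, 1.0
            )
        slides.append(rgb)
        truth.transforms.append(t)
        truth.z_indices.append(int(z))
        truth.class_masks.append(jittered_mask)
        truth.clean_masks.append(clean_mask)

    if not slides:
        raise ValueError("dropout removed every slide; lower dropout_prob")
    return slides, truth


# ----------------------------------------------------- analytic test lattices
def parallel_plates(
    shape: tuple[int, int, int],
    plate_thickness_vox: int = 5,
    gap_vox: int = 10,
    axis: int = 0,
    phase_vox: int = 0,
) -> np.ndarray:
    """Binary plate lattice: plates of known thickness separated by known gaps.

    The analytic geometry makes thickness/separation/anisotropy oracles exact.
    ``phase_vox`` shifts the pattern along ``axis`` (e.g. to keep every plate
    away from the volume faces).
    """
    n = shape[axis]
    period = plate_thickness_vox + gap_vox
    coords = (np.arange(n) + phase_vox) % period
    line = coords < plate_thickness_vox
    out = np.zeros(shape, dtype=bool)
    expander = [np.newaxis] * 3
    expander[axis] = slice(None)
    out |= line[tuple(expander)]
    return out


def solid_ball(radius_vox: float, pad: int = 4) -> np.ndarray:
    """Voxelized solid ball: centre-inclusion rule ``x² + y² + z² <= r²``."""
    n = int(np.ceil(radius_vox)) + pad
    ax = np.arange(-n, n + 1)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    return zz**2 + yy**2 + xx**2 <= radius_vox**2


def hollow_shell(outer_radius_vox: float, inner_radius_vox: float, pad: int = 4) -> np.ndarray:
    """Spherical shell enclosing one cavity (Euler characteristic 2)."""
    n = int(np.ceil(outer_radius_vox)) + pad
    ax = np.arange(-n, n + 1)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    r2 = zz**2 + yy**2 + xx**2
    return (r2 <= outer_radius_vox**2) & (r2 > inner_radius_vox**2)


# ------------------------------------------------------------------------ i/o
def save_stack(slides, out_dir, prefix: str = "slide") -> list[Path]:
    """Write slides as numbered PNGs; returns the written paths."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, s in enumerate(slides):
        p = out_dir / f"{prefix}_{i:04d}.png"
        iio.imwrite(p, (np.clip(s, 0, 1) * 255).astype(np.uint8))
        paths.append(p)
    return paths


def load_stack(in_dir, prefix: str = "slide") -> list[np.ndarray]:
    import imageio.v3 as iio

    paths = sorted(Path(in_dir).glob(f"{prefix}_*.png"))
    return [iio.imread(p).astype(float) / 255.0 for p in paths]
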