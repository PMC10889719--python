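"""End-to-end orchestration: phantom → prep → prealign → segment →
reconstruct → morphometry → compare, as one configured, logged, resumable
run with a manifest.

The configuration is a single YAML mapping (see ``DEFAULT_CONFIG``);
:func:`validate_config` fills defaults, rejects unknown keys and checks
cross-field constraints.  :func:`run` executes the enabled stages in order,
records per-stage status, output checksums and warnings into a
:class:`RunManifest`, and writes the manifest even when a stage fails.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from trabekit import phantom as phantom_mod
from trabekit import wsi_prep
from trabekit.cross_modal import Plane, register_and_assemble, slice_volume
from trabekit.morphometry import binarize, morphometry_table, tile_volume
from trabekit.registration import AffineBounds, ClassicalMatcher, prealign_stack
from trabekit.segmentation import UNetConfig, predict_ensemble, postprocess, tile_image, train_kfold
from trabekit.compare_stats import DEFAULT_PARAMETERS, build_agreement_report, plot_agreement
from trabekit.volumes import LabeledVolume, save_grayscale_volume

logger = logging.getLogger(__name__)

STAGES = ["phantom", "prep", "prealign", "segment", "reconstruct", "morphometry", "compare"]

DEFAULT_CONFIG: dict = {
    "out_dir": "runs/demo",
    "seed": 0,
    "stages": {s: True for s in STAGES},
    "phantom": {
        # in-plane aspect deliberately non-square so the upright-rotation
        # convention (width >= height) is stable across jittered slides
        "grid_shape": [40, 96, 128],
        "voxel_size_um": 11.0,
        "target_bvtv": 0.30,
        "correlation_length_um": 44.0,
        "graft_fraction": 0.25,
        "blur_sigma_vox": 1.0,
        "noise_sd": 0.05,
        "histology": {
            "slice_thickness_um": 11.0,
            "max_rotation_deg": 10.0,
            "max_translation_px": 20.0,
            "max_scale_dev": 0.03,
            "dropout_prob": 0.0,
            "stain_noise_sd": 0.03,
        },
    },
    "prep": {
        "downsample": 1.0,
        "adaptive_kind": "gaussian",
        "margin_px": 16,
    },
    "prealign": {
        "window": 3,
        "matcher": {"backend": "classical", "n_keypoints": 400},
        "translation_px": 16.0,
        "rotation_deg": 22.0,
    },
    "segment": {
        "preset": "tiny",
        "n_training_slides": 4,
        "n_training_tiles": 75,
        "folds": 5,
    },
    "reconstruct": {
        "z_search_radius": 8,
        "fill_missing": True,
        "enforce_monotone": False,
        "matcher": {"backend": "classical", "n_keypoints": 400},
    },
    "morphometry": {
        "prism_size_um": [220.0, 176.0, 176.0],
        "ct_binarize": "otsu",
        "hist_binarize": "labels:bone,graft",
        "tb_n_model": "inverse-thickness",
    },
    "compare": {
        "parameters": list(DEFAULT_PARAMETERS),
        "orientation": "b-minus-a",
        "plots": True,
    },
}


class ConfigError(ValueError):
    pass


def validate_config(config: dict | str | Path | None) -> dict:
    """Normalize a pipeline configuration: defaults, unknown keys, units.

    ``config`` may be a mapping, a YAML path, or None/empty (fully-defaulted
    phantom demo).  Each violation is reported with its field path.
    """
    if config is None:
        raw: dict = {}
    elif isinstance(config, (str, Path)):
        text = Path(config).read_text()
        raw = yaml.safe_load(text) or {}
    else:
        raw = copy.deepcopy(config)
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")

    errors: list[str] = []

    def merge(defaults, override, path=""):
        out = copy.deepcopy(defaults)
        for k, v in override.items():
            p = f"{path}.{k}" if path else k
            if k not in defaults:
                errors.append(f"unknown key: {p}")
                continue
            if isinstance(defaults[k], dict) and isinstance(v, dict):
                out[k] = merge(defaults[k], v, p)
            else:
                out[k] = v
        return out

    cfg = merge(DEFAULT_CONFIG, raw)

    ph = cfg["phantom"]
    if not (0 < ph["target_bvtv"] < 1):
        errors.append("phantom.target_bvtv: must be in (0, 1)")
    if ph["voxel_size_um"] <= 0:
        errors.append("phantom.voxel_size_um: must be positive (µm)")
    if ph["histology"]["slice_thickness_um"] <= 0:
        errors.append("phantom.histology.slice_thickness_um: must be positive (µm)")
    seg = cfg["segment"]
    if seg["preset"] not in ("tiny", "paper"):
        errors.append("segment.preset: must be 'tiny' or 'paper'")
    else:
        ucfg = UNetConfig.tiny() if seg["preset"] == "tiny" else UNetConfig.paper()
        if ucfg.tile % 2**ucfg.depth:
            errors.append(
                f"segment: input size {ucfg.tile} not divisible by {2 ** ucfg.depth}"
            )
    if any(v <= 0 for v in cfg["morphometry"]["prism_size_um"]):
        errors.append("morphometry.prism_size_um: must be positive (µm)")
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


@dataclass
class StageRecord:
    status: str = "pending"  # pending | complete | failed | skipped
    seconds: float = 0.0
    outputs: dict = field(default_factory=dict)  # filename -> sha256
    warnings: list = field(default_factory=list)
    error: str | None = None


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict = field(default_factory=dict)

    def save(self, path) -> None:
        payload = {
            "config": self.config,
            "version": self.version,
            "stages": {
                k: {
                    "status": v.status,
                    "seconds": round(v.seconds, 3),
                    "outputs": v.outputs,
                    "warnings": v.warnings,
                    "error": v.error,
                }
                for k, v in self.stages.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _checksum_outputs(rec: StageRecord, paths) -> None:
    for p in paths:
        p = Path(p)
        if p.exists():
            rec.outputs[p.name] = _sha256(p)


def _pseudo_ct(rgb: np.ndarray) -> np.ndarray:
    """Map a stained slide to CT-like contrast (mineralized bright)."""
    gray = rgb @ np.array([0.2125, 0.7154, 0.0721]) if rgb.ndim == 3 else rgb
    return 1.0 - gray


def run(config: dict | str | Path | None = None) -> RunManifest:
    """Execute the configured pipeline; returns the run manifest.

    Stage outputs land under ``out_dir``; a failing stage halts the run, and
    the manifest (written in all cases) records the failure and leaves the
    earlier outputs intact.
    """
    from trabekit import __version__

    cfg = validate_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, version=__version__)
    state: dict = {}
    try:
        for stage in STAGES:
            rec = StageRecord()
            manifest.stages[stage] = rec
            if not cfg["stages"].get(stage, True):
                rec.status = "skipped"
                continue
            t0 = time.time()
            try:
                _STAGE_FNS[stage](cfg, state, out, rec)
                rec.status = "complete"
            except Exception as e:  # noqa: BLE001 - manifest must record any failure
                rec.status = "failed"
                rec.error = f"{type(e).__name__}: {e}"
                logger.exception("stage %s failed", stage)
                raise
            finally:
                rec.seconds = time.time() - t0
    finally:
        manifest.save(out / "manifest.json")
    return manifest


# ------------------------------------------------------------------- stages
def _stage_phantom(cfg, state, out, rec):
    p = cfg["phantom"]
    seed = cfg["seed"]
    spec = phantom_mod.PhantomSpec(
        grid_shape=tuple(p["grid_shape"]),
        voxel_size_um=p["voxel_size_um"],
        target_bvtv=p["target_bvtv"],
        correlation_length_um=p["correlation_length_um"],
        graft_fraction=p["graft_fraction"],
        seed=seed,
    )
    vol, _ = phantom_mod.generate_trabecular_volume(spec)
    ct = phantom_mod.simulate_microct(vol, p["blur_sigma_vox"], p["noise_sd"], seed=seed + 1)
    h = p["histology"]
    sim = phantom_mod.HistologySimSpec(seed=seed + 2, **{k: h[k] for k in h})
    slides, truth = phantom_mod.simulate_histology_stack(vol, sim)
    state.update(volume=vol, ct=ct, slides=slides, truth=truth, spec=spec)
    vol.save(out / "phantom_labels.tif")
    save_grayscale_volume(out / "phantom_ct.tif", ct, vol.spacing_um)
    truth.save(out / "ground_truth.json")
    _checksum_outputs(rec, [out / "phantom_labels.tif", out / "phantom_ct.tif", out / "ground_truth.json"])


def _stage_prep(cfg, state, out, rec):
    p = cfg["prep"]
    margin = int(p["margin_px"])
    working = []
    for i, rgb in enumerate(state["slides"]):
        framed = np.pad(
            rgb, ((margin, margin), (margin, margin), (0, 0)), constant_values=1.0
        )
        slide = wsi_prep.Slide(framed, pixel_ratio_um=state["spec"].voxel_size_um, slide_id=i)
        try:
            roi = wsi_prep.detect_roi(slide, adaptive_kind=p["adaptive_kind"])
            wi = wsi_prep.coarse_align_and_export(slide, roi, downsample=p["downsample"])
            working.append(wi)
        except wsi_prep.EmptySlideError:
            rec.warnings.append(f"slide {i}: empty, skipped")
    if not working:
        raise RuntimeError("prep produced no working images")
    # embed on a common canvas for stackwise registration
    hmax = max(w.image.shape[0] for w in working)
    wmax = max(w.image.shape[1] for w in working)
    canvas_shape = (hmax, wmax)
    from trabekit.cross_modal import _embed

    images = []
    masks = []
    for w in working:
        img = np.stack(
            [_embed(w.image[..., c], canvas_shape, fill=1.0) for c in range(3)], axis=-1
        )
        images.append(img)
        masks.append(_embed(w.roi_mask.astype(np.uint8), canvas_shape, fill=0) > 0)
    state["working"] = images
    state["working_masks"] = masks
    state["pixel_ratio_um"] = working[0].pixel_ratio_um
    rec.outputs["n_working_images"] = str(len(images))


def _stage_prealign(cfg, state, out, rec):
    p = cfg["prealign"]
    matcher = ClassicalMatcher(n_keypoints=p["matcher"]["n_keypoints"])
    res = prealign_stack(
        state["working"],
        matcher=matcher,
        window=p["window"],
        bounds=AffineBounds(p["translation_px"], p["rotation_deg"]),
        roi_masks=state.get("working_masks"),
    )
    if res.flagged:
        rec.warnings.append(f"slides flagged (no matches): {res.flagged}")
    state["aligned"] = res.aligned
    state["prealign_transforms"] = res.transforms
    (out / "prealign_transforms.json").write_text(
        json.dumps(
            {
                "convention": "[tx, ty, theta_deg, scale] about image centre",
                "transforms": [t.to_list() for t in res.transforms],
            },
            indent=2,
        )
    )
    _checksum_outputs(rec, [out / "prealign_transforms.json"])


def _stage_segment(cfg, state, out, rec):
    p = cfg["segment"]
    seed = cfg["seed"]
    truth = state["truth"]
    ucfg = (
        UNetConfig.tiny(seed=seed, folds=p["folds"])
        if p["preset"] == "tiny"
        else UNetConfig.paper(seed=seed, folds=p["folds"])
    )
    # annotation emulation: stain tiles + class masks from a few slides
    rng = np.random.default_rng(seed + 10)
    step = max(1, len(state["slides"]) // p["n_training_slides"])
    tiles, masks = [], []
    for i in range(0, len(state["slides"]), step):
        tiles.append(tile_image(state["slides"][i], tile=ucfg.tile, overlap=ucfg.overlap).tiles)
        masks.append(
            tile_image(truth.class_masks[i], tile=ucfg.tile, overlap=ucfg.overlap).tiles
        )
    tiles = np.concatenate(tiles)
    masks = np.concatenate(masks)
    if len(tiles) > p["n_training_tiles"]:
        sel = rng.choice(len(tiles), p["n_training_tiles"], replace=False)
        tiles, masks = tiles[sel], masks[sel]
    ensemble = train_kfold(tiles, masks, ucfg)
    rec.outputs["fold_accuracies"] = json.dumps([round(a, 4) for a in ensemble.val_accuracies])
    pred_masks = []
    for img in state["aligned"]:
        prob = predict_ensemble(img, ensemble)
        pred_masks.append(postprocess(prob, filter_size=8, sigma_color=64, sigma_space=8))
    state["ensemble"] = ensemble
    state["pred_masks"] = pred_masks


def _stage_reconstruct(cfg, state, out, rec):
    p = cfg["reconstruct"]
    matcher = ClassicalMatcher(n_keypoints=p["matcher"]["n_keypoints"])
    ct_stack = slice_volume(
        state["ct"], Plane(), voxel_size_um=state["spec"].voxel_size_um
    )
    pseudo = [_pseudo_ct(img) for img in state["aligned"]]
    vol, report = register_and_assemble(
        pseudo,
        state["pred_masks"],
        ct_stack,
        matcher=matcher,
        hist_pixel_um=state.get("pixel_ratio_um", state["spec"].voxel_size_um),
        fill_missing=p["fill_missing"],
        enforce_monotone=p["enforce_monotone"],
        z_search_radius=p["z_search_radius"],
    )
    if report.collisions:
        rec.warnings.append(f"z-collisions: {report.collisions}")
    if report.skipped:
        rec.warnings.append(f"slides without CT correspondence: {report.skipped}")
    if report.monotone_violations:
        rec.warnings.append(f"non-monotone matches at slides {report.monotone_violations}")
    state["reconstruction"] = vol
    state["assembly"] = report
    vol.save(out / "reconstruction.tif")
    pd.DataFrame(
        {
            "slide": range(len(report.matched_indices)),
            "matched_z": report.matched_indices,
        }
    ).to_csv(out / "slice_matches.csv", index=False)
    # per-slide match-count profiles for bell-curve diagnostics
    rows = []
    for slide_id, prof in enumerate(report.profiles):
        if prof is None:
            continue
        for k, c in enumerate(prof.counts):
            rows.append({"slide_id": slide_id, "z": prof.z_offset + k, "count": int(c)})
    pd.DataFrame(rows).to_csv(out / "match_profiles.csv", index=False)
    _checksum_outputs(
        rec,
        [out / "reconstruction.tif", out / "slice_matches.csv", out / "match_profiles.csv"],
    )


def _stage_morphometry(cfg, state, out, rec):
    p = cfg["morphometry"]
    spec = state["spec"]
    ct_bin = binarize(state["ct"], p["ct_binarize"], spacing_um=(spec.voxel_size_um,) * 3)
    hist_bin = binarize(state["reconstruction"], p["hist_binarize"])
    # prisms must lie where the reconstruction carries evidence on every plane
    from trabekit.volumes import CLASS_MISSING

    roi = state["reconstruction"].voxels != CLASS_MISSING
    grid = tile_volume(ct_bin, roi_mask=roi, prism_size_um=tuple(p["prism_size_um"]))
    t_ct = morphometry_table(ct_bin, grid, tb_n_model=p["tb_n_model"])
    t_hist = morphometry_table(hist_bin, grid, tb_n_model=p["tb_n_model"])
    t_ct.to_csv(out / "morphometry_ct.csv", index=False)
    t_hist.to_csv(out / "morphometry_histology.csv", index=False)
    state["morph_ct"] = t_ct
    state["morph_hist"] = t_hist
    state["prism_grid"] = grid
    rec.outputs["n_prisms"] = str(grid.count)
    _checksum_outputs(rec, [out / "morphometry_ct.csv", out / "morphometry_histology.csv"])


def _stage_compare(cfg, state, out, rec):
    p = cfg["compare"]
    table, reports = build_agreement_report(
        state["morph_ct"],
        state["morph_hist"],
        parameters=p["parameters"],
        orientation=p["orientation"],
    )
    table.to_csv(out / "agreement.csv", index=False)
    if p["plots"]:
        for r in reports:
            safe = r.parameter.replace("/", "-").replace(".", "_")
            plot_agreement(r, out / f"agreement_{safe}.png")
    state["agreement"] = table
    _checksum_outputs(rec, [out / "agreement.csv"])


_STAGE_FNS = {
    "phantom": _stage_phantom,
    "prep": _stage_prep,
    "prealign": _stage_prealign,
    "segment": _stage_segment,
    "reconstruct": _stage_reconstruct,
    "morphometry": _stage_morphometry,
    "compare": _stage_compare,
}
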