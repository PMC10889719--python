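"""Tile-based three-class tissue segmentation.

Slides are split into overlapping square tiles; a class-weighted U-Net is
trained in a k-fold cross-validation setup and the fold models are ensembled
at prediction time.  Per-pixel class probabilities from overlapping tiles are
averaged at the seams, bilateral-filtered to remove network artifacts without
blurring tissue edges, and finally thresholded to the single most probable
class per pixel.

Class codes follow the package convention: 0 non-mineralized, 1 bone,
2 graft.  Probability maps are (H, W, 3) in that channel order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from trabekit.nn import Adam, UNet, softmax, weighted_cross_entropy
from trabekit.volumes import CLASS_BONE, CLASS_GRAFT, CLASS_NON_MINERALIZED

logger = logging.getLogger(__name__)

#: argmax tie-break priority (highest first)
CLASS_PRIORITY = (CLASS_BONE, CLASS_GRAFT, CLASS_NON_MINERALIZED)


# -------------------------------------------------------------------- tiling
@dataclass
class TileSet:
    tiles: np.ndarray  # (n, tile, tile, C) or (n, tile, tile)
    origins: list[tuple[int, int]]
    tile: int
    overlap: int
    parent_shape: tuple[int, int]
    pad: tuple[int, int] = (0, 0)  # reflect padding applied to a small parent

    def __len__(self) -> int:
        return len(self.origins)


def _tile_origins(size: int, tile: int, stride: int) -> list[int]:
    if size <= tile:
        return [0]
    xs = list(range(0, size - tile + 1, stride))
    if xs[-1] != size - tile:
        xs.append(size - tile)  # border tile shifted inward
    return xs


def tile_image(image: np.ndarray, tile: int = 512, overlap: int = 64) -> TileSet:
    """Split an image into ``tile``-sized patches overlapping by ``overlap``.

    Adjacent origins differ by ``tile - overlap`` except at borders, where the
    last tile is shifted inward so every tile is full size.  Images smaller
    than one tile are reflect-padded.
    """
    if overlap >= tile:
        raise ValueError("overlap must be smaller than the tile size")
    h, w = image.shape[:2]
    pad_h, pad_w = max(0, tile - h), max(0, tile - w)
    if pad_h or pad_w:
        pads = [(0, pad_h), (0, pad_w)] + [(0, 0)] * (image.ndim - 2)
        image = np.pad(image, pads, mode="reflect")
    stride = tile - overlap
    ys = _tile_origins(image.shape[0], tile, stride)
    xs = _tile_origins(image.shape[1], tile, stride)
    origins = [(y, x) for y in ys for x in xs]
    tiles = np.stack([image[y : y + tile, x : x + tile] for y, x in origins])
    return TileSet(
        tiles=tiles,
        origins=origins,
        tile=tile,
        overlap=overlap,
        parent_shape=(h, w),
        pad=(pad_h, pad_w),
    )


def stitch_tiles(values: np.ndarray, tileset: TileSet) -> np.ndarray:
    """Reassemble per-tile maps to the parent frame, averaging overlaps."""
    tile = tileset.tile
    ph = tileset.parent_shape[0] + tileset.pad[0]
    pw = tileset.parent_shape[1] + tileset.pad[1]
    extra = values.shape[3:] if values.ndim > 3 else ()
    acc = np.zeros((ph, pw) + extra, dtype=float)
    cnt = np.zeros((ph, pw), dtype=float)
    for v, (y, x) in zip(values, tileset.origins):
        acc[y : y + tile, x : x + tile] += v
        cnt[y : y + tile, x : x + tile] += 1.0
    acc /= cnt[(...,) + (None,) * len(extra)]
    h, w = tileset.parent_shape
    return acc[:h, :w]


# ------------------------------------------------------------- class weights
def compute_class_weights(masks) -> np.ndarray:
    """Inverse-frequency class weights ``w_c = N / (3 N_c)`` over all masks.

    Balanced data gives (1, 1, 1); the weights are invariant to duplicating
    the dataset.  Raises if a class is entirely absent, naming it.
    """
    counts = np.zeros(3, dtype=np.int64)
    for m in masks:
        counts += np.bincount(np.asarray(m).ravel(), minlength=3)[:3]
    names = {0: "non-mineralized", 1: "bone", 2: "graft"}
    for c in range(3):
        if counts[c] == 0:
            raise ValueError(f"class {c} ({names[c]}) absent from the training masks")
    return counts.sum() / (3.0 * counts)


# ------------------------------------------------------------------ training
@dataclass
class UNetConfig:
    """Architecture and schedule of the tissue segmenter.

    The ``paper`` preset (depth 4, 512-pixel tiles, 200 epochs) reproduces
    the published geometry — a 32 x 32 bottleneck; the ``tiny`` preset is a
    desk-scale configuration for CPU runs and CI.  The learning rate starts
    at ``lr_start`` and divides by ``lr_factor`` whenever validation loss
    fails to improve for ``patience`` epochs, floored at ``lr_floor``.
    """

    depth: int = 4
    base_channels: int = 16
    dropout_rate: float = 0.05
    batch_size: int = 16
    epochs: int = 200
    lr_start: float = 1e-3
    lr_floor: float = 1e-5
    lr_factor: float = 10.0
    patience: int = 30
    folds: int = 5
    tile: int = 512
    overlap: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tile % 2**self.depth:
            raise ValueError(
                f"input size {self.tile} not divisible by {2 ** self.depth}"
            )
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.lr_floor > self.lr_start:
            raise ValueError("lr_floor must not exceed lr_start")

    @classmethod
    def paper(cls, **kw) -> "UNetConfig":
        return cls(**kw)

    @classmethod
    def tiny(cls, **kw) -> "UNetConfig":
        kw.setdefault("depth", 2)
        kw.setdefault("base_channels", 8)
        kw.setdefault("epochs", 20)
        kw.setdefault("batch_size", 8)
        kw.setdefault("patience", 6)
        kw.setdefault("tile", 32)
        kw.setdefault("overlap", 8)
        return cls(**kw)

    def build(self, seed=None) -> UNet:
        return UNet(
            in_channels=3,
            n_classes=3,
            depth=self.depth,
            base_channels=self.base_channels,
            dropout_rate=self.dropout_rate,
            seed=self.seed if seed is None else seed,
        )


def kfold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic disjoint validation folds covering ``range(n)``."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, folds)]


@dataclass
class LRSchedule:
    """Reduce-on-plateau: divide by ``factor`` after ``patience`` stale epochs."""

    lr: float
    floor: float
    factor: float
    patience: int
    best: float = np.inf
    stale: int = 0

    def update(self, val_loss: float) -> float:
        if val_loss < self.best - 1e-9:
            self.best = val_loss
            self.stale = 0
        else:
            self.stale += 1
            if self.stale > self.patience:
                self.lr = max(self.floor, self.lr / self.factor)
                self.stale = 0
        return self.lr


@dataclass
class TrainedFold:
    model: UNet
    val_accuracy: float
    val_loss: float
    lr_trace: list[float] = field(default_factory=list)


def _to_nchw(tiles: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(tiles.transpose(0, 3, 1, 2), dtype=np.float32)


def train_fold(
    model: UNet,
    x_tr, y_tr, x_va, y_va,
    class_weights,
    cfg: UNetConfig,
    rng: np.random.Generator,
) -> TrainedFold:
    opt = Adam(model.params, lr=cfg.lr_start)
    sched = LRSchedule(cfg.lr_start, cfg.lr_floor, cfg.lr_factor, cfg.patience)
    n = len(x_tr)
    lr_trace = []
    best_state, best_val = None, np.inf
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for s in range(0, n, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            opt.zero_grad()
            logits = model.forward(x_tr[idx], train=True)
            loss, dlog = weighted_cross_entropy(logits, y_tr[idx], class_weights)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/inf training loss at epoch {epoch}; fold aborted"
                )
            model.backward(dlog)
            opt.step()
        val_loss, _ = _evaluate(model, x_va, y_va, class_weights, cfg.batch_size)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state()
        opt.lr = sched.update(val_loss)
        lr_trace.append(opt.lr)
    if best_state is not None:
        model.load_state(best_state)
    val_loss, val_acc = _evaluate(model, x_va, y_va, class_weights, cfg.batch_size)
    return TrainedFold(model=model, val_accuracy=val_acc, val_loss=val_loss, lr_trace=lr_trace)


def _evaluate(model, x, y, class_weights, batch_size):
    losses, correct, total = [], 0, 0
    for s in range(0, len(x), batch_size):
        logits = model.forward(x[s : s + batch_size], train=False)
        loss, _ = weighted_cross_entropy(logits, y[s : s + batch_size], class_weights)
        losses.append(loss * len(logits))
        pred = logits.argmax(axis=1)
        correct += (pred == y[s : s + batch_size]).sum()
        total += pred.size
    return float(np.sum(losses) / len(x)), float(correct / total)


@dataclass
class Ensemble:
    models: list[UNet]
    val_accuracies: list[float]
    cfg: UNetConfig
    class_weights: np.ndarray


def train_kfold(tiles: np.ndarray, masks: np.ndarray, cfg: UNetConfig) -> Ensemble:
    """Train one model per cross-validation fold; returns the fold ensemble.

    ``tiles`` is (n, t, t, 3) float RGB in [0, 1]; ``masks`` is (n, t, t)
    integer classes.  Fold membership, weight initialization and batch order
    all derive from ``cfg.seed``, so a fixed seed reproduces the folds and
    the models exactly.
    """
    tiles = np.asarray(tiles)
    masks = np.asarray(masks)
    if len(tiles) < cfg.folds:
        raise ValueError(f"need at least {cfg.folds} tiles for {cfg.folds} folds")
    weights = compute_class_weights(masks)
    x = _to_nchw(tiles)
    y = masks.astype(np.int64)
    folds = kfold_indices(len(tiles), cfg.folds, cfg.seed)
    models, accs = [], []
    for f, va_idx in enumerate(folds):
        tr_idx = np.setdiff1d(np.arange(len(tiles)), va_idx)
        model = cfg.build(seed=cfg.seed * 1000 + f)
        rng = np.random.default_rng(cfg.seed * 1000 + 500 + f)
        fold = train_fold(
            model, x[tr_idx], y[tr_idx], x[va_idx], y[va_idx], weights, cfg, rng
        )
        logger.info("fold %d: val acc %.4f", f, fold.val_accuracy)
        models.append(fold.model)
        accs.append(fold.val_accuracy)
    return Ensemble(models=models, val_accuracies=accs, cfg=cfg, class_weights=weights)


# ---------------------------------------------------------------- prediction
def predict_ensemble(image: np.ndarray, ensemble: Ensemble) -> np.ndarray:
    """Per-pixel class probabilities from the fold ensemble.

    The image is tiled as in training; each tile goes through every fold
    model; softmax outputs are averaged over models, stitched with overlap
    averaging, and renormalized.  Returns (H, W, 3).
    """
    if not ensemble.models:
        raise ValueError("empty ensemble")
    cfg = ensemble.cfg
    ts = tile_image(image, tile=cfg.tile, overlap=cfg.overlap)
    x = _to_nchw(ts.tiles)
    probs = np.zeros((len(x), cfg.tile, cfg.tile, 3), dtype=float)
    for model in ensemble.models:
        for s in range(0, len(x), cfg.batch_size):
            p = softmax(model.forward(x[s : s + cfg.batch_size], train=False))
            probs[s : s + cfg.batch_size] += p.transpose(0, 2, 3, 1)
    probs /= len(ensemble.models)
    stitched = stitch_tiles(probs, ts)
    total = stitched.sum(axis=-1, keepdims=True)
    return stitched / np.clip(total, 1e-12, None)


def predict_from_stubs(image_shape, stub_outputs, tileset: TileSet) -> np.ndarray:
    """Stitch fixed per-tile probability outputs (testing hook)."""
    return stitch_tiles(np.asarray(stub_outputs, dtype=float), tileset)


# --------------------------------------------------------------- persistence
def save_ensemble(ensemble: Ensemble, path) -> None:
    """Write the fold models and configuration to one .npz checkpoint."""
    import json

    arrays = {}
    for m, model in enumerate(ensemble.models):
        for p, state in enumerate(model.state()):
            arrays[f"model{m}_param{p}"] = state
    arrays["class_weights"] = np.asarray(ensemble.class_weights)
    arrays["val_accuracies"] = np.asarray(ensemble.val_accuracies)
    from dataclasses import asdict

    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(ensemble.cfg)).encode(), dtype=np.uint8
    )
    np.savez_compressed(path, **arrays)


def load_ensemble(path) -> Ensemble:
    import json

    data = np.load(path)
    cfg = UNetConfig(**json.loads(bytes(data["config_json"]).decode()))
    models = []
    m = 0
    while f"model{m}_param0" in data:
        model = cfg.build(seed=m)
        state = []
        p = 0
        while f"model{m}_param{p}" in data:
            state.append(data[f"model{m}_param{p}"])
            p += 1
        model.load_state(state)
        models.append(model)
        m += 1
    return Ensemble(
        models=models,
        val_accuracies=list(data["val_accuracies"]),
        cfg=cfg,
        class_weights=data["class_weights"],
    )


# ------------------------------------------------------------ postprocessing
def postprocess(
    prob_map: np.ndarray,
    filter_size: int = 32,
    sigma_color: float = 64.0,
    sigma_space: float = 64.0,
) -> np.ndarray:
    """Bilateral-filter the probability channels, then take the argmax class.

    Bilateral filtering removes isolated network artifacts while keeping
    tissue boundaries sharp (a Gaussian blur would move them).  ``sigma_color``
    is on the 0-255 intensity scale.  Ties resolve by class priority
    bone > graft > non-mineralized.
    """
    from skimage.restoration import denoise_bilateral

    prob_map = np.asarray(prob_map, dtype=float)
    win = int(filter_size) | 1  # odd window
    smoothed = np.empty_like(prob_map)
    for c in range(prob_map.shape[-1]):
        smoothed[..., c] = denoise_bilateral(
            np.ascontiguousarray(prob_map[..., c]),
            win_size=win,
            sigma_color=sigma_color / 255.0,
            sigma_spatial=sigma_space,
        )
    total = smoothed.sum(axis=-1, keepdims=True)
    smoothed /= np.clip(total, 1e-12, None)
    # argmax with explicit priority: scan channels in priority order
    reordered = np.stack([smoothed[..., c] for c in CLASS_PRIORITY], axis=-1)
    winner = np.argmax(reordered, axis=-1)  # first (highest-priority) max wins
    return np.asarray(CLASS_PRIORITY, dtype=np.uint8)[winner]
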