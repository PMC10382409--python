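"""Patch sampling, augmentation strategies, the combined loss, and training.

Training draws random 72^3 mm patches; to correct the strong class imbalance
between node and background voxels, half of every minibatch is guaranteed to
contain foreground (patch centers jittered around a uniformly chosen labeled
voxel), while the other half is sampled uniformly. Each minibatch holds 12
patches drawn from distinct volumes whenever enough volumes exist.

Four augmentation strategies are exposed, applied on the fly per patch:

* ``affine``                    -- random scaling (<= 1.2) and rotation (<= 10 deg);
* ``affine+mirror``             -- plus sagittal (left-right) flips, p = 0.5;
* ``affine+bspline``            -- plus local order-1 B-spline distortion on a
                                   5x5x5 control grid (sigma = 0.2 of the
                                   control spacing);
* ``affine+mirror+bspline``     -- all of the above.

The loss is the equally weighted sum of voxelwise cross-entropy and the soft
Dice loss; optimization uses AdaDelta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._nn import AdaDelta
from .core import Volume, NodeLabelMap, ValidationError
from .foveal_net import (FovealNet, ModelGeometry, extract_foveal_patches,
                         required_input_geometry)

STRATEGIES = ("affine", "affine+mirror", "affine+bspline",
              "affine+mirror+bspline")


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int, minibatch: int):
        super().__init__(
            f"non-finite loss at epoch {epoch}, minibatch {minibatch}"
        )
        self.epoch = epoch
        self.minibatch = minibatch


@dataclass
class AugmentConfig:
    strategy: str = "affine+mirror+bspline"
    max_scale: float = 1.2
    max_rotation_deg: float = 10.0
    mirror_prob: float = 0.5
    bspline_grid: tuple[int, int, int] = (5, 5, 5)
    bspline_sigma: float = 0.2   # fraction of the control-point spacing
    bspline_order: int = 1

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValidationError(
                f"strategy must be one of {STRATEGIES}, got {self.strategy!r}"
            )
        if self.max_scale < 1.0:
            raise ValidationError("max_scale must be >= 1")
        if self.max_rotation_deg < 0:
            raise ValidationError("max_rotation_deg must be >= 0")
        if any(g < 2 for g in self.bspline_grid):
            raise ValidationError("bspline_grid must be >= 2 per axis")

    @property
    def use_mirror(self) -> bool:
        return "mirror" in self.strategy

    @property
    def use_bspline(self) -> bool:
        return "bspline" in self.strategy


@dataclass
class TrainConfig:
    patch_extent_mm: float = 72.0
    minibatch_size: int = 12
    epochs: int = 2000
    minibatches_per_epoch: int = 50
    foreground_fraction: float = 0.5
    loss_weights: tuple[float, float] = (0.5, 0.5)  # (cross-entropy, Dice)
    adadelta_rho: float = 0.95
    adadelta_eps: float = 1e-6
    learning_rate: float = 1.0
    dice_smooth: float = 1e-5
    n_val_patches: int = 24
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.foreground_fraction <= 1.0:
            raise ValidationError("foreground_fraction must be in [0, 1]")
        if abs(sum(self.loss_weights) - 1.0) > 1e-9:
            raise ValidationError("loss weights must sum to 1")
        if self.minibatch_size < 1:
            raise ValidationError("minibatch_size must be >= 1")


# ---------------------------------------------------------------------------
# Patch sampling
# ---------------------------------------------------------------------------

@dataclass
class TrainingCase:
    """A preprocessed (normalized, isotropic) volume with its labels."""
    volume: Volume
    labels: NodeLabelMap
    name: str = ""

    def __post_init__(self):
        if self.volume.shape != self.labels.shape:
            raise ValidationError("volume and label grids differ")
        self._fg_idx = np.argwhere(self.labels.foreground())

    @property
    def has_foreground(self) -> bool:
        return len(self._fg_idx) > 0


def _crop_with_pad(arr: np.ndarray, start: np.ndarray, size: tuple[int, ...],
                   fill=0) -> np.ndarray:
    """Crop ``arr[start : start+size]`` with out-of-bounds filled."""
    out = np.full(size, fill, dtype=arr.dtype)
    src_lo = np.maximum(start, 0)
    src_hi = np.minimum(start + np.asarray(size), arr.shape)
    if np.any(src_lo >= src_hi):
        return out
    dst_lo = src_lo - start
    dst_hi = dst_lo + (src_hi - src_lo)
    out[tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))] = \
        arr[tuple(slice(a, b) for a, b in zip(src_lo, src_hi))]
    return out


def sample_training_patches(cases: list[TrainingCase], geometry: ModelGeometry,
                            cfg: TrainConfig, rng: np.random.Generator,
                            pad_value: float = -3.0
                            ) -> tuple[list[np.ndarray], np.ndarray]:
    """Draw one minibatch: per-level input batches and binary target patches.

    Exactly ``round(minibatch_size * foreground_fraction)`` slots are
    foreground-guaranteed (centered near a uniformly chosen labeled voxel);
    the rest are uniform over the volume. Minibatch members come from
    distinct volumes when enough volumes exist.
    """
    if not cases:
        raise ValidationError("empty training dataset")
    if not any(c.has_foreground for c in cases):
        raise ValidationError("dataset contains no foreground voxels")
    b = cfg.minibatch_size
    n_fg = int(round(b * cfg.foreground_fraction))
    o = np.asarray(geometry.output_size)

    # choose source volumes, distinct when possible
    if len(cases) >= b:
        case_idx = rng.permutation(len(cases))[:b]
    else:
        case_idx = rng.integers(0, len(cases), size=b)

    levels = [np.empty((b, *size), dtype=np.float32)
              for size in required_input_geometry(geometry)]
    targets = np.empty((b, *geometry.output_size), dtype=np.float32)
    for slot in range(b):
        ci = int(case_idx[slot])
        case = cases[ci]
        if slot < n_fg:
            while not case.has_foreground:  # re-draw volume for fg slots
                ci = int(rng.integers(0, len(cases)))
                case = cases[ci]
            vox = case._fg_idx[rng.integers(0, len(case._fg_idx))]
            jitter_max = np.maximum(o // 2 - 1, 0)
            jitter = rng.integers(-jitter_max, jitter_max + 1)
            center_idx = vox + jitter
        else:
            center_idx = np.array(
                [rng.integers(0, s) for s in case.volume.shape])
        # align the output window to the voxel grid
        start = center_idx - (o - 1) // 2
        center_mm = case.volume.index_to_world(start + (o - 1) / 2.0)
        patches = extract_foveal_patches(case.volume, center_mm, geometry,
                                         pad_value=pad_value)
        for k in range(geometry.n_levels):
            levels[k][slot] = patches.levels[k][0]
        fg = (case.labels.labels > 0).astype(np.float32)
        targets[slot] = _crop_with_pad(fg, start, tuple(o), fill=0.0)
    return levels, targets


# ---------------------------------------------------------------------------
# Augmentation operations
# ---------------------------------------------------------------------------

def _rotation_matrix(angles_rad) -> np.ndarray:
    ax, ay, az = angles_rad
    rx = np.array([[1, 0, 0],
                   [0, np.cos(ax), -np.sin(ax)],
                   [0, np.sin(ax), np.cos(ax)]])
    ry = np.array([[np.cos(ay), 0, np.sin(ay)],
                   [0, 1, 0],
                   [-np.sin(ay), 0, np.cos(ay)]])
    rz = np.array([[np.cos(az), -np.sin(az), 0],
                   [np.sin(az), np.cos(az), 0],
                   [0, 0, 1]])
    return rz @ ry @ rx


def _warp_about_center(arr: np.ndarray, matrix: np.ndarray, order: int,
                       cval: float) -> np.ndarray:
    """Apply ``y = M (x - c) + c`` to the image content; ``matrix`` is the
    inverse (output-to-input) map handed to ``affine_transform``."""
    center = (np.asarray(arr.shape) - 1) / 2.0
    offset = center - matrix @ center
    return ndimage.affine_transform(arr, matrix, offset=offset, order=order,
                                    mode="constant", cval=cval)


def draw_affine_params(cfg: AugmentConfig, rng: np.random.Generator
                       ) -> tuple[float, np.ndarray]:
    """Scale symmetric in log-space over [1/max, max]; per-axis rotations
    uniform in [-max_rotation, +max_rotation]."""
    log_s = rng.uniform(-np.log(cfg.max_scale), np.log(cfg.max_scale))
    angles = np.deg2rad(rng.uniform(-cfg.max_rotation_deg,
                                    cfg.max_rotation_deg, size=3))
    return float(np.exp(log_s)), angles


def augment_affine(patches: list[np.ndarray], target: np.ndarray,
                   scale: float, angles_rad,
                   pad_value: float = -3.0
                   ) -> tuple[list[np.ndarray], np.ndarray]:
    """Rotate + scale every level patch and the target about their centers.

    ``scale`` is the object zoom factor: the imaged content becomes
    ``scale`` times larger. The same world transform is applied at every
    level (per-level voxel grids are isotropic, so the rotation matrix is
    identical in each level's index space). Images use linear, the target
    nearest-neighbor interpolation; the grid sizes are unchanged.
    """
    rot = _rotation_matrix(angles_rad)
    inv = rot.T / scale  # inverse mapping for affine_transform
    out_patches = [
        np.stack([_warp_about_center(p, inv, order=1, cval=pad_value)
                  for p in lvl]) if lvl.ndim == 4
        else _warp_about_center(lvl, inv, order=1, cval=pad_value)
        for lvl in patches
    ]
    out_target = _warp_about_center(target, inv, order=0, cval=0.0)
    return out_patches, out_target


def augment_mirror(patches: list[np.ndarray], target: np.ndarray,
                   rng: np.random.Generator, prob: float = 0.5
                   ) -> tuple[list[np.ndarray], np.ndarray, bool]:
    """Flip image and target together along the left-right (x) axis with the
    given probability; returns whether the flip was applied."""
    if rng.uniform() >= prob:
        return patches, target, False
    return mirror_sagittal(patches, target) + (True,)


def mirror_sagittal(patches: list[np.ndarray], target: np.ndarray
                    ) -> tuple[list[np.ndarray], np.ndarray]:
    """Deterministic sagittal flip (an involution)."""
    axis = -3  # x is the third-from-last axis for both (X,Y,Z) and (N,X,Y,Z)
    return ([np.flip(lvl, axis=axis).copy() for lvl in patches],
            np.flip(target, axis=-3).copy())


def bspline_displacement_field(shape: tuple[int, ...], cfg: AugmentConfig,
                               rng: np.random.Generator) -> np.ndarray:
    """Dense displacement (voxels) from normal control-point displacements.

    Control points form a ``bspline_grid`` lattice spanning the patch; each
    control displacement component is N(0, sigma * control_spacing). The
    dense field is the order-1 (trilinear) B-spline interpolation of the
    control displacements, so every dense value is a convex combination of
    control values.
    """
    grid = np.asarray(cfg.bspline_grid)
    spacing = (np.asarray(shape) - 1) / (grid - 1)
    ctrl = rng.normal(0.0, 1.0, size=(3, *grid)) * \
        (cfg.bspline_sigma * spacing).reshape(3, 1, 1, 1)
    coords = np.meshgrid(
        *[np.arange(s) / sp for s, sp in zip(shape, spacing)], indexing="ij"
    )
    coords = np.stack(coords)
    dense = np.stack([
        ndimage.map_coordinates(ctrl[ax], coords, order=cfg.bspline_order,
                                mode="nearest")
        for ax in range(3)
    ])
    return dense


def augment_bspline(patches: list[np.ndarray], target: np.ndarray,
                    cfg: AugmentConfig, rng: np.random.Generator,
                    pad_value: float = -3.0
                    ) -> tuple[list[np.ndarray], np.ndarray]:
    """Locally distort the finest-level patch and the target.

    The displacement field is drawn on the finest patch (where the loss is
    computed); coarser context patches pass through unchanged -- a fine-scale
    local distortion has no unambiguous realization on patches of different
    physical extent, and keeping image/target alignment exact at the output
    grid is what matters for training.
    """
    fine = patches[0]
    single = fine.ndim == 3
    shape = fine.shape if single else fine.shape[1:]
    disp = bspline_displacement_field(shape, cfg, rng)
    base = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    coords = np.stack(base) + disp

    def _warp(a, order, cval):
        return ndimage.map_coordinates(a, coords, order=order,
                                       mode="constant", cval=cval)

    if single:
        warped_fine = _warp(fine, 1, pad_value)
    else:
        warped_fine = np.stack([_warp(p, 1, pad_value) for p in fine])
    out = [warped_fine] + [lvl.copy() for lvl in patches[1:]]

    tshape = target.shape if target.ndim == 3 else target.shape[1:]
    if tshape == shape:
        tcoords = coords
    else:
        # target grid is the centered crop of the fine patch: shift the field
        off = (np.asarray(shape) - np.asarray(tshape)) // 2
        sl = tuple(slice(o, o + s) for o, s in zip(off, tshape))
        tcoords = (np.stack(np.meshgrid(*[np.arange(s) for s in tshape],
                                        indexing="ij"))
                   + disp[(slice(None),) + sl])
    warped_t = ndimage.map_coordinates(target, tcoords, order=0,
                                       mode="constant", cval=0.0)
    return out, warped_t


def augment_pair(levels: list[np.ndarray], target: np.ndarray,
                 cfg: AugmentConfig, rng: np.random.Generator,
                 pad_value: float = -3.0
                 ) -> tuple[list[np.ndarray], np.ndarray]:
    """Apply the configured strategy to a single (patch set, target) pair."""
    scale, angles = draw_affine_params(cfg, rng)
    levels, target = augment_affine(levels, target, scale, angles, pad_value)
    if cfg.use_mirror:
        levels, target, _ = augment_mirror(levels, target, rng,
                                           cfg.mirror_prob)
    if cfg.use_bspline:
        levels, target = augment_bspline(levels, target, cfg, rng, pad_value)
    return levels, target


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def combined_loss(probs: np.ndarray, target: np.ndarray,
                  weights: tuple[float, float] = (0.5, 0.5),
                  smooth: float = 1e-5,
                  return_grad: bool = False):
    """Equally weighted cross-entropy + soft Dice loss.

    ``probs`` is the softmax output ``(N,) + grid + (2,)`` (channels last,
    channel 1 foreground); ``target`` is binary ``(N,) + grid``. The soft
    Dice uses ``(2 sum(p t) + smooth) / (sum(p) + sum(t) + smooth)`` pooled
    over the minibatch, so the loss stays finite (and zero) for
    all-background minibatches predicted as background. Returns the scalar
    loss, and optionally the gradient w.r.t. ``probs``.
    """
    if probs.shape[:-1] != target.shape:
        raise ValidationError(
            f"probability grid {probs.shape} does not match target "
            f"{target.shape}")
    w_ce, w_dice = weights
    t = target.astype(np.float64)
    p1 = probs[..., 1].astype(np.float64)
    p0 = probs[..., 0].astype(np.float64)
    nvox = t.size
    tiny = 1e-12
    ce = -np.sum(t * np.log(p1 + tiny) + (1 - t) * np.log(p0 + tiny)) / nvox

    inter = float((p1 * t).sum())
    denom = float(p1.sum() + t.sum()) + smooth
    dice = (2.0 * inter + smooth) / denom
    loss = w_ce * ce + w_dice * (1.0 - dice)
    if not return_grad:
        return float(loss)

    dprobs = np.zeros(probs.shape, dtype=np.float64)
    dprobs[..., 1] = -w_ce * t / (p1 + tiny) / nvox
    dprobs[..., 0] = -w_ce * (1 - t) / (p0 + tiny) / nvox
    # d(1 - dice)/dp1 = -(2 t denom - (2 inter + smooth)) / denom^2
    dprobs[..., 1] += -w_dice * (2.0 * t * denom - (2.0 * inter + smooth)) \
        / denom ** 2
    return float(loss), dprobs.astype(np.float32)


def hard_dice(pred_fg: np.ndarray, target: np.ndarray) -> float:
    """Plain Dice of two binary masks (pooled)."""
    p = pred_fg.astype(bool)
    t = target.astype(bool)
    s = p.sum() + t.sum()
    if s == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, t).sum() / s)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def train_model(train_cases: list[TrainingCase],
                val_cases: list[TrainingCase],
                geometry: ModelGeometry,
                cfg: TrainConfig,
                progress: bool = False
                ) -> tuple[FovealNet, pd.DataFrame]:
    """Sample -> augment -> forward -> loss -> AdaDelta, fully seeded.

    Logs per-epoch mean training loss and validation Dice (hard Dice on a
    fixed, seeded set of validation patches, evaluated with frozen batch-norm
    statistics); the best-validation-Dice parameters are restored at the end.
    Raises :class:`TrainingDivergedError` on a non-finite loss.
    """
    rng = np.random.default_rng(cfg.seed)
    net = FovealNet(geometry, seed=int(rng.integers(0, 2 ** 31 - 1)))
    opt = AdaDelta(net.params(), rho=cfg.adadelta_rho, eps=cfg.adadelta_eps,
                   lr=cfg.learning_rate)

    # fixed validation patch set, half foreground-guaranteed
    val_levels = val_targets = None
    if val_cases:
        vrng = np.random.default_rng(cfg.seed + 1)
        vcfg_bs = max(1, cfg.n_val_patches)
        vcfg = TrainConfig(minibatch_size=vcfg_bs,
                           foreground_fraction=cfg.foreground_fraction,
                           augment=cfg.augment, seed=cfg.seed + 1)
        val_levels, val_targets = sample_training_patches(
            val_cases, geometry, vcfg, vrng)

    rows = []
    best = {"dice": -1.0, "state": net.state_copy(), "epoch": -1}
    for epoch in range(cfg.epochs):
        losses = []
        for mb in range(cfg.minibatches_per_epoch):
            levels, targets = sample_training_patches(train_cases, geometry,
                                                      cfg, rng)
            for i in range(cfg.minibatch_size):
                sample = [lvl[i] for lvl in levels]
                sample, targets[i] = augment_pair(sample, targets[i],
                                                  cfg.augment, rng)
                for k in range(geometry.n_levels):
                    levels[k][i] = sample[k]
            probs = net.forward_batch(levels, train=True)
            loss, dprobs = combined_loss(
                probs, targets, cfg.loss_weights, cfg.dice_smooth,
                return_grad=True)
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch, mb)
            opt.zero_grad()
            net.backward_from_probs(dprobs)
            opt.step()
            losses.append(loss)
        train_loss = float(np.mean(losses))

        val_dice = np.nan
        if val_levels is not None:
            vp = net.forward_batch(val_levels, train=False)
            val_dice = hard_dice(vp[..., 1] > 0.5, val_targets)
            if val_dice > best["dice"]:
                best = {"dice": val_dice, "state": net.state_copy(),
                        "epoch": epoch}
        rows.append({"epoch": epoch, "train_loss": train_loss,
                     "val_dice": val_dice})
        if progress:
            print(f"epoch {epoch:4d}  loss {train_loss:.4f}  "
                  f"val_dice {val_dice:.3f}")
    if best["epoch"] >= 0:
        net.load_state_copy(best["state"])
    log = pd.DataFrame(rows)
    log.attrs["best_epoch"] = best["epoch"]
    log.attrs["best_val_dice"] = best["dice"]
    return net, log


__all__ = [
    "STRATEGIES", "AugmentConfig", "TrainConfig", "TrainingCase",
    "TrainingDivergedError", "sample_training_patches",
    "draw_affine_params", "augment_affine", "augment_mirror",
    "mirror_sagittal", "augment_bspline", "bspline_displacement_field",
    "augment_pair", "combined_loss", "hard_dice", "train_model",
]
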