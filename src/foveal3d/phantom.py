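"""Synthetic CT phantoms with ground-truth lymph-node masks of known SAD.

The generator builds a neck-like scene: an air border, a soft-tissue body
cross-section (fat-dominated field), rectangular muscle blocks, a bright bone
cylinder, and vessel-like tubes that act as designed false-positive bait
(bright, round in the axial plane, but elongated). Lymph nodes are rendered
as ellipsoids rotated within the axial plane, so the short-axis diameter
(SAD) of the largest axial cross-section is analytically ``2 * b`` where
``b`` is the smaller in-plane semi-axis. This makes the RECIST-style SAD
measurement of the evaluation module exactly controllable.

Default tissue values (HU): fat -80, muscle 50, bone 500, vessels ~200,
nodes ~60 +- 15 -- all chosen so that nodes sit well inside the 395/10
normalization window while muscle is nearly isodense with nodes (the
clinically confusable case).

All randomness flows from a single seed per volume; no global RNG state.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .core import Volume, NodeLabelMap, ValidationError, write_volume, \
    write_node_labels


class PlacementError(RuntimeError):
    """Raised when a node cannot be placed inside the grid."""


@dataclass
class NodeRecord:
    """Analytic ground truth for a single generated node."""
    node_id: int
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]  # (a >= b in-plane, c axial)
    rotation_deg: float                       # in-plane rotation about z
    sad_mm: float                             # requested SAD = 2 * b


@dataclass
class PhantomTruth:
    label_map: NodeLabelMap
    records: list[NodeRecord]

    def __post_init__(self):
        ids_in_map = self.label_map.node_ids
        ids_in_records = {r.node_id for r in self.records}
        if ids_in_map != ids_in_records:
            raise ValidationError(
                f"label map ids {ids_in_map} do not match records "
                f"{ids_in_records}"
            )


@dataclass
class PhantomConfig:
    grid_size: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_nodes: int | tuple[int, int] = (5, 10)
    # log-normal SAD distribution in mm; the clinical cohort spans ~3-45 mm
    # with mostly sub-centimeter nodes, so median 8 mm with sigma 0.45.
    sad_lognormal_mu: float = float(np.log(8.0))
    sad_lognormal_sigma: float = 0.45
    sad_range_mm: tuple[float, float] = (4.0, 18.0)
    sad_list_mm: tuple[float, ...] | None = None  # explicit per-node override
    node_axis_ratio_max: float = 1.6     # in-plane a/b aspect
    node_axial_ratio: tuple[float, float] = (0.7, 1.2)  # c relative to b
    node_hu_mean: float = 60.0
    node_hu_std: float = 15.0
    background: tuple[str, ...] = ("air", "fat", "muscle", "bone", "vessels")
    vessel_hu: tuple[float, float] = (150.0, 300.0)
    conglomerate_prob: float = 0.0
    noise_sigma: float = 10.0
    seed: int = 0
    max_placement_attempts: int = 200

    def __post_init__(self):
        lo, hi = self.sad_range_mm
        if lo <= 0 or hi <= lo:
            raise ValidationError("sad_range_mm must be positive and increasing")
        n = self.n_nodes if isinstance(self.n_nodes, int) else min(self.n_nodes)
        if n < 0:
            raise ValidationError("n_nodes must be >= 0")
        if self.sad_list_mm is not None and any(s <= 0 for s in self.sad_list_mm):
            raise ValidationError("explicit SADs must be > 0")


# ---------------------------------------------------------------------------
# Scene rendering helpers
# ---------------------------------------------------------------------------

def _voxel_grids_mm(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _render_background(cfg: PhantomConfig, rng: np.random.Generator
                       ) -> np.ndarray:
    shape = cfg.grid_size
    sx, sy, sz = cfg.spacing
    hu = np.full(shape, -1000.0, dtype=np.float32)  # air everywhere
    gx, gy, gz = _voxel_grids_mm(shape, cfg.spacing)
    ext = [n * s for n, s in zip(shape, cfg.spacing)]
    cx, cy = ext[0] / 2.0, ext[1] / 2.0

    if "fat" in cfg.background or "air" in cfg.background:
        # body: elliptic cylinder filling ~90% of the in-plane extent
        rx, ry = 0.45 * ext[0], 0.45 * ext[1]
        body = ((gx - cx) / rx) ** 2 + ((gy - cy) / ry) ** 2 <= 1.0
        hu[body] = -80.0
    else:
        body = np.ones(shape, dtype=bool)
        hu[:] = -80.0

    if "muscle" in cfg.background:
        for _ in range(rng.integers(2, 5)):
            size = rng.uniform(0.15, 0.4, size=3) * np.asarray(ext)
            lo = rng.uniform(0.05, 0.55, size=3) * np.asarray(ext)
            block = ((gx >= lo[0]) & (gx <= lo[0] + size[0]) &
                     (gy >= lo[1]) & (gy <= lo[1] + size[1]) &
                     (gz >= lo[2]) & (gz <= lo[2] + size[2]))
            hu[block & body] = rng.normal(50.0, 5.0)

    if "bone" in cfg.background:
        # spine-like cylinder toward the posterior side
        r = 0.1 * min(ext[0], ext[1])
        bx, by = cx, cy + 0.22 * ext[1]
        bone = ((gx - bx) ** 2 + (gy - by) ** 2) <= r ** 2
        hu[bone & body] = 500.0

    if "vessels" in cfg.background:
        for _ in range(rng.integers(2, 5)):
            r = rng.uniform(1.5, 3.5)
            vx = rng.uniform(0.2, 0.8) * ext[0]
            vy = rng.uniform(0.2, 0.8) * ext[1]
            tilt = rng.uniform(-0.15, 0.15, size=2)  # slight obliquity
            dx = gx - (vx + tilt[0] * gz)
            dy = gy - (vy + tilt[1] * gz)
            tube = (dx ** 2 + dy ** 2) <= r ** 2
            hu[tube & body] = rng.uniform(*cfg.vessel_hu)
    return hu


def _node_mask(shape, spacing, center_mm, semi_axes_mm, rot_deg) -> np.ndarray:
    """Rasterize an ellipsoid rotated by ``rot_deg`` within the axial plane."""
    gx, gy, gz = _voxel_grids_mm(shape, spacing)
    a, b, c = semi_axes_mm
    th = np.deg2rad(rot_deg)
    dx = gx - center_mm[0]
    dy = gy - center_mm[1]
    dz = gz - center_mm[2]
    u = np.cos(th) * dx + np.sin(th) * dy
    v = -np.sin(th) * dx + np.cos(th) * dy
    return (u / a) ** 2 + (v / b) ** 2 + (dz / c) ** 2 <= 1.0


def _sample_node_shape(cfg: PhantomConfig, sad_mm: float,
                       rng: np.random.Generator):
    b = sad_mm / 2.0
    a = b * rng.uniform(1.0, cfg.node_axis_ratio_max)
    c = b * rng.uniform(*cfg.node_axial_ratio)
    rot = rng.uniform(0.0, 180.0)
    return (a, b, c), rot


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def generate_phantom(cfg: PhantomConfig) -> tuple[Volume, PhantomTruth]:
    """Generate one CT-like phantom with per-node ground truth.

    Deterministic under a fixed ``cfg.seed``. Raises :class:`PlacementError`
    when a node cannot be placed after ``cfg.max_placement_attempts`` tries
    (grid too small or too crowded).
    """
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(cfg.grid_size)
    hu = _render_background(cfg, rng)
    labels = np.zeros(shape, dtype=np.int32)

    if cfg.sad_list_mm is not None:
        sads = list(cfg.sad_list_mm)
    else:
        n = cfg.n_nodes if isinstance(cfg.n_nodes, int) else \
            int(rng.integers(cfg.n_nodes[0], cfg.n_nodes[1] + 1))
        raw = rng.lognormal(cfg.sad_lognormal_mu, cfg.sad_lognormal_sigma,
                            size=n)
        sads = list(np.clip(raw, *cfg.sad_range_mm))

    ext = np.asarray([n * s for n, s in zip(shape, cfg.spacing)])
    records: list[NodeRecord] = []
    prev: NodeRecord | None = None
    for i, sad in enumerate(sads, start=1):
        semi, rot = _sample_node_shape(cfg, sad, rng)
        rmax = max(semi)
        placed = False
        for _ in range(cfg.max_placement_attempts):
            if prev is not None and rng.uniform() < cfg.conglomerate_prob:
                # place touching the previous node: centers closer than the
                # sum of nominal radii so the rasterized masks are adjacent
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                gap = 0.95 * (min(prev.semi_axes_mm) + min(semi))
                center = np.asarray(prev.center_mm) + direction * gap
            else:
                margin = rmax + 1.0
                if np.any(ext - 2 * margin <= 0):
                    raise PlacementError(
                        f"node {i} (SAD {sad:.1f} mm) does not fit in the grid"
                    )
                center = rng.uniform(margin, ext - margin)
            if np.any(center < rmax) or np.any(center > ext - rmax):
                continue
            mask = _node_mask(shape, cfg.spacing, center, semi, rot)
            if not mask.any():
                continue
            overlap = labels[mask] > 0
            if prev is None or cfg.conglomerate_prob == 0.0:
                # keep isolated nodes truly isolated: also require a 1-voxel
                # moat so face-connectivity cannot merge them
                pad = _node_mask(shape, cfg.spacing, center,
                                 tuple(s + 1.5 * max(cfg.spacing) for s in semi),
                                 rot)
                if (labels[pad] > 0).any():
                    continue
            elif overlap.mean() > 0.5:
                continue  # mostly swallowed by the previous node; retry
            labels[mask & (labels == 0)] = i
            if not (labels == i).any():
                continue
            hu_node = rng.normal(cfg.node_hu_mean, cfg.node_hu_std)
            hu[mask] = hu_node
            rec = NodeRecord(node_id=i, center_mm=tuple(map(float, center)),
                             semi_axes_mm=tuple(map(float, semi)),
                             rotation_deg=float(rot), sad_mm=float(sad))
            records.append(rec)
            prev = rec
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place node {i} (SAD {sad:.1f} mm) after "
                f"{cfg.max_placement_attempts} attempts"
            )

    if cfg.noise_sigma > 0:
        hu = hu + rng.normal(0.0, cfg.noise_sigma,
                             size=shape).astype(np.float32)

    vol = Volume(data=hu.astype(np.float32), spacing=cfg.spacing)
    truth = PhantomTruth(
        label_map=NodeLabelMap(labels=labels, spacing=cfg.spacing),
        records=records,
    )
    return vol, truth


def generate_cohort(cfg: PhantomConfig, n_volumes: int, out_dir: str,
                    base_seed: int = 0,
                    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
                    overwrite: bool = False) -> pd.DataFrame:
    """Write a cohort of (image, label) NIfTI pairs plus a manifest.

    Each volume gets its own derived seed ``base_seed + index``. The manifest
    CSV has one row per node (case, node_id, SAD, geometry); ``splits.json``
    lists train/val/test case names, assigned in order by the configured
    fractions.
    """
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not overwrite:
        raise FileExistsError(
            f"output directory {out_dir} is not empty (pass overwrite=True)"
        )
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    names = []
    for i in range(n_volumes):
        case = f"case_{i:04d}"
        vcfg = replace_seed(cfg, base_seed + i)
        vol, truth = generate_phantom(vcfg)
        write_volume(vol, os.path.join(out_dir, f"{case}_img.nii.gz"))
        write_node_labels(truth.label_map,
                          os.path.join(out_dir, f"{case}_lbl.nii.gz"))
        names.append(case)
        for rec in truth.records:
            rows.append({"case": case, "seed": vcfg.seed, **asdict(rec)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)

    n_train = int(round(split_fractions[0] * n_volumes))
    n_val = int(round(split_fractions[1] * n_volumes))
    splits = {
        "train": names[:n_train],
        "val": names[n_train:n_train + n_val],
        "test": names[n_train + n_val:],
    }
    with open(os.path.join(out_dir, "splits.json"), "w") as fh:
        json.dump(splits, fh, indent=2)
    return manifest


def replace_seed(cfg: PhantomConfig, seed: int) -> PhantomConfig:
    from dataclasses import replace
    return replace(cfg, seed=int(seed))


__all__ = [
    "PhantomConfig", "PhantomTruth", "NodeRecord", "PlacementError",
    "generate_phantom", "generate_cohort", "replace_seed",
]
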