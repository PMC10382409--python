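"""Node-level evaluation: components, SAD, matching, and stratified metrics.

The evaluation separates a binary prediction into connected components,
discards components smaller than 3^3 voxels (their short-axis diameter is
clearly below the 5 mm annotation floor), and matches the remaining
components against the ground-truth node label map. From the matching it
derives, per volume and in aggregate:

* the localization rate (LR) -- percentage of ground-truth nodes overlapped
  by at least one retained predicted component (reported both as the mean of
  per-volume LRs and pooled over nodes);
* false positives per volume (FP/V) -- retained components overlapping no
  node;
* the global true-positive-only Dice per volume -- Dice between the union of
  TP component voxels and the full ground-truth foreground (false-positive
  components excluded, missed nodes still penalized);
* per-node segmentation sensitivity -- the covered fraction of each node's
  volume (used instead of a per-node Dice because touching predicted nodes
  merge into a single component).

Nodes are stratified by their short-axis diameter (SAD) into the RECIST 1.1
motivated groups 5-10 mm, >= 10 mm, and >= 15 mm (the >= 15 mm group is a
subset of >= 10 mm), plus the overall >= 5 mm group. The SAD of a voxel set
is measured the way a radiologist measures it: per axial slice, the long
axis is the maximal Feret diameter of the cross-section and the short axis
the maximal extent perpendicular to it; the SAD is the maximum short axis
over slices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .core import NodeLabelMap, ValidationError

DEFAULT_SAD_GROUPS = (
    ("5-10mm", 5.0, 10.0),
    (">=10mm", 10.0, np.inf),
    (">=15mm", 15.0, np.inf),
)


@dataclass
class EvalConfig:
    min_component_voxels: int = 27        # components < 3^3 voxels excluded
    connectivity: int = 6                 # 6 (face) or 26 (full)
    annotation_floor_mm: float = 5.0
    sad_groups: tuple = DEFAULT_SAD_GROUPS
    min_overlap_fraction: float = 0.0     # extra TP requirement (default any)
    review_small_nodes: bool = False      # reclassify sub-floor hits as TP
    dice_vs_localized_only: bool = False  # non-default Dice variant

    def __post_init__(self):
        if self.min_component_voxels < 1:
            raise ValidationError("min_component_voxels must be >= 1")
        if self.connectivity not in (6, 26):
            raise ValidationError("connectivity must be 6 or 26")


@dataclass
class Component:
    comp_id: int
    voxel_count: int
    status: str = "retained"              # retained -> TP/FP after matching
    sad_mm: float | None = None
    matched_node_ids: tuple[int, ...] = ()


@dataclass
class ComponentSet:
    """Connected components of a prediction, as a labeled array plus records."""

    labels: np.ndarray                    # 0 background, 1..n components
    spacing: tuple[float, float, float]
    components: list[Component] = field(default_factory=list)

    def retained(self) -> list[Component]:
        return [c for c in self.components if c.status != "filtered"]

    def mask(self, comp_id: int) -> np.ndarray:
        return self.labels == comp_id

    def retained_mask(self) -> np.ndarray:
        keep = [c.comp_id for c in self.retained()]
        return np.isin(self.labels, keep) if keep else \
            np.zeros_like(self.labels, dtype=bool)

    def tp_mask(self) -> np.ndarray:
        tp = [c.comp_id for c in self.components if c.status == "TP"]
        return np.isin(self.labels, tp) if tp else \
            np.zeros_like(self.labels, dtype=bool)


# ---------------------------------------------------------------------------
# Components
# ---------------------------------------------------------------------------

def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)


def connected_components(mask: np.ndarray, connectivity: int = 6,
                         spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
                         ) -> ComponentSet:
    """Maximal connected voxel sets of a binary mask, deterministically
    labeled in scan order."""
    mask = np.asarray(mask).astype(bool)
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    comps = [Component(comp_id=i, voxel_count=int(counts[i]))
             for i in range(1, n + 1)]
    return ComponentSet(labels=labels, spacing=tuple(spacing),
                        components=comps)


def filter_small_components(cs: ComponentSet, min_voxels: int = 27
                            ) -> ComponentSet:
    """Mark components with fewer than ``min_voxels`` voxels as filtered;
    they are excluded from every subsequent metric."""
    for c in cs.components:
        if c.voxel_count < min_voxels:
            c.status = "filtered"
    return cs


# ---------------------------------------------------------------------------
# SAD measurement
# ---------------------------------------------------------------------------

def _slice_short_axis(points_mm: np.ndarray, spacing_xy: np.ndarray) -> float:
    """Short axis of one axial cross-section given voxel-center coordinates.

    The long axis is the maximal Feret diameter (farthest point pair); the
    short axis is the extent of the projections onto the perpendicular
    direction, plus the voxel footprint along that direction (so a single
    voxel measures one voxel, not zero).
    """
    pts = np.asarray(points_mm, dtype=float)
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear points: use them all
    if len(pts) == 1:
        return float(np.min(spacing_xy))
    diffs = pts[:, None, :] - pts[None, :, :]
    d2 = (diffs ** 2).sum(axis=-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    u = pts[i] - pts[j]
    norm = np.linalg.norm(u)
    if norm == 0:
        return float(np.min(spacing_xy))
    u /= norm
    v = np.array([-u[1], u[0]])
    proj = pts @ v
    footprint = float(np.sqrt(((spacing_xy * v) ** 2).sum()))
    return float(proj.max() - proj.min() + footprint)


def measure_sad(mask: np.ndarray,
                spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
                ) -> float:
    """RECIST-style short-axis diameter (mm) of a 3D voxel set.

    Maximum over axial (x-y) slices of the per-slice short axis; see
    :func:`_slice_short_axis` for the in-plane convention.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValidationError("cannot measure the SAD of an empty voxel set")
    spacing_xy = np.asarray(spacing[:2], dtype=float)
    best = 0.0
    for z in np.flatnonzero(mask.any(axis=(0, 1))):
        pts = np.argwhere(mask[:, :, z]) * spacing_xy
        best = max(best, _slice_short_axis(pts, spacing_xy))
    return best


# ---------------------------------------------------------------------------
# Matching and per-volume metrics
# ---------------------------------------------------------------------------

def match_nodes(pred: ComponentSet, gt: NodeLabelMap,
                cfg: EvalConfig | None = None
                ) -> tuple[ComponentSet, dict[int, bool]]:
    """Match retained components to ground-truth nodes by voxel overlap.

    A node is *localized* iff at least one retained predicted voxel lies
    inside it; a component is TP iff it overlaps at least one node (it may
    credit several touching nodes) and FP otherwise. With
    ``cfg.min_overlap_fraction > 0`` a component must additionally place
    that fraction of its voxels inside nodes to count as TP.
    """
    cfg = cfg or EvalConfig()
    if pred.labels.shape != gt.labels.shape:
        raise ValidationError(
            f"prediction grid {pred.labels.shape} does not match ground "
            f"truth {gt.labels.shape}")
    localized = {nid: False for nid in gt.node_ids}
    for comp in pred.retained():
        overlap_labels = gt.labels[pred.labels == comp.comp_id]
        hit = overlap_labels[overlap_labels > 0]
        frac = len(hit) / comp.voxel_count
        if len(hit) > 0 and frac >= cfg.min_overlap_fraction:
            comp.status = "TP"
            comp.matched_node_ids = tuple(int(i) for i in np.unique(hit))
            for nid in comp.matched_node_ids:
                localized[nid] = True
        else:
            comp.status = "FP"
    return pred, localized


def localization_rate(localized_flags) -> float:
    """Percentage of localized nodes; flags may be a dict or a sequence."""
    flags = list(localized_flags.values()) if isinstance(localized_flags, dict) \
        else list(localized_flags)
    if not flags:
        raise ValidationError("localization rate needs >= 1 eligible node")
    return 100.0 * sum(bool(f) for f in flags) / len(flags)


def global_dice_tp(pred: ComponentSet, gt_foreground: np.ndarray,
                   restrict_to_localized: bool = False,
                   localized_mask: np.ndarray | None = None) -> float | None:
    """Dice between TP-component voxels and the ground-truth foreground.

    False-positive components are excluded from the prediction side; by
    default missed nodes still count against the Dice. Returns None
    (undefined) for an empty ground truth.
    """
    gt_fg = np.asarray(gt_foreground).astype(bool)
    if restrict_to_localized and localized_mask is not None:
        gt_fg = gt_fg & localized_mask
    if not gt_fg.any():
        return None
    p = pred.tp_mask()
    return 2.0 * np.logical_and(p, gt_fg).sum() / (p.sum() + gt_fg.sum())


def node_sensitivity(node_mask: np.ndarray, pred_foreground: np.ndarray
                     ) -> float:
    """Covered fraction of a single node's voxels."""
    node = np.asarray(node_mask).astype(bool)
    n = node.sum()
    if n == 0:
        raise ValidationError("node mask is empty")
    return float(np.logical_and(node, pred_foreground).sum() / n)


def false_positive_review(total_findings: int, small_node_tp: int,
                          mediastinal_tp: int, unclear: int) -> int:
    """Arithmetic of a reader FP review: findings that remain FPs after
    removing re-identified true nodes (too small to annotate), true nodes
    outside the annotated region, and unclear findings."""
    residual = total_findings - small_node_tp - mediastinal_tp - unclear
    if residual < 0:
        raise ValidationError("review categories exceed the total findings")
    return residual


# ---------------------------------------------------------------------------
# Per-volume evaluation and the aggregate report
# ---------------------------------------------------------------------------

@dataclass
class VolumeEvaluation:
    name: str
    components: ComponentSet
    localized: dict[int, bool]
    node_rows: list[dict]
    lr_percent: float | None
    fp_count: int
    dice_tp: float | None


@dataclass
class EvaluationReport:
    per_volume: pd.DataFrame
    per_node: pd.DataFrame
    summary: dict

    def to_files(self, out_dir: str) -> None:
        import os
        os.makedirs(out_dir, exist_ok=True)
        self.per_volume.to_csv(os.path.join(out_dir, "per_volume.csv"),
                               index=False)
        self.per_node.to_csv(os.path.join(out_dir, "per_node.csv"),
                             index=False)
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(self.summary, fh, indent=2, default=float)


def evaluate_volume(pred_mask: np.ndarray, gt: NodeLabelMap,
                    cfg: EvalConfig | None = None, name: str = ""
                    ) -> VolumeEvaluation:
    """Run the full per-volume pipeline on one (prediction, truth) pair."""
    cfg = cfg or EvalConfig()
    cs = connected_components(pred_mask, cfg.connectivity, gt.spacing)
    filter_small_components(cs, cfg.min_component_voxels)

    # node eligibility by measured SAD
    node_sads = {nid: measure_sad(gt.node_mask(nid), gt.spacing)
                 for nid in gt.node_ids}
    eligible = {nid for nid, sad in node_sads.items()
                if sad >= cfg.annotation_floor_mm}

    cs, localized = match_nodes(cs, gt, cfg)

    if cfg.review_small_nodes:
        # review mode: a component whose only overlaps are sub-floor nodes
        # counts as a small-node TP rather than an FP -- mirrors a reader
        # re-review of the raw FP list
        for comp in cs.retained():
            if comp.status == "TP" and \
                    not any(n in eligible for n in comp.matched_node_ids):
                comp.status = "TP-small"
    else:
        # default accounting: overlaps with sub-floor nodes do not rescue a
        # component from being an FP
        for comp in cs.retained():
            if comp.status == "TP" and \
                    not any(n in eligible for n in comp.matched_node_ids):
                comp.status = "FP"

    pred_fg = cs.retained_mask()
    node_rows = []
    for nid in sorted(gt.node_ids):
        node_mask = gt.node_mask(nid)
        node_rows.append({
            "name": name, "node_id": nid, "sad_mm": node_sads[nid],
            "eligible": nid in eligible,
            "localized": bool(localized[nid]),
            "sensitivity": node_sensitivity(node_mask, pred_fg),
        })

    eligible_flags = [r["localized"] for r in node_rows if r["eligible"]]
    lr = localization_rate(eligible_flags) if eligible_flags else None
    fp_count = sum(1 for c in cs.retained() if c.status == "FP")
    dice = global_dice_tp(cs, gt.foreground())
    for comp in cs.retained():
        comp.sad_mm = measure_sad(cs.mask(comp.comp_id), gt.spacing)
    return VolumeEvaluation(name=name, components=cs, localized=localized,
                            node_rows=node_rows, lr_percent=lr,
                            fp_count=fp_count, dice_tp=dice)


def _group_members(df: pd.DataFrame, lo: float, hi: float) -> pd.DataFrame:
    return df[(df.sad_mm >= lo) & (df.sad_mm < hi)]


def build_report(volumes: list[tuple[np.ndarray, NodeLabelMap, str]],
                 cfg: EvalConfig | None = None) -> EvaluationReport:
    """Evaluate a list of ``(pred_mask, gt, name)`` volumes and aggregate.

    The summary contains the per-volume means (LR, FP/V, TP-only Dice), the
    pooled per-node LR overall and per SAD group as ``detected/total``
    cells, and mean +- sd sensitivity per group.
    """
    cfg = cfg or EvalConfig()
    vol_rows, node_rows = [], []
    for pred_mask, gt, name in volumes:
        ev = evaluate_volume(pred_mask, gt, cfg, name=name)
        vol_rows.append({
            "name": name, "n_nodes": len(ev.node_rows),
            "n_eligible": sum(r["eligible"] for r in ev.node_rows),
            "lr_percent": ev.lr_percent, "fp_count": ev.fp_count,
            "dice_tp": ev.dice_tp,
        })
        node_rows.extend(ev.node_rows)
    per_volume = pd.DataFrame(vol_rows)
    per_node = pd.DataFrame(node_rows)

    elig = per_node[per_node.eligible] if len(per_node) else per_node
    groups = {}
    floor_groups = (("overall", cfg.annotation_floor_mm, np.inf),) \
        + tuple(cfg.sad_groups)
    for gname, lo, hi in floor_groups:
        sub = _group_members(elig, lo, hi) if len(elig) else elig
        detected = int(sub.localized.sum()) if len(sub) else 0
        total = int(len(sub))
        groups[gname] = {
            "detected": detected, "total": total,
            "pooled_lr_percent": 100.0 * detected / total if total else None,
            "sensitivity_mean": float(sub.sensitivity.mean())
            if total else None,
            "sensitivity_sd": float(sub.sensitivity.std(ddof=1))
            if total > 1 else None,
        }

    with_lr = per_volume.dropna(subset=["lr_percent"]) if len(per_volume) \
        else per_volume
    dice_vals = per_volume.dice_tp.dropna() if len(per_volume) else []
    summary = {
        "n_volumes": int(len(per_volume)),
        "mean_lr_percent": float(with_lr.lr_percent.mean())
        if len(with_lr) else None,
        "mean_fp_per_volume": float(per_volume.fp_count.mean())
        if len(per_volume) else None,
        "mean_dice_tp": float(np.mean(dice_vals)) if len(dice_vals) else None,
        "groups": groups,
    }
    return EvaluationReport(per_volume=per_volume, per_node=per_node,
                            summary=summary)


__all__ = [
    "EvalConfig", "Component", "ComponentSet", "EvaluationReport",
    "VolumeEvaluation", "connected_components", "filter_small_components",
    "measure_sad", "match_nodes", "localization_rate", "global_dice_tp",
    "node_sensitivity", "false_positive_review", "evaluate_volume",
    "build_report", "DEFAULT_SAD_GROUPS",
]
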