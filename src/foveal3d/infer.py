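"""Full-volume prediction by tiled foveal inference and thresholding.

The network predicts a fixed-size output tile per forward pass; a whole
volume is covered by sliding the tile over the grid (default stride = tile
size, i.e. non-overlapping). Each tile's multi-resolution context is sampled
around its center, with out-of-volume regions padded with normalized air.
Where tiles overlap (e.g. at the trailing border, or with a smaller stride)
the predicted probabilities are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Volume, ValidationError
from .foveal_net import FovealNet, ProbabilityMap, extract_foveal_patches


@dataclass
class InferenceConfig:
    threshold: float = 0.5
    tile_stride: tuple[int, int, int] | None = None  # None -> output size
    pad_value: float = -3.0
    batch_tiles: int = 8

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValidationError("threshold must be in (0, 1)")


def _tile_starts(dim: int, tile: int, stride: int) -> list[int]:
    if dim <= tile:
        return [0]
    starts = list(range(0, dim - tile + 1, stride))
    if starts[-1] + tile < dim:
        starts.append(dim - tile)
    return starts


def predict_volume(model: FovealNet, v: Volume,
                   cfg: InferenceConfig | None = None) -> ProbabilityMap:
    """Foreground probability map congruent with the (preprocessed) volume."""
    cfg = cfg or InferenceConfig()
    g = model.geometry
    if not np.allclose(v.spacing, g.finest_spacing):
        raise ValidationError(
            f"volume spacing {v.spacing} does not match checkpoint finest "
            f"spacing {g.finest_spacing}; preprocess first"
        )
    o = np.asarray(g.output_size)
    stride = np.asarray(cfg.tile_stride if cfg.tile_stride is not None else o)
    if np.any(stride > o) or np.any(stride < 1):
        raise ValidationError("tile_stride must be in [1, output_size]")
    starts = [np.asarray(s) for s in
              np.array(np.meshgrid(
                  *[_tile_starts(d, t, st) for d, t, st in
                    zip(v.shape, o, stride)], indexing="ij"
              )).reshape(3, -1).T]

    acc = np.zeros(v.shape, dtype=np.float64)
    cnt = np.zeros(v.shape, dtype=np.int32)
    for i in range(0, len(starts), cfg.batch_tiles):
        chunk = starts[i:i + cfg.batch_tiles]
        centers = np.stack([
            v.index_to_world(s + (o - 1) / 2.0) for s in chunk])
        patches = extract_foveal_patches(v, centers, g,
                                         pad_value=cfg.pad_value)
        fg = model.predict_patches(patches)
        for s, tile in zip(chunk, fg):
            # clip the tile to the volume (tiles can overhang when an axis
            # is smaller than the output size)
            lo = np.maximum(s, 0)
            hi = np.minimum(s + o, v.shape)
            src = tuple(slice(a - b, c - b) for a, b, c in zip(lo, s, hi))
            dst = tuple(slice(a, c) for a, c in zip(lo, hi))
            acc[dst] += tile[src]
            cnt[dst] += 1
    assert cnt.min() >= 1, "tiling must cover the whole volume"
    prob = (acc / cnt).astype(np.float32)
    return ProbabilityMap(prob=np.clip(prob, 0.0, 1.0),
                          spacing=v.spacing, origin=v.origin)


def threshold_probability(p: ProbabilityMap | np.ndarray,
                          threshold: float = 0.5) -> np.ndarray:
    """Binary mask: a voxel is foreground iff its probability exceeds the
    threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must lie in the open interval (0, 1)")
    prob = p.prob if isinstance(p, ProbabilityMap) else np.asarray(p)
    return prob > threshold


__all__ = ["InferenceConfig", "predict_volume", "threshold_probability"]
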