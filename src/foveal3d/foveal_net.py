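"""The foveal multi-resolution 3D fully convolutional architecture.

The network takes a stack of patches centered at the same world location but
with different physical extents and resolutions: level 0 is a small patch at
the finest spacing (the "fovea"), each coarser level doubles the spacing and
physical footprint. Every level runs a feature pathway of ``convs_per_block``
CBR units (valid 3x3x3 convolution, batch normalization, ReLU). A feature
integration pathway then merges coarse to fine: the coarser result is
upsampled (CBRU), concatenated with the finer feature map, and passed
through another CBR unit. A final 1x1x1 convolution and a two-channel
softmax yield per-voxel foreground pseudo-probabilities at the finest
spacing.

Because every convolution is valid (unpadded), each level must be fed an
input patch of a specific size for the requested output to be produced;
:func:`required_input_geometry` back-propagates the output size through the
layer graph to obtain those sizes, and the constructed network is guaranteed
to reproduce them (property-tested against forward shape simulation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import _nn
from .core import Volume, ValidationError


class GeometryError(ValueError):
    """Raised when an output size cannot be aligned across resolution levels."""


@dataclass
class ModelGeometry:
    """Structural hyperparameters of the foveal network.

    ``output_size`` is the voxel size of the predicted patch at
    ``finest_spacing``; level ``k`` operates at
    ``finest_spacing * level_scale**k``. Validity of the size chain is
    checked at construction.
    """

    n_levels: int = 4
    convs_per_block: int = 3
    kernel: int = 3
    level_scale: int = 2
    channels: tuple[int, ...] = (32, 64, 64, 64)
    output_size: tuple[int, int, int] = (18, 18, 18)
    finest_spacing: float = 1.0
    bn_momentum: float = 0.1

    def __post_init__(self):
        if self.n_levels < 1:
            raise GeometryError("n_levels must be >= 1")
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise GeometryError("kernel must be odd and positive")
        if self.level_scale < 2 and self.n_levels > 1:
            raise GeometryError("level_scale must be >= 2")
        if len(self.channels) != self.n_levels:
            raise GeometryError(
                f"channels must list one width per level "
                f"({self.n_levels}), got {len(self.channels)}"
            )
        self.output_size = tuple(int(s) for s in self.output_size)
        required_input_geometry(self)  # raises GeometryError if invalid

    def level_spacing(self, level: int) -> float:
        return self.finest_spacing * self.level_scale ** level


def _axis_chain(out: int, g: ModelGeometry) -> tuple[list[int], list[int], list[int]]:
    """Per-axis size bookkeeping.

    Returns ``(M, F, inputs)`` where ``M[k]`` is the integration-pathway
    output size at level k, ``F[k]`` the feature-pathway output size, and
    ``inputs[k]`` the required input patch size, all in level-k voxels.
    """
    shrink = g.kernel - 1                  # per valid conv
    block_shrink = g.convs_per_block * shrink
    m = [int(out)]
    for k in range(g.n_levels - 1):
        f = m[k] + shrink                  # consumed by the integration conv
        if f % g.level_scale != 0:
            raise GeometryError(
                f"output size {out} cannot be aligned at level {k + 1}: "
                f"pre-upsampling size {f} is not divisible by "
                f"{g.level_scale}"
            )
        m.append(f // g.level_scale)
    feats = [m[k] + shrink for k in range(g.n_levels - 1)] + [m[-1]]
    inputs = [f + block_shrink for f in feats]
    if feats[-1] < 1 or inputs[-1] < g.kernel:
        raise GeometryError(
            f"output size {out} leaves no voxels at the coarsest level"
        )
    return m, feats, inputs


def required_input_geometry(g: ModelGeometry) -> list[tuple[int, int, int]]:
    """Exact per-level input patch sizes implied by ``g.output_size``.

    Raises :class:`GeometryError` naming the failing axis when the size
    chain cannot be aligned across levels.
    """
    per_axis = []
    for ax, out in enumerate(g.output_size):
        try:
            _, _, inputs = _axis_chain(out, g)
        except GeometryError as exc:
            raise GeometryError(f"axis {ax}: {exc}") from exc
        per_axis.append(inputs)
    return [tuple(per_axis[ax][lvl] for ax in range(3))
            for lvl in range(g.n_levels)]


def valid_output_sizes(n_levels: int, convs_per_block: int = 3,
                       kernel: int = 3, level_scale: int = 2,
                       lo: int = 1, hi: int = 128) -> list[int]:
    """All per-axis output sizes in [lo, hi] the level chain can align."""
    from types import SimpleNamespace
    g = SimpleNamespace(n_levels=n_levels, convs_per_block=convs_per_block,
                        kernel=kernel, level_scale=level_scale)
    ok = []
    for o in range(lo, hi + 1):
        try:
            _axis_chain(o, g)
            ok.append(o)
        except GeometryError:
            pass
    return ok


def output_size_for_patch_extent(g: ModelGeometry, extent_mm: float) -> int:
    """Largest valid per-axis output size whose finest-level input patch
    fits within ``extent_mm`` (the physical training-patch footprint)."""
    max_in = int(np.floor(extent_mm / g.finest_spacing))
    best = None
    for o in range(1, max_in + 1):
        try:
            _, _, inputs = _axis_chain(o, g)
        except GeometryError:
            continue
        if inputs[0] <= max_in:
            best = o
    if best is None:
        raise GeometryError(
            f"no valid output size fits a {extent_mm} mm patch for this "
            f"geometry"
        )
    return best


# ---------------------------------------------------------------------------
# Foveal patch extraction
# ---------------------------------------------------------------------------

@dataclass
class FovealPatchSet:
    """Multi-resolution input patches sharing one world center.

    ``levels[k]`` has shape ``(n,) + input_size[k]`` (a batch of patches at
    level-k spacing); ``centers_mm`` holds the shared world center of each
    batch member.
    """

    levels: list[np.ndarray]
    centers_mm: np.ndarray
    geometry: ModelGeometry

    @property
    def n(self) -> int:
        return self.levels[0].shape[0]


@dataclass
class ProbabilityMap:
    """Per-voxel foreground pseudo-probabilities on a stated grid."""

    prob: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        p = self.prob
        if p.min() < -1e-6 or p.max() > 1 + 1e-6:
            raise ValidationError("probabilities must lie in [0, 1]")


def extract_foveal_patches(v: Volume, centers_mm: np.ndarray,
                           g: ModelGeometry,
                           pad_value: float = -3.0) -> FovealPatchSet:
    """Sample the per-level input patches around one or more world centers.

    The volume must already be preprocessed (normalized intensities,
    isotropic at ``g.finest_spacing``). Level k is sampled at
    ``finest_spacing * level_scale**k`` by linear interpolation; regions
    outside the volume are filled with ``pad_value`` (normalized air, -3).
    """
    centers = np.atleast_2d(np.asarray(centers_mm, dtype=float))
    if not np.all(np.isfinite(centers)):
        raise ValidationError("patch centers must be finite")
    if not np.allclose(v.spacing, g.finest_spacing):
        raise ValidationError(
            f"volume spacing {v.spacing} does not match the model's finest "
            f"spacing {g.finest_spacing}"
        )
    input_sizes = required_input_geometry(g)
    data = v.data.astype(np.float32)
    levels = []
    for k, size in enumerate(input_sizes):
        scale = float(g.level_scale ** k)
        offsets = [scale * (np.arange(s) - (s - 1) / 2.0) for s in size]
        batch = np.empty((centers.shape[0], *size), dtype=np.float32)
        for i, c in enumerate(centers):
            cidx = v.world_to_index(c)
            coords = np.meshgrid(
                *[cidx[ax] + offsets[ax] for ax in range(3)], indexing="ij"
            )
            batch[i] = ndimage.map_coordinates(
                data, np.stack(coords), order=1, mode="constant",
                cval=pad_value,
            )
        levels.append(batch)
    return FovealPatchSet(levels=levels, centers_mm=centers, geometry=g)


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------

class _CBR:
    """Convolution + batch normalization + ReLU."""

    def __init__(self, in_ch, out_ch, kernel, momentum, rng, name):
        self.conv = _nn.Conv3d(in_ch, out_ch, kernel, rng, name=name)
        self.bn = _nn.BatchNorm3d(out_ch, momentum=momentum, name=name)
        self.relu = _nn.ReLU()

    @property
    def params(self):
        return self.conv.params + self.bn.params

    def forward(self, x, train=True):
        return self.relu.forward(
            self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, g):
        return self.conv.backward(self.bn.backward(self.relu.backward(g)))


class FovealNet:
    """Assembled foveal network (see module docstring for the dataflow)."""

    def __init__(self, geometry: ModelGeometry, seed: int = 0):
        self.geometry = geometry
        g = geometry
        rng = np.random.default_rng(seed)
        mom = g.bn_momentum
        self.level_blocks: list[list[_CBR]] = []
        for k in range(g.n_levels):
            blocks = []
            for i in range(g.convs_per_block):
                in_ch = 1 if i == 0 else g.channels[k]
                blocks.append(_CBR(in_ch, g.channels[k], g.kernel, mom, rng,
                                   name=f"lvl{k}_cbr{i}"))
            self.level_blocks.append(blocks)
        # integration pathway: one CBR per merge, finest last
        self.integration: list[_CBR] = []
        self.upsamplers: list[_nn.UpsampleNearest] = []
        for k in range(g.n_levels - 2, -1, -1):
            in_ch = g.channels[k] + g.channels[k + 1]
            self.integration.append(
                _CBR(in_ch, g.channels[k], g.kernel, mom, rng,
                     name=f"int{k}_cbr"))
            self.upsamplers.append(_nn.UpsampleNearest(g.level_scale))
        self.final = _nn.Conv3d(g.channels[0], 2, 1, rng, name="final")
        self._cache = None

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[_nn.Param]:
        out = []
        for blocks in self.level_blocks:
            for b in blocks:
                out.extend(b.params)
        for b in self.integration:
            out.extend(b.params)
        out.extend(self.final.params)
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def _bn_layers(self):
        for blocks in self.level_blocks:
            for b in blocks:
                yield b.bn
        for b in self.integration:
            yield b.bn

    # -- forward / backward -------------------------------------------------
    def forward_batch(self, level_inputs: list[np.ndarray],
                      train: bool = False) -> np.ndarray:
        """Run a batch; each ``level_inputs[k]`` is ``(N,) + input_size[k]``.

        Returns softmax probabilities ``(N,) + output_size + (2,)``
        (channels last; channel 1 is foreground).
        """
        g = self.geometry
        expected = required_input_geometry(g)
        feats = []
        for k, x in enumerate(level_inputs):
            if tuple(x.shape[1:]) != expected[k]:
                ax = next(a for a in range(3)
                          if x.shape[1 + a] != expected[k][a])
                raise ValidationError(
                    f"level {k} axis {ax}: patch size {tuple(x.shape[1:])} "
                    f"!= required {expected[k]}"
                )
            h = np.ascontiguousarray(x[..., None].astype(np.float32))
            for b in self.level_blocks[k]:
                h = b.forward(h, train)
            feats.append(h)
        h = feats[-1]
        for i, k in enumerate(range(g.n_levels - 2, -1, -1)):
            up = self.upsamplers[i].forward(h, train)
            h = np.concatenate([feats[k], up], axis=-1)
            h = self.integration[i].forward(h, train)
        logits = self.final.forward(h, train)
        probs = _nn.softmax_channels(logits)
        if train:
            self._cache = probs
        return probs

    def backward_from_probs(self, dprobs: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the softmax probabilities."""
        g = self.geometry
        grad = _nn.softmax_backward(self._cache, dprobs)
        grad = self.final.backward(grad)
        dfeats = [None] * g.n_levels
        for i in range(len(self.integration) - 1, -1, -1):
            k = g.n_levels - 2 - i
            grad = self.integration[i].backward(grad)
            c_fine = g.channels[k]
            dfeats[k] = grad[..., :c_fine]
            grad = self.upsamplers[i].backward(grad[..., c_fine:])
        dfeats[g.n_levels - 1] = grad
        for k in range(g.n_levels):
            h = dfeats[k]
            for b in reversed(self.level_blocks[k]):
                h = b.backward(h)
        self._cache = None

    def predict_patches(self, patches: FovealPatchSet) -> np.ndarray:
        """Inference-mode foreground probabilities ``(N,) + output_size``."""
        probs = self.forward_batch(patches.levels, train=False)
        return probs[..., 1]

    # -- serialization ------------------------------------------------------
    def save(self, path: str) -> None:
        """Self-describing checkpoint: geometry + weights + BN statistics."""
        arrays = {}
        for p in self.params():
            arrays[f"param/{p.name}"] = p.value
        for i, bn in enumerate(self._bn_layers()):
            arrays[f"bnstat/{i}/mean"] = bn.running_mean
            arrays[f"bnstat/{i}/var"] = bn.running_var
        meta = json.dumps({
            "n_levels": self.geometry.n_levels,
            "convs_per_block": self.geometry.convs_per_block,
            "kernel": self.geometry.kernel,
            "level_scale": self.geometry.level_scale,
            "channels": list(self.geometry.channels),
            "output_size": list(self.geometry.output_size),
            "finest_spacing": self.geometry.finest_spacing,
            "bn_momentum": self.geometry.bn_momentum,
        })
        np.savez(path, geometry=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str) -> "FovealNet":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["geometry"]).decode())
            geometry = ModelGeometry(
                n_levels=meta["n_levels"],
                convs_per_block=meta["convs_per_block"],
                kernel=meta["kernel"],
                level_scale=meta["level_scale"],
                channels=tuple(meta["channels"]),
                output_size=tuple(meta["output_size"]),
                finest_spacing=meta["finest_spacing"],
                bn_momentum=meta["bn_momentum"],
            )
            net = cls(geometry)
            by_name = {p.name: p for p in net.params()}
            for key in npz.files:
                if key.startswith("param/"):
                    name = key[len("param/"):]
                    if name not in by_name:
                        raise ValidationError(
                            f"checkpoint parameter {name} does not match the "
                            f"stored geometry")
                    by_name[name].value = npz[key].astype(np.float32)
                    by_name[name].grad = np.zeros_like(by_name[name].value)
            for i, bn in enumerate(net._bn_layers()):
                bn.running_mean = npz[f"bnstat/{i}/mean"].astype(np.float32)
                bn.running_var = npz[f"bnstat/{i}/var"].astype(np.float32)
        return net

    def state_copy(self) -> dict:
        """Deep copy of all learnable state (for best-checkpoint retention)."""
        return {
            "params": [p.value.copy() for p in self.params()],
            "bn": [(bn.running_mean.copy(), bn.running_var.copy())
                   for bn in self._bn_layers()],
        }

    def load_state_copy(self, state: dict) -> None:
        for p, v in zip(self.params(), state["params"]):
            p.value = v.copy()
            p.grad = np.zeros_like(p.value)
        for bn, (m, va) in zip(self._bn_layers(), state["bn"]):
            bn.running_mean = m.copy()
            bn.running_var = va.copy()


def forward(model: FovealNet, patches: FovealPatchSet) -> ProbabilityMap:
    """Single-patch inference returning a :class:`ProbabilityMap` centered at
    the patch center, on the finest-spacing grid."""
    fg = model.predict_patches(patches)[0]
    g = model.geometry
    o = np.asarray(g.output_size, dtype=float)
    origin = (patches.centers_mm[0]
              - (o - 1) / 2.0 * g.finest_spacing)
    return ProbabilityMap(prob=fg, spacing=(g.finest_spacing,) * 3,
                          origin=tuple(origin))


__all__ = [
    "GeometryError", "ModelGeometry", "FovealPatchSet", "ProbabilityMap",
    "required_input_geometry", "valid_output_sizes",
    "output_size_for_patch_extent", "extract_foveal_patches",
    "FovealNet", "forward",
]
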