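"""Domain types, image I/O, geometry, and intensity preprocessing.

The pipeline operates on contrast-enhanced CT volumes in Hounsfield units (HU)
together with per-node ground-truth label maps. Before any network sees a
volume it is (1) resampled to an isotropic grid (default 1 mm), (2) normalized
with a soft-tissue window/level (default 395/10 HU mapped onto [-3, 3]), and
(3) cropped to a head-and-neck region of interest of at least 200 x 200 x 250
mm that contains every annotated node.

Conventions (used consistently across the package):

* arrays are indexed ``[x, y, z]`` with x = left-right, y =
  anterior-posterior, z = inferior-superior; the axial plane is x-y;
* voxel indices are 0-based and refer to voxel centers: the world coordinate
  of index ``i`` is ``origin + i * spacing``;
* physical sizes in mm are converted to voxel counts by rounding half away
  from zero.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage


class DimensionalityError(ValueError):
    """Raised when an image on disk is not a 3D scalar volume."""


class ValidationError(ValueError):
    """Raised when an argument violates a documented precondition."""


def _round_half_away(x) -> np.ndarray:
    """Round half away from zero (``0.5 -> 1``, ``-0.5 -> -1``)."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Volume:
    """A 3D scalar grid with physical geometry.

    ``data`` holds HU values before normalization, or dimensionless
    intensities afterwards. ``spacing`` is mm per voxel along (x, y, z);
    ``origin`` is the world coordinate (mm) of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"Volume data must be 3D, got {self.data.ndim}D"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        if any(n < 1 for n in self.data.shape):
            raise ValidationError("every volume axis must have size >= 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size of the grid per axis (voxel-extent convention)."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))

    def index_to_world(self, index) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def world_to_index(self, world) -> np.ndarray:
        return (np.asarray(world) - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class NodeLabelMap:
    """Integer label grid where each ground-truth node has a distinct id > 0."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DimensionalityError(
                f"label map must be 3D, got {self.labels.ndim}D"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("label map must have an integer dtype")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def node_ids(self) -> set[int]:
        ids = np.unique(self.labels)
        return {int(i) for i in ids if i > 0}

    def foreground(self) -> np.ndarray:
        return self.labels > 0

    def node_mask(self, node_id: int) -> np.ndarray:
        return self.labels == node_id


@dataclass
class NormalizationSpec:
    """A CT window/level mapped linearly onto a target interval.

    HU value ``level - window/2`` maps to ``out_lo`` and ``level + window/2``
    to ``out_hi``; values outside saturate at the interval bounds.
    """

    window: float = 395.0
    level: float = 10.0
    out_lo: float = -3.0
    out_hi: float = 3.0

    def __post_init__(self):
        if self.window <= 0:
            raise ValidationError(f"window must be > 0, got {self.window}")
        if not self.out_lo < self.out_hi:
            raise ValidationError("out_lo must be < out_hi")


@dataclass
class PreprocessConfig:
    target_spacing: float = 1.0
    min_crop_size_mm: tuple[float, float, float] = (200.0, 200.0, 250.0)
    normalization: NormalizationSpec = field(default_factory=NormalizationSpec)
    neighborhood_mm: float = 3.0  # dilation radius for window auto-estimation

    def __post_init__(self):
        if self.target_spacing <= 0:
            raise ValidationError("target_spacing must be > 0")
        if any(s <= 0 for s in self.min_crop_size_mm):
            raise ValidationError("min_crop_size_mm must be positive per axis")


# ---------------------------------------------------------------------------
# File I/O (NIfTI and MetaImage via SimpleITK)
# ---------------------------------------------------------------------------

def _read_sitk(path: str) -> sitk.Image:
    if not os.path.exists(path):
        raise IOError(f"image file not found: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # pragma: no cover - backend-specific message
        raise IOError(f"could not read image file {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise DimensionalityError(
            f"{path}: expected a 3D image, got {img.GetDimension()}D"
        )
    return img


def read_volume(path: str) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) intensity volume."""
    img = _read_sitk(path)
    # SimpleITK arrays come back as (z, y, x); transpose to our (x, y, z).
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return Volume(data=data, spacing=img.GetSpacing(), origin=img.GetOrigin())


def read_node_labels(path: str) -> NodeLabelMap:
    """Read a per-node ground-truth label map (integer labels, 0=background)."""
    img = _read_sitk(path)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded):
            raise ValidationError(f"{path}: label map contains non-integer values")
        data = rounded.astype(np.int32)
    return NodeLabelMap(labels=data, spacing=img.GetSpacing(), origin=img.GetOrigin())


def read_case(image_path: str, label_path: str | None = None
              ) -> tuple[Volume, NodeLabelMap | None]:
    """Read an (image, labels) pair; the label file is optional."""
    vol = read_volume(image_path)
    lbl = read_node_labels(label_path) if label_path is not None else None
    if lbl is not None and lbl.shape != vol.shape:
        raise ValidationError(
            f"label grid {lbl.shape} does not match image grid {vol.shape}"
        )
    return vol, lbl


def _to_sitk(data: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def write_volume(vol: Volume, path: str) -> None:
    """Write an intensity volume; format inferred from the file extension."""
    sitk.WriteImage(_to_sitk(vol.data.astype(np.float32), vol.spacing, vol.origin),
                    str(path))


def write_node_labels(lbl: NodeLabelMap, path: str) -> None:
    sitk.WriteImage(
        _to_sitk(lbl.labels.astype(np.int32), lbl.spacing, lbl.origin), str(path)
    )


# ---------------------------------------------------------------------------
# Intensity normalization
# ---------------------------------------------------------------------------

def normalize_intensity(v: Volume, spec: NormalizationSpec | None = None) -> Volume:
    """Window/level normalization with saturation.

    Applies the linear map that sends ``[level - window/2, level + window/2]``
    onto ``[out_lo, out_hi]`` and clips everything outside. Geometry is
    unchanged. The default spec is the learned lymph-node window/level
    395/10 HU mapped onto [-3, 3].
    """
    spec = spec or NormalizationSpec()
    lo_hu = spec.level - spec.window / 2.0
    scaled = spec.out_lo + (v.data.astype(np.float64) - lo_hu) / spec.window \
        * (spec.out_hi - spec.out_lo)
    out = np.clip(scaled, spec.out_lo, spec.out_hi).astype(np.float32)
    return Volume(data=out, spacing=v.spacing, origin=v.origin)


def estimate_normalization_window(v: Volume, gt: NodeLabelMap,
                                  neighborhood_mm: float = 3.0,
                                  out_lo: float = -3.0,
                                  out_hi: float = 3.0) -> NormalizationSpec:
    """Estimate a window/level from node intensities and their neighborhoods.

    Pools the HU values of all ground-truth node voxels together with a
    morphological dilation of the node mask by ``neighborhood_mm`` and
    returns ``level = mean`` and ``window = 6 * std`` so that +-3 standard
    deviations span the normalized interval. On realistic soft-tissue
    statistics this lands near the standard CT soft-tissue window/level of
    about 350/50 HU.
    """
    fg = gt.foreground()
    if not fg.any():
        raise ValidationError("cannot estimate a window from an empty label map")
    if neighborhood_mm > 0:
        structure = _ball_structure(neighborhood_mm, v.spacing)
        region = ndimage.binary_dilation(fg, structure=structure)
    else:
        region = fg
    values = v.data[region].astype(np.float64)
    mean = float(values.mean())
    std = float(values.std())
    if std == 0.0:
        raise ValidationError(
            "zero intensity variance inside nodes and neighborhoods; "
            "degenerate window"
        )
    return NormalizationSpec(window=6.0 * std, level=mean,
                             out_lo=out_lo, out_hi=out_hi)


def _ball_structure(radius_mm: float, spacing) -> np.ndarray:
    """Boolean ellipsoidal structuring element of physical radius ``radius_mm``."""
    r_vox = [max(0, int(np.floor(radius_mm / s))) for s in spacing]
    grids = np.meshgrid(*[np.arange(-r, r + 1) for r in r_vox], indexing="ij")
    dist2 = sum((g * s / radius_mm) ** 2 for g, s in zip(grids, spacing))
    return dist2 <= 1.0 + 1e-9


# ---------------------------------------------------------------------------
# Resampling and cropping
# ---------------------------------------------------------------------------

def resample_isotropic(v: Volume, target_spacing: float = 1.0,
                       interp: str = "linear") -> Volume:
    """Resample to an isotropic grid (default 1 mm).

    Output size per axis is ``round(in_size * in_spacing / target)``; sample
    positions follow the voxel-center convention, with edge samples clamped.
    Intensities use linear interpolation, label maps nearest-neighbor.
    """
    if target_spacing <= 0:
        raise ValidationError("target_spacing must be > 0")
    if interp not in ("linear", "nearest"):
        raise ValidationError(f"unknown interpolation {interp!r}")
    in_spacing = np.asarray(v.spacing)
    if np.allclose(in_spacing, target_spacing):
        return Volume(data=v.data.copy(), spacing=(target_spacing,) * 3,
                      origin=v.origin)
    out_shape = _round_half_away(
        np.asarray(v.shape) * in_spacing / target_spacing
    )
    out_shape = np.maximum(out_shape, 1)
    coords = np.meshgrid(
        *[np.arange(n) * target_spacing / s for n, s in zip(out_shape, in_spacing)],
        indexing="ij",
    )
    order = 1 if interp == "linear" else 0
    data = ndimage.map_coordinates(
        v.data.astype(np.float32 if order else v.data.dtype),
        np.stack(coords), order=order, mode="nearest"
    )
    return Volume(data=data, spacing=(target_spacing,) * 3, origin=v.origin)


def resample_labels_isotropic(lbl: NodeLabelMap,
                              target_spacing: float = 1.0) -> NodeLabelMap:
    """Nearest-neighbor resampling that preserves integer node identities."""
    v = Volume(data=lbl.labels, spacing=lbl.spacing, origin=lbl.origin)
    out = resample_isotropic(v, target_spacing, interp="nearest")
    return NodeLabelMap(labels=out.data.astype(lbl.labels.dtype),
                        spacing=out.spacing, origin=out.origin)


def crop_to_roi(v: Volume, gt: NodeLabelMap,
                min_size_mm: tuple[float, float, float] = (200.0, 200.0, 250.0)
                ) -> tuple[Volume, NodeLabelMap, tuple[slice, slice, slice]]:
    """Crop to a region of interest that contains every annotated node.

    The crop box has per-axis physical size of at least
    ``min(min_size_mm, volume extent)``, grows when the annotations span
    more, is centered on the annotation bounding box, and is clamped to the
    volume. Intensities and labels are cropped identically.
    """
    fg = gt.foreground()
    if not fg.any():
        raise ValidationError("annotation-driven cropping requires a nonempty "
                              "label map")
    spacing = np.asarray(v.spacing)
    shape = np.asarray(v.shape)
    idx = np.argwhere(fg)
    bb_lo, bb_hi = idx.min(axis=0), idx.max(axis=0)  # inclusive voxel bounds

    want_vox = _round_half_away(np.asarray(min_size_mm) / spacing)
    need_vox = bb_hi - bb_lo + 1
    size = np.minimum(np.maximum(want_vox, need_vox), shape)

    center = (bb_lo + bb_hi) / 2.0
    start = _round_half_away(center - (size - 1) / 2.0)
    start = np.clip(start, 0, shape - size)
    # size >= annotation extent and the box is centered on it, so clamping to
    # the volume can never push an annotated voxel outside; keep a hard check.
    start = np.minimum(start, bb_lo)
    start = np.maximum(start, bb_hi + 1 - size)
    end = start + size
    box = tuple(slice(int(s), int(e)) for s, e in zip(start, end))

    new_origin = tuple(np.asarray(v.origin) + start * spacing)
    cropped_v = Volume(data=v.data[box], spacing=v.spacing, origin=new_origin)
    cropped_l = NodeLabelMap(labels=gt.labels[box], spacing=v.spacing,
                             origin=new_origin)
    return cropped_v, cropped_l, box


def preprocess_case(v: Volume, gt: NodeLabelMap | None,
                    cfg: PreprocessConfig | None = None,
                    auto_window: bool = False
                    ) -> tuple[Volume, NodeLabelMap | None]:
    """Full preprocessing chain: resample -> (crop) -> normalize.

    ``auto_window=True`` replaces the fixed 395/10 window with the
    mean/std estimate from the node neighborhoods (requires labels).
    """
    cfg = cfg or PreprocessConfig()
    v_iso = resample_isotropic(v, cfg.target_spacing, interp="linear")
    gt_iso = resample_labels_isotropic(gt, cfg.target_spacing) if gt is not None \
        else None
    if gt_iso is not None and gt_iso.foreground().any():
        v_iso, gt_iso, _ = crop_to_roi(v_iso, gt_iso, cfg.min_crop_size_mm)
    spec = cfg.normalization
    if auto_window:
        if gt_iso is None:
            raise ValidationError("auto_window requires ground-truth labels")
        spec = estimate_normalization_window(
            v_iso, gt_iso, cfg.neighborhood_mm,
            out_lo=spec.out_lo, out_hi=spec.out_hi,
        )
    return normalize_intensity(v_iso, spec), gt_iso


__all__ = [
    "Volume", "NodeLabelMap", "NormalizationSpec", "PreprocessConfig",
    "DimensionalityError", "ValidationError",
    "read_volume", "read_node_labels", "read_case",
    "write_volume", "write_node_labels",
    "normalize_intensity", "estimate_normalization_window",
    "resample_isotropic", "resample_labels_isotropic",
    "crop_to_roi", "preprocess_case",
]
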