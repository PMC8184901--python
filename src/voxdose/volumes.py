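"""Volume data model, file I/O, resampling and CT pre/post-processing.

A :class:`VoxelGrid` is the package's in-memory currency for CT (HU),
quantitative SPECT (Bq/ml), cumulated-activity (Bq·s) and dose (Gy)
volumes.  Conventions, used by every module:

* voxel data are indexed ``data[i, j, k]`` with axes (x, y, z); axial
  slices are planes of constant ``k``, sagittal of constant ``i``,
  coronal of constant ``j``;
* world coordinates are millimetres, voxel indices are 0-based, and a
  voxel's world position refers to its centre:
  ``world = origin + index * spacing`` (axis-aligned grids only);
* on-disk formats are NIfTI-1 and MetaImage via SimpleITK, with an
  optional YAML sidecar (``<path>.yaml``) carrying ``intensity_kind``
  and a quantitative calibration factor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import yaml
from scipy import ndimage

INTENSITY_KINDS = (
    "HU",
    "activity_conc_Bq_per_ml",
    "activity_Bq",
    "cumulated_activity_Bq_s",
    "dose_Gy",
    "unitless",
)


class GeometryError(ValueError):
    """Raised when two grids are incompatible in world space."""


class FormatError(ValueError):
    """Raised when a volume file lacks required metadata."""


@dataclass
class VoxelGrid:
    """A 3D scalar lattice with physical spacing and origin.

    Parameters
    ----------
    data:
        3D array indexed (x, y, z).
    spacing:
        Voxel size (dx, dy, dz) in mm, strictly positive.
    origin:
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    intensity_kind:
        Physical meaning of the stored values, one of
        :data:`INTENSITY_KINDS`.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity_kind: str = "unitless"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.intensity_kind not in INTENSITY_KINDS:
            raise ValueError(
                f"unknown intensity_kind {self.intensity_kind!r}; "
                f"expected one of {INTENSITY_KINDS}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in ml (= cm³); spacing is mm so divide by 1000."""
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    def world_coords(self, index: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centre(s) ``index`` (…, 3)."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def with_data(self, data: np.ndarray, intensity_kind: str | None = None) -> "VoxelGrid":
        """A copy of this grid's geometry carrying ``data``."""
        return replace(
            self,
            data=data,
            intensity_kind=intensity_kind or self.intensity_kind,
        )


@dataclass
class BinaryMask:
    """Organ occupancy on a :class:`VoxelGrid`; values exactly {0, 1}."""

    grid: VoxelGrid
    label: str = ""

    def __post_init__(self) -> None:
        vals = np.unique(self.grid.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be 0/1, found {vals[:10]}")
        if self.grid.data.dtype != np.uint8:
            self.grid = self.grid.with_data(self.grid.data.astype(np.uint8))

    @property
    def data(self) -> np.ndarray:
        return self.grid.data

    @property
    def voxel_count(self) -> int:
        return int(self.grid.data.sum())

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_ml

    def as_bool(self) -> np.ndarray:
        return self.grid.data.astype(bool)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMAT_EXT = {
    "NIfTI": (".nii", ".nii.gz"),
    "MetaImage": (".mha", ".mhd"),
}


def _sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".yaml")


def _to_sitk(v: VoxelGrid) -> sitk.Image:
    # SimpleITK array order is (z, y, x); our storage is (x, y, z).
    img = sitk.GetImageFromArray(np.ascontiguousarray(v.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in v.spacing))
    img.SetOrigin(tuple(float(o) for o in v.origin))
    return img


def _from_sitk(img: sitk.Image, intensity_kind: str = "unitless") -> VoxelGrid:
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = img.GetSpacing()
    if any(s <= 0 for s in spacing):
        raise FormatError(f"volume has non-positive spacing {spacing}")
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(np.abs(direction), np.eye(3), atol=1e-6):
        raise FormatError("oblique direction matrices are not supported")
    origin = np.asarray(img.GetOrigin(), dtype=float)
    # Normalise flipped axes so stored data always runs along +x, +y, +z.
    for ax in range(3):
        if direction[ax, ax] < 0:
            data = np.flip(data, axis=ax)
            origin[ax] -= spacing[ax] * (data.shape[ax] - 1)
    return VoxelGrid(
        data=np.ascontiguousarray(data),
        spacing=tuple(spacing),
        origin=tuple(origin),
        intensity_kind=intensity_kind,
    )


def read_volume(path: str | Path, format: str | None = None) -> VoxelGrid:
    """Read a NIfTI or MetaImage volume into a :class:`VoxelGrid`.

    The axis order is normalised to (x, y, z) with axial = z.  If a YAML
    sidecar ``<path>.yaml`` exists, its ``intensity_kind`` is applied and
    a ``calibration_Bq_per_ml_per_unit`` factor, when present, rescales
    stored units to Bq/ml.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    if format is not None and format not in _FORMAT_EXT:
        raise ValueError(f"unknown format {format!r}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # SimpleITK wraps parse failures
        raise IOError(f"could not read volume {path}: {exc}") from exc

    kind = "unitless"
    sidecar = _sidecar_path(path)
    calibration = None
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
        kind = meta.get("intensity_kind", kind)
        calibration = meta.get("calibration_Bq_per_ml_per_unit")
    v = _from_sitk(img, intensity_kind=kind)
    if calibration is not None and kind == "activity_conc_Bq_per_ml":
        v = v.with_data(v.data.astype(np.float64) * float(calibration))
    return v


def write_volume(v: VoxelGrid, path: str | Path, format: str | None = None) -> None:
    """Write a volume as NIfTI or MetaImage, plus an intensity sidecar.

    Integer data round-trips bit-compatibly; float data within 1e-6.
    """
    path = Path(path)
    if format is not None:
        exts = _FORMAT_EXT.get(format)
        if exts is None:
            raise ValueError(f"unknown format {format!r}")
        if not str(path).endswith(exts):
            raise ValueError(f"path {path} does not match format {format}")
    if path.parent != Path("") and not path.parent.exists():
        raise IOError(f"directory does not exist: {path.parent}")
    try:
        sitk.WriteImage(_to_sitk(v), str(path))
    except RuntimeError as exc:
        raise IOError(f"could not write volume {path}: {exc}") from exc
    _sidecar_path(path).write_text(
        yaml.safe_dump({"intensity_kind": v.intensity_kind})
    )


def write_mask(m: BinaryMask, path: str | Path, format: str | None = None) -> None:
    """Write a mask as an 8-bit integer volume."""
    write_volume(m.grid, path, format)


def read_mask(path: str | Path, label: str = "") -> BinaryMask:
    v = read_volume(path)
    return BinaryMask(grid=v.with_data((v.data > 0.5).astype(np.uint8)), label=label)


# ---------------------------------------------------------------------------
# CT pre/post-processing primitives
# ---------------------------------------------------------------------------


def hu_window(ct: VoxelGrid, lo: float = -100.0, hi: float = 200.0) -> VoxelGrid:
    """Window a CT volume to [lo, hi] HU and rescale to [0, 1].

    The [-100, 200] HU default brackets abdominal soft tissue while
    suppressing air and bone; it is the only CT pre-processing the
    segmentation stage needs.  The mapping is monotone:
    ``out = (clip(ct, lo, hi) - lo) / (hi - lo)``.
    """
    if lo >= hi:
        raise ValueError(f"window requires lo < hi, got [{lo}, {hi}]")
    if ct.intensity_kind != "HU":
        raise ValueError(f"hu_window expects HU data, got {ct.intensity_kind!r}")
    out = (np.clip(ct.data.astype(np.float64), lo, hi) - lo) / (hi - lo)
    return ct.with_data(out, intensity_kind="unitless")


def window_slice(frame: np.ndarray, lo: float = -100.0, hi: float = 200.0) -> np.ndarray:
    """2D counterpart of :func:`hu_window` for per-slice backends."""
    if lo >= hi:
        raise ValueError(f"window requires lo < hi, got [{lo}, {hi}]")
    return (np.clip(np.asarray(frame, dtype=np.float64), lo, hi) - lo) / (hi - lo)


def _world_bounds(v: VoxelGrid) -> tuple[np.ndarray, np.ndarray]:
    lo = np.asarray(v.origin) - 0.5 * np.asarray(v.spacing)
    hi = lo + np.asarray(v.spacing) * np.asarray(v.shape)
    return lo, hi


def resample_to(
    v: VoxelGrid,
    target: VoxelGrid,
    interpolation: str = "linear",
    default_value: float = 0.0,
) -> VoxelGrid:
    """Resample ``v`` onto the geometry of ``target``.

    ``interpolation`` is ``"linear"`` for images and ``"nearest"`` for
    masks.  Raises :class:`GeometryError` when the two grids do not
    overlap in world space.
    """
    if v.same_geometry(target):
        return target.with_data(v.data.copy(), intensity_kind=v.intensity_kind)
    lo_v, hi_v = _world_bounds(v)
    lo_t, hi_t = _world_bounds(target)
    if (hi_v <= lo_t).any() or (hi_t <= lo_v).any():
        raise GeometryError("source and target grids do not overlap in world space")
    interp = {"linear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor}.get(
        interpolation
    )
    if interp is None:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    out = sitk.Resample(
        _to_sitk(v),
        _to_sitk(target),
        sitk.Transform(),
        interp,
        float(default_value),
        _to_sitk(v).GetPixelID(),
    )
    res = _from_sitk(out, intensity_kind=v.intensity_kind)
    return res


def resample_mask_to(m: BinaryMask, target: VoxelGrid) -> BinaryMask:
    """Nearest-neighbour mask resampling; never leaves {0, 1}."""
    res = resample_to(m.grid, target, interpolation="nearest")
    return BinaryMask(grid=res.with_data(res.data.astype(np.uint8)), label=m.label)


def resize_mask(m: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Resize a 2D binary mask by linear interpolation then 0.5 threshold.

    This mirrors the post-processing step that takes per-slice network
    masks from the prediction resolution (e.g. 256×256) back to the
    ground-truth resolution (e.g. 512×512).
    """
    m = np.asarray(m)
    if m.ndim != 2:
        raise ValueError(f"expected a 2D mask, got {m.ndim}D")
    vals = np.unique(m)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("resize_mask requires a binary {0,1} input")
    if m.shape == tuple(out_shape):
        return m.astype(np.uint8)
    zoom = [o / s for o, s in zip(out_shape, m.shape)]
    field = ndimage.zoom(m.astype(np.float64), zoom, order=1, grid_mode=True,
                         mode="nearest")
    field = field[: out_shape[0], : out_shape[1]]
    return (field >= 0.5).astype(np.uint8)
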