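"""Containers and file I/O for time-resolved three-component velocity volumes.

The in-memory model mirrors what a phase-contrast MRI reconstruction delivers:
one scalar lattice per velocity component and cardiac phase, a voxel spacing,
a world origin, and (optionally) a lumen mask.  All lengths are millimetres
and all velocities millimetres per second, so vorticity comes out in s^-1 and
the lambda2 scalar in s^-2 without unit juggling.

World coordinates are right-handed and voxel-centred:

    world = origin + index * spacing

Files travel as one 4D NIfTI per velocity component plus a small JSON sidecar
(``spacing_mm``, ``phase_times``, ``velocity_unit``, optional ``origin_mm`` /
``venc``).  A raw little-endian float64 dump with the same sidecar (plus a
``dims`` entry) is accepted as a fallback dialect.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VelocityField4D",
    "ScalarField3",
    "VectorField3",
    "read_velocity_volume",
    "write_velocity_volume",
    "write_scalar_nifti",
    "write_vector_nifti",
    "write_mask_nifti",
    "read_scalar_nifti",
    "segment_lumen",
]

#: multiplicative factors converting a stored unit into mm/s
_UNIT_TO_MM_S = {"mm/s": 1.0, "cm/s": 10.0, "m/s": 1000.0}

_COMPONENT_KEYS = ("vx", "vy", "vz")


def _as_f64(a) -> np.ndarray:
    return np.ascontiguousarray(np.asarray(a, dtype=np.float64))


@dataclass
class VelocityField4D:
    """Time series of three-component velocity lattices.

    Attributes
    ----------
    vx, vy, vz : (nt, nx, ny, nz) float64 arrays, mm/s
    spacing : (hx, hy, hz) voxel spacing in mm, strictly positive
    origin : world position of voxel (0, 0, 0) in mm
    phase_times : nt fractions of the cardiac cycle in [0, 1), increasing
    mask : optional boolean lumen mask, (nx, ny, nz) or (nt, nx, ny, nz)
    """

    vx: np.ndarray
    vy: np.ndarray
    vz: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)
    phase_times: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.vx = _as_f64(self.vx)
        self.vy = _as_f64(self.vy)
        self.vz = _as_f64(self.vz)
        if self.vx.ndim != 4:
            raise ValueError(f"velocity lattices must be 4D (nt,nx,ny,nz), got {self.vx.ndim}D")
        if not (self.vx.shape == self.vy.shape == self.vz.shape):
            raise ValueError(
                f"component dims disagree: vx{self.vx.shape} vy{self.vy.shape} vz{self.vz.shape}"
            )
        self.spacing = tuple(float(h) for h in np.broadcast_to(self.spacing, (3,)))
        if any(h <= 0 for h in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in np.broadcast_to(self.origin, (3,)))
        nt = self.vx.shape[0]
        if self.phase_times is None:
            self.phase_times = np.arange(nt, dtype=np.float64) / nt
        self.phase_times = _as_f64(self.phase_times)
        if self.phase_times.shape != (nt,):
            raise ValueError(f"phase_times must have length nt={nt}")
        if nt > 1 and not np.all(np.diff(self.phase_times) > 0):
            raise ValueError("phase_times must be strictly increasing")
        if np.any(self.phase_times < 0) or np.any(self.phase_times >= 1):
            raise ValueError("phase_times must lie in [0, 1)")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape not in (self.spatial_shape, self.vx.shape):
                raise ValueError(
                    f"mask shape {self.mask.shape} matches neither {self.spatial_shape} "
                    f"nor {self.vx.shape}"
                )

    # -- geometry -----------------------------------------------------------

    @property
    def nt(self) -> int:
        return self.vx.shape[0]

    @property
    def spatial_shape(self) -> tuple:
        return self.vx.shape[1:]

    @property
    def dims(self) -> tuple:
        return self.vx.shape

    def bounds(self) -> np.ndarray:
        """Axis-aligned world bounding box, (2, 3): rows are lower/upper corners."""
        n = np.array(self.spatial_shape, dtype=np.float64)
        o = np.array(self.origin)
        h = np.array(self.spacing)
        return np.stack([o, o + (n - 1) * h])

    def mask_at(self, t: int) -> np.ndarray:
        """Boolean lumen mask for phase ``t`` (all-true when no mask is set)."""
        if self.mask is None:
            return np.ones(self.spatial_shape, dtype=bool)
        if self.mask.ndim == 4:
            return self.mask[t]
        return self.mask

    def frame(self, t: int) -> tuple:
        return self.vx[t], self.vy[t], self.vz[t]

    def sampler(self, t: int, out_of_bounds: str = "raise"):
        """Dynamic-degree spatial interpolant of the three components at phase ``t``."""
        from .interpolate import LatticeSampler

        return LatticeSampler(
            self.frame(t), self.spacing, self.origin,
            valid=self.mask_at(t) if self.mask is not None else None,
            out_of_bounds=out_of_bounds,
        )


@dataclass
class ScalarField3:
    """A scalar lattice sharing the parent velocity grid.

    Invalid voxels (stencil not fully inside the mask) hold NaN, never a
    silent zero; ``valid`` marks the usable ones.
    """

    values: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)
    unit: str = ""
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.values = _as_f64(self.values)
        if self.values.ndim != 3:
            raise ValueError("ScalarField3 expects a 3D lattice")
        self.spacing = tuple(float(h) for h in np.broadcast_to(self.spacing, (3,)))
        self.origin = tuple(float(o) for o in np.broadcast_to(self.origin, (3,)))
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.values.shape:
            raise ValueError("validity lattice must match values")


@dataclass
class VectorField3:
    """Three scalar lattices (e.g. the vorticity vector) on the velocity grid."""

    wx: np.ndarray
    wy: np.ndarray
    wz: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)
    unit: str = "1/s"
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.wx = _as_f64(self.wx)
        self.wy = _as_f64(self.wy)
        self.wz = _as_f64(self.wz)
        if not (self.wx.shape == self.wy.shape == self.wz.shape) or self.wx.ndim != 3:
            raise ValueError("vector components must be three identical 3D lattices")
        self.spacing = tuple(float(h) for h in np.broadcast_to(self.spacing, (3,)))
        self.origin = tuple(float(o) for o in np.broadcast_to(self.origin, (3,)))
        if self.valid is None:
            self.valid = np.isfinite(self.wx) & np.isfinite(self.wy) & np.isfinite(self.wz)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.wx.shape:
            raise ValueError("validity lattice must match components")

    @property
    def components(self) -> tuple:
        return self.wx, self.wy, self.wz

    def magnitude(self) -> ScalarField3:
        mag = np.sqrt(self.wx**2 + self.wy**2 + self.wz**2)
        return ScalarField3(mag, self.spacing, self.origin, unit=self.unit, valid=self.valid.copy())

    def sampler(self, out_of_bounds: str = "raise"):
        from .interpolate import LatticeSampler

        return LatticeSampler(
            self.components, self.spacing, self.origin, valid=self.valid,
            out_of_bounds=out_of_bounds,
        )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _load_component(path: str, dims=None) -> np.ndarray:
    """Load one component volume as (nt, nx, ny, nz)."""
    path = os.fspath(path)
    if path.endswith(".raw"):
        if dims is None:
            raise ValueError("raw component files require a 'dims' sidecar entry")
        data = np.fromfile(path, dtype="<f8").reshape(tuple(dims))
    else:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj).astype(np.float64)
        if data.ndim == 3:
            data = data[..., None]
        if data.ndim != 4:
            raise ValueError(f"{path}: expected a 3D or 4D volume, got {data.ndim}D")
        data = np.moveaxis(data, -1, 0)  # (nx,ny,nz,nt) -> (nt,nx,ny,nz)
    return np.ascontiguousarray(data)


def read_velocity_volume(paths: Mapping[str, str] | Sequence[str], sidecar: str) -> VelocityField4D:
    """Read a three-component velocity time series plus its JSON sidecar.

    Parameters
    ----------
    paths : mapping with keys ``vx``/``vy``/``vz`` (or a 3-sequence in that
        order) of per-component NIfTI (or ``.raw``) file paths.
    sidecar : JSON file declaring ``spacing_mm``, ``velocity_unit`` and
        optionally ``phase_times``, ``origin_mm``, ``dims`` and ``venc``.

    Velocities are converted to mm/s on load.
    """
    with open(sidecar) as fh:
        meta = json.load(fh)
    if not isinstance(paths, Mapping):
        paths = dict(zip(_COMPONENT_KEYS, paths))
    missing = [k for k in _COMPONENT_KEYS if k not in paths]
    if missing:
        raise ValueError(f"missing velocity component(s): {missing}")
    unit = meta.get("velocity_unit", "mm/s")
    if unit not in _UNIT_TO_MM_S:
        raise ValueError(f"unknown velocity unit {unit!r}; expected one of {sorted(_UNIT_TO_MM_S)}")
    scale = _UNIT_TO_MM_S[unit]
    dims = meta.get("dims")
    comps = []
    for key in _COMPONENT_KEYS:
        if not os.path.exists(os.fspath(paths[key])):
            raise FileNotFoundError(f"missing component file for {key}: {paths[key]}")
        comps.append(_load_component(paths[key], dims) * scale)
    shapes = {c.shape for c in comps}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent component dims: {sorted(shapes)}")
    mask = None
    if "mask" in meta and meta["mask"]:
        mask_path = os.path.join(os.path.dirname(os.fspath(sidecar)), meta["mask"])
        mask = np.asanyarray(nib.load(mask_path).dataobj) > 0
    return VelocityField4D(
        *comps,
        spacing=meta["spacing_mm"],
        origin=meta.get("origin_mm", (0.0, 0.0, 0.0)),
        phase_times=meta.get("phase_times"),
        mask=mask,
    )


def write_velocity_volume(field: VelocityField4D, out_dir: str, prefix: str = "vel") -> dict:
    """Write one 4D NIfTI per component plus the JSON sidecar (and mask if set).

    Round-trip through :func:`read_velocity_volume` is bit-exact (float64).
    Returns the mapping of written paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    aff = _affine(field.spacing, field.origin)
    written = {}
    for key in _COMPONENT_KEYS:
        data = np.moveaxis(getattr(field, key), 0, -1)  # (nx,ny,nz,nt)
        path = os.path.join(out_dir, f"{prefix}_{key}.nii.gz")
        nib.save(nib.Nifti1Image(np.ascontiguousarray(data), aff), path)
        written[key] = path
    meta = {
        "spacing_mm": list(field.spacing),
        "origin_mm": list(field.origin),
        "phase_times": field.phase_times.tolist(),
        "velocity_unit": "mm/s",
    }
    if field.mask is not None:
        mask_name = f"{prefix}_mask.nii.gz"
        write_mask_nifti(field.mask, field.spacing, field.origin,
                         os.path.join(out_dir, mask_name))
        meta["mask"] = mask_name
    sidecar = os.path.join(out_dir, f"{prefix}_sidecar.json")
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=1)
    written["sidecar"] = sidecar
    return written


def write_scalar_nifti(sf: ScalarField3, path: str) -> str:
    nib.save(nib.Nifti1Image(sf.values, _affine(sf.spacing, sf.origin)), path)
    return path


def read_scalar_nifti(path: str, unit: str = "") -> ScalarField3:
    img = nib.load(path)
    vals = np.asanyarray(img.dataobj).astype(np.float64)
    spacing = tuple(float(abs(img.affine[i, i])) for i in range(3))
    origin = tuple(float(img.affine[i, 3]) for i in range(3))
    return ScalarField3(vals, spacing, origin, unit=unit)


def write_vector_nifti(vf: VectorField3, path: str) -> str:
    """Write a 3-component lattice as a single 4D NIfTI (last axis = component)."""
    data = np.stack(vf.components, axis=-1)
    nib.save(nib.Nifti1Image(data, _affine(vf.spacing, vf.origin)), path)
    return path


def write_mask_nifti(mask: np.ndarray, spacing, origin, path: str) -> str:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(spacing, origin)), path)
    return path


# ---------------------------------------------------------------------------
# lumen segmentation
# ---------------------------------------------------------------------------

def segment_lumen(
    field: VelocityField4D,
    magnitude: np.ndarray | None = None,
    threshold: float = 1.0,
) -> np.ndarray:
    """Threshold-based lumen segmentation on a velocity time series.

    Score per voxel = temporal mean speed ``mean_t |v|``, multiplied by the
    magnitude-image value when one is supplied.  Voxels with score >=
    ``threshold`` are kept and the largest 26-connected component is returned.

    Raises ``ValueError`` when no voxel clears the threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    speed = np.sqrt(field.vx**2 + field.vy**2 + field.vz**2).mean(axis=0)
    if magnitude is not None:
        magnitude = np.asarray(magnitude, dtype=np.float64)
        if magnitude.shape != field.spatial_shape:
            raise ValueError("magnitude image must match the spatial grid")
        speed = speed * magnitude
    raw = speed >= threshold
    if not raw.any():
        raise ValueError("empty mask: no voxel reaches the segmentation threshold")
    labels, n = ndimage.label(raw, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 1:
        return raw
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))
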