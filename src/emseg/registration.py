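"""Rigid / affine registration, resampling, repeat fusion, and the
deformable-backend plug-in contract.

Transforms map *fixed* physical coordinates (mm) to *moving* physical
coordinates (pull-back convention): resampling a moving image onto the fixed
grid evaluates the moving image at the transformed coordinates.  Rigid and
affine transforms are optimized multi-resolution with Powell's method on a
mean-squares (default) or mutual-information similarity.  Deformable
registration is an external plug-in only; when no plug-in is available the
caller is expected to fall back to affine.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage, optimize

from .image_io import Volume

logger = logging.getLogger("emseg")

__all__ = ["SpatialTransform", "RegistrationError", "DeformableUnavailableError",
           "register_rigid", "register_affine", "deformable_backend",
           "resample", "fuse_repeats"]


class RegistrationError(RuntimeError):
    pass


class DeformableUnavailableError(RuntimeError):
    """Raised when no deformable plug-in is configured or it fails."""


@dataclass
class SpatialTransform:
    """kind 'rigid' / 'affine': 4x4 homogeneous matrix in physical mm.
    kind 'displacement': per-voxel mm displacement (3, nx, ny, nz) defined on
    the fixed grid, added to fixed physical coordinates."""

    kind: str
    matrix: np.ndarray | None = None
    displacement: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind in ("rigid", "affine"):
            self.matrix = np.asarray(self.matrix, dtype=np.float64)
            if self.matrix.shape != (4, 4):
                raise ValueError("matrix transforms must be 4x4")
            if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
                raise ValueError("singular transform matrix")
            if self.kind == "rigid":
                R = self.matrix[:3, :3]
                if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
                    raise ValueError("rigid matrix is not orthonormal")
        elif self.kind == "displacement":
            self.displacement = np.asarray(self.displacement, dtype=np.float64)
            if self.displacement.ndim != 4 or self.displacement.shape[0] != 3:
                raise ValueError("displacement must be (3, nx, ny, nz)")
            if not np.isfinite(self.displacement).all():
                raise ValueError("non-finite displacement field")
        else:
            raise ValueError(f"unknown transform kind {self.kind!r}")

    @classmethod
    def identity(cls, kind: str = "rigid") -> "SpatialTransform":
        return cls(kind=kind, matrix=np.eye(4))

    def compose(self, other: "SpatialTransform") -> "SpatialTransform":
        """self ∘ other as a pull-back: apply ``other`` first when resampling."""
        if self.matrix is None or other.matrix is None:
            raise ValueError("only matrix transforms compose")
        mat = self.matrix @ other.matrix
        R = mat[:3, :3]
        kind = ("rigid" if self.kind == other.kind == "rigid"
                and np.allclose(R @ R.T, np.eye(3), atol=1e-6) else "affine")
        return SpatialTransform(kind=kind, matrix=mat)

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Map (3, ...) fixed physical coordinates to moving coordinates."""
        if self.kind == "displacement":
            if pts.shape != self.displacement.shape:
                raise ValueError("displacement grid does not match points")
            return pts + self.displacement
        flat = pts.reshape(3, -1)
        out = self.matrix[:3, :3] @ flat + self.matrix[:3, 3:4]
        return out.reshape(pts.shape)

    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3].copy()


def _phys_grid(shape, spacing, origin) -> np.ndarray:
    idx = np.indices(shape, dtype=np.float64)
    sp = np.asarray(spacing)[:, None, None, None]
    og = np.asarray(origin)[:, None, None, None]
    return og + idx * sp


def resample(vol: Volume, transform: SpatialTransform,
             shape=None, spacing=None, origin=None,
             interpolation: str = "linear") -> Volume:
    """Pull-back resampling of ``vol`` onto a target grid (default: its own).

    Out-of-domain voxels get 0.  ``interpolation`` is 'linear' for
    intensities and priors, 'nearest' for label maps.
    """
    shape = tuple(shape) if shape is not None else vol.shape
    spacing = tuple(spacing) if spacing is not None else vol.spacing
    origin = tuple(origin) if origin is not None else vol.origin
    pts = _phys_grid(shape, spacing, origin)
    moved = transform.apply_points(pts)
    sp = np.asarray(vol.spacing)[:, None, None, None]
    og = np.asarray(vol.origin)[:, None, None, None]
    voxel = (moved - og) / sp
    order = {"linear": 1, "nearest": 0}[interpolation]
    out = ndimage.map_coordinates(vol.data, voxel, order=order,
                                  mode="constant", cval=0.0)
    return Volume(out, spacing=spacing, origin=origin)


def resample_prior_stack(maps: np.ndarray, atlas_spacing, atlas_origin,
                         transform: SpatialTransform, shape, spacing, origin,
                         air_index: int = 0) -> np.ndarray:
    """Resample each class map, clip interpolation negatives, renormalize."""
    out = np.empty((maps.shape[0],) + tuple(shape))
    for k in range(maps.shape[0]):
        v = Volume(maps[k], spacing=atlas_spacing, origin=atlas_origin)
        out[k] = resample(v, transform, shape, spacing, origin).data
    np.clip(out, 0.0, None, out=out)
    total = out.sum(axis=0)
    degenerate = total == 0
    safe = np.where(degenerate, 1.0, total)
    out /= safe
    if degenerate.any():
        out[:, degenerate] = 0.0
        out[air_index, degenerate] = 1.0
    return out


# ---------------------------------------------------------------------------
# Similarity metrics (lower is better)


def _msq(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a - b) ** 2))


def _neg_mi(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    pxy = hist / hist.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    mi = float((pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])).sum())
    return -mi


_METRICS = {"msq": _msq, "mi": _neg_mi}


def _shrink(vol: Volume, factor: int) -> Volume:
    if factor == 1:
        return vol
    sm = ndimage.gaussian_filter(vol.data, sigma=factor / 2.0)
    data = sm[::factor, ::factor, ::factor]
    spacing = tuple(s * factor for s in vol.spacing)
    return Volume(data, spacing=spacing, origin=vol.origin)


def _euler_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation from per-axis angles in degrees (Rz @ Ry @ Rx)."""
    ax, ay, az = np.deg2rad([rx, ry, rz])
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _center(vol: Volume) -> np.ndarray:
    return (np.asarray(vol.origin)
            + (np.asarray(vol.shape) - 1) * np.asarray(vol.spacing) / 2.0)


def _matrix_about_center(R: np.ndarray, t: np.ndarray, c: np.ndarray) -> np.ndarray:
    mat = np.eye(4)
    mat[:3, :3] = R
    mat[:3, 3] = c - R @ c + t
    return mat


def _rigid_matrix(params: np.ndarray, center: np.ndarray) -> np.ndarray:
    t = params[:3]
    R = _euler_matrix(*params[3:6])
    return _matrix_about_center(R, t, center)


def _optimize(cost, x0: np.ndarray, maxiter: int = 60) -> np.ndarray:
    res = optimize.minimize(cost, x0, method="Powell",
                            options={"xtol": 1e-4, "ftol": 1e-8,
                                     "maxiter": maxiter})
    if not np.isfinite(res.fun):
        raise RegistrationError(f"optimizer diverged (metric {res.fun})")
    return np.asarray(res.x, dtype=np.float64)


def register_rigid(fixed: Volume, moving: Volume, metric: str = "msq",
                   levels=(4, 2, 1), seed: int = 0) -> SpatialTransform:
    """Multi-resolution rigid registration.

    Parameters are [tx, ty, tz] in mm and [rx, ry, rz] in degrees about the
    fixed-image center; deterministic given the inputs.
    """
    metric_fn = _METRICS[metric]
    center = _center(fixed)
    params = np.zeros(6)
    for level in levels:
        f = _shrink(fixed, level)
        m = _shrink(moving, level)

        def cost(p):
            tr = SpatialTransform(kind="rigid", matrix=_rigid_matrix(p, center))
            warped = resample(m, tr, f.shape, f.spacing, f.origin)
            return metric_fn(f.data, warped.data)

        params = _optimize(cost, params)
    logger.info("rigid registration: t=%s mm, r=%s deg",
                np.round(params[:3], 3), np.round(params[3:], 3))
    return SpatialTransform(kind="rigid", matrix=_rigid_matrix(params, center))


def register_affine(fixed: Volume, moving: Volume,
                    init: SpatialTransform | None = None, metric: str = "msq",
                    levels=(4, 2), seed: int = 0) -> SpatialTransform:
    """12-parameter affine refinement, initialized from a rigid transform.

    The matrix part is parametrized as a perturbation of the initial rotation
    (unit step = 1% of scale); translation steps are 1 mm.
    """
    metric_fn = _METRICS[metric]
    center = _center(fixed)
    if init is None:
        init = register_rigid(fixed, moving, metric=metric, seed=seed)
    R0 = init.matrix[:3, :3].copy()
    t0 = init.matrix[:3, 3] - (center - R0 @ center)
    params = np.zeros(12)
    for level in levels:
        f = _shrink(fixed, level)
        m = _shrink(moving, level)

        def cost(p):
            B = R0 + 0.01 * p[:9].reshape(3, 3)
            t = t0 + p[9:]
            mat = _matrix_about_center(B, t, center)
            if abs(np.linalg.det(B)) < 1e-6:
                return np.inf
            tr = SpatialTransform(kind="affine", matrix=mat)
            warped = resample(m, tr, f.shape, f.spacing, f.origin)
            return metric_fn(f.data, warped.data)

        params = _optimize(cost, params, maxiter=80)
    B = R0 + 0.01 * params[:9].reshape(3, 3)
    t = t0 + params[9:]
    return SpatialTransform(kind="affine",
                            matrix=_matrix_about_center(B, t, center))


def deformable_backend(fixed: Volume, moving: Volume, plugin=None
                       ) -> SpatialTransform:
    """Run an external deformable-registration plug-in.

    ``plugin`` is either a callable ``plugin(fixed_path, moving_path,
    out_field_path)`` or a shell command template with ``{fixed}``,
    ``{moving}`` and ``{out}`` placeholders.  The plug-in must write a 4-D
    NIfTI displacement field (nx, ny, nz, 3) in mm on the fixed grid.
    Raises :class:`DeformableUnavailableError` when no plug-in is configured
    (the pipeline then falls back to affine).
    """
    if plugin is None:
        raise DeformableUnavailableError("no deformable plug-in configured")
    from .image_io import write_volume

    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        f_path, m_path, o_path = tmp / "fixed.nii", tmp / "moving.nii", tmp / "field.nii"
        write_volume(fixed, f_path)
        write_volume(moving, m_path)
        try:
            if callable(plugin):
                plugin(str(f_path), str(m_path), str(o_path))
            else:
                cmd = str(plugin).format(fixed=f_path, moving=m_path, out=o_path)
                subprocess.run(cmd, shell=True, check=True)
        except Exception as exc:
            raise DeformableUnavailableError(f"plug-in failed: {exc}") from exc
        if not o_path.exists():
            raise DeformableUnavailableError("plug-in produced no output field")
        img = nib.load(str(o_path))
        field = np.asanyarray(img.dataobj).astype(np.float64)
    if field.ndim != 4 or field.shape[-1] != 3:
        raise DeformableUnavailableError(
            f"displacement field must be (nx, ny, nz, 3), got {field.shape}")
    if field.shape[:3] != fixed.shape:
        raise DeformableUnavailableError("displacement grid does not match fixed image")
    disp = np.moveaxis(field, -1, 0)
    return SpatialTransform(kind="displacement", displacement=disp)


def fuse_repeats(repeats: list[Volume]) -> Volume:
    """Voxel-wise arithmetic mean of co-registered repeats."""
    if not repeats:
        raise ValueError("need at least one repeat")
    ref = repeats[0]
    for r in repeats[1:]:
        if not ref.same_grid(r):
            raise ValueError("repeats must share one grid")
    data = np.mean([r.data for r in repeats], axis=0)
    return ref.like(data)
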