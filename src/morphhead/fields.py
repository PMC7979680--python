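"""Scalar volumes and dense displacement fields.

This module provides the algebra that links image registration to mesh
morphing: trilinear sampling at world coordinates, image warping by a
displacement field, field composition, and fixed-point field inversion.

Conventions
-----------
* World units are millimetres throughout. Voxel coordinates are 0-based
  with voxel centers at integer indices (NIfTI convention); the 4x4
  affine maps voxel indices to world mm.
* Displacement fields store world-mm vectors on a voxel grid and carry an
  explicit *convention* tag:

  - ``"resampling"`` (pull-back): ``out(x) = in(x + u(x))`` — used to warp
    images. Registration returns fields in this convention with
    fixed = subject, moving = baseline.
  - ``"forward"`` (push-forward): ``x' = x + u(x)`` — used to move mesh
    nodes. The numerical inverse of a resampling field is a forward field
    and vice versa.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "DomainError",
    "ConventionError",
    "ImageVolume",
    "VectorField",
    "RigidTransform",
    "sample_trilinear",
    "warp_image",
    "compose_fields",
    "invert_field",
    "jacobian_determinant",
    "load_image",
    "save_image",
    "load_field",
    "save_field",
]

RESAMPLING = "resampling"
FORWARD = "forward"
_CONVENTIONS = (RESAMPLING, FORWARD)


class DomainError(ValueError):
    """A world point falls outside the sampling domain beyond tolerance."""


class ConventionError(ValueError):
    """A displacement field was used under the wrong convention."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is not invertible")
    return affine


@dataclass
class ImageVolume:
    """A 3-D scalar grid with a voxel-to-world affine (mm).

    ``is_mask`` marks binary content; mask volumes must contain only {0, 1}.
    """

    data: np.ndarray
    affine: np.ndarray
    is_mask: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D data, got shape {self.data.shape}")
        self.affine = _check_affine(self.affine)
        if self.is_mask:
            vals = np.unique(self.data)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("mask volume contains values outside {0, 1}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_to_world(self, vox: np.ndarray) -> np.ndarray:
        vox = np.atleast_2d(np.asarray(vox, dtype=float))
        return vox @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, world: np.ndarray) -> np.ndarray:
        world = np.atleast_2d(np.asarray(world, dtype=float))
        inv = np.linalg.inv(self.affine)
        return world @ inv[:3, :3].T + inv[:3, 3]

    def grid_world_points(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (*shape, 3)."""
        idx = np.indices(self.shape, dtype=float)
        vox = np.stack([c.ravel() for c in idx], axis=1)
        return self.voxel_to_world(vox).reshape(*self.shape, 3)

    def same_grid(self, other: "ImageVolume | VectorField") -> bool:
        return self.shape == tuple(other.shape) and np.allclose(
            self.affine, other.affine, atol=1e-9
        )


@dataclass
class VectorField:
    """Dense displacement field: world-mm vectors on a voxel grid.

    ``data`` has shape (nx, ny, nz, 3); components are along world axes.
    """

    data: np.ndarray
    affine: np.ndarray
    convention: str = RESAMPLING

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError(
                f"expected (nx,ny,nz,3) displacement data, got {self.data.shape}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("displacement field contains non-finite values")
        self.affine = _check_affine(self.affine)
        if self.convention not in _CONVENTIONS:
            raise ConventionError(
                f"convention must be one of {_CONVENTIONS}, got {self.convention!r}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]

    voxel_to_world = ImageVolume.voxel_to_world
    world_to_voxel = ImageVolume.world_to_voxel
    grid_world_points = ImageVolume.grid_world_points
    same_grid = ImageVolume.same_grid

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def max_displacement_voxels(self) -> float:
        """Max |u| expressed in (mean) voxel units."""
        return float(np.abs(self.data).max() / self.voxel_size.mean())


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (mm)."""

    rotation: np.ndarray = dc_field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation is a reflection (det = -1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return points @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


# ---------------------------------------------------------------------------
# Sampling


def _voxel_coords_checked(
    vol: ImageVolume | VectorField, points: np.ndarray, tol_vox: float = 0.5
) -> np.ndarray:
    """World points -> clamped voxel coordinates; error beyond tol_vox outside."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.isfinite(points).all():
        raise ValueError("sample points contain non-finite values")
    vox = vol.world_to_voxel(points)
    upper = np.asarray(vol.shape, dtype=float) - 1.0
    below = vox < -tol_vox
    above = vox > upper + tol_vox
    bad = below.any(axis=1) | above.any(axis=1)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise DomainError(
            f"{int(bad.sum())} point(s) outside domain beyond {tol_vox} voxel; "
            f"first offending world point {points[i]} -> voxel {vox[i]} "
            f"(grid shape {vol.shape})"
        )
    return np.clip(vox, 0.0, upper)


def _interp_voxel(data: np.ndarray, vox: np.ndarray, order: int) -> np.ndarray:
    """Interpolate 3-D ``data`` at voxel coordinates (n,3)."""
    return ndimage.map_coordinates(
        np.asarray(data, dtype=float), vox.T, order=order, mode="nearest"
    )


def sample_trilinear(
    vol: ImageVolume | VectorField,
    points: np.ndarray,
    *,
    tol_vox: float = 0.5,
    order: int = 1,
) -> np.ndarray:
    """Trilinear sampling of a scalar volume or displacement field at world points.

    Points up to ``tol_vox`` voxels outside the grid are clamped to the
    boundary; farther points raise :class:`DomainError` (silent zero-fill
    would corrupt mesh morphing). Linear functions of position are
    reproduced exactly.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    vox = _voxel_coords_checked(vol, points, tol_vox)
    if isinstance(vol, VectorField):
        out = np.stack(
            [_interp_voxel(vol.data[..., c], vox, order) for c in range(3)], axis=1
        )
    else:
        out = _interp_voxel(vol.data, vox, order)
    return out


def warp_image(
    img: ImageVolume,
    u: VectorField,
    interp: str = "linear",
    *,
    cval: float = 0.0,
) -> ImageVolume:
    """Warp an image by a resampling field: ``out(x) = img(x + u(x))``.

    The output lives on the field's grid. Voxels whose pulled-back location
    leaves the image domain receive ``cval`` (background). ``interp`` is
    ``"linear"`` or ``"nearest"``; nearest preserves label sets and mask
    binarity.
    """
    if u.convention != RESAMPLING:
        raise ConventionError(
            "warp_image requires a resampling-convention field "
            f"(got {u.convention!r}); invert a forward field first"
        )
    if interp not in ("linear", "nearest"):
        raise ValueError(f"interp must be 'linear' or 'nearest', got {interp!r}")
    order = 1 if interp == "linear" else 0
    targets = u.grid_world_points().reshape(-1, 3) + u.data.reshape(-1, 3)
    vox = img.world_to_voxel(targets)
    out = ndimage.map_coordinates(
        np.asarray(img.data, dtype=float), vox.T, order=order,
        mode="constant", cval=cval,
    ).reshape(u.shape)
    if img.is_mask or (interp == "nearest" and img.data.dtype.kind in "iub"):
        out = out.astype(img.data.dtype)
    return ImageVolume(out, u.affine.copy(), is_mask=img.is_mask and interp == "nearest")


def compose_fields(
    u1: VectorField, u2: VectorField, mode: str = "compose", tol_vox: float = 0.5
) -> VectorField:
    """Combine two displacement fields on u1's grid.

    ``mode="compose"`` (default) is true composition
    ``u(x) = u1(x) + u2(x + u1(x))`` — warping by the result equals warping
    by u2 first and then u1 under the resampling convention.
    ``mode="sum"`` is the literal voxelwise sum ``u1(x) + u2(x)`` (the two
    fields "adding up"); it requires a common grid. ``tol_vox`` bounds how
    far the image of id+u1 may leave u2's grid before a DomainError
    (boundary voxels of registration fields routinely land fractionally
    outside and are clamped).
    """
    if u1.convention != u2.convention:
        raise ConventionError(
            f"cannot combine fields with conventions {u1.convention!r} and "
            f"{u2.convention!r}"
        )
    if mode == "sum":
        if not u1.same_grid(u2):
            raise ValueError("sum mode requires fields on the same grid")
        return VectorField(u1.data + u2.data, u1.affine.copy(), u1.convention)
    if mode != "compose":
        raise ValueError(f"mode must be 'compose' or 'sum', got {mode!r}")
    pts = u1.grid_world_points().reshape(-1, 3)
    moved = pts + u1.data.reshape(-1, 3)
    u2_at = sample_trilinear(u2, moved, tol_vox=tol_vox)
    total = u1.data + u2_at.reshape(u1.data.shape)
    return VectorField(total, u1.affine.copy(), u1.convention)


def invert_field(
    u: VectorField,
    tol: float | None = None,
    max_iter: int = 30,
) -> VectorField:
    """Numerically invert a diffeomorphic displacement field.

    Fixed-point iteration ``v_{k+1}(x) = -u(x + v_k(x))`` on u's grid; the
    returned ``v`` satisfies ``max |u(x + v(x)) + v(x)| <= tol`` (default
    0.01 voxel). The convention tag flips: the inverse of a resampling
    field is the forward map and vice versa.
    """
    if tol is None:
        tol = 0.01 * float(u.voxel_size.mean())
    pts = u.grid_world_points().reshape(-1, 3)
    v = np.zeros_like(u.data.reshape(-1, 3))
    residual = np.inf
    for _ in range(max_iter):
        u_at = sample_trilinear(u, pts + v, tol_vox=1e9)
        new_v = -u_at
        residual = float(np.abs(u_at + v).max())
        v = new_v
        if residual <= tol:
            break
    else:
        u_at = sample_trilinear(u, pts + v, tol_vox=1e9)
        residual = float(np.abs(u_at + v).max())
    if residual > tol:
        raise RuntimeError(
            f"field inversion did not converge: residual {residual:.4g} mm "
            f"> tol {tol:.4g} mm after {max_iter} iterations "
            "(is the field diffeomorphic?)"
        )
    flipped = FORWARD if u.convention == RESAMPLING else RESAMPLING
    return VectorField(v.reshape(u.data.shape), u.affine.copy(), flipped)


def jacobian_determinant(u: VectorField) -> np.ndarray:
    """det(∇(id + u)) at every voxel (world-space gradient, central differences).

    Positive everywhere on the interior iff the map id + u is locally
    orientation-preserving; returned array has the field's grid shape.
    """
    inv_dir = np.linalg.inv(u.affine[:3, :3])  # d(voxel)/d(world)
    # du_i/dx_j = sum_k du_i/dvox_k * dvox_k/dx_j
    grads = np.empty(u.shape + (3, 3))
    for i in range(3):
        gvox = np.stack(np.gradient(u.data[..., i]), axis=-1)  # d u_i / d vox
        grads[..., i, :] = gvox @ inv_dir
    jac = grads + np.eye(3)
    return np.linalg.det(jac)


# ---------------------------------------------------------------------------
# NIfTI I/O


def load_image(path: str | Path, is_mask: bool = False) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if is_mask:
        data = (data > 0.5).astype(np.uint8)
    return ImageVolume(data, img.affine, is_mask=is_mask)


def save_image(vol: ImageVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(vol.data), vol.affine), str(path))


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_field(field: VectorField, path: str | Path) -> None:
    """Vector field as 4-D NIfTI (3 world-mm components last) + JSON sidecar."""
    path = Path(path)
    nib.save(nib.Nifti1Image(field.data, field.affine), str(path))
    _sidecar_path(path).write_text(
        json.dumps({"convention": field.convention, "units": "mm",
                    "components": "world axes"}, indent=2)
    )


def load_field(path: str | Path, convention: str | None = None) -> VectorField:
    """Load a 4-D NIfTI displacement field; convention from the JSON sidecar
    unless given explicitly (imported external fields default to resampling
    with a warning)."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 5:  # ITK-style (x,y,z,1,3)
        data = data[:, :, :, 0, :]
    if convention is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            convention = json.loads(sidecar.read_text())["convention"]
        else:
            warnings.warn(
                f"no convention sidecar for {path.name}; assuming 'resampling'",
                stacklevel=2,
            )
            convention = RESAMPLING
    return VectorField(data, img.affine, convention)
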