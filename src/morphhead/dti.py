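"""Diffusion-tensor analysis: eigen-decomposition, fractional anisotropy,
deterministic streamline tractography, and voxel-to-element fiber mapping.

The fiber mapping assigns every finite element the FA and first principal
eigenvector of the diffusion tensor in the voxel nearest the element
centroid; the per-element unit direction is what the axonal-strain
projection ε_axon = vᵀ E v consumes (sign-ambiguous v is harmless there —
the projection is a quadratic form).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import nibabel as nib
import numpy as np

from .fields import ImageVolume, _check_affine
from .hexmesh import HexMesh

__all__ = [
    "TensorVolume",
    "ElementFiberMap",
    "FiberSet",
    "TrackingParams",
    "tensor_eigen",
    "fractional_anisotropy",
    "map_dti_to_elements",
    "track_streamlines",
    "load_tensor_volume",
    "save_tensor_volume",
]

#: storage order of the six unique tensor components
TENSOR_ORDER = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")
_I6 = {name: i for i, name in enumerate(TENSOR_ORDER)}


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensors, 6 components in TENSOR_ORDER."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 6:
            raise ValueError(
                f"expected (nx,ny,nz,6) tensor data, got {self.data.shape}"
            )
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]

    voxel_to_world = ImageVolume.voxel_to_world
    world_to_voxel = ImageVolume.world_to_voxel

    def matrices(self, flat6: np.ndarray | None = None) -> np.ndarray:
        """Expand 6-component storage to full symmetric 3×3 matrices."""
        d = self.data if flat6 is None else np.asarray(flat6, dtype=float)
        m = np.empty(d.shape[:-1] + (3, 3))
        m[..., 0, 0] = d[..., _I6["Dxx"]]
        m[..., 1, 1] = d[..., _I6["Dyy"]]
        m[..., 2, 2] = d[..., _I6["Dzz"]]
        m[..., 0, 1] = m[..., 1, 0] = d[..., _I6["Dxy"]]
        m[..., 0, 2] = m[..., 2, 0] = d[..., _I6["Dxz"]]
        m[..., 1, 2] = m[..., 2, 1] = d[..., _I6["Dyz"]]
        return m


@dataclass
class ElementFiberMap:
    """Per-element FA and unit fiber direction (the ⟨v1⟩ of each element)."""

    fa: np.ndarray
    v1: np.ndarray
    outside_count: int = 0

    def __post_init__(self) -> None:
        self.fa = np.asarray(self.fa, dtype=float)
        self.v1 = np.asarray(self.v1, dtype=float)
        if self.v1.shape != (len(self.fa), 3):
            raise ValueError("v1 must be (n_elements, 3)")
        if ((self.fa < -1e-12) | (self.fa > 1 + 1e-12)).any():
            raise ValueError("FA values outside [0, 1]")
        norms = np.linalg.norm(self.v1, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("fiber directions must be unit vectors")


@dataclass
class FiberSet:
    """Streamline tracts: world-mm polylines with seed ids and mean FA."""

    polylines: list[np.ndarray] = dc_field(default_factory=list)
    seed_ids: list[int] = dc_field(default_factory=list)
    mean_fa: list[float] = dc_field(default_factory=list)

    def __len__(self) -> int:
        return len(self.polylines)


@dataclass
class TrackingParams:
    """Deterministic streamline settings (standard DTI tractography defaults)."""

    step: float = 0.5  # mm
    fa_stop: float = 0.2
    angle_stop: float = 45.0  # degrees
    max_points: int = 2000  # per direction


def tensor_eigen(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of one symmetric 3×3 tensor.

    Returns eigenvalues in descending order and a right-handed orthonormal
    basis (columns v1, v2, v3); v1 and v2 signs are canonicalized so each
    vector's largest-magnitude component is nonnegative, v3 = v1 × v2.
    """
    D = np.asarray(D, dtype=float)
    if D.shape != (3, 3):
        raise ValueError(f"expected 3×3 tensor, got {D.shape}")
    if np.abs(D - D.T).max() > 1e-8:
        raise ValueError("tensor is not symmetric within 1e-8")
    w, v = np.linalg.eigh(0.5 * (D + D.T))
    w = w[::-1]
    v = v[:, ::-1]
    for k in range(2):
        j = int(np.argmax(np.abs(v[:, k])))
        if v[j, k] < 0:
            v[:, k] = -v[:, k]
    v[:, 2] = np.cross(v[:, 0], v[:, 1])
    return w, v


def fractional_anisotropy(lambdas: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) · ||λ − λ̄|| / ||λ||, clipped to [0, 1].

    0 for isotropic tensors, 1 in the rank-one limit; scale invariant.
    All-zero eigenvalue triples are defined as FA 0 (with a warning).
    Accepts a single (3,) triple or an (..., 3) stack.
    """
    lam = np.asarray(lambdas, dtype=float)
    scalar = lam.ndim == 1
    lam = np.atleast_2d(lam)
    if lam.shape[-1] != 3:
        raise ValueError("expected eigenvalue triples (..., 3)")
    norm = np.linalg.norm(lam, axis=-1)
    zero = norm == 0
    if zero.any():
        warnings.warn("all-zero eigenvalues: FA defined as 0", stacklevel=2)
    mean = lam.mean(axis=-1, keepdims=True)
    dev = np.linalg.norm(lam - mean, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * dev / norm
    fa = np.where(zero, 0.0, fa)
    fa = np.clip(fa, 0.0, 1.0)
    return float(fa[0]) if scalar else fa


def _clip_negative_eigenvalues(w: np.ndarray, counter: list[int]) -> np.ndarray:
    if (w < 0).any():
        counter[0] += 1
        w = np.maximum(w, 0.0)
    return w


def map_dti_to_elements(mesh: HexMesh, tensors: TensorVolume) -> ElementFiberMap:
    """Link each element to the diffusion tensor of the voxel nearest its
    centroid (world coordinates; ties resolve to the lowest linear index).

    Centroids outside the tensor volume get FA 0 and direction x̂ with a
    warning; negative eigenvalues are clipped at zero and counted.
    """
    cent = mesh.centroids()
    vox = tensors.world_to_voxel(cent)
    idx = np.ceil(vox - 0.5).astype(np.int64)
    shape = np.asarray(tensors.shape)
    outside = ((idx < 0) | (idx >= shape)).any(axis=1)
    idx_c = np.clip(idx, 0, shape - 1)

    fa = np.zeros(mesh.n_elements)
    v1 = np.tile([1.0, 0.0, 0.0], (mesh.n_elements, 1))
    neg = [0]
    # decompose each distinct voxel once
    lin = np.ravel_multi_index(tuple(idx_c.T), tensors.shape)
    uniq, inverse = np.unique(lin, return_inverse=True)
    fa_u = np.zeros(len(uniq))
    v1_u = np.tile([1.0, 0.0, 0.0], (len(uniq), 1))
    for k, flat in enumerate(uniq):
        i, j, l = np.unravel_index(flat, tensors.shape)
        D = tensors.matrices(tensors.data[i, j, l])
        w, v = tensor_eigen(D)
        w = _clip_negative_eigenvalues(w, neg)
        if w.max() > 0:
            fa_u[k] = fractional_anisotropy(w)
            v1_u[k] = v[:, 0]
    fa = fa_u[inverse]
    v1 = v1_u[inverse]
    fa[outside] = 0.0
    v1[outside] = (1.0, 0.0, 0.0)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} element centroid(s) outside tensor volume; "
            "assigned FA 0",
            stacklevel=2,
        )
    if neg[0]:
        warnings.warn(
            f"negative eigenvalues clipped in {neg[0]} voxel(s)", stacklevel=2
        )
    return ElementFiberMap(fa, v1, outside_count=int(outside.sum()))


def _tensor_at(tensors: TensorVolume, point: np.ndarray) -> np.ndarray | None:
    """Trilinearly interpolated 3×3 tensor at a world point; None outside."""
    vox = tensors.world_to_voxel(point)[0]
    hi = np.asarray(tensors.shape) - 1
    if (vox < 0).any() or (vox > hi).any():
        return None
    lo = np.floor(vox).astype(int)
    lo = np.minimum(lo, hi - (hi > 0))  # keep the +1 corner in range
    f = vox - lo
    c = tensors.data[lo[0] : lo[0] + 2, lo[1] : lo[1] + 2, lo[2] : lo[2] + 2]
    wx = np.array([1 - f[0], f[0]])[: c.shape[0]]
    wy = np.array([1 - f[1], f[1]])[: c.shape[1]]
    wz = np.array([1 - f[2], f[2]])[: c.shape[2]]
    flat6 = np.einsum("ijkc,i,j,k->c", c, wx, wy, wz)
    return tensors.matrices(flat6)


def _fa_v1_at(tensors: TensorVolume, point: np.ndarray):
    D = _tensor_at(tensors, point)
    if D is None:
        return None, None
    w, v = tensor_eigen(D)
    w = np.maximum(w, 0.0)
    if w.max() == 0:
        return 0.0, v[:, 0]
    return float(fractional_anisotropy(w)), v[:, 0]


def _track_one_direction(
    tensors: TensorVolume,
    seed: np.ndarray,
    initial_dir: np.ndarray,
    p: TrackingParams,
) -> list[np.ndarray]:
    pts: list[np.ndarray] = []
    x = seed.astype(float).copy()
    d_prev = initial_dir / np.linalg.norm(initial_dir)
    cos_stop = np.cos(np.deg2rad(p.angle_stop))
    for _ in range(p.max_points):
        fa, v1 = _fa_v1_at(tensors, x)
        if fa is None or fa < p.fa_stop:
            break
        d = v1 if np.dot(v1, d_prev) >= 0 else -v1  # sign continuity
        if np.dot(d, d_prev) < cos_stop:
            break
        x = x + p.step * d
        pts.append(x.copy())
        d_prev = d
    return pts


def track_streamlines(
    tensors: TensorVolume,
    seeds: np.ndarray,
    params: TrackingParams | None = None,
) -> FiberSet:
    """Deterministic streamline tractography along the first eigenvector.

    From each valid seed (inside the volume with FA ≥ fa_stop) the tract is
    integrated bidirectionally with Euler steps of ``params.step`` mm,
    keeping sign continuity of v1 between steps, and terminates on low FA,
    sharp turning (> angle_stop), domain exit, or the per-direction point
    budget.
    """
    p = params or TrackingParams()
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    fibers = FiberSet()
    for sid, seed in enumerate(seeds):
        fa, v1 = _fa_v1_at(tensors, seed)
        if fa is None or fa < p.fa_stop:
            continue
        fwd = _track_one_direction(tensors, seed, v1, p)
        bwd = _track_one_direction(tensors, seed, -v1, p)
        poly = np.array(bwd[::-1] + [seed] + fwd)
        if len(poly) < 2:
            continue
        fas = [_fa_v1_at(tensors, q)[0] or 0.0 for q in poly]
        fibers.polylines.append(poly)
        fibers.seed_ids.append(sid)
        fibers.mean_fa.append(float(np.mean(fas)))
    if not fibers.polylines:
        warnings.warn("no valid seeds: empty fiber set", stacklevel=2)
    return fibers


def load_tensor_volume(path) -> TensorVolume:
    """Tensor volume from 4-D NIfTI with 6 components in TENSOR_ORDER."""
    img = nib.load(str(path))
    return TensorVolume(np.asarray(img.dataobj, dtype=float), img.affine)


def save_tensor_volume(vol: TensorVolume, path) -> None:
    nib.save(nib.Nifti1Image(vol.data, vol.affine), str(path))
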