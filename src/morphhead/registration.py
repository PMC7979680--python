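"""Hierarchical deformable registration driving mesh personalization.

The pipeline mirrors a two-stage morphing workflow for subject-specific
head models: a 6-DOF rigid alignment of cranial masks, a diffeomorphic
demons registration of the binary cranial masks (stage 1, captures overall
cranial shape), image warping and skull stripping, a second dense
registration of the skull-stripped intensity images (stage 2, aligns inner
brain structures; an externally computed field can be imported here as a
drop-in), composition of the two fields, inversion, and morphing of the
baseline hexahedral mesh — followed by element-quality gating and DICE
scoring of the warped template against the subject.

Registration returns *resampling*-convention fields with fixed = subject
and moving = baseline; the mesh is moved by the numerical inverse (the
forward baseline→subject map), which keeps the warped template image and
the morphed mesh mutually consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .fields import (
    FORWARD,
    RESAMPLING,
    ImageVolume,
    RigidTransform,
    VectorField,
    compose_fields,
    invert_field,
    warp_image,
)
from .hexmesh import HexMesh, QualityReport, morph_mesh, quality_report
from .rating import dice

logger = logging.getLogger(__name__)

__all__ = [
    "DemonsSettings",
    "PersonalizeConfig",
    "PersonalizationResult",
    "RegistrationError",
    "rigid_register",
    "demons_register",
    "skull_strip",
    "personalize",
]


class RegistrationError(RuntimeError):
    """Registration failed to improve or inputs violate its contract."""


@dataclass
class DemonsSettings:
    """Diffeomorphic demons parameters.

    Multi-resolution pyramid ``pyramid_factors`` (downsampling per level,
    coarse to fine) with ``iters_per_level`` iterations each. Per
    iteration the demons force is capped at ``max_step`` voxels, smoothed
    with ``sigma_update`` (fluid-like), accumulated into a stationary
    velocity smoothed with ``sigma_field`` (diffusion-like), and the
    displacement is the velocity exponential via scaling-and-squaring with
    at least ``squaring_min`` squarings (more if max |v|/2^N >= 0.5 voxel).
    """

    pyramid_factors: tuple[int, ...] = (4, 2, 1)
    iters_per_level: tuple[int, ...] = (100, 50, 20)
    sigma_update: float = 1.0  # voxels
    sigma_field: float = 1.5  # voxels
    max_step: float = 2.0  # voxels
    squaring_min: int = 4
    stall_patience: int = 8  # iterations without SSD improvement before stopping a level

    def __post_init__(self) -> None:
        if len(self.pyramid_factors) != len(self.iters_per_level):
            raise ValueError("pyramid_factors and iters_per_level lengths differ")
        if min(self.sigma_update, self.sigma_field) <= 0:
            raise ValueError("smoothing sigmas must be positive")
        if self.max_step <= 0:
            raise ValueError("max_step must be positive")


# ---------------------------------------------------------------------------
# Rigid registration (centroid + principal axes, deterministic)


def _mask_moments(mask: ImageVolume) -> tuple[np.ndarray, np.ndarray]:
    idx = np.argwhere(np.asarray(mask.data) > 0.5)
    if len(idx) == 0:
        raise RegistrationError("empty mask")
    pts = mask.voxel_to_world(idx.astype(float))
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    return centroid, cov


def _principal_axes(cov: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(cov)
    v = v[:, ::-1]  # descending variance
    for k in range(3):  # canonical signs: largest-|component| nonnegative
        j = int(np.argmax(np.abs(v[:, k])))
        if v[j, k] < 0:
            v[:, k] = -v[:, k]
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return v


def _resample_mask_rigid(
    moving: ImageVolume, fixed: ImageVolume, transform: RigidTransform
) -> np.ndarray:
    """Nearest-neighbour pull-back of ``moving`` onto fixed's grid under the
    moving→fixed rigid map."""
    pts = fixed.grid_world_points().reshape(-1, 3)
    back = transform.inverse().apply(pts)
    vox = moving.world_to_voxel(back)
    vals = ndimage.map_coordinates(
        np.asarray(moving.data, dtype=float), vox.T, order=0,
        mode="constant", cval=0.0,
    )
    return vals.reshape(fixed.shape)


def rigid_register(
    fixed_mask: ImageVolume, moving_mask: ImageVolume
) -> RigidTransform:
    """6-DOF rigid alignment of two binary masks (moving → fixed, world mm).

    Centroids are matched exactly; the rotation aligns the masks' principal
    axes, testing the four proper axis-sign assignments and keeping the one
    with the highest mask overlap. Sign assignments whose overlap ties the
    best within 0.005 are disambiguated by preferring the smallest rotation
    angle — an ellipsoid-symmetric mask cannot distinguish a shape-preserving
    180° flip by overlap alone, and the least rotation is the physically
    sensible reading. Deterministic; for (near-)spherical masks the
    rotation is unconstrained by the data and the principal-axes choice is
    arbitrary, but the translation remains exact.
    """
    cf, covf = _mask_moments(fixed_mask)
    cm, covm = _mask_moments(moving_mask)
    vf = _principal_axes(covf)
    vm = _principal_axes(covm)
    candidates = []
    for signs in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
        rot = vf @ np.diag(signs) @ vm.T
        cand = RigidTransform(rot, cf - rot @ cm)
        resampled = _resample_mask_rigid(moving_mask, fixed_mask, cand)
        overlap = dice(fixed_mask.data, resampled)
        angle = float(np.arccos(np.clip((np.trace(rot) - 1.0) / 2.0, -1.0, 1.0)))
        candidates.append((overlap, angle, cand))
    best_overlap = max(c[0] for c in candidates)
    near = [c for c in candidates if c[0] >= best_overlap - 0.005]
    overlap, angle, best = min(near, key=lambda c: c[1])
    logger.info(
        "rigid_register: overlap DICE=%.4f rotation %.2f deg "
        "(%d near-tie candidates)", overlap, np.rad2deg(angle), len(near),
    )
    return best


# ---------------------------------------------------------------------------
# Diffeomorphic demons


def _warp_disp_voxel(img: np.ndarray, disp: np.ndarray, order: int = 1) -> np.ndarray:
    """Sample ``img`` at x + disp(x), everything in voxel coordinates."""
    idx = np.indices(img.shape, dtype=float)
    coords = idx + np.moveaxis(disp, -1, 0)
    return ndimage.map_coordinates(img, coords, order=order, mode="nearest")


def _compose_disp_voxel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(a ∘ b)(x) = b(x) + a(x + b(x)) for voxel-space displacement grids."""
    idx = np.indices(a.shape[:-1], dtype=float)
    coords = idx + np.moveaxis(b, -1, 0)
    out = np.empty_like(a)
    for c in range(3):
        out[..., c] = b[..., c] + ndimage.map_coordinates(
            a[..., c], coords, order=1, mode="nearest"
        )
    return out


def _exp_velocity(v: np.ndarray, squaring_min: int) -> np.ndarray:
    """Displacement field exp(v) by scaling and squaring (voxel units)."""
    vmax = float(np.abs(v).max())
    n = squaring_min
    if vmax > 0:
        n = max(n, int(np.ceil(np.log2(vmax / 0.5))) + 1)
    u = v / (2.0 ** n)
    for _ in range(n):
        u = _compose_disp_voxel(u, u)
    return u


def _ssd(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    return float(np.dot(d.ravel(), d.ravel()))


def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img
    sm = ndimage.gaussian_filter(img, sigma=factor / 2.0)
    return ndimage.zoom(sm, 1.0 / factor, order=1)


def _upsample_velocity(v: np.ndarray, target_shape: tuple[int, ...]) -> np.ndarray:
    ratios = [t / s for t, s in zip(target_shape, v.shape[:3])]
    out = np.empty(tuple(target_shape) + (3,))
    for c in range(3):
        comp = ndimage.zoom(v[..., c], ratios, order=1)
        # pad/trim rounding mismatches
        slices = tuple(slice(0, t) for t in target_shape)
        padded = np.zeros(target_shape)
        src = tuple(slice(0, min(a, b)) for a, b in zip(comp.shape, target_shape))
        padded[src] = comp[src]
        out[..., c] = padded[slices] * ratios[c]
    return out


def demons_register(
    fixed: ImageVolume,
    moving: ImageVolume,
    settings: DemonsSettings | None = None,
    return_diagnostics: bool = False,
):
    """Diffeomorphic demons registration on a common grid.

    Returns a resampling-convention field ``u`` on the fixed grid such that
    ``moving(x + u(x)) ≈ fixed(x)``. The displacement is the exponential of
    a smoothed stationary velocity, so det(∇(id+u)) stays positive. The
    per-level SSD trace is logged; the best (lowest-SSD) field of each
    level is kept, so the similarity never increases across levels. A final
    field worse than the identity raises :class:`RegistrationError`.
    """
    s = settings or DemonsSettings()
    if fixed.shape != moving.shape or not np.allclose(
        fixed.affine, moving.affine, atol=1e-6
    ):
        raise RegistrationError("fixed and moving grids differ; rigid-align first")
    f_full = np.asarray(fixed.data, dtype=float)
    m_full = np.asarray(moving.data, dtype=float)

    v: np.ndarray | None = None
    ssd_trace: list[list[float]] = []
    for factor, iters in zip(s.pyramid_factors, s.iters_per_level):
        f = _downsample(f_full, factor)
        m = _downsample(m_full, factor)
        if v is None:
            v = np.zeros(f.shape + (3,))
        elif v.shape[:3] != f.shape:
            v = _upsample_velocity(v, f.shape)
        grad_f = np.stack(np.gradient(f), axis=-1)
        grad_sq = (grad_f ** 2).sum(axis=-1)

        u = _exp_velocity(v, s.squaring_min)
        best_ssd = _ssd(_warp_disp_voxel(m, u), f)
        level_trace = [best_ssd]
        best_v = v.copy()
        stall = 0
        for _ in range(iters):
            warped = _warp_disp_voxel(m, u)
            diff = warped - f
            denom = grad_sq + diff ** 2
            with np.errstate(invalid="ignore", divide="ignore"):
                step = -diff[..., None] * grad_f / denom[..., None]
            step[denom[..., None].repeat(3, axis=-1) < 1e-12] = 0.0
            norm = np.linalg.norm(step, axis=-1, keepdims=True)
            over = norm > s.max_step
            step = np.where(over, step * (s.max_step / np.maximum(norm, 1e-12)), step)
            step = ndimage.gaussian_filter(step, sigma=(s.sigma_update,) * 3 + (0,))
            v = v + step
            v = ndimage.gaussian_filter(v, sigma=(s.sigma_field,) * 3 + (0,))
            u = _exp_velocity(v, s.squaring_min)
            cur = _ssd(_warp_disp_voxel(m, u), f)
            level_trace.append(cur)
            if cur < best_ssd:
                best_ssd = cur
                best_v = v.copy()
                stall = 0
            else:
                stall += 1
                if stall >= s.stall_patience:
                    break
        v = best_v
        ssd_trace.append(level_trace)
        logger.info(
            "demons level /%d: SSD %.6g -> %.6g (%d iters)",
            factor, level_trace[0], best_ssd, len(level_trace) - 1,
        )

    assert v is not None
    if v.shape[:3] != f_full.shape:  # pyramid may stop above full resolution
        v = _upsample_velocity(v, f_full.shape)
    u_vox = _exp_velocity(v, s.squaring_min)
    final_ssd = _ssd(_warp_disp_voxel(m_full, u_vox), f_full)
    initial_ssd = _ssd(m_full, f_full)
    if final_ssd > initial_ssd:
        raise RegistrationError(
            f"demons diverged: final SSD {final_ssd:.6g} > initial {initial_ssd:.6g}; "
            f"per-level trace {[t[-1] for t in ssd_trace]}"
        )
    u_world = u_vox @ fixed.affine[:3, :3].T
    field = VectorField(u_world, fixed.affine.copy(), RESAMPLING)
    if return_diagnostics:
        return field, {"ssd_per_level": ssd_trace, "initial_ssd": initial_ssd,
                       "final_ssd": final_ssd}
    return field


def skull_strip(t1: ImageVolume, brain_mask: ImageVolume) -> ImageVolume:
    """Voxelwise product of an intensity image and its brain mask."""
    if not t1.same_grid(brain_mask):
        raise ValueError("image and brain mask live on different grids")
    return ImageVolume(
        np.asarray(t1.data, dtype=float) * (np.asarray(brain_mask.data) > 0.5),
        t1.affine.copy(),
    )


# ---------------------------------------------------------------------------
# Personalization pipeline


@dataclass
class PersonalizeConfig:
    """Pipeline configuration; stage2_field substitutes an imported dense
    field (e.g. from an external attribute-matching registration) for the
    built-in stage-2 intensity demons."""

    stage1: DemonsSettings = dc_field(default_factory=DemonsSettings)
    stage2: DemonsSettings = dc_field(default_factory=DemonsSettings)
    compose_mode: str = "compose"  # "compose" | "sum"
    stage2_field: VectorField | None = None
    quality_floor: float = 0.2


@dataclass
class PersonalizationResult:
    rigid: RigidTransform
    field1: VectorField
    field2: VectorField
    field_total: VectorField
    forward_total: VectorField
    warped_t1: ImageVolume
    morphed_mesh: HexMesh
    quality: QualityReport
    dice_table: dict[str, float]


def _resample_rigid(
    img: ImageVolume, grid: ImageVolume, transform: RigidTransform, order: int
) -> ImageVolume:
    """Pull ``img`` onto ``grid`` under the moving→fixed rigid transform."""
    pts = grid.grid_world_points().reshape(-1, 3)
    vox = img.world_to_voxel(transform.inverse().apply(pts))
    vals = ndimage.map_coordinates(
        np.asarray(img.data, dtype=float), vox.T, order=order,
        mode="constant", cval=0.0,
    ).reshape(grid.shape)
    if img.is_mask:
        vals = vals.astype(np.uint8)
    return ImageVolume(vals, grid.affine.copy(), is_mask=img.is_mask and order == 0)


def personalize(
    baseline: dict,
    subject: dict,
    cfg: PersonalizeConfig | None = None,
) -> PersonalizationResult:
    """Run the full hierarchical personalization pipeline.

    ``baseline`` needs keys ``t1``, ``cranial_mask``, ``brain_mask``,
    ``mesh`` (and optionally ``labels``); ``subject`` needs ``t1``,
    ``cranial_mask``, ``brain_mask`` (optionally ``labels``). Steps: rigid
    mask alignment → stage-1 demons on cranial masks (field #1) → warp the
    aligned baseline T1 → skull strip both → stage-2 demons on the stripped
    intensity images, or an imported field (field #2) → compose → invert →
    morph the mesh → quality gate → DICE table. A failed quality gate is
    reported in the result (``quality.passed``), not raised.
    """
    cfg = cfg or PersonalizeConfig()
    mesh: HexMesh = baseline["mesh"]
    subj_cran: ImageVolume = subject["cranial_mask"]

    rigid = rigid_register(subj_cran, baseline["cranial_mask"])

    aligned_t1 = _resample_rigid(baseline["t1"], subj_cran, rigid, order=1)
    aligned_cran = _resample_rigid(baseline["cranial_mask"], subj_cran, rigid, order=0)
    aligned_brain = _resample_rigid(baseline["brain_mask"], subj_cran, rigid, order=0)

    field1 = demons_register(subj_cran, aligned_cran, cfg.stage1)

    t1_after1 = warp_image(aligned_t1, field1, interp="linear")
    brain_after1 = warp_image(aligned_brain, field1, interp="nearest")

    stripped_baseline = skull_strip(t1_after1, brain_after1)
    stripped_subject = skull_strip(subject["t1"], subject["brain_mask"])

    if cfg.stage2_field is not None:
        field2 = cfg.stage2_field
        if field2.convention != RESAMPLING:
            raise ValueError("imported stage-2 field must be resampling-convention")
    else:
        field2 = demons_register(stripped_subject, stripped_baseline, cfg.stage2)

    # warping by field1 then field2 == warping once by compose(field2, field1)
    field_total = compose_fields(field2, field1, mode=cfg.compose_mode, tol_vox=3.0)
    forward_total = invert_field(field_total)
    assert forward_total.convention == FORWARD

    aligned_mesh = HexMesh(
        rigid.apply(mesh.nodes), mesh.elements.copy(), mesh.part_id.copy()
    )
    morphed = morph_mesh(aligned_mesh, forward_total)
    quality = quality_report(morphed, floor=cfg.quality_floor)
    if not quality.passed:
        logger.warning(
            "quality gate failed: frac(J>=0.5)=%.3f min=%.3f",
            quality.frac_ge_050, quality.min_jacobian,
        )

    warped_t1 = warp_image(aligned_t1, field_total, interp="linear")

    dice_table: dict[str, float] = {}
    warped_cran = warp_image(aligned_cran, field_total, interp="nearest")
    dice_table["cranial_mask"] = dice(subj_cran.data, warped_cran.data)
    warped_brain = warp_image(aligned_brain, field_total, interp="nearest")
    dice_table["brain_mask"] = dice(subject["brain_mask"].data, warped_brain.data)
    if "labels" in baseline and "labels" in subject:
        aligned_labels = _resample_rigid(baseline["labels"], subj_cran, rigid, order=0)
        warped_labels = warp_image(aligned_labels, field_total, interp="nearest")
        subj_labels = subject["labels"]
        for code in np.unique(np.asarray(subj_labels.data)):
            code = int(code)
            if code == 0:
                continue
            dice_table[f"region_{code}"] = dice(
                np.asarray(subj_labels.data) == code,
                np.asarray(warped_labels.data) == code,
            )

    return PersonalizationResult(
        rigid=rigid,
        field1=field1,
        field2=field2,
        field_total=field_total,
        forward_total=forward_total,
        warped_t1=warped_t1,
        morphed_mesh=morphed,
        quality=quality,
        dice_table=dice_table,
    )
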