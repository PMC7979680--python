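"""Hexahedral mesh model: morphing, scaled-Jacobian quality, region labeling.

Meshes are node/element arrays in VTK hexahedron corner ordering (bottom
face 0-1-2-3 counterclockwise, top face 4-5-6-7 above). Personalization
moves nodes with a forward displacement field while connectivity and part
ids stay untouched; the scaled Jacobian gates whether the morphed mesh is
usable for explicit dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .fields import FORWARD, ConventionError, ImageVolume, VectorField, sample_trilinear

__all__ = [
    "HexMesh",
    "QualityReport",
    "Region",
    "RegionLabels",
    "scaled_jacobian",
    "scaled_jacobians",
    "quality_report",
    "morph_mesh",
    "label_elements_by_image",
]


class Region(IntEnum):
    """Brain region codes used for element labeling and strain reporting."""

    BACKGROUND = 0
    CEREBRAL_GM = 1
    CEREBRAL_WM = 2
    CORPUS_CALLOSUM = 3
    BRAIN_STEM = 4
    HIPPOCAMPUS = 5
    THALAMUS = 6
    CEREBELLUM = 7
    VENTRICLES = 8


#: Regions anisotropic enough that axonal strain is evaluated there
#: (deep gray matter — thalamus, hippocampus — is excluded).
ANISOTROPIC_REGIONS = frozenset(
    {Region.CEREBRAL_WM, Region.CORPUS_CALLOSUM, Region.BRAIN_STEM}
)


@dataclass
class HexMesh:
    """Nodes (N×3 world mm) + 8-node elements (M×8) + per-element part id."""

    nodes: np.ndarray
    elements: np.ndarray
    part_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError(f"nodes must be N×3, got {self.nodes.shape}")
        if self.elements.ndim != 2 or self.elements.shape[1] != 8:
            raise ValueError(f"elements must be M×8, got {self.elements.shape}")
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= len(self.nodes)
        ):
            raise ValueError("element connectivity references out-of-range nodes")
        if (np.sort(self.elements, axis=1)[:, 1:] == np.sort(self.elements, axis=1)[:, :-1]).any():
            raise ValueError("degenerate element: repeated node index")
        if self.part_id is None:
            self.part_id = np.zeros(len(self.elements), dtype=np.int64)
        else:
            self.part_id = np.asarray(self.part_id, dtype=np.int64)
            if self.part_id.shape != (len(self.elements),):
                raise ValueError("part_id must have one entry per element")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_corners(self) -> np.ndarray:
        """Corner coordinates per element, shape (M, 8, 3)."""
        return self.nodes[self.elements]

    def centroids(self) -> np.ndarray:
        return self.element_corners().mean(axis=1)


@dataclass
class QualityReport:
    """Element-quality summary with the 95%-over-0.5 / min-over-floor gate."""

    min_jacobian: float
    frac_ge_050: float
    frac_ge_045: float
    passed: bool
    floor: float = 0.2
    per_element: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "min_jacobian": self.min_jacobian,
            "frac_ge_050": self.frac_ge_050,
            "frac_ge_045": self.frac_ge_045,
            "pass": self.passed,
            "floor": self.floor,
        }


@dataclass
class RegionLabels:
    """Element → region code, with a count of centroids that fell outside
    the label volume (those become background)."""

    codes: np.ndarray
    outside_count: int = 0

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)

    def elements_in(self, region: int) -> np.ndarray:
        return np.flatnonzero(self.codes == int(region))

    def present_regions(self) -> list[int]:
        return [int(r) for r in np.unique(self.codes)]


# Corner triads: for each of the 8 VTK corners, the three edge-connected
# neighbours ordered so the triad is right-handed on a reference cube.
_CORNER_NEIGHBOURS = np.array(
    [
        [1, 3, 4],
        [2, 0, 5],
        [3, 1, 6],
        [0, 2, 7],
        [7, 5, 0],
        [4, 6, 1],
        [5, 7, 2],
        [6, 4, 3],
    ]
)


def scaled_jacobians(corners: np.ndarray) -> np.ndarray:
    """Scaled Jacobian of each hexahedron in a (M, 8, 3) corner array.

    At every corner the three emanating edges form a triad; the corner
    quality is det[e1 e2 e3] / (|e1||e2||e3|) and the element value is the
    minimum over its 8 corners. The result lies in [-1, 1]: 1 for a
    rectangular box, negative where a corner is inverted. Invariant to
    rigid motion and uniform scaling.
    """
    corners = np.asarray(corners, dtype=float)
    squeeze = corners.ndim == 2
    if squeeze:
        corners = corners[None]
    if corners.shape[1:] != (8, 3):
        raise ValueError(f"expected (M, 8, 3) corners, got {corners.shape}")
    # edges[m, c, k, :] = corner neighbour k - corner c
    edges = corners[:, _CORNER_NEIGHBOURS, :] - corners[:, :, None, :]
    norms = np.linalg.norm(edges, axis=-1)
    if (norms < 1e-14).any():
        bad = np.argwhere(norms < 1e-14)[0]
        raise ValueError(
            f"zero-length edge at element {bad[0]}, corner {bad[1]}"
        )
    dets = np.linalg.det(edges)
    vals = (dets / norms.prod(axis=-1)).min(axis=-1)
    return vals[0] if squeeze else vals


def scaled_jacobian(corners: np.ndarray) -> float:
    """Scaled Jacobian of one hexahedron (8×3 corners, VTK order)."""
    return float(scaled_jacobians(np.asarray(corners)))


def quality_report(
    mesh: HexMesh, floor: float = 0.2, keep_per_element: bool = True
) -> QualityReport:
    """Per-element scaled Jacobians and the pass/fail gate.

    The gate passes when at least 95% of elements have a scaled Jacobian
    of 0.5 or more AND the minimum is at or above ``floor``. Fractions are
    exact integer counts over the element total.
    """
    sj = scaled_jacobians(mesh.element_corners())
    m = len(sj)
    frac_050 = float(np.count_nonzero(sj >= 0.5)) / m
    frac_045 = float(np.count_nonzero(sj >= 0.45)) / m
    min_j = float(sj.min())
    passed = frac_050 >= 0.95 and min_j >= floor
    return QualityReport(
        min_jacobian=min_j,
        frac_ge_050=frac_050,
        frac_ge_045=frac_045,
        passed=passed,
        floor=floor,
        per_element=sj if keep_per_element else None,
    )


def morph_mesh(mesh: HexMesh, forward_field: VectorField) -> HexMesh:
    """Move nodes by a forward field (x' = x + u(x)); connectivity unchanged.

    Nodes outside the field domain raise a DomainError listing them; mesh
    morphing must never silently extrapolate.
    """
    if forward_field.convention != FORWARD:
        raise ConventionError(
            "morph_mesh requires a forward-convention field "
            f"(got {forward_field.convention!r}); invert a resampling field first"
        )
    u = sample_trilinear(forward_field, mesh.nodes)
    return HexMesh(mesh.nodes + u, mesh.elements.copy(), mesh.part_id.copy())


def label_elements_by_image(mesh: HexMesh, labels: ImageVolume) -> RegionLabels:
    """Assign each element the region label of the voxel nearest its centroid.

    Ties at exact half-voxel offsets resolve to the lowest linear index
    (round toward smaller indices). Centroids outside the volume map to
    background and are counted.
    """
    if not np.issubdtype(np.asarray(labels.data).dtype, np.integer):
        if not np.allclose(labels.data, np.round(labels.data)):
            raise ValueError("label volume must be integer-valued")
    cent = mesh.centroids()
    vox = labels.world_to_voxel(cent)
    idx = np.ceil(vox - 0.5).astype(np.int64)  # nearest, ties toward lower index
    shape = np.asarray(labels.shape)
    outside = ((idx < 0) | (idx >= shape)).any(axis=1)
    idx_c = np.clip(idx, 0, shape - 1)
    codes = np.asarray(labels.data)[idx_c[:, 0], idx_c[:, 1], idx_c[:, 2]].astype(
        np.int64
    )
    codes[outside] = int(Region.BACKGROUND)
    n_out = int(outside.sum())
    if n_out:
        warnings.warn(
            f"{n_out} element centroid(s) outside the label volume -> background",
            stacklevel=2,
        )
    return RegionLabels(codes, outside_count=n_out)
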