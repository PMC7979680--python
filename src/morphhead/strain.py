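"""Green–Lagrange strain from nodal motion, principal/axonal strain, and
regional peak extraction.

Strain is computed at each hexahedron's centroid from trilinear shape
functions: F = I + ∂u/∂X, E = ½(FᵀF − I). E is objective (exactly zero
under rigid motion) and exact for affine motions. The axonal strain of an
element is the projection of E onto its fiber direction, ε_axon = vᵀ E v,
a quadratic form bounded by the extreme principal strains.

Storage order of the six unique components is Exx, Eyy, Ezz, Exy, Eyz, Ezx
with *tensor* shear (Exy = γ/2, not engineering shear).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .dti import ElementFiberMap
from .hexmesh import ANISOTROPIC_REGIONS, HexMesh, Region, RegionLabels

__all__ = [
    "NodalHistory",
    "StrainHistory",
    "PeakRecord",
    "PeakTable",
    "STRAIN_ORDER",
    "element_strain_history",
    "principal_strain",
    "axonal_strain",
    "regional_peaks",
    "save_nodal_history",
    "load_nodal_history",
    "save_strain_history",
    "load_strain_history",
]

STRAIN_ORDER = ("Exx", "Eyy", "Ezz", "Exy", "Eyz", "Ezx")


@dataclass
class NodalHistory:
    """Nodal displacement time histories: times (ms, strictly increasing),
    displacements (T, N, 3) in mm; frame 0 is the reference configuration."""

    times: np.ndarray
    displacements: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=float)
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if self.displacements.ndim != 3 or self.displacements.shape[-1] != 3:
            raise ValueError("displacements must be (T, N, 3)")
        if len(self.times) != len(self.displacements):
            raise ValueError("times and displacements disagree on frame count")
        if np.abs(self.displacements[0]).max() > 1e-12:
            raise ValueError("first frame must be the zero reference configuration")


@dataclass
class StrainHistory:
    """Per-element symmetric Green–Lagrange tensors per time step.

    ``tensors`` has shape (T, M, 6) in STRAIN_ORDER (tensor shear)."""

    times: np.ndarray
    tensors: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 3 or self.tensors.shape[-1] != 6:
            raise ValueError("tensors must be (T, M, 6)")
        if len(self.times) != len(self.tensors):
            raise ValueError("times and tensors disagree on frame count")

    @property
    def n_elements(self) -> int:
        return self.tensors.shape[1]

    def matrices(self, frame: int | None = None) -> np.ndarray:
        """Full symmetric 3×3 matrices, (M,3,3) for one frame or (T,M,3,3)."""
        t = self.tensors if frame is None else self.tensors[frame]
        return _to_matrices(t)


def _to_matrices(flat6: np.ndarray) -> np.ndarray:
    flat6 = np.asarray(flat6, dtype=float)
    m = np.empty(flat6.shape[:-1] + (3, 3))
    m[..., 0, 0] = flat6[..., 0]
    m[..., 1, 1] = flat6[..., 1]
    m[..., 2, 2] = flat6[..., 2]
    m[..., 0, 1] = m[..., 1, 0] = flat6[..., 3]
    m[..., 1, 2] = m[..., 2, 1] = flat6[..., 4]
    m[..., 0, 2] = m[..., 2, 0] = flat6[..., 5]
    return m


def _to_flat6(mat: np.ndarray) -> np.ndarray:
    return np.stack(
        [
            mat[..., 0, 0],
            mat[..., 1, 1],
            mat[..., 2, 2],
            mat[..., 0, 1],
            mat[..., 1, 2],
            mat[..., 0, 2],
        ],
        axis=-1,
    )


# Natural-coordinate gradients of the 8 trilinear shape functions at the
# element centroid (ξ=η=ζ=0), VTK corner ordering; rows are dN_i/d(ξ,η,ζ).
_DN_CENTROID = 0.125 * np.array(
    [
        [-1, -1, -1],
        [+1, -1, -1],
        [+1, +1, -1],
        [-1, +1, -1],
        [-1, -1, +1],
        [+1, -1, +1],
        [+1, +1, +1],
        [-1, +1, +1],
    ],
    dtype=float,
)


def element_strain_history(mesh: HexMesh, motion: NodalHistory) -> StrainHistory:
    """Green–Lagrange strain tensor per element and time from nodal motion.

    The deformation gradient is evaluated at each element centroid via the
    trilinear shape-function gradients of the reference configuration:
    F = I + (Σᵢ uᵢ ⊗ dNᵢ/dξ) (Σᵢ Xᵢ ⊗ dNᵢ/dξ)⁻¹, E = ½(FᵀF − I).
    Exact for affine motions; identically zero for rigid ones.
    """
    if motion.displacements.shape[1] < mesh.n_nodes:
        raise ValueError(
            f"motion covers {motion.displacements.shape[1]} nodes, "
            f"mesh has {mesh.n_nodes}"
        )
    X = mesh.element_corners()  # (M, 8, 3)
    # reference Jacobian dX/dξ per element: (M, 3, 3)
    jac_ref = np.einsum("mka,kb->mab", X, _DN_CENTROID)
    dets = np.linalg.det(jac_ref)
    if (np.abs(dets) < 1e-14).any():
        bad = int(np.flatnonzero(np.abs(dets) < 1e-14)[0])
        raise ValueError(f"singular reference element {bad}")
    jac_inv = np.linalg.inv(jac_ref)

    T = len(motion.times)
    out = np.zeros((T, mesh.n_elements, 6))
    eye = np.eye(3)
    for t in range(T):
        u = motion.displacements[t][mesh.elements]  # (M, 8, 3)
        du_dxi = np.einsum("mka,kb->mab", u, _DN_CENTROID)
        F = eye + du_dxi @ jac_inv
        E = 0.5 * (np.swapaxes(F, -1, -2) @ F - eye)
        out[t] = _to_flat6(E)
    return StrainHistory(motion.times.copy(), out)


def principal_strain(E: np.ndarray) -> np.ndarray:
    """First (largest) principal value of symmetric strain tensor(s).

    Accepts a single 3×3 tensor, a (...,3,3) stack, or 6-component
    (...,6) storage in STRAIN_ORDER.
    """
    E = np.asarray(E, dtype=float)
    if E.shape[-1] == 6 and (E.ndim == 1 or E.shape[-2:] != (3, 3)):
        E = _to_matrices(E)
    scalar = E.ndim == 2
    vals = np.linalg.eigvalsh(E)[..., -1]
    return float(vals) if scalar else vals


def axonal_strain(E: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Strain along the fiber direction: ε_axon = vᵀ E v.

    ``v`` must be unit length within 1e-6 (no silent normalization). The
    result is invariant to v → −v and bounded by the extreme principal
    strains (Rayleigh quotient).
    """
    E = np.asarray(E, dtype=float)
    if E.shape[-1] == 6 and (E.ndim == 1 or E.shape[-2:] != (3, 3)):
        E = _to_matrices(E)
    v = np.asarray(v, dtype=float)
    norms = np.linalg.norm(v, axis=-1)
    if np.abs(norms - 1.0).max() > 1e-6:
        raise ValueError(
            f"fiber direction must be unit length within 1e-6 "
            f"(max deviation {np.abs(norms - 1.0).max():.3g})"
        )
    out = np.einsum("...i,...ij,...j->...", v, E, v)
    return float(out) if out.ndim == 0 else out


@dataclass
class PeakRecord:
    """One region × metric peak: value, where, and when."""

    region: int
    metric: str  # "MPS" | "MAS"
    value: float
    element: int  # global element id at the peak (per-element-peak reading)
    time_ms: float
    percentile: float = 100.0
    # peak of the regional envelope max-over-elements; same value, possibly
    # different element bookkeeping (both localizations reported)
    envelope_element: int | None = None
    envelope_time_ms: float | None = None


@dataclass
class PeakTable:
    """Regional MPS/MAS peaks with element/time localization."""

    records: list[PeakRecord] = dc_field(default_factory=list)

    def get(self, region: int, metric: str) -> PeakRecord:
        for r in self.records:
            if r.region == int(region) and r.metric == metric:
                return r
        raise KeyError(f"no {metric} record for region {int(region)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps([vars(r) for r in self.records], indent=2))


def _nearest_rank(values: np.ndarray, percentile: float) -> int:
    """Index (into ascending order) of the nearest-rank percentile."""
    n = len(values)
    rank = int(np.ceil(percentile / 100.0 * n))
    return max(rank, 1) - 1


def regional_peaks(
    strains: StrainHistory,
    labels: RegionLabels,
    fibers: ElementFiberMap | None = None,
    percentile: float = 100.0,
    anisotropic_regions: frozenset = ANISOTROPIC_REGIONS,
) -> PeakTable:
    """Regional peak principal (MPS) and axonal (MAS) strain.

    For each labeled region the per-element peak-over-time principal strain
    is reduced to the stated percentile (nearest-rank; 100 = maximum),
    reporting the element and time of that peak. MAS is computed the same
    way from ε_axon, restricted to regions flagged anisotropic (by default
    cerebral WM, corpus callosum, brain stem — axonal strain is not
    evaluated for deep gray matter). The envelope localization (arg of the
    per-time regional maximum at its global peak) is also recorded.
    """
    if labels.codes.shape[0] != strains.n_elements:
        raise ValueError("labels and strain history disagree on element count")
    if fibers is not None and len(fibers.fa) != strains.n_elements:
        raise ValueError("fiber map and strain history disagree on element count")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")

    mats = strains.matrices()  # (T, M, 3, 3)
    mps_tm = np.linalg.eigvalsh(mats)[..., -1]  # (T, M)
    metrics: dict[str, np.ndarray] = {"MPS": mps_tm}
    if fibers is not None:
        mas_tm = np.einsum("mi,tmij,mj->tm", fibers.v1, mats, fibers.v1)
        metrics["MAS"] = mas_tm

    table = PeakTable()
    for region in sorted(set(labels.present_regions()) - {int(Region.BACKGROUND)}):
        els = labels.elements_in(region)
        if els.size == 0:
            warnings.warn(f"region {region} empty: omitted", stacklevel=2)
            continue
        for metric, tm in metrics.items():
            if metric == "MAS" and region not in {int(r) for r in anisotropic_regions}:
                continue
            sub = tm[:, els]  # (T, n_region)
            per_el_peak = sub.max(axis=0)
            per_el_argt = sub.argmax(axis=0)
            order = np.argsort(per_el_peak, kind="stable")
            pick = order[_nearest_rank(per_el_peak, percentile)]
            value = float(per_el_peak[pick])
            element = int(els[pick])
            time_ms = float(strains.times[per_el_argt[pick]])
            # envelope localization (identical value at percentile 100)
            env = sub.max(axis=1)
            t_env = int(env.argmax())
            e_env = int(els[sub[t_env].argmax()])
            table.records.append(
                PeakRecord(
                    region=int(region),
                    metric=metric,
                    value=value,
                    element=element,
                    time_ms=time_ms,
                    percentile=percentile,
                    envelope_element=e_env,
                    envelope_time_ms=float(strains.times[t_env]),
                )
            )
    return table


# ---------------------------------------------------------------------------
# CSV I/O (long format with a JSON header declaring units and shear convention)


def save_nodal_history(motion: NodalHistory, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    T, N, _ = motion.displacements.shape
    df = pd.DataFrame(
        {
            "time_ms": np.repeat(motion.times, N),
            "node_id": np.tile(np.arange(N), T),
            "ux": motion.displacements[..., 0].ravel(),
            "uy": motion.displacements[..., 1].ravel(),
            "uz": motion.displacements[..., 2].ravel(),
        }
    )
    df.to_csv(csv_path, index=False)
    csv_path.with_suffix(".json").write_text(
        json.dumps({"units": {"time": "ms", "displacement": "mm"}}, indent=2)
    )


def load_nodal_history(csv_path: str | Path) -> NodalHistory:
    df = pd.read_csv(csv_path)
    times = np.sort(df["time_ms"].unique())
    n = int(df["node_id"].max()) + 1
    disp = np.zeros((len(times), n, 3))
    t_idx = np.searchsorted(times, df["time_ms"].to_numpy())
    disp[t_idx, df["node_id"].to_numpy()] = df[["ux", "uy", "uz"]].to_numpy()
    return NodalHistory(times, disp)


def save_strain_history(strains: StrainHistory, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    T, M, _ = strains.tensors.shape
    cols = {
        "time_ms": np.repeat(strains.times, M),
        "element_id": np.tile(np.arange(M), T),
    }
    for i, name in enumerate(STRAIN_ORDER):
        cols[name] = strains.tensors[..., i].reshape(-1)
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    csv_path.with_suffix(".json").write_text(
        json.dumps(
            {"units": {"time": "ms"}, "shear_convention": "tensor",
             "component_order": list(STRAIN_ORDER)},
            indent=2,
        )
    )


def load_strain_history(csv_path: str | Path) -> StrainHistory:
    """Read a strain-history CSV; the JSON header's ``shear_convention``
    (``"tensor"`` or ``"engineering"``) controls shear conversion on import
    — solver dialects differ."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    shear = "tensor"
    header = csv_path.with_suffix(".json")
    if header.exists():
        shear = json.loads(header.read_text()).get("shear_convention", "tensor")
    if shear not in ("tensor", "engineering"):
        raise ValueError(f"unknown shear convention {shear!r}")
    times = np.sort(df["time_ms"].unique())
    m = int(df["element_id"].max()) + 1
    tens = np.zeros((len(times), m, 6))
    t_idx = np.searchsorted(times, df["time_ms"].to_numpy())
    tens[t_idx, df["element_id"].to_numpy()] = df[list(STRAIN_ORDER)].to_numpy()
    if shear == "engineering":
        tens[..., 3:] *= 0.5
    return StrainHistory(times, tens)
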