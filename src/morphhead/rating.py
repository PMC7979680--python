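"""Validation metrics: DICE segmentation overlap and the CORA
cross-correlation rating of time-history curve pairs.

The CORA score of a model/experiment curve pair is the equal-weight mean
(V + G + P)/3 of three sub-ratings obtained from normalized
cross-correlation: V (shape, correlation at the best shift), G (size,
ratio of curve energies after shifting), and P (phase, penalty on the
shift itself). Scores are aggregated in two levels — all evaluated NDT
channels of one impact case are averaged into a per-case score, and cases
are summarized as mean ± sample SD. The corridor sub-method is
deliberately absent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fields import ImageVolume

__all__ = [
    "CurvePair",
    "CoraSettings",
    "CoraComponents",
    "dice",
    "cora_components",
    "cora_score",
    "rate_pair",
    "aggregate_scores",
    "rate_cases",
]


def dice(a: ImageVolume | np.ndarray, b: ImageVolume | np.ndarray) -> float:
    """DICE(A, B) = 2|A∩B| / (|A| + |B|) for two binary masks on one grid.

    Two empty masks are defined to overlap perfectly (1, with a warning).
    """
    if isinstance(a, ImageVolume) and isinstance(b, ImageVolume):
        if not a.same_grid(b):
            raise ValueError("masks live on different grids")
        a_arr, b_arr = a.data, b.data
    else:
        a_arr = a.data if isinstance(a, ImageVolume) else np.asarray(a)
        b_arr = b.data if isinstance(b, ImageVolume) else np.asarray(b)
        if a_arr.shape != b_arr.shape:
            raise ValueError("masks live on different grids")
    a_bool = a_arr > 0.5
    b_bool = b_arr > 0.5
    na = int(a_bool.sum())
    nb = int(b_bool.sum())
    if na + nb == 0:
        warnings.warn("both masks empty: DICE defined as 1", stacklevel=2)
        return 1.0
    return 2.0 * int((a_bool & b_bool).sum()) / (na + nb)


@dataclass
class CurvePair:
    """Reference (experiment) and candidate (model) time-history curves."""

    ref_t: np.ndarray
    ref_y: np.ndarray
    cand_t: np.ndarray
    cand_y: np.ndarray

    def __post_init__(self) -> None:
        self.ref_t = np.asarray(self.ref_t, dtype=float)
        self.ref_y = np.asarray(self.ref_y, dtype=float)
        self.cand_t = np.asarray(self.cand_t, dtype=float)
        self.cand_y = np.asarray(self.cand_y, dtype=float)
        for t, y, name in (
            (self.ref_t, self.ref_y, "reference"),
            (self.cand_t, self.cand_y, "candidate"),
        ):
            if len(t) != len(y) or len(t) < 2:
                raise ValueError(f"{name} curve needs >= 2 (t, y) samples")
            if (np.diff(t) <= 0).any():
                raise ValueError(f"{name} times must be strictly increasing")
        if (
            min(self.ref_t[-1], self.cand_t[-1])
            <= max(self.ref_t[0], self.cand_t[0])
        ):
            raise ValueError("curves have no overlapping time interval")


@dataclass
class CoraSettings:
    """Cross-correlation sub-method parameters.

    ``d_min``/``d_max`` are shift thresholds as fractions of the evaluation
    interval length; ``k_v``/``k_g``/``k_p`` are the sub-rating exponents.
    ``interval`` optionally restricts evaluation to [t_min, t_max] ms;
    ``resample_dt`` fixes the resampling step (default: the smaller of the
    two native median steps).
    """

    d_min: float = 0.01
    d_max: float = 0.12
    k_v: float = 1.0
    k_g: float = 1.0
    k_p: float = 1.0
    interval: tuple[float, float] | None = None
    resample_dt: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.d_min < self.d_max <= 1:
            raise ValueError("need 0 <= d_min < d_max <= 1")
        if min(self.k_v, self.k_g, self.k_p) <= 0:
            raise ValueError("exponents must be positive")


@dataclass
class CoraComponents:
    """Shape V, size G, phase P (each in [0, 1]) + the shift that won."""

    V: float
    G: float
    P: float
    best_shift_ms: float
    interval: tuple[float, float]

    @property
    def score(self) -> float:
        return cora_score(self)


def cora_score(c: CoraComponents | tuple[float, float, float]) -> float:
    """Combined CORA score: the equal-weight mean (V + G + P) / 3."""
    if isinstance(c, CoraComponents):
        v, g, p = c.V, c.G, c.P
    else:
        v, g, p = c
    for name, x in (("V", v), ("G", g), ("P", p)):
        if not 0 <= x <= 1:
            raise ValueError(f"component {name}={x} outside [0, 1]")
    return (v + g + p) / 3.0


def cora_components(pair: CurvePair, settings: CoraSettings | None = None) -> CoraComponents:
    """Cross-correlation sub-ratings of a curve pair.

    Both curves are linearly resampled onto a uniform grid over the
    evaluation interval. The normalized cross-correlation K(δ) is scanned
    over shifts |δ| ≤ d_max·T; at the argmax δ*:

    * V = max(K(δ*), 0)^k_v
    * P = 1 if |δ*|/T ≤ d_min; 0 if ≥ d_max; else the linear falloff
      ((d_max − |δ*|/T)/(d_max − d_min))^k_p
    * G = (min(Q_ref, Q_cand)/max(Q_ref, Q_cand))^k_g with Q = ∫ curve² dt
      evaluated on the common support after applying δ* to the candidate.
    """
    s = settings or CoraSettings()
    t0 = max(pair.ref_t[0], pair.cand_t[0])
    t1 = min(pair.ref_t[-1], pair.cand_t[-1])
    if s.interval is not None:
        t0, t1 = max(t0, s.interval[0]), min(t1, s.interval[1])
        if t1 <= t0:
            raise ValueError("requested interval does not intersect the curves")
    dt = s.resample_dt or min(
        float(np.median(np.diff(pair.ref_t))), float(np.median(np.diff(pair.cand_t)))
    )
    n = max(int(round((t1 - t0) / dt)) + 1, 8)
    grid = np.linspace(t0, t1, n)
    dt = grid[1] - grid[0]
    ref = np.interp(grid, pair.ref_t, pair.ref_y)
    cand = np.interp(grid, pair.cand_t, pair.cand_y)

    ref_energy = float(ref @ ref)
    if ref_energy == 0:
        raise ValueError("flat zero reference curve: CORA normalization undefined")

    T = t1 - t0
    max_shift = s.d_max * T

    def _overlap(delta: float):
        """ref(t) paired with cand(t + δ) on the valid common support.

        Positive δ means the candidate lags (peaks later than) the
        reference and is advanced to meet it."""
        shifted_t = grid + delta
        valid = (shifted_t >= t0 - 1e-12) & (shifted_t <= t1 + 1e-12)
        if valid.sum() < 2:
            return None
        c = np.interp(shifted_t[valid], grid, cand)
        return ref[valid], c

    # scan integer multiples of dt plus the exact ±d_max·T boundary so a
    # candidate shifted beyond the window pins δ* to the boundary (P = 0)
    lags = np.arange(-int(np.floor(max_shift / dt)), int(np.floor(max_shift / dt)) + 1)
    deltas = np.unique(np.concatenate([lags * dt, [-max_shift, max_shift, 0.0]]))
    best_k, best_delta = -np.inf, 0.0
    for delta in deltas:
        pair_rc = _overlap(float(delta))
        if pair_rc is None:
            continue
        r, c = pair_rc
        denom = np.sqrt(float(r @ r) * float(c @ c))
        k = float(r @ c) / denom if denom > 0 else 0.0
        if k > best_k or (k == best_k and abs(delta) < abs(best_delta)):
            best_k, best_delta = k, float(delta)

    V = float(np.clip(max(best_k, 0.0) ** s.k_v, 0.0, 1.0))

    frac = abs(best_delta) / T
    if frac <= s.d_min:
        P = 1.0
    elif frac >= s.d_max - 1e-12:
        P = 0.0
    else:
        P = ((s.d_max - frac) / (s.d_max - s.d_min)) ** s.k_p
    P = float(np.clip(P, 0.0, 1.0))

    r, c = _overlap(best_delta)
    q_ref = float(r @ r) * dt
    q_cand = float(c @ c) * dt
    if max(q_ref, q_cand) == 0:
        G = 1.0
    else:
        G = (min(q_ref, q_cand) / max(q_ref, q_cand)) ** s.k_g
    G = float(np.clip(G, 0.0, 1.0))

    return CoraComponents(
        V=V, G=G, P=P, best_shift_ms=best_delta, interval=(t0, t1)
    )


def rate_pair(pair: CurvePair, settings: CoraSettings | None = None) -> float:
    """Convenience: components then combined score."""
    return cora_score(cora_components(pair, settings))


def aggregate_scores(scores, level: str = "case") -> tuple[float, float]:
    """Mean and sample standard deviation (n − 1 denominator) of scores.

    ``level`` is bookkeeping only ("ndt": channels → one case score;
    "case": per-case scores → the across-case summary row). A single score
    aggregates to (score, 0) with a warning.
    """
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ValueError("cannot aggregate an empty score list")
    if level not in ("ndt", "case"):
        raise ValueError(f"level must be 'ndt' or 'case', got {level!r}")
    mean = float(scores.mean())
    if scores.size == 1:
        warnings.warn("single score: SD reported as 0", stacklevel=2)
        return mean, 0.0
    return mean, float(scores.std(ddof=1))


def rate_cases(
    cases: dict[str, list[CurvePair]],
    settings: CoraSettings | None = None,
) -> dict:
    """Two-level aggregation: per-NDT scores → per-case mean → summary.

    All evaluated channels of a case enter its mean with the same weight.
    Returns {"per_case": {case: {"ndt_scores": [...], "score": mean}},
    "summary": {"mean": m, "sd": s}}.
    """
    per_case = {}
    for name, pairs in cases.items():
        ndt_scores = [rate_pair(p, settings) for p in pairs]
        mean, _ = aggregate_scores(ndt_scores, level="ndt")
        per_case[name] = {"ndt_scores": ndt_scores, "score": mean}
    case_scores = [v["score"] for v in per_case.values()]
    mean, sd = aggregate_scores(case_scores, level="case")
    return {"per_case": per_case, "summary": {"mean": mean, "sd": sd}}
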