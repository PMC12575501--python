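"""Simulation-vs-imaging validation: registration, distances, scoring.

Mirrors the study's validation protocol: rigid registration of the two
geometries (centroid alignment followed by iterative closest point),
corresponding-point distances between equal-count resampled centerlines,
their mean/std/max statistics, the placement accuracy score (percentage
of points closer than a 3 mm tolerance: 2 mm imaging + 1 mm segmentation
error), and the aortic protrusion-length criterion (clinical band
3.4-4.3 mm around a 3.88 mm reference).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .centerline import Centerline
from .errors import InvalidConfigError, InvalidInputError

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE_MM = 3.0
PROTRUSION_BAND_MM = (3.4, 4.3)
PROTRUSION_REFERENCE_MM = 3.88
DEFAULT_N_CORRESPONDING = 100


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: x -> R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-10:
            raise InvalidInputError("rotation must be orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-10:
            raise InvalidInputError("rotation must be proper (det +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ np.asarray(self.rotation).T + np.asarray(self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then self."""
        R1, t1 = np.asarray(other.rotation), np.asarray(other.translation)
        R2, t2 = np.asarray(self.rotation), np.asarray(self.translation)
        return RigidTransform(R2 @ R1, R2 @ t1 + t2)


@dataclass
class DistanceProfile:
    """Per-corresponding-point distances with summary statistics (mm)."""

    distances: np.ndarray
    mean: float = field(init=False)
    std: float = field(init=False)
    max: float = field(init=False)

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.size == 0:
            raise InvalidInputError("distance profile must be non-empty")
        if np.any(self.distances < 0):
            raise InvalidInputError("distances must be non-negative")
        self.mean = float(self.distances.mean())
        self.std = float(self.distances.std(ddof=0))
        self.max = float(self.distances.max())


@dataclass
class ValidationConfig:
    """Thresholds of the validation protocol."""

    tolerance_mm: float = DEFAULT_TOLERANCE_MM
    protrusion_band_mm: tuple = PROTRUSION_BAND_MM
    protrusion_reference_mm: float = PROTRUSION_REFERENCE_MM

    def __post_init__(self) -> None:
        if self.tolerance_mm <= 0:
            raise InvalidConfigError("tolerance must be positive")
        if not self.protrusion_band_mm[0] < self.protrusion_band_mm[1]:
            raise InvalidConfigError("protrusion band must be ordered")


@dataclass
class ScoreReport:
    """Placement accuracy score with its supporting distance profile."""

    accuracy_score: float  # percent
    profile: DistanceProfile
    n_points: int
    threshold_mm: float


def kabsch_align(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``source`` onto ``target``.

    SVD-based, with the determinant branch corrected so the result is
    always a proper rotation.  Raises on degenerate (collinear or
    too-small) configurations.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape or len(src) < 3:
        raise InvalidInputError("need equal point counts >= 3")
    sc, tc = src.mean(axis=0), tgt.mean(axis=0)
    H = (src - sc).T @ (tgt - tc)
    U, sing, Vt = np.linalg.svd(H)
    if sing[1] < 1e-12 * max(sing[0], 1.0):
        raise InvalidInputError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ sc
    return RigidTransform(R, t)


def icp(
    source: np.ndarray,
    target: np.ndarray,
    max_iter: int = 100,
    tol_mm: float = 1e-6,
) -> tuple[RigidTransform, list[float]]:
    """Iterative closest point registration of ``source`` onto ``target``.

    Centroids are aligned first; then nearest-neighbor correspondence and
    Kabsch alignment alternate until the RMS improvement falls below
    ``tol_mm`` or ``max_iter`` is reached.  Returns the cumulative
    transform and the (non-increasing) RMS history.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if len(src) < 10 or len(tgt) < 10:
        raise InvalidInputError("both point sets need at least 10 points")

    transform = RigidTransform(np.eye(3), tgt.mean(axis=0) - src.mean(axis=0))
    moved = transform.apply(src)
    tree = cKDTree(tgt)
    d, _ = tree.query(moved)
    history = [float(np.sqrt(np.mean(d**2)))]

    for _ in range(max_iter):
        d, idx = tree.query(moved)
        try:
            step = kabsch_align(moved, tgt[idx])
        except InvalidInputError:
            warnings.warn("degenerate correspondence; returning centroid alignment", stacklevel=2)
            break
        moved = step.apply(moved)
        transform = step.compose(transform)
        d, _ = tree.query(moved)
        rms = float(np.sqrt(np.mean(d**2)))
        improvement = history[-1] - rms
        history.append(rms)
        if improvement < tol_mm:
            if len(history) == 2 and improvement < 0 and rms > tol_mm:
                warnings.warn("ICP made no progress beyond centroid alignment", stacklevel=2)
            break
    return transform, history


def centerline_distance(
    a: Centerline,
    b: Centerline,
    n_corresponding: int = DEFAULT_N_CORRESPONDING,
) -> DistanceProfile:
    """Corresponding-point distances between two centerlines.

    Both lines are resampled to ``n_corresponding`` arc-length-proportional
    points (index 0 at the ostium end) and same-index distances are
    measured.  If the endpoint pairing indicates opposite storage
    orientations, the second line is reversed (logged, not an error).
    """
    if n_corresponding < 10:
        raise InvalidConfigError("need at least 10 corresponding points")
    pa = a.resample_count(n_corresponding).points
    pb_line = b
    same = np.linalg.norm(a.points[0] - b.points[0]) + np.linalg.norm(
        a.points[-1] - b.points[-1]
    )
    crossed = np.linalg.norm(a.points[0] - b.points[-1]) + np.linalg.norm(
        a.points[-1] - b.points[0]
    )
    if crossed < same:
        logger.info("centerline orientations differ; auto-reversing the second line")
        pb_line = b.reversed()
    pb = pb_line.resample_count(n_corresponding).points
    return DistanceProfile(np.linalg.norm(pa - pb, axis=1))


def placement_accuracy_score(
    profile: DistanceProfile, tolerance_mm: float = DEFAULT_TOLERANCE_MM
) -> ScoreReport:
    """Percentage of corresponding points strictly below the tolerance.

    A point at exactly the tolerance counts as a failure, so the score is
    100 exactly when the maximum distance is below the threshold.
    """
    if tolerance_mm <= 0:
        raise InvalidConfigError("tolerance must be positive")
    n = len(profile.distances)
    score = 100.0 * float(np.count_nonzero(profile.distances < tolerance_mm)) / n
    return ScoreReport(score, profile, n, float(tolerance_mm))


def check_protrusions(
    deployed_list, config: ValidationConfig | None = None
) -> dict:
    """Protrusion-length criterion over a set of deployed stent-grafts.

    Each protrusion (a :class:`~fevarsim.stents.DeployedSG` or a bare
    length in mm) is checked against the clinical band, and the arithmetic
    mean is reported alongside the clinical reference value.
    """
    cfg = config or ValidationConfig()
    if not deployed_list:
        raise InvalidInputError("need at least one deployed stent-graft")
    lengths = np.array(
        [float(getattr(d, "protrusion_length", d)) for d in deployed_list]
    )
    lo, hi = cfg.protrusion_band_mm
    passes = (lengths >= lo) & (lengths <= hi)
    return {
        "protrusions_mm": lengths,
        "pass": passes,
        "all_pass": bool(passes.all()),
        "mean_mm": float(lengths.mean()),
        "max_mm": float(lengths.max()),
        "band_mm": (lo, hi),
        "reference_mm": cfg.protrusion_reference_mm,
    }
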