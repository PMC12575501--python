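"""Centerline morphometry: curvature, branching angle, end-stent angle.

These are the geometric outcome measures of the study.  Curvature is the
discrete Menger estimate (reciprocal circumradius of consecutive point
triples) evaluated on a 1 mm resampling, with the maximum over interior
points reported.  The branching angle is measured between the aorta
tangent at the ostium and the least-squares direction of the proximal
branch; 90 degrees means a perpendicular branch.  The end-stent angle is
measured between the stented and unstented branch directions at the distal
stent end; 0 means collinear.  Inspiration-to-expiration differences are
reported as absolute values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .centerline import Centerline
from .errors import InvalidConfigError, InvalidInputError, InvalidPairingError

DEFAULT_SPACING_MM = 1.0
DEFAULT_FIT_WINDOW_MM = 5.0


@dataclass
class MorphoMetrics:
    """Morphometric readout for one branch in one configuration."""

    branching_angle_deg: float
    max_curvature_per_mm: float
    curvature_profile: np.ndarray
    end_stent_angle_deg: float | None = None
    patient: str = ""
    artery: str = ""
    configuration: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.branching_angle_deg < 180.0:
            raise InvalidInputError("branching angle must lie in (0, 180)")
        if self.max_curvature_per_mm < 0:
            raise InvalidInputError("max curvature must be non-negative")


@dataclass
class MorphoDelta:
    """Absolute inspiration-to-expiration metric changes."""

    d_branching_angle_deg: float
    d_max_curvature_per_mm: float
    d_end_stent_angle_deg: float | None
    patient: str = ""
    artery: str = ""
    configuration: str = ""


def resample_centerline(centerline: Centerline, spacing_mm: float = DEFAULT_SPACING_MM) -> Centerline:
    """Uniform arc-length resampling (endpoints preserved exactly)."""
    return centerline.resample(spacing_mm)


def menger_curvature(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Reciprocal circumradius of a point triple; 0 for collinear points."""
    a = np.linalg.norm(p1 - p0)
    b = np.linalg.norm(p2 - p1)
    c = np.linalg.norm(p2 - p0)
    cross = np.cross(p1 - p0, p2 - p0)
    area2 = np.linalg.norm(cross)  # twice the triangle area
    if area2 < 1e-14 * a * b * c or a * b * c == 0.0:
        return 0.0
    return float(2.0 * area2 / (a * b * c))


def pointwise_curvature(centerline: Centerline) -> tuple[np.ndarray, float]:
    """Menger curvature at each interior point, plus its maximum.

    Endpoints carry no curvature estimate and are excluded; the input is
    expected to be resampled (1 mm by default) beforehand.
    """
    pts = centerline.points
    if len(pts) < 3:
        raise InvalidInputError("need at least 3 points for curvature")
    p0, p1, p2 = pts[:-2], pts[1:-1], pts[2:]
    a = np.linalg.norm(p1 - p0, axis=1)
    b = np.linalg.norm(p2 - p1, axis=1)
    c = np.linalg.norm(p2 - p0, axis=1)
    area2 = np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)
    abc = a * b * c
    kappa = np.where(area2 < 1e-14 * abc, 0.0, 2.0 * area2 / abc)
    return kappa, float(kappa.max())


def _ls_direction(points: np.ndarray) -> np.ndarray:
    """Least-squares line direction of a point run, oriented first->last."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    if np.dot(d, points[-1] - points[0]) < 0:
        d = -d
    return d / np.linalg.norm(d)


def _window_points(centerline: Centerline, s_lo: float, s_hi: float) -> np.ndarray:
    """Points of the 1 mm resampled centerline with arc length in [s_lo, s_hi]."""
    res = centerline.resample(min(DEFAULT_SPACING_MM, centerline.length / 4))
    cum = res.arc_lengths()
    mask = (cum >= s_lo - 1e-9) & (cum <= s_hi + 1e-9)
    return res.points[mask]


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def branching_angle(
    aorta: Centerline,
    branch: Centerline,
    fit_window_mm: float = DEFAULT_FIT_WINDOW_MM,
) -> float:
    """Angle between the aorta and the proximal renal branch, in degrees.

    The aorta direction is its tangent at the point nearest the ostium; the
    branch direction is the least-squares line through the branch's first
    ``fit_window_mm`` of arc length.  Reported in (0, 180) with 90 meaning
    a perpendicular branch.
    """
    if fit_window_mm < 3.0:
        raise InvalidConfigError("fit window must be at least 3 mm")
    if fit_window_mm > branch.length:
        warnings.warn(
            f"branch ({branch.length:.1f} mm) shorter than fit window "
            f"({fit_window_mm} mm); shrinking the window",
            stacklevel=2,
        )
        fit_window_mm = branch.length

    ostium = branch.points[0]
    cum = aorta.arc_lengths()
    dists = np.linalg.norm(aorta.points - ostium, axis=1)
    s_near = float(cum[np.argmin(dists)])
    t_aorta = aorta.tangent_at(s_near)

    d_branch = _ls_direction(_window_points(branch, 0.0, fit_window_mm))
    angle = _angle_deg(t_aorta, d_branch)
    return min(max(angle, 1e-9), 180.0 - 1e-9)


def end_stent_angle(
    branch: Centerline,
    deployed_sg,
    fit_window_mm: float = DEFAULT_FIT_WINDOW_MM,
) -> float | None:
    """Angle between stented and unstented branch directions, in degrees.

    Measured at the distal stent end: least-squares direction of the last
    ``fit_window_mm`` of stented centerline versus the first
    ``fit_window_mm`` beyond it.  Returns None (metric unavailable) when
    fewer than ``fit_window_mm`` of artery remain distal to the stent.
    """
    s_end = float(deployed_sg.s_end)
    if branch.length - s_end < fit_window_mm - 1e-9:
        return None
    stented = _window_points(branch, max(0.0, s_end - fit_window_mm), s_end)
    distal = _window_points(branch, s_end, s_end + fit_window_mm)
    if len(stented) < 2 or len(distal) < 2:
        return None
    return _angle_deg(_ls_direction(stented), _ls_direction(distal))


def compute_metrics(
    aorta: Centerline,
    branch: Centerline,
    deployed_sg=None,
    fit_window_mm: float = DEFAULT_FIT_WINDOW_MM,
    branching_window_mm: float | None = None,
    spacing_mm: float = DEFAULT_SPACING_MM,
    **labels,
) -> MorphoMetrics:
    """Full morphometric readout for one branch configuration.

    ``branching_window_mm`` optionally overrides ``fit_window_mm`` for the
    branching angle only (the study pipeline uses a wider window there to
    emulate whole-centerline angle measurement).
    """
    res = branch.resample(spacing_mm)
    profile, kmax = pointwise_curvature(res)
    esa = None if deployed_sg is None else end_stent_angle(branch, deployed_sg, fit_window_mm)
    return MorphoMetrics(
        branching_angle_deg=branching_angle(aorta, branch, branching_window_mm or fit_window_mm),
        max_curvature_per_mm=kmax,
        curvature_profile=profile,
        end_stent_angle_deg=esa,
        **labels,
    )


def breathing_deltas(inspiration: MorphoMetrics, expiration: MorphoMetrics) -> MorphoDelta:
    """Absolute metric differences between the two respiratory states."""
    for attr in ("patient", "artery"):
        a, b = getattr(inspiration, attr), getattr(expiration, attr)
        if a and b and a != b:
            raise InvalidPairingError(f"metrics pair different {attr}s: {a!r} vs {b!r}")
    if (inspiration.end_stent_angle_deg is None) != (expiration.end_stent_angle_deg is None):
        raise InvalidPairingError("one state is stented, the other is not")
    d_esa = None
    if inspiration.end_stent_angle_deg is not None:
        d_esa = abs(expiration.end_stent_angle_deg - inspiration.end_stent_angle_deg)
    return MorphoDelta(
        d_branching_angle_deg=abs(
            expiration.branching_angle_deg - inspiration.branching_angle_deg
        ),
        d_max_curvature_per_mm=abs(
            expiration.max_curvature_per_mm - inspiration.max_curvature_per_mm
        ),
        d_end_stent_angle_deg=d_esa,
        patient=inspiration.patient,
        artery=inspiration.artery,
        configuration=inspiration.configuration or expiration.configuration,
    )
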