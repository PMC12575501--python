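"""Synthetic patient vasculature and respiratory boundary conditions.

Stands in for CT-derived geometry: an abdominal aorta running along the
cranio-caudal axis with two renal branches (lumen diameter 5-7 mm) leaving
it at branching angles around 60-100 degrees.  Breathing is represented by
one displacement vector per renal branch, applied at the distal branch end,
with the aorta ends held fixed; the cranio-caudal component dominates.

All randomness flows from a single master seed through fixed stream keys,
so generation is bitwise reproducible and independent of call order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .centerline import Centerline
from .errors import (
    InvalidConfigError,
    SelfIntersectionWarning,
    ShortBranchWarning,
)

# patient frame: x = left-right (left positive), y = antero-posterior,
# z = cranio-caudal (superior positive); units mm
_AXIS_LR = np.array([1.0, 0.0, 0.0])
_AXIS_CC = np.array([0.0, 0.0, 1.0])

# longest device in the bridging stent-graft catalog (mm); branches shorter
# than this cannot host every catalog entry and trigger a warning
_MAX_CATALOG_LENGTH_MM = 28.0

# fixed sub-stream keys (counter-based seeding: stage order cannot matter)
_STREAM_AORTA = 11
_STREAM_BRANCH = {"left": 21, "right": 22}
_STREAM_BREATHING = 31
_STREAM_ANATOMY = 41


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(stream,)))


def _smooth_ramp(t: np.ndarray) -> np.ndarray:
    """C1 ramp: 0 for t<=0, 1 for t>=1, smoothstep between."""
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


@dataclass
class BreathingBC:
    """Respiratory displacement per renal branch, aorta ends fixed.

    Vectors are (x, y, z) = (left-right, antero-posterior, cranio-caudal)
    in mm; the cranio-caudal component is the largest in magnitude.
    """

    displacements: dict  # branch name -> (3,) array, mm
    fixed_aorta_ends: bool = True

    def __post_init__(self) -> None:
        self.displacements = {
            k: np.asarray(v, dtype=float) for k, v in self.displacements.items()
        }
        for name, v in self.displacements.items():
            if abs(v[2]) + 1e-12 < max(abs(v[0]), abs(v[1])):
                raise InvalidConfigError(
                    f"branch {name}: cranio-caudal displacement component must "
                    f"dominate, got {v}"
                )


@dataclass
class SyntheticPatient:
    """Aorta + two renal branches with breathing boundary conditions."""

    aorta: Centerline
    aorta_radius: float
    renal_left: Centerline
    renal_right: Centerline
    renal_radii: dict
    ostium_s: dict  # branch name -> aorta arc length of the ostium (mm)
    breathing: BreathingBC
    seed: int
    label: str = ""

    @property
    def branches(self) -> dict:
        return {"left": self.renal_left, "right": self.renal_right}


@dataclass
class PatientConfig:
    """Geometry and breathing ranges for the synthetic cohort.

    Ranges are (low, high) for per-patient uniform draws.  Defaults follow
    adult abdominal anatomy: a 200 mm aorta of 20 mm lumen diameter, renal
    branches 35-50 mm long with 5-7 mm lumen, branching angles 60-100
    degrees, and visibly curved branch courses (arc radius about 35-65 mm),
    which give the artery the geometric slack it uses to accommodate
    breathing by bending rather than by stretching.  The breathing
    displacement is dominated by the cranio-caudal component (3 mm, with
    antero-posterior and left-right at 1/5 and 1/10 of it); together with
    the geometry defaults this reproduces pre-EVAR breathing-induced
    branching-angle changes around 9-15 degrees.
    """

    aorta_length_mm: float = 200.0
    aorta_radius_mm: float = 10.0
    aorta_tortuosity_mm: float = 2.0
    aorta_n_points: int = 201
    branch_length_mm: tuple = (35.0, 50.0)
    branching_angle_deg: tuple = (60.0, 100.0)
    renal_radius_mm: tuple = (2.5, 3.5)
    branch_arc_curvature: tuple = (0.015, 0.03)  # 1/mm, curved branch course
    breathing_cc_mm: float = 3.0
    breathing_ap_mm: float = 0.6
    breathing_lr_mm: float = 0.3
    breathing_jitter: float = 0.1


def generate_aorta_centerline(
    length_mm: float,
    radius_mm: float,
    tortuosity_amp_mm: float,
    n_points: int,
    seed: int,
    straight_windows: list | None = None,
) -> Centerline:
    """Generate an aorta centerline running along the cranio-caudal axis.

    Points are ordered cranial to caudal (descending z, matching blood-flow
    direction), so branching angles below 90 degrees denote caudally
    directed branches.  The baseline is a straight vertical line; a seeded
    two-harmonic lateral perturbation of amplitude ``tortuosity_amp_mm``
    adds tortuosity.  ``straight_windows`` is an optional list of
    ``(s_center, half_width)`` pairs (mm) inside which the perturbation is
    smoothly suppressed, so branch ostia sit on a locally straight segment.
    """
    if length_mm <= 0 or radius_mm <= 0:
        raise InvalidConfigError("aorta length and radius must be positive")
    if n_points < 10:
        raise InvalidConfigError("need at least 10 aorta points")
    if tortuosity_amp_mm < 0:
        raise InvalidConfigError("tortuosity amplitude must be non-negative")

    z = np.linspace(length_mm, 0.0, n_points)
    x = np.zeros_like(z)
    y = np.zeros_like(z)
    if tortuosity_amp_mm > 0:
        rng = _rng(seed, _STREAM_AORTA)
        phases = rng.uniform(0, 2 * np.pi, size=4)
        weights = rng.uniform(0.5, 1.0, size=4)
        u = (length_mm - z) / length_mm
        # endpoint envelope keeps both aorta ends on the nominal axis
        env = np.sin(np.pi * u)
        x = tortuosity_amp_mm * env * (
            weights[0] * np.sin(2 * np.pi * u + phases[0])
            + 0.5 * weights[1] * np.sin(4 * np.pi * u + phases[1])
        )
        y = tortuosity_amp_mm * env * (
            weights[2] * np.sin(2 * np.pi * u + phases[2])
            + 0.5 * weights[3] * np.sin(4 * np.pi * u + phases[3])
        )
        s_axis = length_mm - z  # arc-length station when tortuosity is mild
        for s_center, half_width in straight_windows or []:
            # 0 inside the window, ramping back to 1 over another half_width
            gate = _smooth_ramp((np.abs(s_axis - s_center) - half_width) / half_width)
            x *= gate
            y *= gate
    pts = np.column_stack([x, y, z])
    return Centerline(
        pts,
        radii=np.full(n_points, float(radius_mm)),
        metadata={"seed": int(seed), "kind": "aorta"},
    )


def _ostium_frame(aorta: Centerline, ostium_s: float, side: str):
    """Ostium vertex, aorta tangent there, and the lateral branch normal."""
    cum = aorta.arc_lengths()
    i = int(np.argmin(np.abs(cum - ostium_s)))
    i = min(max(i, 1), len(cum) - 2)
    t = aorta.points[i + 1] - aorta.points[i - 1]
    t = t / np.linalg.norm(t)
    lateral = _AXIS_LR if side == "left" else -_AXIS_LR
    n = lateral - np.dot(lateral, t) * t
    n = n / np.linalg.norm(n)
    return i, t, n


def generate_renal_branch(
    aorta: Centerline,
    side: str,
    branching_angle_deg: float,
    length_mm: float,
    radius_mm: float,
    curvature_profile: float | dict | None,
    seed: int,
    ostium_s: float | None = None,
) -> Centerline:
    """Grow a renal branch off the aorta tube surface.

    The branch leaves the aorta at ``branching_angle_deg`` to the aorta
    tangent (90 = perpendicular) on the given ``side`` ('left' or 'right').
    ``curvature_profile`` is either a constant arc curvature (1/mm, caudal
    bowing), a dict with keys ``arc_curvature``, ``sin_amp_mm`` and
    ``sin_cycles`` for an added seeded sinusoidal perturbation, or
    None/0 for a straight branch.
    """
    if side not in ("left", "right"):
        raise InvalidConfigError("side must be 'left' or 'right'")
    if not 10.0 < branching_angle_deg < 170.0:
        raise InvalidConfigError("branching angle must be in (10, 170) degrees")
    if not 20.0 <= length_mm <= 80.0:
        raise InvalidConfigError("branch length must be in [20, 80] mm")
    if not 2.5 <= radius_mm <= 3.5:
        raise InvalidConfigError(
            "renal radius must be in [2.5, 3.5] mm (lumen diameter 5-7 mm)"
        )
    if length_mm < _MAX_CATALOG_LENGTH_MM:
        warnings.warn(
            f"branch length {length_mm} mm is shorter than the longest "
            f"catalog stent-graft ({_MAX_CATALOG_LENGTH_MM} mm)",
            ShortBranchWarning,
            stacklevel=2,
        )

    if isinstance(curvature_profile, dict):
        kappa = float(curvature_profile.get("arc_curvature", 0.0))
        sin_amp = float(curvature_profile.get("sin_amp_mm", 0.0))
        sin_cycles = float(curvature_profile.get("sin_cycles", 1.0))
    else:
        kappa = float(curvature_profile or 0.0)
        sin_amp = 0.0
        sin_cycles = 1.0

    if ostium_s is None:
        ostium_s = aorta.metadata.get(f"ostium_s_{side}", aorta.length / 2)
    aorta_radius = float(aorta.radii[0]) if aorta.radii is not None else 0.0

    i, t, n = _ostium_frame(aorta, ostium_s, side)
    p0 = aorta.points[i] + aorta_radius * n

    theta = np.radians(branching_angle_deg)
    d = np.cos(theta) * t + np.sin(theta) * n  # initial branch direction
    # in-plane arc normal perpendicular to d: caudal droop (t points caudal)
    m = t - np.dot(t, d) * d
    m_norm = np.linalg.norm(m)
    m = m / m_norm if m_norm > 1e-12 else np.cross(d, _AXIS_LR)

    s = np.arange(0.0, length_mm + 0.5, 1.0)
    s[-1] = length_mm
    if abs(kappa) > 1e-12:
        pts = (
            p0[None, :]
            + (np.sin(kappa * s) / kappa)[:, None] * d[None, :]
            + ((1 - np.cos(kappa * s)) / kappa)[:, None] * m[None, :]
        )
    else:
        pts = p0[None, :] + s[:, None] * d[None, :]
    if sin_amp > 0:
        rng = _rng(seed, _STREAM_BRANCH[side])
        phase = rng.uniform(0, 2 * np.pi)
        b = np.cross(d, m)
        env = np.sin(np.pi * s / length_mm)  # endpoints untouched
        pts = pts + (sin_amp * env * np.sin(2 * np.pi * sin_cycles * s / length_mm + phase))[
            :, None
        ] * b[None, :]

    return Centerline(
        pts,
        radii=np.full(len(pts), float(radius_mm)),
        metadata={
            "seed": int(seed),
            "kind": f"renal_{side}",
            "branching_angle_deg": float(branching_angle_deg),
            "ostium_s": float(ostium_s),
        },
    )


def sweep_tube_mesh(
    centerline: Centerline, radius_mm: float, n_circumferential: int
) -> trimesh.Trimesh:
    """Sweep a circular tube of ``radius_mm`` along a centerline.

    Uses parallel-transported frames (no spurious twist) and returns an
    open-ended triangulated tube.  Emits :class:`SelfIntersectionWarning`
    when the centerline's curvature radius drops below the tube radius.
    """
    if radius_mm <= 0:
        raise InvalidConfigError("tube radius must be positive")
    if n_circumferential < 8:
        raise InvalidConfigError("need at least 8 circumferential vertices")

    from .morpho import pointwise_curvature  # local import avoids a cycle

    if centerline.n_points >= 3:
        kappa, kmax = pointwise_curvature(centerline)
        if kmax > 0 and 1.0 / kmax < radius_mm:
            warnings.warn(
                f"centerline curvature radius {1.0 / kmax:.2f} mm is below the "
                f"tube radius {radius_mm} mm; the swept surface self-intersects",
                SelfIntersectionWarning,
                stacklevel=2,
            )

    pts = centerline.points
    tangents = np.gradient(pts, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1)[:, None]

    # parallel transport an initial normal along the tangent field
    ref = _AXIS_LR if abs(np.dot(tangents[0], _AXIS_LR)) < 0.9 else np.array([0.0, 1.0, 0.0])
    normal = ref - np.dot(ref, tangents[0]) * tangents[0]
    normal /= np.linalg.norm(normal)
    normals = [normal]
    for k in range(1, len(pts)):
        n_prev = normals[-1]
        t_new = tangents[k]
        n_new = n_prev - np.dot(n_prev, t_new) * t_new
        norm = np.linalg.norm(n_new)
        if norm < 1e-12:  # degenerate fold-back; restart the frame
            n_new = ref - np.dot(ref, t_new) * t_new
            norm = np.linalg.norm(n_new)
        normals.append(n_new / norm)
    normals = np.array(normals)
    binormals = np.cross(tangents, normals)

    phi = 2 * np.pi * np.arange(n_circumferential) / n_circumferential
    rings = (
        pts[:, None, :]
        + radius_mm * np.cos(phi)[None, :, None] * normals[:, None, :]
        + radius_mm * np.sin(phi)[None, :, None] * binormals[:, None, :]
    )
    vertices = rings.reshape(-1, 3)

    faces = []
    m = n_circumferential
    for k in range(len(pts) - 1):
        for j in range(m):
            a = k * m + j
            b = k * m + (j + 1) % m
            c = (k + 1) * m + j
            d = (k + 1) * m + (j + 1) % m
            faces.append([a, b, d])
            faces.append([a, d, c])
    return trimesh.Trimesh(vertices=vertices, faces=np.array(faces), process=False)


def generate_breathing_bc(
    cc_mm: float,
    ap_mm: float,
    lr_mm: float,
    per_branch_jitter: float = 0.0,
    seed: int = 0,
) -> BreathingBC:
    """Build the respiratory displacement vectors for both renal branches.

    The left branch receives (+lr, ap, cc), the right branch (-lr, ap, cc),
    optionally jittered per branch by a relative amount ``per_branch_jitter``.
    The cranio-caudal magnitude must dominate the other two components.
    """
    if cc_mm < 0 or cc_mm + 1e-12 < max(abs(ap_mm), abs(lr_mm)):
        raise InvalidConfigError(
            "cranio-caudal displacement must dominate: "
            f"cc={cc_mm}, ap={ap_mm}, lr={lr_mm}"
        )
    rng = _rng(seed, _STREAM_BREATHING)
    disps = {}
    for name, sign in (("left", 1.0), ("right", -1.0)):
        base = np.array([sign * lr_mm, ap_mm, cc_mm])
        if per_branch_jitter > 0:
            # jitter the transverse components only, so dominance is kept
            fac = 1.0 + per_branch_jitter * rng.uniform(-1, 1, size=3)
            fac[2] = 1.0 + per_branch_jitter * rng.uniform(0, 1)
            base = base * fac
        disps[name] = base
    return BreathingBC(displacements=disps)


def generate_patient(seed: int, config: PatientConfig | None = None, label: str = "") -> SyntheticPatient:
    """Generate one reproducible synthetic patient.

    Draws per-patient anatomy (branch lengths, angles, radii, bowing) from
    the ranges in ``config``, builds the aorta with locally straight ostium
    windows so each branch root sits exactly on the aorta tube surface, and
    attaches the breathing boundary conditions.
    """
    cfg = config or PatientConfig()
    rng = _rng(seed, _STREAM_ANATOMY)

    # ostium stations near mid-aorta (arc measured from the cranial end),
    # right renal artery slightly superior to the left
    s_right = 0.48 * cfg.aorta_length_mm + rng.uniform(-3, 3)
    s_left = 0.52 * cfg.aorta_length_mm + rng.uniform(-3, 3)
    windows = [(s_right, 10.0), (s_left, 10.0)]

    aorta = generate_aorta_centerline(
        cfg.aorta_length_mm,
        cfg.aorta_radius_mm,
        cfg.aorta_tortuosity_mm,
        cfg.aorta_n_points,
        seed,
        straight_windows=windows,
    )
    aorta.metadata["ostium_s_right"] = float(s_right)
    aorta.metadata["ostium_s_left"] = float(s_left)

    branches = {}
    radii = {}
    ostia = {"left": float(s_left), "right": float(s_right)}
    for side in ("left", "right"):
        angle = rng.uniform(*cfg.branching_angle_deg)
        length = rng.uniform(*cfg.branch_length_mm)
        radius = rng.uniform(*cfg.renal_radius_mm)
        kappa = rng.uniform(*cfg.branch_arc_curvature)
        branches[side] = generate_renal_branch(
            aorta, side, angle, length, radius, kappa, seed, ostium_s=ostia[side]
        )
        radii[side] = radius

    breathing = generate_breathing_bc(
        cfg.breathing_cc_mm,
        cfg.breathing_ap_mm,
        cfg.breathing_lr_mm,
        per_branch_jitter=cfg.breathing_jitter,
        seed=seed,
    )

    patient = SyntheticPatient(
        aorta=aorta,
        aorta_radius=cfg.aorta_radius_mm,
        renal_left=branches["left"],
        renal_right=branches["right"],
        renal_radii=radii,
        ostium_s=ostia,
        breathing=breathing,
        seed=int(seed),
        label=label or f"synthetic-{seed}",
    )
    for side, branch in patient.branches.items():
        gap = abs(aorta.distance_to(branch.points[0]) - cfg.aorta_radius_mm)
        if gap > 1e-6:
            raise InvalidConfigError(
                f"{side} branch root is {gap:.2e} mm off the aorta surface"
            )
    return patient
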