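"""Ordered 3-D vessel centerlines and their arc-length bookkeeping.

A :class:`Centerline` is the currency passed between every stage of the
pipeline: the synthetic generator emits them, the rod solver deforms them,
the morphometry and registration stages consume them.  Coordinates are in
millimetres in a right-handed patient frame (x = left-right, y =
antero-posterior, z = cranio-caudal, superior positive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError

_MIN_SPACING_MM = 1e-9


@dataclass
class Centerline:
    """Ordered 3-D polyline (mm) with an optional per-point radius (mm).

    Invariants enforced at construction: at least two points, consecutive
    points separated by more than 1e-9 mm, and a strictly positive arc
    length (the sum of segment lengths).
    """

    points: np.ndarray
    radii: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise InvalidInputError("centerline points must be an (n, 3) array")
        if len(self.points) < 2:
            raise InvalidInputError("centerline needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= _MIN_SPACING_MM):
            raise InvalidInputError("consecutive centerline points coincide")
        if self.radii is not None:
            self.radii = np.asarray(self.radii, dtype=float)
            if self.radii.shape != (len(self.points),):
                raise InvalidInputError("radii must match point count")

    # -- geometry ----------------------------------------------------------

    @property
    def n_points(self) -> int:
        return len(self.points)

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length per point, starting at 0."""
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths())])

    @property
    def length(self) -> float:
        return float(self.segment_lengths().sum())

    def point_at(self, s: float) -> np.ndarray:
        """Linearly interpolated point at arc length ``s``."""
        cum = self.arc_lengths()
        s = float(np.clip(s, 0.0, cum[-1]))
        return np.array(
            [np.interp(s, cum, self.points[:, k]) for k in range(3)]
        )

    def tangent_at(self, s: float) -> np.ndarray:
        """Unit tangent at arc length ``s`` (central difference, 0.5 mm)."""
        eps = min(0.5, self.length / 4)
        t = self.point_at(min(s + eps, self.length)) - self.point_at(max(s - eps, 0.0))
        return t / np.linalg.norm(t)

    def reversed(self) -> "Centerline":
        radii = None if self.radii is None else self.radii[::-1].copy()
        return Centerline(self.points[::-1].copy(), radii, dict(self.metadata))

    def distance_to(self, p: np.ndarray) -> float:
        """Minimum distance from point ``p`` to the polyline."""
        p = np.asarray(p, dtype=float)
        a = self.points[:-1]
        d = np.diff(self.points, axis=0)
        t = np.einsum("ij,ij->i", p - a, d) / np.einsum("ij,ij->i", d, d)
        proj = a + np.clip(t, 0.0, 1.0)[:, None] * d
        return float(np.linalg.norm(proj - p, axis=1).min())

    # -- resampling --------------------------------------------------------

    def resample(self, spacing_mm: float) -> "Centerline":
        """Resample at uniform arc-length ``spacing_mm``.

        Points sit at 0, spacing, 2*spacing, ...; the original endpoint is
        always kept, so the final interval may be shorter than ``spacing_mm``.
        """
        if spacing_mm <= 0:
            raise InvalidConfigError("spacing must be positive")
        total = self.length
        if spacing_mm >= total:
            raise InvalidConfigError(
                f"spacing {spacing_mm} mm >= arc length {total:.3f} mm"
            )
        stations = list(np.arange(0.0, total, spacing_mm))
        if total - stations[-1] > _MIN_SPACING_MM:
            stations.append(total)
        return self._at_stations(np.array(stations))

    def resample_count(self, n: int) -> "Centerline":
        """Resample to ``n`` arc-length-proportional points, endpoints kept."""
        if n < 2:
            raise InvalidConfigError("need at least 2 points")
        return self._at_stations(np.linspace(0.0, self.length, n))

    def _at_stations(self, stations: np.ndarray) -> "Centerline":
        cum = self.arc_lengths()
        pts = np.column_stack(
            [np.interp(stations, cum, self.points[:, k]) for k in range(3)]
        )
        # endpoints preserved exactly, not via interpolation rounding
        pts[0] = self.points[0]
        pts[-1] = self.points[-1]
        radii = None
        if self.radii is not None:
            radii = np.interp(stations, cum, self.radii)
        return Centerline(pts, radii, dict(self.metadata))

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        cols = {"x_mm": self.points[:, 0], "y_mm": self.points[:, 1], "z_mm": self.points[:, 2]}
        if self.radii is not None:
            cols["r_mm"] = self.radii
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Centerline":
        df = pd.read_csv(path)
        pts = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        radii = df["r_mm"].to_numpy(dtype=float) if "r_mm" in df.columns else None
        return cls(pts, radii)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "frame": "x=left-right, y=antero-posterior, z=cranio-caudal (mm)",
            "metadata": self.metadata,
            "points_mm": self.points.tolist(),
        }
        if self.radii is not None:
            payload["radii_mm"] = self.radii.tolist()
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Centerline":
        payload = json.loads(Path(path).read_text())
        return cls(
            np.array(payload["points_mm"], dtype=float),
            np.array(payload["radii_mm"], dtype=float) if "radii_mm" in payload else None,
            payload.get("metadata", {}),
        )
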