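"""Bridging stent-graft catalog, materials, rigidity, and deployment.

The catalog holds the commercially sized balloon-expandable covered stents
(Co-Cr stent + ePTFE graft) bridging an aortic-graft fenestration to each
renal artery: three lengths per artery (shorter / nominal / longer) for
two reference patients.  The composite bending rigidity of the stented
artery segment is reduced to a single rigidity ratio consumed by the rod
model, and deployment is represented geometrically as an arc-length
interval on the host branch with a flared aortic protrusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .centerline import Centerline
from .errors import DeploymentInfeasibleError, InvalidConfigError, OutOfValidityError

# unit note: moduli are stored in N/mm^2 (MPa); 1 GPa = 1000 N/mm^2, so
# rigidities E*I come out directly in N*mm^2


@dataclass(frozen=True)
class MaterialProperties:
    """Constituent material constants of the bridging stent-graft.

    Co-Cr stent: isotropic.  ePTFE graft: orthotropic lamina; E1 is the
    longitudinal modulus from uniaxial tension, the remaining constants
    from three-point-bending calibration.  Units: N/mm^2 (MPa) and mm.
    """

    stent_E: float = 268e3
    stent_nu: float = 0.3
    graft_E1: float = 1.2e3
    graft_E2: float = 1.8
    graft_nu12: float = 0.16
    graft_G12: float = 1.0
    graft_G13: float = 60.0
    graft_G23: float = 35.0
    graft_thickness: float = 0.2

    def __post_init__(self) -> None:
        moduli = (
            self.stent_E, self.graft_E1, self.graft_E2,
            self.graft_G12, self.graft_G13, self.graft_G23,
        )
        if any(m <= 0 for m in moduli) or self.graft_thickness < 0:
            raise InvalidConfigError("moduli must be positive, thickness non-negative")
        if not (0 < self.stent_nu < 0.5 and 0 < self.graft_nu12 < 0.5):
            raise InvalidConfigError("Poisson ratios must lie in (0, 0.5)")


@dataclass(frozen=True)
class StrutCrossSection:
    """Rectangular Co-Cr strut profile (mm)."""

    width: float = 0.115
    height: float = 0.145

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise InvalidConfigError("strut dimensions must be positive")

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def inertia(self) -> float:
        """Second moment about the strut's own bending axis (mm^4)."""
        return self.width * self.height**3 / 12.0


@dataclass(frozen=True)
class StentGraftSpec:
    """One catalog entry: a commercially sized bridging stent-graft."""

    patient: str  # "Patient 1" / "Patient 2"
    artery: str  # "RRA" / "LRA"
    size_class: str  # "shorter" / "nominal" / "longer"
    length_mm: float
    diameter_mm: float


_CATALOG_ROWS = [
    # patient, artery, class, length (mm), diameter (mm)
    ("Patient 1", "RRA", "nominal", 23, 7),
    ("Patient 1", "RRA", "shorter", 18, 7),
    ("Patient 1", "RRA", "longer", 27, 7),
    ("Patient 1", "LRA", "nominal", 22, 5),
    ("Patient 1", "LRA", "shorter", 18, 5),
    ("Patient 1", "LRA", "longer", 28, 5),
    ("Patient 2", "RRA", "nominal", 22, 6),
    ("Patient 2", "RRA", "shorter", 18, 6),
    ("Patient 2", "RRA", "longer", 28, 6),
    ("Patient 2", "LRA", "nominal", 22, 5),
    ("Patient 2", "LRA", "shorter", 18, 5),
    ("Patient 2", "LRA", "longer", 28, 5),
]

# protrusion of each deployed device past the ostium into the aortic lumen,
# as measured after simulated deployment in the two-patient study (mm)
_PROTRUSION_ROWS = {
    ("Patient 1", "RRA", "nominal"): 4.27,
    ("Patient 1", "LRA", "nominal"): 4.01,
    ("Patient 2", "RRA", "nominal"): 3.90,
    ("Patient 2", "LRA", "nominal"): 4.01,
    ("Patient 1", "RRA", "shorter"): 3.51,
    ("Patient 1", "LRA", "shorter"): 4.02,
    ("Patient 2", "RRA", "shorter"): 3.68,
    ("Patient 2", "LRA", "shorter"): 3.63,
    ("Patient 1", "RRA", "longer"): 4.27,
    ("Patient 1", "LRA", "longer"): 4.00,
    ("Patient 2", "RRA", "longer"): 4.01,
    ("Patient 2", "LRA", "longer"): 4.12,
}


def sg_catalog() -> list[StentGraftSpec]:
    """All 12 catalog entries (2 patients x 2 arteries x 3 size classes)."""
    return [StentGraftSpec(p, a, c, float(l), float(d)) for p, a, c, l, d in _CATALOG_ROWS]


def catalog_lookup(patient: str, artery: str, size_class: str) -> StentGraftSpec:
    for spec in sg_catalog():
        if (spec.patient, spec.artery, spec.size_class) == (patient, artery, size_class):
            return spec
    raise KeyError(f"no catalog entry for {(patient, artery, size_class)}")


def deployment_protrusions() -> dict[tuple, float]:
    """Measured aortic protrusion length (mm) per deployed catalog device."""
    return dict(_PROTRUSION_ROWS)


def catalog_to_csv(path: str | Path) -> None:
    pd.DataFrame(
        _CATALOG_ROWS,
        columns=["patient", "artery", "size_class", "length_mm", "diameter_mm"],
    ).to_csv(path, index=False)


def catalog_from_csv(path: str | Path) -> list[StentGraftSpec]:
    df = pd.read_csv(path)
    return [
        StentGraftSpec(r.patient, r.artery, r.size_class, float(r.length_mm), float(r.diameter_mm))
        for r in df.itertuples()
    ]


def effective_bending_rigidity(
    material: MaterialProperties,
    cross_section: StrutCrossSection,
    spec: StentGraftSpec,
    struts_per_ring: int,
    artery_rigidity: float,
) -> float:
    """Composite bending rigidity of the stented artery segment (N*mm^2).

    Sums three contributions about the tube axis's neutral plane:

    * the artery wall itself (``artery_rigidity``, an input);
    * ``struts_per_ring`` Co-Cr struts distributed around the tube at the
      stent radius: E_s * n * (I_strut + A_strut * r^2 / 2), the r^2/2
      factor being the mean squared neutral-axis offset of points evenly
      spaced on a circle of radius r;
    * the ePTFE graft as a thin-walled tube, E1 * pi * r^3 * t.

    Only the ratio of this value to ``artery_rigidity`` enters the rod
    model, so the strut count sets an order of magnitude, not a precise
    stiffness.
    """
    if struts_per_ring < 0 or (struts_per_ring != 0 and struts_per_ring < 2):
        raise InvalidConfigError("struts_per_ring must be 0 or >= 2")
    if artery_rigidity <= 0:
        raise InvalidConfigError("artery rigidity must be positive")
    r = spec.diameter_mm / 2.0
    stent = material.stent_E * struts_per_ring * (
        cross_section.inertia + cross_section.area * r**2 / 2.0
    )
    graft = material.graft_E1 * np.pi * r**3 * material.graft_thickness
    return float(artery_rigidity + stent + graft)


def three_point_bending_force(
    rigidity: float, span_mm: float, deflection_mm: float
) -> float:
    """Midspan force (N) of a simply supported beam at a given deflection.

    Linear-elastic only: deflections above 3 mm leave the validated regime
    (Co-Cr plasticity is not modeled) and raise :class:`OutOfValidityError`.
    """
    if span_mm <= 0:
        raise InvalidConfigError("span must be positive")
    if rigidity <= 0:
        raise InvalidConfigError("rigidity must be positive")
    if deflection_mm > 3.0:
        raise OutOfValidityError(
            "deflection beyond 3 mm enters the plastic regime, not modeled"
        )
    return 48.0 * rigidity * deflection_mm / span_mm**3


@dataclass
class DeployedSG:
    """A stent-graft realized on a renal branch centerline.

    Arc length is ostium-anchored: s = 0 at the ostium, negative values
    protrude into the aortic lumen.  The stent occupies [s_start, s_end],
    with s_end - s_start equal to the catalog length and
    protrusion_length = -s_start >= 0.
    """

    spec: StentGraftSpec
    host: Centerline
    s_start: float
    s_end: float
    flared_diameter_mm: float
    protrusion_length: float = field(init=False)

    def __post_init__(self) -> None:
        if abs((self.s_end - self.s_start) - self.spec.length_mm) > 1e-6:
            raise InvalidConfigError("stent interval must equal the spec length")
        if self.s_start > 1e-12:
            raise InvalidConfigError("stent must reach the ostium (s_start <= 0)")
        self.protrusion_length = -self.s_start

    @property
    def in_artery_length(self) -> float:
        return self.s_end


def deploy_geometric(
    branch: Centerline,
    spec: StentGraftSpec,
    protrusion_target_mm: float,
    fenestration_diameter_mm: float,
) -> DeployedSG:
    """Geometric deployment surrogate: place the stent on the branch.

    The device occupies [-protrusion, length - protrusion] in
    ostium-anchored arc length; its proximal end is flared to the
    fenestration diameter.  Balloon mechanics is not modeled.
    """
    if protrusion_target_mm < 0:
        raise InvalidConfigError("protrusion target must be non-negative")
    in_artery = spec.length_mm - protrusion_target_mm
    if in_artery > branch.length + 1e-9:
        raise DeploymentInfeasibleError(
            f"stent {spec.length_mm} mm with {protrusion_target_mm} mm protrusion "
            f"needs {in_artery} mm of artery; branch is {branch.length:.1f} mm"
        )
    return DeployedSG(
        spec=spec,
        host=branch,
        s_start=-protrusion_target_mm,
        s_end=in_artery,
        flared_diameter_mm=float(fenestration_diameter_mm),
    )
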