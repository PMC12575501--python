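"""Study orchestration: generate -> deploy -> breathe -> metrics -> validate.

Runs the full desk-scale study over a cohort of synthetic patients: for
each patient and renal branch, simulate breathing pre-EVAR and with each
of the three catalog stent-graft lengths (shorter / nominal / longer),
compute the morphometric deltas, check the protrusion criterion, and
validate the deployed geometry against a synthetic imaging surrogate with
ICP registration and the placement accuracy score.

Stages communicate through artifacts on disk (CSV/JSON), so each stage is
independently runnable and testable; :func:`run_study` simply executes
the stages in sequence on one output directory, which makes stage-wise
and monolithic execution identical by construction.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .centerline import Centerline
from .errors import MissingArtifactError
from .morpho import breathing_deltas, compute_metrics
from .registration import (
    ValidationConfig,
    centerline_distance,
    check_protrusions,
    icp,
    placement_accuracy_score,
)
from .rod import simulate_breathing
from .stents import DeployedSG, catalog_lookup, deploy_geometric
from .synthetic import PatientConfig, SyntheticPatient, generate_patient

logger = logging.getLogger(__name__)

SIZE_CLASSES = ("shorter", "nominal", "longer")
_STREAM_PROTRUSION = 77
_STREAM_IMAGING = 88


@dataclass
class StudyConfig:
    """Everything needed to reproduce a study run, seeds included."""

    n_patients: int = 2
    seed: int = 42
    patient: PatientConfig = field(default_factory=PatientConfig)
    artery_rigidity: float = 100.0  # N*mm^2
    struts_per_ring: int = 6
    protrusion_range_mm: tuple = (3.6, 4.2)  # clinical nominal band
    fenestration_oversize_mm: float = 1.0
    branching_window_mm: float = 20.0
    fit_window_mm: float = 5.0
    n_corresponding: int = 100
    tolerance_mm: float = 3.0
    imaging_noise_amp_mm: float = 2.0
    sg_classes: tuple = SIZE_CLASSES

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        patient = PatientConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("patient", {}).items()
        })
        raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        return cls(patient=patient, **raw)


@dataclass
class StudyReport:
    """The three result tables of one study run."""

    distance_table: pd.DataFrame  # per-artery distance stats + score
    protrusion_table: pd.DataFrame  # per-deployment protrusion + band check
    delta_table: pd.DataFrame  # per-configuration breathing deltas

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.distance_table.to_csv(out / "distance_table.csv", index=False)
        self.protrusion_table.to_csv(out / "protrusion_table.csv", index=False)
        self.delta_table.to_csv(out / "delta_table.csv", index=False)
        (out / "report.json").write_text(
            json.dumps(
                {
                    "distance": self.distance_table.to_dict(orient="records"),
                    "protrusion": self.protrusion_table.to_dict(orient="records"),
                    "deltas": self.delta_table.to_dict(orient="records"),
                },
                indent=1,
            )
        )


# -- helpers ---------------------------------------------------------------


def _patient_dir(out: Path, i: int) -> Path:
    return out / "patients" / f"patient_{i:03d}"


def _catalog_patient(i: int) -> str:
    return "Patient 1" if i % 2 == 0 else "Patient 2"


_ARTERY = {"left": "LRA", "right": "RRA"}


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing artifact {path}; run the '{producer}' stage first"
        )
    return path


def _perturbed_imaging_surrogate(
    line: Centerline, amp_mm: float, seed: int
) -> Centerline:
    """Synthetic stand-in for a post-op imaged centerline.

    Applies a smooth seeded deformation of amplitude ``amp_mm`` plus a
    rigid offset; real segmentations additionally carry voxelization and
    topology artifacts that this surrogate does not emulate.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAM_IMAGING,)))
    u = line.arc_lengths() / line.length
    d1 = rng.normal(size=3)
    d1 /= np.linalg.norm(d1)
    d2 = rng.normal(size=3)
    d2 /= np.linalg.norm(d2)
    disp = (
        amp_mm * np.sin(np.pi * u)[:, None] * d1[None, :]
        + 0.5 * amp_mm * np.sin(2 * np.pi * u)[:, None] * d2[None, :]
    )
    pts = line.points + disp
    # rigid offset removed later by the ICP step
    angle = np.radians(8.0)
    R = np.array(
        [
            [np.cos(angle), -np.sin(angle), 0.0],
            [np.sin(angle), np.cos(angle), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    pts = pts @ R.T + np.array([5.0, -3.0, 2.0])
    return Centerline(pts, metadata={"kind": "imaging_surrogate", "seed": int(seed)})


# -- stages ----------------------------------------------------------------


def stage_generate(config: StudyConfig, out_dir: str | Path) -> list[SyntheticPatient]:
    """Generate the synthetic cohort and write its geometry artifacts."""
    out = Path(out_dir)
    patients = []
    for i in range(config.n_patients):
        seed_i = int(config.seed) + i
        patient = generate_patient(seed_i, config.patient, label=f"SP{i + 1}")
        pdir = _patient_dir(out, i)
        pdir.mkdir(parents=True, exist_ok=True)
        patient.aorta.to_csv(pdir / "aorta.csv")
        patient.renal_left.to_csv(pdir / "renal_left.csv")
        patient.renal_right.to_csv(pdir / "renal_right.csv")
        (pdir / "breathing.json").write_text(
            json.dumps(
                {
                    "displacements_mm": {
                        k: v.tolist() for k, v in patient.breathing.displacements.items()
                    },
                    "fixed_aorta_ends": patient.breathing.fixed_aorta_ends,
                },
                indent=1,
            )
        )
        (pdir / "meta.json").write_text(
            json.dumps(
                {
                    "label": patient.label,
                    "seed": seed_i,
                    "catalog_patient": _catalog_patient(i),
                    "aorta_radius_mm": patient.aorta_radius,
                    "ostium_s_mm": patient.ostium_s,
                    "renal_radii_mm": patient.renal_radii,
                },
                indent=1,
            )
        )
        logger.info("generated %s (seed %d)", patient.label, seed_i)
        patients.append(patient)
    return patients


def _load_patients(config: StudyConfig, out: Path) -> list[tuple[SyntheticPatient, dict]]:
    from .synthetic import BreathingBC

    patients = []
    for i in range(config.n_patients):
        pdir = _patient_dir(out, i)
        _require(pdir / "aorta.csv", "generate")
        meta = json.loads((pdir / "meta.json").read_text())
        breathing_raw = json.loads((pdir / "breathing.json").read_text())
        patient = SyntheticPatient(
            aorta=Centerline.from_csv(pdir / "aorta.csv"),
            aorta_radius=meta["aorta_radius_mm"],
            renal_left=Centerline.from_csv(pdir / "renal_left.csv"),
            renal_right=Centerline.from_csv(pdir / "renal_right.csv"),
            renal_radii=meta["renal_radii_mm"],
            ostium_s=meta["ostium_s_mm"],
            breathing=BreathingBC(
                displacements={
                    k: np.array(v) for k, v in breathing_raw["displacements_mm"].items()
                },
                fixed_aorta_ends=breathing_raw["fixed_aorta_ends"],
            ),
            seed=meta["seed"],
            label=meta["label"],
        )
        patients.append((patient, meta))
    return patients


def stage_deploy(config: StudyConfig, out_dir: str | Path) -> None:
    """Deploy all three catalog size classes on every renal branch."""
    out = Path(out_dir)
    for i, (patient, meta) in enumerate(_load_patients(config, out)):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(meta["seed"]), spawn_key=(_STREAM_PROTRUSION,))
        )
        ddir = out / "deployments" / f"patient_{i:03d}"
        ddir.mkdir(parents=True, exist_ok=True)
        for side, branch in patient.branches.items():
            for size_class in config.sg_classes:
                spec = catalog_lookup(meta["catalog_patient"], _ARTERY[side], size_class)
                protrusion = float(rng.uniform(*config.protrusion_range_mm))
                sg = deploy_geometric(
                    branch,
                    spec,
                    protrusion,
                    spec.diameter_mm + config.fenestration_oversize_mm,
                )
                (ddir / f"{side}_{size_class}.json").write_text(
                    json.dumps(
                        {
                            "spec": dataclasses.asdict(spec),
                            "s_start": sg.s_start,
                            "s_end": sg.s_end,
                            "flared_diameter_mm": sg.flared_diameter_mm,
                            "protrusion_length_mm": sg.protrusion_length,
                        },
                        indent=1,
                    )
                )


def _load_deployed(config: StudyConfig, out: Path, i: int, patient: SyntheticPatient) -> dict:
    from .stents import StentGraftSpec

    ddir = out / "deployments" / f"patient_{i:03d}"
    deployed = {}
    for side, branch in patient.branches.items():
        for size_class in config.sg_classes:
            path = _require(ddir / f"{side}_{size_class}.json", "deploy")
            raw = json.loads(path.read_text())
            deployed[(side, size_class)] = DeployedSG(
                spec=StentGraftSpec(**raw["spec"]),
                host=branch,
                s_start=raw["s_start"],
                s_end=raw["s_end"],
                flared_diameter_mm=raw["flared_diameter_mm"],
            )
    return deployed


def stage_breathe(config: StudyConfig, out_dir: str | Path) -> None:
    """Run the breathing equilibria pre-EVAR and for each stented class."""
    out = Path(out_dir)
    for i, (patient, meta) in enumerate(_load_patients(config, out)):
        deployed = _load_deployed(config, out, i, patient)
        bdir = out / "breathing" / f"patient_{i:03d}"
        bdir.mkdir(parents=True, exist_ok=True)
        configurations = {"pre_evar": None}
        for size_class in config.sg_classes:
            configurations[size_class] = {
                side: deployed[(side, size_class)] for side in patient.branches
            }
        for name, dep in configurations.items():
            insp, expi = simulate_breathing(
                patient, dep, patient.breathing, artery_rigidity=config.artery_rigidity
            )
            for side in patient.branches:
                insp[side].to_csv(bdir / f"{side}_{name}_inspiration.csv")
                expi[side].to_csv(bdir / f"{side}_{name}_expiration.csv")


def stage_metrics(config: StudyConfig, out_dir: str | Path) -> pd.DataFrame:
    """Morphometric deltas per (patient, artery, configuration)."""
    out = Path(out_dir)
    rows = []
    for i, (patient, meta) in enumerate(_load_patients(config, out)):
        deployed = _load_deployed(config, out, i, patient)
        bdir = out / "breathing" / f"patient_{i:03d}"
        for side in patient.branches:
            for name in ("pre_evar",) + tuple(config.sg_classes):
                sg = deployed.get((side, name))
                insp_path = _require(bdir / f"{side}_{name}_inspiration.csv", "breathe")
                expi_path = _require(bdir / f"{side}_{name}_expiration.csv", "breathe")
                labels = {
                    "patient": patient.label,
                    "artery": _ARTERY[side],
                    "configuration": name,
                }
                m_insp = compute_metrics(
                    patient.aorta,
                    Centerline.from_csv(insp_path),
                    deployed_sg=sg,
                    fit_window_mm=config.fit_window_mm,
                    branching_window_mm=config.branching_window_mm,
                    **labels,
                )
                m_expi = compute_metrics(
                    patient.aorta,
                    Centerline.from_csv(expi_path),
                    deployed_sg=sg,
                    fit_window_mm=config.fit_window_mm,
                    branching_window_mm=config.branching_window_mm,
                    **labels,
                )
                delta = breathing_deltas(m_insp, m_expi)
                rows.append(
                    {
                        "patient": patient.label,
                        "artery": _ARTERY[side],
                        "configuration": name,
                        "sg_length_mm": None if sg is None else sg.spec.length_mm,
                        "sg_diameter_mm": None if sg is None else sg.spec.diameter_mm,
                        "d_branching_angle_deg": delta.d_branching_angle_deg,
                        "d_end_stent_angle_deg": delta.d_end_stent_angle_deg,
                        "d_max_curvature_per_mm": delta.d_max_curvature_per_mm,
                    }
                )
    mdir = out / "metrics"
    mdir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(rows)
    df.to_csv(mdir / "deltas.csv", index=False)
    return df


def stage_validate(config: StudyConfig, out_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distance/score validation and the protrusion criterion."""
    out = Path(out_dir)
    vcfg = ValidationConfig(tolerance_mm=config.tolerance_mm)
    dist_rows, prot_rows = [], []
    for i, (patient, meta) in enumerate(_load_patients(config, out)):
        deployed = _load_deployed(config, out, i, patient)
        bdir = out / "breathing" / f"patient_{i:03d}"
        for side in patient.branches:
            # distance validation on the nominal deployed configuration,
            # against a synthetic imaging surrogate
            sim_path = _require(bdir / f"{side}_nominal_inspiration.csv", "breathe")
            sim = Centerline.from_csv(sim_path)
            surrogate = _perturbed_imaging_surrogate(
                sim, config.imaging_noise_amp_mm, meta["seed"] * 100 + (0 if side == "left" else 1)
            )
            transform, history = icp(surrogate.points, sim.points)
            registered = Centerline(transform.apply(surrogate.points))
            profile = centerline_distance(sim, registered, config.n_corresponding)
            report = placement_accuracy_score(profile, vcfg.tolerance_mm)
            dist_rows.append(
                {
                    "patient": patient.label,
                    "artery": _ARTERY[side],
                    "mean_mm": profile.mean,
                    "std_mm": profile.std,
                    "max_mm": profile.max,
                    "score_pct": report.accuracy_score,
                    "icp_final_rms_mm": history[-1],
                }
            )
            for size_class in config.sg_classes:
                sg = deployed[(side, size_class)]
                lo, hi = vcfg.protrusion_band_mm
                prot_rows.append(
                    {
                        "patient": patient.label,
                        "artery": _ARTERY[side],
                        "size_class": size_class,
                        "protrusion_mm": sg.protrusion_length,
                        "in_band": bool(lo <= sg.protrusion_length <= hi),
                    }
                )
    vdir = out / "validation"
    vdir.mkdir(parents=True, exist_ok=True)
    dist = pd.DataFrame(dist_rows)
    prot = pd.DataFrame(prot_rows)
    dist.to_csv(vdir / "distance.csv", index=False)
    prot.to_csv(vdir / "protrusion.csv", index=False)
    return dist, prot


def stage_report(config: StudyConfig, out_dir: str | Path) -> StudyReport:
    """Assemble the three result tables from stage artifacts."""
    out = Path(out_dir)
    deltas = pd.read_csv(_require(out / "metrics" / "deltas.csv", "metrics"))
    dist = pd.read_csv(_require(out / "validation" / "distance.csv", "validate"))
    prot = pd.read_csv(_require(out / "validation" / "protrusion.csv", "validate"))
    summary = check_protrusions(list(prot["protrusion_mm"]), ValidationConfig(config.tolerance_mm))
    logger.info(
        "mean protrusion %.2f mm (reference %.2f mm), all in band: %s",
        summary["mean_mm"],
        summary["reference_mm"],
        summary["all_pass"],
    )
    report = StudyReport(dist, prot, deltas)
    report.write(out / "report")
    return report


def run_study(config: StudyConfig, out_dir: str | Path) -> StudyReport:
    """Run the whole study: all stages in order on one output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "study_config.yaml")
    stage_generate(config, out)
    stage_deploy(config, out)
    stage_breathe(config, out)
    stage_metrics(config, out)
    stage_validate(config, out)
    return stage_report(config, out)
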