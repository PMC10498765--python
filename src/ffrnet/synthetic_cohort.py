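"""Parametric synthetic coronary cohorts.

Trees are rooted binary trees whose daughter diameters obey the Murray
relation D_parent^m = Σ D_daughter^m (exponent m = 3 by default) with a
random asymmetry ratio, segment lengths proportional to diameter, and
branching stopped below the 1 mm reconstruction limit. Each cohort vessel
carries one graded stenosis and a physiology draw centred on the clinical
cohort statistics (mean blood pressure ≈ 95 mmHg, cardiac output
4.2 ± 1.6 L/min, heart rate 68 ± 24 bpm, myocardial mass 142.5 ± 46.6 g).

The reference ("invasive") FFR of each vessel is the exact linear-model
FFR computed with the direct network solve, plus additive Gaussian noise
on the FFR scale (default sd 0.02, the order of wire-measurement error),
clipped to (0, 1]. Everything is driven by one seed and is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bc_solver import SolverSettings
from .errors import DomainError
from .ffr import ffr_u
from .tree_model import (CoronaryTree, PatientPhysiology, Segment, Stenosis,
                         validate_tree, write_tree)


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of the synthetic cohort."""

    n_vessels: int = 86
    seed: int = 0
    depth_range: tuple[int, int] = (3, 5)
    root_diameter_range_mm: tuple[float, float] = (3.0, 4.5)
    murray_exponent: float = 3.0
    asymmetry_range: tuple[float, float] = (0.6, 1.0)
    length_diameter_ratio: float = 8.0
    min_diameter_mm: float = 1.0
    severity_range: tuple[float, float] = (0.2, 0.8)
    lesion_length_mm: float = 5.0
    noise_sd: float = 0.02
    stenosis_model: str = "linear"

    def __post_init__(self) -> None:
        if self.n_vessels < 1:
            raise DomainError("n_vessels must be >= 1")
        lo, hi = self.severity_range
        if not (0 < lo <= hi < 1):
            raise DomainError("severity range must lie inside (0, 1)")
        if self.noise_sd < 0:
            raise DomainError("noise sd must be >= 0")


@dataclass
class CohortVessel:
    vessel_id: str
    patient_id: str
    tree: CoronaryTree
    physiology: PatientPhysiology
    severity: float
    reference_ffr: float
    oracle_ffr: float


@dataclass
class Cohort:
    spec: CohortSpec
    vessels: list[CohortVessel] = field(default_factory=list)

    def physiology_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"vessel_id": v.vessel_id, "patient_id": v.patient_id,
             "p_systolic": v.physiology.p_systolic,
             "p_diastolic": v.physiology.p_diastolic,
             "cardiac_output": v.physiology.cardiac_output,
             "heart_rate": v.physiology.heart_rate,
             "myocardial_mass": v.physiology.myocardial_mass}
            for v in self.vessels])

    def reference_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"vessel_id": v.vessel_id, "patient_id": v.patient_id,
             "severity": v.severity, "reference_ffr": v.reference_ffr,
             "oracle_ffr": v.oracle_ffr}
            for v in self.vessels])

    def write(self, outdir: str | Path) -> dict:
        """Write trees/*.json + physiology.csv + reference.csv + manifest."""
        outdir = Path(outdir)
        (outdir / "trees").mkdir(parents=True, exist_ok=True)
        paths = []
        for v in self.vessels:
            p = outdir / "trees" / f"{v.vessel_id}.json"
            write_tree(v.tree, p, units="mm")
            paths.append(p)
        phys_path = outdir / "physiology.csv"
        ref_path = outdir / "reference.csv"
        self.physiology_frame().to_csv(phys_path, index=False)
        self.reference_frame().to_csv(ref_path, index=False)
        paths += [phys_path, ref_path]
        manifest = {
            "n_vessels": len(self.vessels), "seed": self.spec.seed,
            "files": {str(p.relative_to(outdir)):
                      hashlib.sha256(p.read_bytes()).hexdigest() for p in paths},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return manifest


def generate_tree(seed: int, spec: CohortSpec | None = None) -> CoronaryTree:
    """One random Murray-law binary tree; deterministic for a fixed seed."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed)
    return _generate_tree(rng, spec)


def _generate_tree(rng: np.random.Generator, spec: CohortSpec) -> CoronaryTree:
    m = spec.murray_exponent
    depth = int(rng.integers(spec.depth_range[0], spec.depth_range[1] + 1))
    d_root = rng.uniform(*spec.root_diameter_range_mm) * 1e-3
    min_d = spec.min_diameter_mm * 1e-3
    segments: dict[str, Segment] = {}

    def grow(sid: str, parent: str | None, d: float, level: int) -> None:
        segments[sid] = Segment(id=sid, parent=parent,
                                length=spec.length_diameter_ratio * d,
                                d_prox=d, d_dist=d)
        if level >= depth:
            return
        gamma = rng.uniform(*spec.asymmetry_range)  # D_minor / D_major
        d_major = d / (1.0 + gamma ** m) ** (1.0 / m)
        d_minor = gamma * d_major
        if d_minor < min_d:  # below the reconstruction limit: stop branching
            return
        grow(sid + "0", sid, d_major, level + 1)
        grow(sid + "1", sid, d_minor, level + 1)

    grow("R", None, d_root, 0)
    return CoronaryTree(segments=segments, metadata={"name": "synthetic"})


def _draw_physiology(rng: np.random.Generator) -> PatientPhysiology:
    p_dia = float(np.clip(rng.normal(80.0, 8.0), 55.0, 100.0))
    pulse = float(np.clip(rng.normal(45.0, 10.0), 20.0, 80.0))
    return PatientPhysiology(
        p_systolic=p_dia + pulse, p_diastolic=p_dia,
        cardiac_output=float(np.clip(rng.normal(4.2, 1.6), 2.0, 8.0)),
        heart_rate=float(np.clip(rng.normal(68.0, 24.0), 45.0, 110.0)),
        myocardial_mass=float(np.clip(rng.normal(142.5, 46.6), 60.0, 260.0)),
    )


def _place_stenosis(rng: np.random.Generator, tree: CoronaryTree,
                    spec: CohortSpec) -> Stenosis:
    lesion_len = spec.lesion_length_mm * 1e-3
    candidates = [s for s in tree.segments.values() if s.length > 2.0 * lesion_len]
    if not candidates:
        candidates = sorted(tree.segments.values(), key=lambda s: -s.length)[:1]
        lesion_len = candidates[0].length / 3.0
    seg = candidates[int(rng.integers(len(candidates)))]
    start = float(rng.uniform(0.1, 0.5)) * (seg.length - lesion_len)
    severity = float(rng.uniform(*spec.severity_range))
    ref_d = seg.healthy_diameter(start + lesion_len / 2.0)
    return Stenosis(segment=seg.id, start=start, length=lesion_len,
                    severity=severity, ref_diameter=ref_d)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate ``spec.n_vessels`` stenosed vessels with noisy reference FFR.

    Ground truth is the exact direct linear solve of the full pipeline;
    noise sd 0 makes the reference equal the oracle exactly.
    """
    rng = np.random.default_rng(spec.seed)
    settings = SolverSettings(stenosis_model=spec.stenosis_model)
    cohort = Cohort(spec=spec)
    for i in range(spec.n_vessels):
        while True:
            tree = _generate_tree(rng, spec)
            stenosis = _place_stenosis(rng, tree, spec)
            tree = tree.with_stenoses([stenosis])
            if not validate_tree(tree):
                break
        physiology = _draw_physiology(rng)
        oracle = ffr_u(tree, physiology, settings=settings, flow_solver="direct")[0].ffr
        noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
        reference = float(np.clip(oracle + noise, 1e-6, 1.0))
        cohort.vessels.append(CohortVessel(
            vessel_id=f"V{i:03d}", patient_id=f"P{i:03d}", tree=tree,
            physiology=physiology, severity=stenosis.severity,
            reference_ffr=reference, oracle_ffr=oracle))
    return cohort
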