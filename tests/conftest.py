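import math

import pytest

from ffrnet import (BloodProperties, CoronaryTree, PatientPhysiology, Segment,
                    Stenosis)
from ffrnet.units import MMHG_S_ML_TO_SI


def vessel_with_resistance(r_mmhg_s_ml: float, d: float = 0.003,
                           sid: str = "root", parent: str | None = None,
                           viscosity: float = 0.0035) -> Segment:
    """Uniform segment whose Poiseuille resistance is exactly the given
    clinical value (mmHg·s/mL), by choosing the length."""
    area = math.pi * d * d / 4.0
    length = r_mmhg_s_ml * MMHG_S_ML_TO_SI * area * area / (8 * math.pi * viscosity)
    return Segment(id=sid, length=length, d_prox=d, d_dist=d, parent=parent)


@pytest.fixture
def blood() -> BloodProperties:
    return BloodProperties()


@pytest.fixture
def single_vessel() -> CoronaryTree:
    """One uniform 3 mm × 30 mm vessel."""
    seg = Segment(id="root", length=0.03, d_prox=0.003, d_dist=0.003)
    return CoronaryTree(segments={"root": seg})


@pytest.fixture
def symmetric_bifurcation() -> CoronaryTree:
    """Root 4 mm vessel splitting into two identical 3 mm daughters."""
    segs = {
        "root": Segment(id="root", length=0.02, d_prox=0.004, d_dist=0.004),
        "L": Segment(id="L", length=0.03, d_prox=0.003, d_dist=0.003, parent="root"),
        "R": Segment(id="R", length=0.03, d_prox=0.003, d_dist=0.003, parent="root"),
    }
    return CoronaryTree(segments=segs)


@pytest.fixture
def asymmetric_tree() -> CoronaryTree:
    """Three-level tree with unequal daughters and a long LAD-like branch."""
    segs = {
        "root": Segment(id="root", length=0.015, d_prox=0.004, d_dist=0.0038),
        "lad": Segment(id="lad", length=0.04, d_prox=0.0033, d_dist=0.0028, parent="root"),
        "lcx": Segment(id="lcx", length=0.03, d_prox=0.0027, d_dist=0.0024, parent="root"),
        "d1": Segment(id="d1", length=0.025, d_prox=0.0021, d_dist=0.0018, parent="lad"),
        "lad2": Segment(id="lad2", length=0.03, d_prox=0.0024, d_dist=0.002, parent="lad"),
    }
    return CoronaryTree(segments=segs)


@pytest.fixture
def physiology() -> PatientPhysiology:
    return PatientPhysiology(p_systolic=120, p_diastolic=80, cardiac_output=4.2,
                             heart_rate=68, myocardial_mass=142.5)


@pytest.fixture
def mid_lad_stenosis() -> Stenosis:
    """50% focal lesion in the middle of the 'lad' segment."""
    return Stenosis(segment="lad", start=0.01, length=0.005, severity=0.5,
                    ref_diameter=0.003)
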