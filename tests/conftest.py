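import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from rtqa.dicom_rt_io import StructureSet
from rtqa.synthetic import (
    DoseFieldSpec,
    PhantomSpec,
    make_dose_grid,
    make_structure,
)


@pytest.fixture
def box_structure():
    """20 mm cube centered at the origin, 2 mm slices."""
    return make_structure(
        PhantomSpec("BOX", (0.0, 0.0, 0.0), (20.0, 20.0, 20.0), 2.0),
        name="Box", roi_number=1,
    )


@pytest.fixture
def uniform_grid():
    """Uniform 20 Gy field on a 1 mm grid covering the 20 mm cube, with
    z planes aligned to the phantom slice centers."""
    return make_dose_grid(
        DoseFieldSpec("UNIFORM", {"level": 20.0}),
        origin=(-14.0, -14.0, -13.0),
        spacing=(1.0, 1.0),
        shape=(14, 29, 29),
        z_spacing=2.0,
    )


@pytest.fixture
def prostate_case(tmp_path):
    """A small synthetic prostate case written to genuine DICOM files."""
    from rtqa.dicom_rt_io import (
        PlanSummary,
        write_dose_grid,
        write_plan,
        write_structure_set,
    )

    from pydicom.uid import generate_uid

    bladder = make_structure(
        PhantomSpec("SPHERE", (0.0, 20.0, 0.0), (8.0,), 2.0), "Bladder", 1
    )
    rect = make_structure(
        PhantomSpec("CYLINDER", (0.0, -20.0, 0.0), (6.0, 16.0), 2.0), "rect", 2
    )
    ss = StructureSet([bladder, rect], patient_id="CASE1",
                      frame_of_reference=generate_uid())
    grid = make_dose_grid(
        DoseFieldSpec("SPHERICAL_FALLOFF",
                      {"center": (0.0, 0.0, 0.0), "peak": 78.0, "radius": 60.0}),
        origin=(-30.0, -30.0, -9.0),
        spacing=(2.0, 2.0),
        shape=(10, 31, 31),
        z_spacing=2.0,
        frame_of_reference=ss.frame_of_reference,
    )
    plan = PlanSummary(prescription_dose=78.0, fractions=39, plan_label="prost")
    paths = {
        "rtstruct": tmp_path / "rs.dcm",
        "rtdose": tmp_path / "rd.dcm",
        "rtplan": tmp_path / "rp.dcm",
    }
    write_structure_set(ss, paths["rtstruct"])
    write_dose_grid(grid, paths["rtdose"])
    write_plan(plan, paths["rtplan"], frame_of_reference=ss.frame_of_reference)
    return {"ss": ss, "grid": grid, "plan": plan, "paths": paths}


def random_phantom_and_field(rng):
    """One random (phantom, analytic dose field) pair on a small grid whose
    z planes match the phantom slice centers."""
    shape_kind = rng.choice(["BOX", "CYLINDER", "SPHERE"])
    t = 2.0
    if shape_kind == "BOX":
        dims = tuple(rng.uniform(8, 18, size=3).round(1))
        extent = dims[2]
    elif shape_kind == "CYLINDER":
        dims = (round(rng.uniform(4, 9), 1), float(rng.choice([8, 12, 16])))
        extent = dims[1]
    else:
        dims = (float(rng.choice([4, 6, 8])),)
        extent = 2 * dims[0]
    center = tuple(rng.uniform(-3, 3, size=3).round(1))
    spec = PhantomSpec(shape_kind, center, dims, t,
                       polygon_vertices=int(rng.integers(8, 33)))
    structure = make_structure(spec, "Rand", 1)

    kind = rng.choice(["UNIFORM", "LINEAR_X", "SPHERICAL_FALLOFF"])
    if kind == "UNIFORM":
        fspec = DoseFieldSpec("UNIFORM", {"level": float(rng.uniform(5, 70))})
    elif kind == "LINEAR_X":
        fspec = DoseFieldSpec("LINEAR_X", {"gradient": float(rng.uniform(0.05, 0.5)),
                                           "intercept": float(rng.uniform(20, 40))})
    else:
        fspec = DoseFieldSpec(
            "SPHERICAL_FALLOFF",
            {"center": tuple(rng.uniform(-5, 5, size=3)),
             "peak": float(rng.uniform(40, 80)),
             "radius": float(rng.uniform(40, 80))},
        )
    nz = int(round(extent / t)) + 2
    # offset grid so voxel centers rarely sit exactly on contour edges, but
    # z planes still align with slice centers
    z0 = center[2] - extent / 2 + t / 2 - t
    grid = make_dose_grid(
        fspec,
        origin=(center[0] - 12 + 0.25, center[1] - 12 + 0.25, z0),
        spacing=(1.5, 1.5),
        shape=(nz, 17, 17),
        z_spacing=t,
    )
    return structure, grid
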