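"""Synthetic phantoms, dose fields, and patient records.

Everything downstream is testable without clinical data because every object
generated here has an analytically known truth attached: phantom structures
carry the closed-form volume of the ideal solid, dose fields are sampled from
stated analytic functions, and records are drawn reproducibly from a seeded
generator and always validate cleanly against their template schemas.

Circles are discretized as regular polygons (default 64 vertices), so the
in-plane area deficit is the known regular n-gon factor
1 - (n / 2*pi) * sin(2*pi / n), under 0.2% at n = 64.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constraints import (
    ConstraintReport,
    ConstraintResult,
    DoseConstraint,
    Status,
)
from .dicom_rt_io import DoseGrid, PlanSummary, Structure
from .dvh import parse_metric
from .errors import ConfigurationError, DegeneratePhantomError, DomainError, UnknownFieldError
from .templates import (
    PatientRecord,
    Provenance,
    compute_nccn_risk,
    load_site_schemas,
)


class Shape:
    BOX = "BOX"
    CYLINDER = "CYLINDER"
    SPHERE = "SPHERE"


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric phantom: BOX dimensions=(sx, sy, sz); CYLINDER
    dimensions=(radius, height); SPHERE dimensions=(radius,). All mm."""

    shape: str
    center: tuple = (0.0, 0.0, 0.0)
    dimensions: tuple = ()
    slice_thickness: float = 2.0
    polygon_vertices: int = 64

    def __post_init__(self):
        if self.shape not in (Shape.BOX, Shape.CYLINDER, Shape.SPHERE):
            raise ConfigurationError(f"unknown phantom shape {self.shape}")
        if any(d <= 0 for d in self.dimensions) or not self.dimensions:
            raise ConfigurationError("all phantom dimensions must be > 0")
        if self.slice_thickness <= 0:
            raise ConfigurationError("slice_thickness must be > 0")
        if self.polygon_vertices < 8:
            raise ConfigurationError("polygon_vertices must be >= 8")

    @property
    def z_extent(self) -> float:
        if self.shape == Shape.BOX:
            return self.dimensions[2]
        if self.shape == Shape.CYLINDER:
            return self.dimensions[1]
        return 2.0 * self.dimensions[0]

    @property
    def analytic_volume_mm3(self) -> float:
        if self.shape == Shape.BOX:
            sx, sy, sz = self.dimensions
            return sx * sy * sz
        if self.shape == Shape.CYLINDER:
            r, h = self.dimensions
            return math.pi * r * r * h
        (r,) = self.dimensions
        return 4.0 / 3.0 * math.pi * r**3


def _ngon(cx: float, cy: float, radius: float, n: int, z: float) -> np.ndarray:
    theta = 2.0 * math.pi * np.arange(n) / n
    return np.column_stack([
        cx + radius * np.cos(theta),
        cy + radius * np.sin(theta),
        np.full(n, z),
    ])


def _rectangle(cx: float, cy: float, sx: float, sy: float, z: float) -> np.ndarray:
    hx, hy = sx / 2.0, sy / 2.0
    return np.array([
        [cx - hx, cy - hy, z],
        [cx + hx, cy - hy, z],
        [cx + hx, cy + hy, z],
        [cx - hx, cy + hy, z],
    ])


def make_structure(spec: PhantomSpec, name: str = "Phantom",
                   roi_number: int = 1) -> Structure:
    """Build per-slice closed polygons approximating the solid.

    Slices are centered on the solid's z extent at ``slice_thickness``
    spacing; sphere slice radii are evaluated at slice centers. The analytic
    volume of the ideal solid is attached as metadata.
    """
    cx, cy, cz = spec.center
    extent = spec.z_extent
    n_slices = int(round(extent / spec.slice_thickness))
    if n_slices < 1:
        raise DegeneratePhantomError(
            f"slice thickness {spec.slice_thickness} mm exceeds phantom "
            f"z extent {extent} mm"
        )
    z0 = cz - extent / 2.0 + spec.slice_thickness / 2.0
    contours = []
    for k in range(n_slices):
        z = z0 + k * spec.slice_thickness
        if spec.shape == Shape.BOX:
            sx, sy, _ = spec.dimensions
            contours.append(_rectangle(cx, cy, sx, sy, z))
        elif spec.shape == Shape.CYLINDER:
            r, _ = spec.dimensions
            contours.append(_ngon(cx, cy, r, spec.polygon_vertices, z))
        else:
            (r,) = spec.dimensions
            r_slice = math.sqrt(max(r * r - (z - cz) ** 2, 0.0))
            if r_slice <= 0:
                continue
            contours.append(_ngon(cx, cy, r_slice, spec.polygon_vertices, z))
    return Structure(
        name=name,
        roi_number=roi_number,
        contours=contours,
        meta={
            "analytic_volume_mm3": spec.analytic_volume_mm3,
            "phantom_shape": spec.shape,
            "slice_thickness": spec.slice_thickness,
        },
    )


# ---------------------------------------------------------------------------
# Dose fields
# ---------------------------------------------------------------------------

class FieldKind:
    UNIFORM = "UNIFORM"
    LINEAR_X = "LINEAR_X"
    SPHERICAL_FALLOFF = "SPHERICAL_FALLOFF"


@dataclass(frozen=True)
class DoseFieldSpec:
    """Analytic dose field.

    UNIFORM: parameters {level}. LINEAR_X: {gradient (Gy/mm), intercept}.
    SPHERICAL_FALLOFF: {center (x,y,z), peak, radius} — linear falloff from
    peak at the center to zero at ``radius``.
    """

    kind: str
    parameters: dict = field(default_factory=dict)

    def evaluate(self, x, y, z):
        p = self.parameters
        if self.kind == FieldKind.UNIFORM:
            return np.full(np.broadcast(x, y, z).shape, float(p["level"]))
        if self.kind == FieldKind.LINEAR_X:
            return p.get("intercept", 0.0) + p["gradient"] * np.asarray(x, float)
        if self.kind == FieldKind.SPHERICAL_FALLOFF:
            cx, cy, cz = p["center"]
            dist = np.sqrt(
                (np.asarray(x, float) - cx) ** 2
                + (np.asarray(y, float) - cy) ** 2
                + (np.asarray(z, float) - cz) ** 2
            )
            return p["peak"] * np.clip(1.0 - dist / p["radius"], 0.0, 1.0)
        raise ConfigurationError(f"unknown dose field kind {self.kind}")


def make_dose_grid(spec: DoseFieldSpec, origin: tuple, spacing: tuple,
                   shape: tuple, z_spacing: Optional[float] = None,
                   z_offsets=None, frame_of_reference: str = "") -> DoseGrid:
    """Sample an analytic dose field at voxel centers.

    ``shape`` is (nz, ny, nx). Provide either ``z_spacing`` (uniform planes)
    or explicit ``z_offsets``. Negative field values over the grid extent are
    a spec violation and raise.
    """
    nz, ny, nx = shape
    if z_offsets is None:
        if z_spacing is None:
            raise ConfigurationError("provide z_spacing or z_offsets")
        z_offsets = np.arange(nz) * float(z_spacing)
    z_offsets = np.asarray(z_offsets, dtype=float)
    xs = origin[0] + spacing[0] * np.arange(nx)
    ys = origin[1] + spacing[1] * np.arange(ny)
    zs = origin[2] + z_offsets
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    values = np.asarray(spec.evaluate(xx, yy, zz), dtype=float)
    if np.any(values < 0):
        raise DomainError("dose field is negative over the grid extent")
    return DoseGrid(
        origin=tuple(float(v) for v in origin),
        spacing=tuple(float(v) for v in spacing),
        z_offsets=z_offsets,
        values=values,
        frame_of_reference=frame_of_reference,
    )


# ---------------------------------------------------------------------------
# Patient records
# ---------------------------------------------------------------------------

_FIRST_NAMES = ["James", "Robert", "Mary", "Linda", "Walter", "Harold",
                "Dorothy", "Frank", "Evelyn", "Raymond"]
_LAST_NAMES = ["Smith", "Johnson", "Miller", "Davis", "Garcia", "Wilson",
               "Anderson", "Thomas", "Moore", "Clark"]


def _iso(year: int, day_of_year: int) -> str:
    import datetime
    d = datetime.date(year, 1, 1) + datetime.timedelta(days=int(day_of_year))
    return d.isoformat()


def _choice(rng, seq):
    return seq[int(rng.integers(0, len(seq)))]


def make_patient_record(disease_site: str, seed: int,
                        overrides: Optional[dict] = None,
                        patient_key: Optional[str] = None) -> PatientRecord:
    """Generate a full synthetic record chain (consult through follow-up).

    Values are drawn reproducibly from ``seed`` within the site's template
    schema ranges, so generated records always validate cleanly. ``overrides``
    forces stated field values (applied to whichever template declares the
    field); auto-calculated elements are recomputed afterwards so they stay
    consistent with their inputs. Overriding an unknown field raises.
    """
    site = disease_site.upper()
    bundle = load_site_schemas(site)
    schemas = bundle["schemas"]
    rng = np.random.default_rng(seed)
    key = patient_key or f"{site[:4]}-{seed:08d}"

    rec = PatientRecord(patient_key=key, disease_site=site)
    rec.identity = {
        "patient_name": f"{_choice(rng, _FIRST_NAMES)} {_choice(rng, _LAST_NAMES)}",
        "patient_mrn": f"{int(rng.integers(10**7, 10**8))}",
        "birth_date": _iso(int(rng.integers(1935, 1965)), int(rng.integers(0, 365))),
        "address": f"{int(rng.integers(1, 999))} Main Street",
        "phone": f"555-{int(rng.integers(1000, 9999))}",
        "sex": "M" if site == "PROSTATE" else _choice(rng, ["M", "F"]),
    }

    year = int(rng.integers(2018, 2021))
    consult_day = int(rng.integers(0, 200))

    def fill(tid, values, timestamp):
        for name, value in values.items():
            rec.set_field(tid, name, value)
        rec.encounters[tid].timestamp = timestamp

    if site == "PROSTATE":
        t_stage = _choice(rng, ["T1c", "T2a", "T2b", "T2c", "T3a"])
        gp = int(rng.integers(3, 6))
        gs = int(rng.integers(3, 6))
        psa = round(float(np.exp(rng.normal(2.0, 0.8))), 1)
        consult = {
            "consult_date": _iso(year, consult_day),
            "age": int(rng.integers(55, 86)),
            "ecog_performance_status": int(rng.integers(0, 3)),
            "t_stage": t_stage,
            "n_stage": "N0",
            "m_stage": "M0",
            "gleason_primary": gp,
            "gleason_secondary": gs,
            "psa": psa,
            "treatment_intent": "CURATIVE" if rng.random() < 0.9 else "PALLIATIVE",
            "prior_radiotherapy": bool(rng.random() < 0.05),
        }
        # ADT planning tracks risk: common for high-risk, uncommon otherwise
        risk_now = compute_nccn_risk(t_stage, gp, gs, psa)
        consult["hormone_therapy_planned"] = bool(
            rng.random() < (0.85 if risk_now == "HIGH" else 0.15)
        )
        if rng.random() < 0.7:
            consult["comorbidity"] = _choice(
                rng, ["hypertension", "diabetes mellitus", "COPD", "none"]
            )
        fill("CONSULT", consult, consult["consult_date"])
        sim = {
            "sim_date": _iso(year, consult_day + 10),
            "immobilization": _choice(rng, ["VACUUM_BAG", "KNEE_FOOT_LOCK"]),
            "ct_slice_thickness_mm": float(_choice(rng, [1.5, 2.0, 2.5, 3.0])),
            "bladder_filling": _choice(rng, ["FULL", "COMFORTABLY_FULL"]),
            "image_guidance": _choice(rng, ["CBCT", "FIDUCIALS"]),
        }
        fill("SIM_DIRECTIVE", sim, sim["sim_date"])
        otv = {
            "otv_date": _iso(year, consult_day + 30),
            "week_number": int(rng.integers(1, 6)),
            "toxicity_gu_grade": int(rng.integers(0, 3)),
            "toxicity_gi_grade": int(rng.integers(0, 3)),
            "weight_kg": round(float(rng.normal(85, 12)), 1),
        }
        fill("OTV", otv, otv["otv_date"])
        fractions = int(_choice(rng, [28, 39, 44]))
        dose = {28: 70.0, 39: 78.0, 44: 79.2}[fractions]
        eot = {
            "eot_date": _iso(year, consult_day + 80),
            "total_dose_gy": dose,
            "fractions_delivered": fractions,
            "treatment_completed": bool(rng.random() < 0.95),
            "toxicity_gu_grade": int(rng.integers(0, 4)),
            "toxicity_gi_grade": int(rng.integers(0, 4)),
        }
        fill("EOT", eot, eot["eot_date"])
        fu = {
            "followup_date": _iso(year, consult_day + 170),
            "psa": round(float(np.exp(rng.normal(-0.5, 0.7))), 2),
            "disease_status": "NED" if rng.random() < 0.9
            else "BIOCHEMICAL_RECURRENCE",
            "toxicity_gu_grade": int(rng.integers(0, 3)),
            "toxicity_gi_grade": int(rng.integers(0, 3)),
        }
        fill("FOLLOWUP", fu, fu["followup_date"])
    elif site == "LUNG":
        consult = {
            "consult_date": _iso(year, consult_day),
            "age": int(rng.integers(55, 86)),
            "ecog_performance_status": int(rng.integers(0, 3)),
            "t_stage": _choice(rng, ["T1b", "T1c", "T2a", "T2b", "T3", "T4"]),
            "n_stage": _choice(rng, ["N0", "N1", "N2"]),
            "m_stage": "M0",
            "histology": _choice(
                rng, ["ADENOCARCINOMA", "SQUAMOUS", "NSCLC_NOS"]
            ),
            "smoking_status": _choice(rng, ["CURRENT", "FORMER", "NEVER"]),
            "treatment_intent": "CURATIVE" if rng.random() < 0.85 else "PALLIATIVE",
            "prior_radiotherapy": bool(rng.random() < 0.05),
            "concurrent_chemotherapy_planned": bool(rng.random() < 0.6),
        }
        if rng.random() < 0.6:
            consult["fev1_pct_predicted"] = round(float(rng.uniform(40, 110)), 1)
        fill("CONSULT", consult, consult["consult_date"])
        sim = {
            "sim_date": _iso(year, consult_day + 10),
            "motion_management": _choice(
                rng, ["FOUR_D_CT", "BREATH_HOLD", "FREE_BREATHING"]
            ),
            "immobilization": _choice(rng, ["WING_BOARD", "VACUUM_BAG"]),
            "ct_slice_thickness_mm": float(_choice(rng, [1.0, 2.0, 2.5, 3.0])),
        }
        fill("SIM_DIRECTIVE", sim, sim["sim_date"])
        otv = {
            "otv_date": _iso(year, consult_day + 30),
            "week_number": int(rng.integers(1, 7)),
            "toxicity_esophagitis_grade": int(rng.integers(0, 3)),
            "toxicity_pneumonitis_grade": int(rng.integers(0, 2)),
            "weight_kg": round(float(rng.normal(75, 14)), 1),
        }
        fill("OTV", otv, otv["otv_date"])
        fractions = int(_choice(rng, [30, 33]))
        dose = {30: 60.0, 33: 66.0}[fractions]
        eot = {
            "eot_date": _iso(year, consult_day + 75),
            "total_dose_gy": dose,
            "fractions_delivered": fractions,
            "treatment_completed": bool(rng.random() < 0.93),
            "toxicity_esophagitis_grade": int(rng.integers(0, 4)),
            "toxicity_pneumonitis_grade": int(rng.integers(0, 3)),
        }
        fill("EOT", eot, eot["eot_date"])
        fu = {
            "followup_date": _iso(year, consult_day + 165),
            "disease_status": "NED" if rng.random() < 0.8
            else _choice(rng, ["LOCAL_RECURRENCE", "DISTANT_PROGRESSION"]),
            "imaging_response": _choice(rng, ["CR", "PR", "SD"]),
            "toxicity_pneumonitis_grade": int(rng.integers(0, 3)),
        }
        fill("FOLLOWUP", fu, fu["followup_date"])
    else:
        raise ConfigurationError(f"unsupported disease site {disease_site}")

    if overrides:
        field_home = {}
        for tid, schema in schemas.items():
            for fname in schema.field_map():
                field_home.setdefault(fname, tid)
        for name, value in overrides.items():
            if name not in field_home:
                raise UnknownFieldError(
                    f"override names unknown field '{name}' for site {site}"
                )
            # overrides target the earliest template declaring the field
            rec.set_field(field_home[name], name, value)

    # derived + auto-populated elements, recomputed after overrides
    if site == "PROSTATE":
        c = rec.encounters["CONSULT"].fields
        risk = compute_nccn_risk(
            c["t_stage"], c["gleason_primary"], c["gleason_secondary"], c["psa"]
        )
        rec.set_field("CONSULT", "nccn_risk_group", risk,
                      provenance=Provenance.AUTO_CALCULATED)
    from .templates import autopopulate
    autopopulate("EOT", rec, bundle["flows"], schemas)
    return rec


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortMember:
    practice_id: str
    record: PatientRecord
    plan: PlanSummary
    constraint_report: ConstraintReport


def _synthetic_report(rng, site: str) -> ConstraintReport:
    """A plausible constraint report without running a full DVH pipeline:
    statuses drawn PASS-heavy, on the structures the example rulesets read."""
    rows = {
        "PROSTATE": [("Rectum", "V70Gy", 25.0, 30.0), ("Bladder", "V70Gy", 30.0, 35.0)],
        "LUNG": [("Lungs", "V20Gy", 35.0, 37.0), ("SpinalCord", "Dmax", 45.0, 50.0)],
    }[site]
    report = ConstraintReport()
    for structure, metric, pass_lim, var_lim in rows:
        u = rng.random()
        if u < 0.85:
            status, value = Status.PASS, pass_lim * rng.uniform(0.5, 0.99)
        elif u < 0.95:
            status, value = Status.VARIATION, rng.uniform(pass_lim, var_lim)
        else:
            status, value = Status.FAIL, var_lim * rng.uniform(1.01, 1.3)
        c = DoseConstraint(
            structure=structure, metric=parse_metric(metric),
            comparator="LE", pass_limit=pass_lim, variation_limit=var_lim,
        )
        report.results.append(
            ConstraintResult(c, round(float(value), 2), status)
        )
    return report


def make_cohort(n: int, sites, seed: int,
                disease_site: str = "PROSTATE") -> list:
    """Reproducible cohort of (practice, record, plan, constraint report),
    partitioned round-robin across practice labels."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    sites = list(sites)
    if not sites:
        raise ConfigurationError("at least one practice label required")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        rec = make_patient_record(
            disease_site, sub_seed,
            patient_key=f"{disease_site[:4]}-{seed}-{i:05d}",
        )
        dose = rec.get_field("EOT", "total_dose_gy")
        fx = rec.get_field("EOT", "fractions_delivered")
        plan = PlanSummary(
            prescription_dose=float(dose), fractions=int(fx),
            plan_label=f"plan-{i:05d}",
        )
        report = _synthetic_report(rng, disease_site.upper())
        out.append(CohortMember(
            practice_id=sites[i % len(sites)],
            record=rec, plan=plan, constraint_report=report,
        ))
    return out
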