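"""Structure rasterization, cumulative DVHs, and dose-volume metrics.

Conventions (stated because planning systems disagree on them):

* Structures are rasterized **onto the dose grid** — the dose is never
  resampled. Membership is decided at voxel centers (``supersample=1``) or at
  an s-by-s lattice of sub-centers averaged into a fractional occupancy
  (``supersample=s``).
* A sample point belongs to a structure on a plane when the crossing-number
  parity over all of that plane's polygons is odd, or when the point lies on
  any polygon edge — boundary points count as inside. Multiple polygons on a
  plane therefore combine by the even-odd rule, so holes subtract.
* Metrics are computed from the exact occupancy-weighted voxel dose
  distribution, never from binned curves. Dx% uses the step convention: the
  dose of the voxel at which the cumulative hottest volume first reaches x%
  of the total. For two equal-volume dose levels at 10 and 30 Gy this gives
  D50% = 30 Gy (the hottest half is exactly the 30 Gy component).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dicom_rt_io import DoseGrid, Structure
from .errors import (
    DegenerateStructureError,
    DomainError,
    OutOfGridError,
    RtqaError,
    WiringError,
)

_EDGE_EPS = 1e-9  # mm tolerance for the on-edge test


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class StructureMask:
    """Per-voxel occupancy fractions of one structure on one dose grid."""

    structure_name: str
    occupancy: np.ndarray  # (nz, ny, nx) in [0, 1]
    voxel_volume: float  # mm^3
    grid_shape: tuple

    @property
    def volume_mm3(self) -> float:
        return float(self.occupancy.sum() * self.voxel_volume)


@dataclass
class DVHCurve:
    """Cumulative DVH: V(d) = percent of structure volume receiving >= d Gy.

    ``sorted_doses``/``weights`` retain the exact weighted voxel dose
    distribution (ascending dose order, weights in mm^3) so that metrics can
    be evaluated without binning error.
    """

    structure_name: str
    dose_edges: np.ndarray  # ascending Gy bin edges
    cum_volume_pct: np.ndarray  # V(d) evaluated at dose_edges
    total_volume_cc: float
    sorted_doses: np.ndarray = field(repr=False, default=None)
    weights: np.ndarray = field(repr=False, default=None)


class MetricKind:
    D_PCT = "D_PCT"
    D_CC = "D_CC"
    V_GY = "V_GY"
    DMEAN = "DMEAN"
    DMAX = "DMAX"
    DMIN = "DMIN"


class Unit:
    GY = "GY"
    PCT = "PCT"
    CC = "CC"


@dataclass(frozen=True)
class MetricSpec:
    kind: str
    argument: Optional[float] = None
    unit_out: Optional[str] = None

    def __post_init__(self):
        if self.kind in (MetricKind.D_PCT, MetricKind.D_CC, MetricKind.V_GY):
            if self.argument is None:
                raise DomainError(f"{self.kind} requires an argument")
        if self.kind == MetricKind.D_PCT:
            if not (0 < self.argument <= 100):
                raise DomainError("Dx% argument must be in (0, 100]")
        default_unit = {
            MetricKind.D_PCT: Unit.GY,
            MetricKind.D_CC: Unit.GY,
            MetricKind.V_GY: Unit.PCT,
            MetricKind.DMEAN: Unit.GY,
            MetricKind.DMAX: Unit.GY,
            MetricKind.DMIN: Unit.GY,
        }[self.kind]
        if self.unit_out is None:
            object.__setattr__(self, "unit_out", default_unit)

    def label(self) -> str:
        if self.kind == MetricKind.D_PCT:
            return f"D{_fmt(self.argument)}%"
        if self.kind == MetricKind.D_CC:
            return f"D{_fmt(self.argument)}cc"
        if self.kind == MetricKind.V_GY:
            return f"V{_fmt(self.argument)}Gy"
        return {"DMEAN": "Dmean", "DMAX": "Dmax", "DMIN": "Dmin"}[self.kind]


def _fmt(x: float) -> str:
    return f"{x:g}"


def parse_metric(text: str) -> MetricSpec:
    """Parse a metric string such as ``"D2%"``, ``"D0.03cc"``, ``"V70Gy"``,
    ``"Dmean"``, ``"Dmax"`` or ``"Dmin"``."""
    s = text.strip()
    low = s.lower()
    if low == "dmean":
        return MetricSpec(MetricKind.DMEAN)
    if low == "dmax":
        return MetricSpec(MetricKind.DMAX)
    if low == "dmin":
        return MetricSpec(MetricKind.DMIN)
    try:
        if low.startswith("d") and low.endswith("%"):
            return MetricSpec(MetricKind.D_PCT, float(s[1:-1]))
        if low.startswith("d") and low.endswith("cc"):
            return MetricSpec(MetricKind.D_CC, float(s[1:-2]))
        if low.startswith("v") and low.endswith("gy"):
            return MetricSpec(MetricKind.V_GY, float(s[1:-2]))
    except ValueError:
        pass
    raise DomainError(f"unrecognized metric string: {text!r}")


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _points_in_polygons(px: np.ndarray, py: np.ndarray, polygons) -> np.ndarray:
    """Membership of points under the stated convention: odd crossing-number
    parity over all polygons, or on any polygon edge."""
    inside = np.zeros(px.shape, dtype=bool)
    boundary = np.zeros(px.shape, dtype=bool)
    for poly in polygons:
        xs = poly[:, 0]
        ys = poly[:, 1]
        n = len(xs)
        for i in range(n):
            x1, y1 = xs[i], ys[i]
            x2, y2 = xs[(i + 1) % n], ys[(i + 1) % n]
            # on-edge test: zero cross product and inside the segment bbox
            cross = (px - x1) * (y2 - y1) - (py - y1) * (x2 - x1)
            seg_len = max(abs(x2 - x1), abs(y2 - y1), 1.0)
            on_seg = (
                (np.abs(cross) <= _EDGE_EPS * seg_len)
                & (px >= min(x1, x2) - _EDGE_EPS)
                & (px <= max(x1, x2) + _EDGE_EPS)
                & (py >= min(y1, y2) - _EDGE_EPS)
                & (py <= max(y1, y2) + _EDGE_EPS)
            )
            boundary |= on_seg
            # crossing-number rule (half-open in y)
            crossing = (y1 > py) != (y2 > py)
            if np.any(crossing):
                with np.errstate(divide="ignore", invalid="ignore"):
                    x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
                inside ^= crossing & (px < x_int)
    return inside | boundary


def rasterize(structure: Structure, grid: DoseGrid, supersample: int = 1,
              frame_check: bool = True) -> StructureMask:
    """Rasterize ``structure`` onto ``grid``'s voxel lattice.

    Each contour is assigned to the nearest grid z-plane; a contour farther
    than half the median plane spacing from every plane raises
    :class:`OutOfGridError`. ``supersample=s`` samples an s-by-s lattice of
    sub-centers per voxel and averages, producing fractional occupancy.
    """
    if supersample < 1:
        raise DomainError("supersample must be >= 1")
    structure.validate()
    if frame_check and structure.meta.get("frame_of_reference") and \
            grid.frame_of_reference and \
            structure.meta["frame_of_reference"] != grid.frame_of_reference:
        raise WiringError("structure and grid frames of reference differ")

    nz, ny, nx = grid.shape
    z_planes = grid.z_centers()
    if len(z_planes) > 1:
        tol = 0.5 * float(np.median(np.diff(z_planes)))
        dz = float(np.median(np.diff(z_planes)))
    else:
        tol = float("inf")
        dz = 1.0
    dx, dy = grid.spacing

    by_plane: dict = {}
    for c_idx, contour in enumerate(structure.contours):
        arr = np.asarray(contour, dtype=float)
        z = float(arr[0, 2])
        k = int(np.argmin(np.abs(z_planes - z)))
        if abs(z_planes[k] - z) > tol + 1e-9:
            raise OutOfGridError(
                f"contour {c_idx} of '{structure.name}' at z={z:.3f} mm is "
                f"farther than {tol:.3f} mm from every grid plane"
            )
        by_plane.setdefault(k, []).append(arr[:, :2])

    s = supersample
    sub = (np.arange(s) + 0.5) / s - 0.5  # sub-center offsets in voxel units
    xc = grid.x_centers()
    yc = grid.y_centers()

    occupancy = np.zeros((nz, ny, nx), dtype=float)
    for k, polys in by_plane.items():
        acc = np.zeros((ny, nx), dtype=float)
        for oy in sub:
            for ox in sub:
                px, py = np.meshgrid(xc + ox * dx, yc + oy * dy)
                acc += _points_in_polygons(px, py, polys)
        occupancy[k] = acc / (s * s)

    if occupancy.sum() <= 0:
        raise DegenerateStructureError(
            f"'{structure.name}' has zero occupancy on this grid"
        )
    return StructureMask(
        structure_name=structure.name,
        occupancy=occupancy,
        voxel_volume=float(dx * dy * dz),
        grid_shape=(nz, ny, nx),
    )


# ---------------------------------------------------------------------------
# DVH computation and metrics
# ---------------------------------------------------------------------------

def compute_dvh(mask: StructureMask, grid: DoseGrid,
                bin_width: float = 0.01) -> DVHCurve:
    """Cumulative DVH of ``mask`` over ``grid``.

    The exported curve is tabulated at ``bin_width`` Gy steps over
    [0, max dose + one bin]; the exact weighted dose distribution is retained
    on the curve so metric evaluation is bin-free.
    """
    if bin_width <= 0:
        raise DomainError("bin_width must be > 0")
    if mask.grid_shape != grid.shape:
        raise WiringError("mask was not built on this grid")

    sel = mask.occupancy > 0
    if not np.any(sel):
        raise DegenerateStructureError("empty mask")
    doses = grid.values[sel].ravel()
    weights = (mask.occupancy[sel] * mask.voxel_volume).ravel()

    order = np.argsort(doses, kind="stable")
    doses = doses[order]
    weights = weights[order]
    total = float(weights.sum())

    d_max = float(doses[-1])
    n_edges = int(np.ceil(d_max / bin_width)) + 2
    edges = np.arange(n_edges) * bin_width
    # volume with dose >= edge: suffix sums of weights
    suffix = np.concatenate([np.cumsum(weights[::-1])[::-1], [0.0]])
    idx = np.searchsorted(doses, edges, side="left")
    cum_pct = 100.0 * suffix[idx] / total

    return DVHCurve(
        structure_name=mask.structure_name,
        dose_edges=edges,
        cum_volume_pct=cum_pct,
        total_volume_cc=total / 1000.0,
        sorted_doses=doses,
        weights=weights,
    )


def evaluate_metric(curve: DVHCurve, spec: MetricSpec) -> float:
    """Evaluate one dose-volume metric on the exact weighted distribution.

    Returns the value in ``spec.unit_out`` (Gy for D-metrics, % or cc for
    V-metrics).
    """
    d = curve.sorted_doses
    w = curve.weights
    total = float(w.sum())

    if spec.kind == MetricKind.DMAX:
        return float(d[-1])
    if spec.kind == MetricKind.DMIN:
        return float(d[0])
    if spec.kind == MetricKind.DMEAN:
        return float(np.dot(d, w) / total)
    if spec.kind == MetricKind.V_GY:
        vol = float(w[d >= spec.argument].sum())
        if spec.unit_out == Unit.CC:
            return vol / 1000.0
        return 100.0 * vol / total
    if spec.kind in (MetricKind.D_PCT, MetricKind.D_CC):
        if spec.kind == MetricKind.D_CC:
            if spec.argument > curve.total_volume_cc + 1e-12:
                raise DomainError(
                    f"D{spec.argument:g}cc exceeds total volume "
                    f"{curve.total_volume_cc:g} cc"
                )
            x_pct = 100.0 * spec.argument / curve.total_volume_cc
        else:
            x_pct = spec.argument
        # hottest-volume step convention: first voxel (descending dose) at
        # which cumulative volume reaches x% of total
        target = x_pct / 100.0 * total
        cum_hot = np.cumsum(w[::-1])
        j = int(np.searchsorted(cum_hot, target * (1 - 1e-12), side="left"))
        j = min(j, len(d) - 1)
        return float(d[::-1][j])
    raise DomainError(f"unknown metric kind {spec.kind}")


def curve_to_rows(curve: DVHCurve):
    """Yield (dose_gy, volume_pct) rows for CSV export."""
    for d, v in zip(curve.dose_edges, curve.cum_volume_pct):
        yield float(d), float(v)
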