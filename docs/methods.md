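# Methods

`rtqa` re-creates, at desk scale, the computational core of a radiotherapy
quality-surveillance pipeline: discrete clinical capture with validation and
derived fields, TG-263 structure-name standardization, DVH computation with
dose-constraint grading, declarative decision-tree quality measures,
de-identification, and practice-level benchmarking. This note records the
models, conventions, and design choices, and what the synthetic study
conditions do and do not demonstrate.

## Geometry and DVH computation

**Coordinate convention.** All geometry lives in the DICOM patient
coordinate system in millimetres. Voxel indices exist only inside the DVH
engine. Only axial, non-tilted dose grids (identity direction cosines) are
supported; any other orientation raises an explicit error rather than
producing silently wrong volumes.

**Rasterization.** Structures are rasterized *onto the dose grid*; dose is
never resampled. Each planar contour is assigned to the nearest grid plane,
with half the median plane spacing as the tolerance. Membership of a sample
point is defined as: the crossing-number parity over all polygons on the
plane is odd, **or** the point lies on any polygon edge. Boundary points
therefore count as inside, and multiple polygons on one plane combine by the
even-odd rule so holes subtract. With `supersample = s`, each voxel is
probed at an s-by-s lattice of sub-centers and the hits are averaged into a
fractional occupancy in [0, 1]. The test suite holds the production
(vectorized) rasterizer to within 1e-9 percentage points of a brute-force
pure-loop implementation of the same stated definition, on 100 random
phantom/field pairs, because both implement one written convention rather
than two private ones.

**Volumes.** Voxel volume is `dx * dy * dz` with `dz` the median plane
spacing (grids are expected to be uniform in z; the synthetic writers only
emit uniform grids). Total structure volume is exactly
`sum(occupancy) * voxel_volume`; DVH curves carry it in cm³.

**DVH and metrics.** The cumulative curve V(d) — percent of structure
volume receiving at least d Gy — is tabulated at a configurable bin width
(default 0.01 Gy) for export only. Metrics never touch bins: the exact
occupancy-weighted voxel dose distribution is retained on the curve, so
pass/fail decisions carry no binning error.

Conventions, since planning systems disagree:

- `VxGy` uses an inclusive threshold (`dose >= x`), so a uniform 20 Gy field
  has V20Gy = 100% and V20.1Gy = 0%.
- `Dx%` uses the step ("infimum") convention on the discrete distribution:
  sort voxels by descending dose and return the dose of the voxel at which
  the cumulative hottest volume first reaches x% of the total. For two
  equal-volume components at 10 and 30 Gy, D50% = 30 Gy — the hottest half
  is exactly the 30 Gy component — and D50.0001% onward returns 10 Gy.
- `Dxcc` converts the absolute volume to a percentage of the structure's
  total volume first; requesting more volume than exists is a domain error,
  which constraint grading converts to NOT_EVALUABLE rather than a crash.

## Synthetic phantoms and dose fields

Phantoms (box, cylinder, sphere) are emitted as per-slice closed polygons
with the closed-form volume of the ideal solid attached as metadata.
Circles are regular polygons with 64 vertices by default; the area deficit
of a regular n-gon against its circumscribed circle is
`1 - (n / 2π) sin(2π/n)`, under 0.2% at n = 64, so the geometric truth used
by the tests is quantifiable. Sphere slice radii are evaluated at slice
centers, which makes the stacked-disk volume a midpoint-rule approximation
of the integral — for the 20 mm sphere at 1 mm slices the residual is about
0.1%, comfortably inside the 2% convergence bound the tests assert at
supersample 4.

Dose fields are analytic: uniform, linear-in-x, and a linear spherical
falloff (peak at a center, zero at a configurable radius), sampled at voxel
centers. Negative field values over the grid are rejected at construction.

## DICOM-RT I/O

Reading and writing use `pydicom`. The writers exist so phantoms and fields
can round-trip through genuine RTSTRUCT/RTDOSE/RTPLAN files; round-trip
equality of names, counts, coordinates and doses (to storage precision) is
the reader contract, and a reader never silently drops a ROI. Dose grids
store 32-bit integers under a grid-scaling factor (default 1e-4 Gy).
RELATIVE dose units are converted to Gy at read time using the prescription
dose; without one, reading RELATIVE dose is an error, because every
downstream metric is absolute. Frame-offset vectors must be strictly
increasing — a deliberate narrowing of "monotonic" matched by what the
writer emits.

## Nomenclature

Matching happens on normalized labels: lowercase, non-alphanumeric runs
collapsed, letter/digit boundaries split, and laterality tokens
(`lt/left/l`, `rt/right/r`) canonicalized. Exact and synonym matches score
1.0; otherwise candidates are ranked by normalized edit similarity
`1 − editdistance / max(len)` (computed with `edlib`, cross-checked in the
tests against a hand-written dynamic-programming oracle), with a default
threshold of 0.70 and k = 5, ties broken alphabetically. Nothing below 1.0
is ever auto-applied: suggestion and mapping are separate acts, and mapping
two raw names onto one canonical is a hard conflict (no merging in v1).
The bundled ~40-entry prostate/lung lexicon is a starter set, replaceable by
a user file. The lexical method is a declared stand-in for whatever matching
a production system would deploy; the machinery (lexicon format, ranking
contract, human-confirmation boundary) is the part meant to be kept.

## Clinical templates

Template schemas for the five workflow encounters (consult, simulation
directive, on-treatment visit, end of treatment, follow-up) are JSON
configuration, not code, with vocabularies labelled by their source (AJCC
stage labels, CTCAE grades 0–5, ECOG). The shipped prostate and lung
schemas are representative reconstructions, deliberately modest (~5–14
fields each). Validation severity is fixed: missing/invalid required field
→ ERROR, missing optional field → WARNING, undeclared field → WARNING.

The NCCN three-tier prostate risk group is the one auto-calculated element:
LOW iff T ≤ T2a and Gleason sum ≤ 6 and PSA < 10 ng/mL; HIGH iff T ≥ T3a or
Gleason sum ≥ 8 or PSA > 20; else INTERMEDIATE. The rule table is a
versioned JSON file, and the tests enumerate the full cross product of five
T stages, Gleason sums 6–9, and PSA {5, 15, 25} against an independently
written encoding of the published table. The favorable/unfavorable
intermediate sub-split is out of scope in v1.

Auto-population copies declared source fields into later templates
(marking them AUTO_POPULATED); a manual entry always wins, which makes
re-running idempotent. Narrative notes use single-line `{field}`
placeholders only — no conditionals — precisely so that extraction is
decidable: the boilerplate splits into literal segments, values are read
between them, the sentinel `[not recorded]` maps back to an absent field,
and any skeleton mismatch is a parse error with a position. Adjacent
placeholders with no separating literal are rejected at configuration time
because they would make extraction ambiguous.

## Quality-measure engine

Measures are acyclic binary decision trees in JSON: decision nodes test one
feature (`EQ/NE/LT/LE/GT/GE/IN/EXISTS`) against a literal; leaves are PASS,
FAIL, or NOT_APPLICABLE. All structural validation — cycles (reported with
the node path), dangling branches, unknown features (reported with the
nearest known name) — happens at load; evaluation is a pure interpreter
that cannot fail at runtime. Two semantics choices are deliberate:

- A predicate on a missing feature (other than EXISTS) yields
  NOT_EVALUABLE, never FAIL: surveillance must distinguish bad care from
  missing data.
- NOT_APPLICABLE is an authored leaf. Eligibility carve-outs live in the
  tree, keeping the engine free of special cases.

Features are flattened under a documented namespace —
`record.<template>.<field>`, `plan.*`, `dvh.<structure>.<metric>.status` and
`dvh.plan_status` — with duplicate keys treated as a wiring error. The
engine is held to exhaustive truth-table enumeration by an independent
recursive evaluator over random trees (depth ≤ 5, 8 mixed binary/ternary
features, every assignment), and every reported path trace must replay to
the reported leaf. The shipped prostate/lung rulesets are structural
illustrations, not transcriptions of any published measure set.

## Constraint grading

A constraint is (structure, metric, comparator ≤/≥, pass limit, optional
variation limit). Boundary equality satisfies a limit, matching how
published constraint tables are written; a variation limit must be weakly
looser than the pass limit under the comparator. Plan status is the worst
status over evaluable constraints; NOT_EVALUABLE rows (absent structures,
metric domain errors) are always listed and never counted. Constraint sets
are editable JSON per site; the shipped files are illustrative placeholders,
labelled as such, because real threshold sets are protocol property and
evolve.

## De-identification and integrity

Pseudonyms and remapped UIDs come from HMAC-SHA256 under a secret key held
in the map store: one-way without the key, deterministic with it, so
longitudinal linkage survives de-identification. Dates shift by one
per-patient offset drawn (keyed) uniformly within ±60 days by default, so
every interval — treatment duration included — is preserved for timing
logic. The policy is fail-closed for identity attributes: an identity field
without an explicit action raises; clinical encounter fields may fall to an
explicitly declared `default_clinical_action: KEEP`, with `*_date` fields
always shifted. DICOM UID remapping walks every UI-valued element
(including nested sequences and file meta), leaving standard class and
transfer-syntax UIDs (the `1.2.840.10008` root) untouched, so a triplet
processed under one map keeps consistent cross-references.

Export bundles are sealed with SHA-256 over a canonical key-sorted
serialization. `verify` never raises: a mismatch or unsupported algorithm
label returns False and appends to an audit trail; the caller's contract is
to reject the transaction.

## Benchmarking

Per-practice, per-measure pass rates exclude NOT_APPLICABLE and
NOT_EVALUABLE from the denominator (a rate over zero evaluable patients is
null, not zero). The national reference is the pooled rate, which by
construction equals the sum of practice counts. Outlier flagging uses the
exact binomial two-tailed rule: a cell with k passes out of n is flagged
BELOW when P(X ≤ k) < α/2 and ABOVE when P(X ≥ k) < α/2 for
X ~ Binomial(n, pooled rate), α = 0.05 by default. This is the simplest
defensible baseline — no funnel plot, no hierarchical shrinkage — and the
rule, α, and the optional Bonferroni switch are reported in the output
metadata rather than hidden. Small practices are structurally hard to flag
(at n = 1 the interval spans almost everything), which is the correct
behaviour for an exact rule, not a bug.

## What the synthetic conditions show — and don't

The generators define the study conditions: analytic phantoms with known
volumes, analytic dose fields, and seeded patient records that always
validate against their schemas, with clinically plausible (but not
population-calibrated) distributions — e.g. hormone-therapy planning tracks
the computed risk group, and prescription patterns follow common prostate
and lung fractionations. Passing tests therefore demonstrate *algorithmic*
correctness: geometry against closed forms and brute-force oracles, engines
against exhaustive enumeration, round-trips against exact recovery. They do
not demonstrate robustness to real planning-system dialects (tilted grids,
non-uniform slice spacing, malformed contours beyond the cases modelled),
realistic anatomy, or real clinical data distributions; cohort pass rates
are generator artefacts, not clinical findings.

## Problem sizes and numerical choices

The default test run and the acceptance script use desk-scale sizes chosen
to keep the whole suite in seconds on one CPU: 17×17×(≤12) dose grids for
the 100 oracle comparisons, a 29×29×20 1 mm grid for sphere convergence,
eight random trees × 6 561 assignments for the engine oracle, 100 records
for the narrative round trip. Tolerances are stated where conventions could
bite: 1e-9 percentage points for oracle equivalence (both sides implement
one written membership rule, so agreement is exact up to float summation
order), 2% for sphere convergence at supersample 4, one voxel-layer volume
for the linear-gradient DVH. Grid origins in random tests are offset by a
quarter voxel so sample points rarely sit exactly on contour edges; when
they do, both implementations apply the same boundary rule, so the
comparison remains exact.
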