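# Methods

## Model overview

`osteovox` builds voxel phantoms of bone segments that contain active
(hematopoietic) marrow. A segment is an idealised solid — box, circular or
elliptic cylinder, truncated cone, right-triangular prism or ellipsoid —
whose interior is spongiosa: an isotropic 3-D lattice of rod trabeculae with
marrow in the pores, wrapped on the anatomically relevant faces by a
homogeneous cortical layer. Tissue labels are 0 outside, 1 marrow, 2
trabecula, 3 cortical. Six reference ages are modeled (0, 1, 5, 10, 15
years and adult); sex-specific parameter rows exist only at 15 years and in
adults, where skeletal size dimorphism becomes relevant.

## Parameter database

The packaged CSV tables hold, per segment and age: dimensions ± SD (mm),
cortical thickness ± SD, BV/TV, Tb.Th and Tb.Sp ± SD, intra-specimen
coefficients of variation CV_IS (%) per bone group (pelvic 10/10,
vertebrae + sacrum 48/43, skull 8/15, all other bones the rounded group
average 22/23), mineral densities 1.65/1.7/1.8/1.83/1.85/1.9 g/cm³ for the
six ages and marrow density 1.0 (0.98 for adults). Combinations in which
hematopoiesis has ceased (e.g. adult long-bone diaphyses) are absent from
the registry and raise a distinct "not modeled at age" error.

The registry enumerates 289 unique segments (34/39/43/38/64/71 per age).
Where the published record fixes identities — rib segments as four 30 mm
representative boxes per sex in adults/15-Y, the five-segment adult lumbar
vertebra with body and transverse processes sex-specific, scapular
glenoid/acromion/body/lateral margin, the 30 × 30 mm skull-vault and
scapular-body fragments — the registry follows it. The remaining part names
and their shape assignments are a synthetic reconstruction constrained to
reproduce the per-site/per-age counts and the aggregate shape census
(140 boxes, 86 cylinders, 58 cones, 4 prisms, 1 ellipsoid); individual
assignments beyond the documented ones should not be read as anatomical
claims.

Dimension coverage is partial: scapula (all ages), skull vault, ribs, adult
clavicle body and the adult lumbar vertebra ship with the package; the
skull-vault thicknesses, rib cross-sections and lumbar-vertebra dimensions
are literature-plausible synthetic values (the lumbar set is chosen so the
body contributes 70.0 % of the five-segment vertebra volume, the model's
independent segmentation check). All other segments carry micro-parameters
but no sizes; `ParameterDatabase.load_s15()` ingests a full per-segment
size table (CSV with site, part, age, sex, param, role, mean, sd) when one
is available. Evidence pooling follows the published weighting: W_N =
min(1, N/25) for study size, W_A = 0.75 for adult micro-parameter studies
whose age range extends past the reference window (sizes use W_N only);
pooled SD is the weighted mean of study SDs and ranges default to ±2 SD.

## Geometry and voxelisation

Voxels are cubic, 50–200 µm (default: the value nearest Tb.Th/2 within that
range); classification is by voxel centre, which is unbiased and converges
to the analytic volume as the voxel shrinks. The grid adds a one-voxel
outside margin, and the solid starts exactly one voxel from the grid
origin, so dimensions that are voxel multiples rasterise exactly. The
cortical shell is `round(Ct.Th / voxel)` whole voxel layers (half-up),
realised by carving the solid shrunk inward by that amount on each covered
face; by construction it conserves the interior voxel count and is uniform
per face. Default covered faces: the two large faces for plate-like boxes,
the lateral surface for cylinders/cones/prisms, the whole surface for
ellipsoids.

## Spongiosa generation

The three tabulated micro-parameters over-determine a cubic rod lattice, so
a priority is needed. BV/TV and Tb.Th are binding — the bone volume
fraction fixes source mass and marrow fraction, and rod thickness controls
electron escape — while the node pitch is calibrated as the unique root
p > t of `target · p³ − 3 t² p + 2 t³ = 0` (the unit-cell bone fraction of
three orthogonal square rods of side t). The realized separation,
`pitch − Tb.Th`, is reported in provenance and generally differs from the
tabulated Tb.Sp; it is deliberately not re-measured.

Step 2 deforms the lattice within intra-specimen variability: node
positions get independent per-axis normal displacements with
σ = (CV_IS,Tb.Sp/100)·pitch and every rod an independent thickness
multiplier from N(1, CV_IS,Tb.Th/100); both are truncated at ±2σ by
clipping so the geometry stays valid, and rendered rod widths are floored
at one voxel. Because truncation and voxelisation shift the realized bone
fraction, a single global thickness rescale (bisection, tolerance 0.005 in
BV/TV, well inside the ±0.02 contract) restores the target. A single seeded
generator drives everything; identical seeds give bit-identical label
grids, and zero CV returns the undeformed lattice unchanged. Rods are
rendered as swept squares between neighbouring (displaced) nodes, which
keeps the network connected through the shared nodes; only rod stubs
clipped by the region boundary can detach.

## Supplementary phantoms

Each basic phantom uses the population means exactly. Twelve supplementary
phantoms vary every dimension, Ct.Th, BV/TV and Tb.Th independently,
uniformly on [mean − SD, mean + SD] (clipped to positivity, one-voxel
cortical minimum and the lattice's BV/TV ceiling of 0.8). Uniform sampling
maximises coverage of the variability range with only 12 draws; no
correlation structure between parameters is imposed because none is
published. Tb.Sp is not sampled independently (it follows from the pitch
calibration). The count 12 is the published convention and is configurable.

## Morphometry

BV/TV is counted on the spongiosa only (trabecula / (trabecula + marrow));
cortical voxels never enter the denominator. Tb.Th and Ct.Th use the local
maximal-inscribed-sphere (Hildebrand-type) thickness averaged over the
phase, computed from the Euclidean distance transform with a sphere-
stamping kernel. Mean-intercept-length estimators are degenerate on an
axis-aligned rod lattice, which is why the inscribed-sphere definition is
used. Two biases of this estimator on a voxel grid are worth knowing:
odd-width rods read up to one voxel thick, and lattice nodes — where three
rods meet — admit inscribed spheres up to ~√2 times the rod side, so
high-BV/TV structures (e.g. skull vault, BV/TV 0.52) read a mean Tb.Th
~15–20 % above the rod side. This is a property of the definition on this
geometry, not a defect of the generator; round-trip checks therefore carry
a tolerance of max(one voxel, one population SD).

Masses are voxel counts × voxel volume × age-specific density (mineral for
trabecula and cortical, marrow density for marrow). Whole-bone aggregation
multiplies each segment by its per-skeleton multiplicity (paired bones ×2,
repeated vertebrae/ribs by count) and by the fragment-to-whole-bone scale
for segments modeled as 30 mm representative fragments. The segmentation
volume check computes the analytic volume share of a segment within a
segment set with those multiplicities; for the adult male lumbar vertebra
the body contributes 70.0 % of the five-segment vertebra. The check is
sensitive to counting paired processes twice (dropping pairing raises the
body share by several points), so the pairing convention is asserted in the
tests rather than absorbed silently.

## Verification problem sizes

The packaged verification (tests and `scripts/acceptance.py`) uses the
following problem sizes, chosen to resolve the micro-architecture while
keeping single-CPU runs in minutes: clavicle-body BV/TV on a 25 mm cube at
100 µm voxels and skull-vault Tb.Th on a 15 mm cube at 50 µm voxels, each
averaged over 10 seeds; property checks (lattice oracle, isotropy,
connectivity, SPS bracketing) run on 5–10 mm cubes. Lattice rasterisation
and thickness stamping are numba-compiled; the first call in a session pays
a one-off compilation cost of a few seconds.

## Serialization

`raw+json` writes the label grid as an unsigned 8-bit stream in x-fastest
order next to a JSON header (shape, voxel size, label codes, provenance,
format version); NRRD output is a standard detached-header pair. Headers
round-trip losslessly; readers reject newer major versions and payloads
whose size contradicts the declared shape. Large provenance arrays (per-rod
thickness multipliers) are summarised, not serialised.

## Known limitations

* Rod-only trabeculae: no plate-like structures, no anisotropy, no
  growth-plate cartilage; the lattice reproduces BV/TV and Tb.Th, not
  topology metrics (SMI, connectivity density).
* The tabulated Tb.Sp is not honoured simultaneously with BV/TV and Tb.Th
  (see above); consumers needing Tb.Sp should read the realized value from
  provenance.
* Segment dimensions beyond the packaged set must be supplied by the user;
  without them only micro-architecture operations are available for those
  segments.
* The synthetic-data aspects of the registry (part identities, some shape
  assignments, skull/rib/lumbar dimensions) match published aggregate
  constraints, not per-segment measurements; passing tests demonstrate
  internal consistency with the published inventory and verification
  figures, not anatomical fidelity of every individual segment.
* Dose-factor computation (Monte Carlo electron/photon transport) is out of
  scope.
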