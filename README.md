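# osteovox

Stochastic parametric voxel phantoms of the hematopoietic human skeleton.

Internal dosimetry of bone-seeking beta emitters (e.g. ⁸⁹Sr/⁹⁰Sr) needs
computational phantoms of the bone regions that contain active (red) marrow:
the electrons emitted from mineralised bone travel only millimetres, so the
absorbed dose to marrow depends on the trabecular micro-architecture and on
the linear dimensions of each bone segment. `osteovox` implements the
anatomical/morphological layer of such a model for six reference ages
(newborn, 1, 5, 10, 15 years, adult):

* a **parameter database** of 289 unique bone segments across the six ages —
  each hematopoietic site split into simple geometric segments (box,
  cylinder, truncated cone, prism, ellipsoid) with population-mean
  dimensions ± SD, cortical thickness Ct.Th, and trabecular
  micro-architecture BV/TV, Tb.Th, Tb.Sp ± SD, plus intra-specimen
  coefficients of variation CV_IS and age-specific tissue densities;
* a **phantom generator**: each segment is voxelised (50–200 µm voxels),
  covered with a uniform cortical layer on its covered faces, and filled
  with an isotropic cubic lattice of square-section rod trabeculae whose
  pitch *p* is calibrated so the cell formula
  `BV/TV = (3 t² p − 2 t³) / p³` (rod side *t* = Tb.Th) hits the target bone
  volume fraction; a stochastic step then perturbs node positions and
  per-rod thicknesses within CV_IS and restores the target BV/TV with one
  global thickness rescale;
* **population variability**: each basic phantom segment (BPS, population
  means) is accompanied by 12 supplementary phantoms (SPS) whose parameters
  are drawn uniformly within ±1 SD;
* **morphometry**: micro-CT-style measurement of the generated volumes
  (BV/TV, Tb.Th by the local maximal-inscribed-sphere method, Ct.Th,
  per-tissue volumes and masses) and mass/volume aggregation over paired
  and repeated segments.

Downstream Monte Carlo transport and dose-factor computation are out of
scope; the phantoms are written in formats (raw+JSON, NRRD) that transport
codes and volume viewers can ingest.

## Worked example

```python
import osteovox as ov
from osteovox.morphometry import measure

db = ov.default_db()
spec = db.get_segment("scapula", "glenoid", "adult")
print(spec.shape, {d.name: d.mean for d in spec.dims}, spec.ctth_mean)
# elliptic-cylinder {'D_1g': 36.0, 'D_2g': 26.0, 'h_g': 20.0} 0.9

ph = ov.build_bps(spec, "adult", voxel_mm=0.2, seed=1)
res = measure(ph, db.densities, "adult")
print(round(res.bvtv, 3), round(res.total_mass, 1), "g")
# 0.221 18.7 g
```

The glenoid is modeled as a 36 × 26 × 20 mm elliptic cylinder with a 0.9 mm
cortical shell; the generated spongiosa recovers the adult scapular bone
volume fraction (target 0.22) and the phantom weighs ≈ 19 g. The same
pipeline is available from the shell:

```sh
osteovox db validate                  # registry totals and shape census
osteovox generate --site scapula --part glenoid --age adult \
    --voxel 0.2 --seed 1 --out glenoid
osteovox measure glenoid.json --age adult
osteovox sample-sps --site scapula --part glenoid --age adult \
    --voxel 0.2 --seed 1 --out-dir glenoid_set
```

`osteovox db validate` prints the per-age unique-segment counts
34/39/43/38/64/71 (289 in total) and the shape census (48.4 % boxes,
29.8 % cylinders, 20.1 % cones, 1.4 % prisms, 0.3 % ellipsoids).

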