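"""Assembly of basic and supplementary phantom segments.

A basic phantom segment (BPS) is built with the population-mean parameters
of its segment: voxelise the primitive, apply the cortical shell, calibrate
the lattice pitch, lay the rod lattice and deform it within intra-specimen
variability.  Twelve supplementary phantom segments (SPS) are then sampled
with every varied parameter — dimensions, cortical thickness, BV/TV and
Tb.Th — drawn independently and uniformly within one population SD of its
mean, propagating population variability into downstream dose factors.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MissingDimensionsError, NotModeledAtAgeError
from .geometry import ShapeDef, VoxelPhantom, VOXEL_RANGE, apply_cortical_shell, voxelize
from .paramdb import SegmentSpec, normalize_age
from .spongiosa import LatticeParams, calibrate_pitch, deform, fill_spongiosa

#: number of supplementary phantoms per segment
N_SPS = 12


@dataclass
class PhantomSet:
    """One BPS plus its supplementary phantoms."""

    bps: VoxelPhantom
    sps: list[VoxelPhantom]
    spec: SegmentSpec
    age: str


def default_voxel_mm(tbth: float) -> float:
    """Voxel edge closest to half the trabecular thickness within 50-200 um."""
    return float(np.clip(tbth / 2.0, *VOXEL_RANGE))


def shape_from_spec(spec: SegmentSpec,
                    overrides: dict[str, float] | None = None) -> ShapeDef:
    """Build the geometric primitive from a segment's dimension roles."""
    if not spec.has_dims:
        raise MissingDimensionsError(
            f"{spec.site}/{spec.part} ({spec.age}, {spec.sex}) has no packaged "
            "dimensions; ingest a segment-size table (ParameterDatabase.load_s15)")
    dims = {d.role: d.mean for d in spec.dims}
    if overrides:
        dims.update(overrides)
    return ShapeDef(kind=spec.shape, dims=dims)


def _pipeline(spec: SegmentSpec, shape: ShapeDef, ctth: float, bvtv: float,
              tbth: float, voxel_mm: float, seed: int) -> VoxelPhantom:
    ph = voxelize(shape, voxel_mm)
    ph = apply_cortical_shell(ph, ctth, spec.cortical_faces)
    pitch = calibrate_pitch(tbth, bvtv)
    lp = LatticeParams(rod_thickness=tbth, pitch=pitch, target_bvtv=bvtv,
                       cvis_tbth=spec.micro.cvis_tbth,
                       cvis_tbsp=spec.micro.cvis_tbsp, seed=seed)
    ph = fill_spongiosa(ph, lp)
    ph = deform(ph, lp)
    ph.meta.update(segment=f"{spec.site}/{spec.part}", age=spec.age,
                   sex=spec.sex, seed=seed,
                   realized=dict(bvtv=bvtv, tbth=tbth, ctth=ctth,
                                 pitch=pitch, tbsp=pitch - tbth,
                                 dims={d.role: shape.dims[d.role] for d in spec.dims}))
    return ph


def build_bps(spec: SegmentSpec, age: str, voxel_mm: float | None = None,
              seed: int = 0) -> VoxelPhantom:
    """Basic phantom segment: population means throughout.

    Only the intra-specimen deformation is stochastic; ``seed`` controls it
    and is recorded in provenance.
    """
    age = normalize_age(age)
    if age not in spec.modeled_ages:
        raise NotModeledAtAgeError(
            f"{spec.site}/{spec.part} is not modeled at {age}")
    if voxel_mm is None:
        voxel_mm = default_voxel_mm(spec.micro.tbth_mean)
    shape = shape_from_spec(spec)
    return _pipeline(spec, shape, spec.ctth_mean, spec.micro.bvtv_mean,
                     spec.micro.tbth_mean, voxel_mm, seed)


def sample_sps(spec: SegmentSpec, age: str, voxel_mm: float | None = None,
               seed: int = 0, n_sps: int = N_SPS) -> PhantomSet:
    """BPS plus ``n_sps`` supplementary phantoms sampled within +/-1 SD.

    Each varied parameter (every dimension, cortical thickness, BV/TV,
    Tb.Th) is drawn independently and uniformly on [mean - SD, mean + SD],
    clipped to validity (positivity, BV/TV < 0.8 ceiling of the lattice,
    cortical thickness of at least one voxel).  Deterministic given
    ``seed``.
    """
    age = normalize_age(age)
    if age not in spec.modeled_ages:
        raise NotModeledAtAgeError(
            f"{spec.site}/{spec.part} is not modeled at {age}")
    if voxel_mm is None:
        voxel_mm = default_voxel_mm(spec.micro.tbth_mean)
    rng = np.random.default_rng(seed)

    bps = build_bps(spec, age, voxel_mm, seed=seed)
    sps = []
    for i in range(n_sps):
        draw = lambda m, s: float(rng.uniform(m - s, m + s))  # noqa: E731
        dims = {d.role: max(draw(d.mean, d.sd), 3.0 * voxel_mm) for d in spec.dims}
        ctth = max(draw(spec.ctth_mean, spec.ctth_sd), voxel_mm)
        bvtv = float(np.clip(draw(spec.micro.bvtv_mean, spec.micro.bvtv_sd),
                             0.01, 0.8))
        tbth = max(draw(spec.micro.tbth_mean, spec.micro.tbth_sd), voxel_mm)
        shape = shape_from_spec(spec, overrides=dims)
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        ph = _pipeline(spec, shape, ctth, bvtv, tbth, voxel_mm, sub_seed)
        ph.meta["sps_index"] = i
        sps.append(ph)
    return PhantomSet(bps=bps, sps=sps, spec=spec, age=age)
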