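"""Trabecular-lattice generation and stochastic deformation.

The spongiosa is modeled as an isotropic cubic lattice of rod trabeculae:
three orthogonal families of square-section rods (side ``rod_thickness``)
running through every lattice node, with marrow filling the pores.  The
node spacing (pitch) is calibrated so the undeformed lattice reaches the
target bone volume fraction analytically; the realized trabecular
separation is then ``pitch - rod_thickness`` and is reported in provenance
rather than imposed (the three tabulated micro-parameters over-determine a
cubic rod lattice; BV/TV and Tb.Th are binding because they control source
mass and electron escape).

A second step perturbs node positions and per-rod thicknesses within the
intra-specimen variability CV_IS, turning the regular grid into a
dosimetrically realistic irregular network, and restores the target BV/TV
with a single global thickness rescale.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from ._kernels import rasterize_lattice
from .errors import LatticeError, RodThinnerThanVoxelError, UnreachableBvtvError
from .geometry import MARROW, TRABECULA, VoxelPhantom


@dataclass(frozen=True)
class LatticeParams:
    """Parameters of one spongiosa realisation."""

    rod_thickness: float          # mm, realizes Tb.Th
    pitch: float                  # mm node spacing; Tb.Sp = pitch - rod_thickness
    target_bvtv: float            # fraction of bone in the spongiosa
    cvis_tbth: float = 0.0        # percent, per-rod thickness variability
    cvis_tbsp: float = 0.0        # percent, node-position variability
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.rod_thickness < self.pitch:
            raise LatticeError(
                f"need 0 < rod_thickness < pitch, got t={self.rod_thickness}, "
                f"p={self.pitch}")
        if not 0.0 < self.target_bvtv < 1.0:
            raise LatticeError(f"target_bvtv must be in (0,1), got {self.target_bvtv}")

    @property
    def realized_tbsp(self) -> float:
        return self.pitch - self.rod_thickness


def lattice_bvtv(t: float, p: float) -> float:
    """Analytic bone fraction of the unit cell: (3 t^2 p - 2 t^3) / p^3."""
    return (3.0 * t * t * p - 2.0 * t ** 3) / p ** 3


def calibrate_pitch(tbth: float, target_bvtv: float) -> float:
    """Node spacing p solving the unit-cell fraction for the target BV/TV.

    The cell fraction is monotone decreasing in p for p > t, so the root
    with p > t is unique; it is found as the real root of
    ``target * p^3 - 3 t^2 p + 2 t^3 = 0``.
    """
    if not 0.0 < target_bvtv <= 0.8:
        raise UnreachableBvtvError(
            f"target BV/TV {target_bvtv} outside the modelable range (0, 0.8]")
    if tbth <= 0:
        raise LatticeError("tbth must be positive")
    roots = np.roots([target_bvtv, 0.0, -3.0 * tbth ** 2, 2.0 * tbth ** 3])
    real = roots[np.abs(roots.imag) < 1e-9].real
    ok = real[real > tbth * (1.0 + 1e-9)]
    if ok.size == 0:
        raise UnreachableBvtvError(
            f"no lattice pitch reaches BV/TV={target_bvtv} at Tb.Th={tbth}")
    return float(ok.max())


def _node_grid(extent_mm: tuple[float, float, float], pitch: float):
    # one node beyond the far face so every voxel lies inside a rod cell
    counts = tuple(int(ceil(e / pitch)) + 2 for e in extent_mm)
    ax = [np.arange(n) * pitch for n in counts]
    pos = np.empty(counts + (3,), dtype=np.float64)
    pos[..., 0] = ax[0][:, None, None]
    pos[..., 1] = ax[1][None, :, None]
    pos[..., 2] = ax[2][None, None, :]
    return pos


def _render(ph_shape, voxel_mm, pos, widths) -> np.ndarray:
    mask = np.zeros(ph_shape, dtype=np.uint8)
    rasterize_lattice(mask, pos, widths, voxel_mm)
    return mask


def fill_spongiosa(ph: VoxelPhantom, lp: LatticeParams) -> VoxelPhantom:
    """Step 1: lay the undeformed rod lattice into the marrow interior.

    The lattice phase is anchored at the grid origin (a node at 0,0,0), so
    identical parameters give identical label grids.
    """
    if lp.rod_thickness < ph.voxel_mm:
        raise RodThinnerThanVoxelError(
            f"rod thickness {lp.rod_thickness} mm below voxel {ph.voxel_mm} mm")
    out = ph.copy()
    marrow = out.labels == MARROW
    if not marrow.any():
        return out
    extent = tuple(n * ph.voxel_mm for n in ph.labels.shape)
    pos = _node_grid(extent, lp.pitch)
    widths = np.full((3,) + pos.shape[:3], lp.rod_thickness, dtype=np.float64)
    mask = _render(out.labels.shape, ph.voxel_mm, pos, widths)
    out.labels[marrow & (mask == 1)] = TRABECULA
    out.meta.update(stage="spongiosa",
                    lattice=dict(rod_thickness=lp.rod_thickness, pitch=lp.pitch,
                                 target_bvtv=lp.target_bvtv,
                                 realized_tbsp=lp.realized_tbsp,
                                 deformed=False))
    return out


def _spongiosa_bvtv(labels: np.ndarray) -> float:
    n_tb = int((labels == TRABECULA).sum())
    n_ma = int((labels == MARROW).sum())
    if n_tb + n_ma == 0:
        return float("nan")
    return n_tb / (n_tb + n_ma)


def deform(ph: VoxelPhantom, lp: LatticeParams,
           bvtv_tol: float = 0.005, max_iter: int = 12) -> VoxelPhantom:
    """Step 2: stochastic 3-D deformation of the lattice within CV_IS.

    Node positions receive independent per-axis normal displacements with
    sigma = (cvis_tbsp/100) * pitch, and every rod an independent thickness
    multiplier from N(1, cvis_tbth/100); both are truncated at +/-2 sigma
    (by clipping) to keep the geometry valid, and rendered widths are
    floored at one voxel.  A single global thickness rescale then restores
    the target BV/TV (to ``bvtv_tol`` when reachable, and always within
    the +/-2% contract).  Deterministic for a given seed; with both CVs
    zero the phantom is returned unchanged, bit-exactly.
    """
    if lp.cvis_tbth == 0.0 and lp.cvis_tbsp == 0.0:
        out = ph.copy()
        lat = dict(out.meta.get("lattice", {}))
        lat["deformed"] = False
        out.meta["lattice"] = lat
        return out
    if lp.rod_thickness < ph.voxel_mm:
        raise RodThinnerThanVoxelError(
            f"rod thickness {lp.rod_thickness} mm below voxel {ph.voxel_mm} mm")

    out = ph.copy()
    spong = (out.labels == MARROW) | (out.labels == TRABECULA)
    if not spong.any():
        return out
    out.labels[out.labels == TRABECULA] = MARROW

    extent = tuple(n * ph.voxel_mm for n in ph.labels.shape)
    pos = _node_grid(extent, lp.pitch)
    rng = np.random.default_rng(lp.seed)
    sigma = lp.cvis_tbsp / 100.0 * lp.pitch
    if sigma > 0.0:
        disp = rng.normal(0.0, sigma, size=pos.shape)
        np.clip(disp, -2.0 * sigma, 2.0 * sigma, out=disp)
        pos = pos + disp
    cv = lp.cvis_tbth / 100.0
    if cv > 0.0:
        mult = rng.normal(1.0, cv, size=(3,) + pos.shape[:3])
        np.clip(mult, 1.0 - 2.0 * cv, 1.0 + 2.0 * cv, out=mult)
        mult = np.maximum(mult, 1e-3)
    else:
        mult = np.ones((3,) + pos.shape[:3])

    def render(scale: float) -> np.ndarray:
        widths = np.maximum(lp.rod_thickness * scale * mult, ph.voxel_mm)
        return _render(out.labels.shape, ph.voxel_mm, pos, widths)

    def bvtv_of(mask: np.ndarray) -> float:
        n_tb = int((spong & (mask == 1)).sum())
        return n_tb / int(spong.sum())

    # bisection on the global thickness rescale (bone fraction is monotone
    # non-decreasing in the scale)
    scale = 1.0
    mask = render(scale)
    value = bvtv_of(mask)
    if abs(value - lp.target_bvtv) > bvtv_tol:
        lo, hi = 0.25, 4.0
        if value > lp.target_bvtv:
            hi = scale
        else:
            lo = scale
        for _ in range(max_iter):
            scale = 0.5 * (lo + hi)
            mask = render(scale)
            value = bvtv_of(mask)
            if abs(value - lp.target_bvtv) <= bvtv_tol:
                break
            if value > lp.target_bvtv:
                hi = scale
            else:
                lo = scale

    out.labels[spong & (mask == 1)] = TRABECULA
    clipped = np.maximum(lp.rod_thickness * mult, ph.voxel_mm)
    out.meta.update(stage="spongiosa-deformed")
    out.meta["lattice"] = dict(
        rod_thickness=lp.rod_thickness, pitch=lp.pitch,
        target_bvtv=lp.target_bvtv, realized_tbsp=lp.realized_tbsp,
        deformed=True, seed=lp.seed,
        cvis_tbth=lp.cvis_tbth, cvis_tbsp=lp.cvis_tbsp,
        thickness_scale=scale, realized_bvtv=value,
        thickness_multipliers=mult.ravel(),
        node_sigma_mm=sigma,
        mean_rod_thickness_mm=float(np.mean(clipped) * scale))
    return out
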