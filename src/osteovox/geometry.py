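"""Voxelisation of the geometric primitives and cortical shells.

Bone segments are idealised as simple solids — boxes, circular/elliptic
cylinders, truncated cones, right-triangular prisms and ellipsoids — that
are rasterised onto an axis-aligned cubic voxel grid by voxel-centre
membership, then covered on the configured faces with a homogeneous
cortical layer a whole number of voxels thick.

Label codes: 0 outside, 1 marrow, 2 trabecula, 3 cortical.  Grids are
indexed ``labels[ix, iy, iz]``; voxel centres sit at ``(i + 0.5) * voxel_mm``
and the solid's bounding box starts one voxel in from the grid origin, so a
dimension that is an exact voxel multiple rasterises exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, pi
from typing import Mapping

import numpy as np

from .errors import (DimensionTooSmallError, GeometryError,
                     ShellExceedsExtentError)

OUTSIDE, MARROW, TRABECULA, CORTICAL = 0, 1, 2, 3

#: voxel edge lengths supported by the generator (mm); spongiosa voxels are
#: chosen within 50-200 um depending on trabecular thickness.
VOXEL_RANGE = (0.05, 0.2)

KINDS = ("box", "cylinder", "elliptic-cylinder", "truncated-cone",
         "prism", "ellipsoid")

_REQUIRED_DIMS = {
    "box": ("a", "b", "c"),
    "cylinder": ("d1", "h"),
    "elliptic-cylinder": ("d1", "d2", "h"),
    "truncated-cone": ("d_base", "d_top", "h"),
    "prism": ("a", "b", "h"),
    "ellipsoid": ("d1", "d2", "d3"),
}


@dataclass(frozen=True)
class ShapeDef:
    """A geometric primitive with named dimensions in mm.

    box: a x b x c.  cylinder: diameter d1 (optional d2 for an elliptic
    base), height h along z.  truncated-cone: d_base >= d_top, height h.
    prism: right triangular base with legs a, b, height h.  ellipsoid:
    diameters d1, d2, d3.
    """

    kind: str
    dims: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise GeometryError(f"unknown shape kind {self.kind!r}")
        for name in _REQUIRED_DIMS[self.kind]:
            if name not in self.dims:
                raise GeometryError(f"{self.kind} requires dimension {name!r}")
        for name, v in self.dims.items():
            if v <= 0:
                raise GeometryError(f"dimension {name}={v} must be positive")
        if self.kind == "truncated-cone" and self.dims["d_top"] > self.dims["d_base"]:
            raise GeometryError("truncated cone requires d_top <= d_base")

    @property
    def extents(self) -> tuple[float, float, float]:
        """Axis-aligned bounding-box extents (mm)."""
        d = self.dims
        if self.kind == "box":
            return d["a"], d["b"], d["c"]
        if self.kind == "cylinder":
            return d["d1"], d.get("d2", d["d1"]), d["h"]
        if self.kind == "elliptic-cylinder":
            return d["d1"], d["d2"], d["h"]
        if self.kind == "truncated-cone":
            return d["d_base"], d["d_base"], d["h"]
        if self.kind == "prism":
            return d["a"], d["b"], d["h"]
        return d["d1"], d["d2"], d["d3"]

    def volume(self) -> float:
        """Analytic volume (mm^3)."""
        d = self.dims
        if self.kind == "box":
            return d["a"] * d["b"] * d["c"]
        if self.kind == "cylinder":
            return pi / 4.0 * d["d1"] * d.get("d2", d["d1"]) * d["h"]
        if self.kind == "elliptic-cylinder":
            return pi / 4.0 * d["d1"] * d["d2"] * d["h"]
        if self.kind == "truncated-cone":
            rb, rt = d["d_base"] / 2.0, d["d_top"] / 2.0
            return pi * d["h"] / 3.0 * (rb * rb + rb * rt + rt * rt)
        if self.kind == "prism":
            return d["a"] * d["b"] / 2.0 * d["h"]
        return pi / 6.0 * d["d1"] * d["d2"] * d["d3"]

    def faces(self) -> tuple[str, ...]:
        """Face identifiers a cortical shell may cover on this shape."""
        if self.kind == "box":
            return ("x-", "x+", "y-", "y+", "z-", "z+")
        if self.kind == "ellipsoid":
            return ("all",)
        return ("lateral", "z-", "z+")


@dataclass
class VoxelPhantom:
    """A labeled 3-D tissue grid with provenance.

    ``meta`` records everything needed to reproduce the phantom: segment
    identity, seed and realized parameter values (including the realized
    trabecular separation, which only exists here).
    """

    labels: np.ndarray
    voxel_mm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise GeometryError("labels must be a 3-D array")
        if not VOXEL_RANGE[0] <= self.voxel_mm <= VOXEL_RANGE[1]:
            raise GeometryError(
                f"voxel_mm={self.voxel_mm} outside supported range {VOXEL_RANGE}")

    def copy(self) -> "VoxelPhantom":
        return VoxelPhantom(self.labels.copy(), self.voxel_mm, dict(self.meta))

    def counts(self) -> dict[int, int]:
        vals, cnts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, cnts)}


# --------------------------------------------------------------------------


def _inside(shape: ShapeDef, x, y, z, shrink: Mapping[str, float] | None = None):
    """Vectorised voxel-centre membership.

    ``shrink`` maps face identifiers to an inward offset in mm, used to
    carve the inner (non-cortical) solid; absent faces are not offset.
    """
    s = dict(shrink or {})
    ex, ey, ez = shape.extents
    # the solid occupies [0, extent] in each axis in these local coordinates
    d = shape.dims
    k = shape.kind
    if k == "box":
        lox, hix = s.get("x-", 0.0), ex - s.get("x+", 0.0)
        loy, hiy = s.get("y-", 0.0), ey - s.get("y+", 0.0)
        loz, hiz = s.get("z-", 0.0), ez - s.get("z+", 0.0)
        if lox >= hix or loy >= hiy or loz >= hiz:
            raise ShellExceedsExtentError("cortical shell consumes the whole box")
        return ((x > lox) & (x < hix) & (y > loy) & (y < hiy)
                & (z > loz) & (z < hiz))
    if k in ("cylinder", "elliptic-cylinder"):
        r1 = d["d1"] / 2.0 - s.get("lateral", 0.0)
        r2 = d.get("d2", d["d1"]) / 2.0 - s.get("lateral", 0.0)
        loz, hiz = s.get("z-", 0.0), ez - s.get("z+", 0.0)
        if r1 <= 0 or r2 <= 0 or loz >= hiz:
            raise ShellExceedsExtentError("cortical shell consumes the cylinder")
        u = (x - ex / 2.0) / r1
        v = (y - ey / 2.0) / r2
        return (u * u + v * v < 1.0) & (z > loz) & (z < hiz)
    if k == "truncated-cone":
        loz, hiz = s.get("z-", 0.0), ez - s.get("z+", 0.0)
        rb = d["d_base"] / 2.0 - s.get("lateral", 0.0)
        rt = d["d_top"] / 2.0 - s.get("lateral", 0.0)
        if rb <= 0 or rt <= 0 or loz >= hiz:
            raise ShellExceedsExtentError("cortical shell consumes the cone")
        t = np.clip(z / ez, 0.0, 1.0)
        r = rb + (rt - rb) * t  # base at z=0
        u = x - ex / 2.0
        v = y - ey / 2.0
        return (u * u + v * v < r * r) & (z > loz) & (z < hiz)
    if k == "prism":
        a, b = d["a"], d["b"]
        t = s.get("lateral", 0.0)
        loz, hiz = s.get("z-", 0.0), ez - s.get("z+", 0.0)
        hyp = (a * b - b * x - a * y) / float(np.hypot(a, b))
        if loz >= hiz:
            raise ShellExceedsExtentError("cortical shell consumes the prism")
        return (x > t) & (y > t) & (hyp > t) & (z > loz) & (z < hiz)
    # ellipsoid
    t = s.get("all", 0.0)
    r1, r2, r3 = d["d1"] / 2.0 - t, d["d2"] / 2.0 - t, d["d3"] / 2.0 - t
    if min(r1, r2, r3) <= 0:
        raise ShellExceedsExtentError("cortical shell consumes the ellipsoid")
    u = (x - ex / 2.0) / r1
    v = (y - ey / 2.0) / r2
    w = (z - ez / 2.0) / r3
    return u * u + v * v + w * w < 1.0


def _center_coords(n: int, voxel_mm: float) -> np.ndarray:
    # local coordinates: solid starts at one voxel in from the grid origin
    return (np.arange(n) + 0.5) * voxel_mm - voxel_mm


def voxelize(shape: ShapeDef, voxel_mm: float) -> VoxelPhantom:
    """Rasterise a primitive: marrow placeholder inside, outside elsewhere.

    The grid tightly bounds the shape plus a one-voxel margin on every
    side.  A voxel belongs to the solid iff its centre does.
    """
    if not VOXEL_RANGE[0] <= voxel_mm <= VOXEL_RANGE[1]:
        raise GeometryError(f"voxel_mm must be within {VOXEL_RANGE}")
    ex, ey, ez = shape.extents
    for e in (ex, ey, ez):
        if e < 2 * voxel_mm:
            raise DimensionTooSmallError(
                f"extent {e} mm < 2 voxels at {voxel_mm} mm")
    nx = int(ceil(ex / voxel_mm - 1e-9)) + 2
    ny = int(ceil(ey / voxel_mm - 1e-9)) + 2
    nz = int(ceil(ez / voxel_mm - 1e-9)) + 2
    x = _center_coords(nx, voxel_mm)[:, None, None]
    y = _center_coords(ny, voxel_mm)[None, :, None]
    z = _center_coords(nz, voxel_mm)[None, None, :]
    labels = np.where(_inside(shape, x, y, z), MARROW, OUTSIDE).astype(np.uint8)
    return VoxelPhantom(labels, voxel_mm,
                        meta={"shape": shape, "stage": "voxelized"})


def apply_cortical_shell(ph: VoxelPhantom, ctth_mm: float,
                         faces: tuple[str, ...]) -> VoxelPhantom:
    """Relabel a uniform cortical layer on the covered faces.

    The layer is ``round(ctth / voxel)`` whole voxel layers thick, realised
    by carving the shape shrunk inward by that amount on each covered face:
    interior voxels outside the shrunk solid become cortical.
    """
    shape: ShapeDef = ph.meta.get("shape")
    if shape is None:
        raise GeometryError("phantom lacks shape provenance; cannot shell")
    if ctth_mm < ph.voxel_mm:
        raise GeometryError(
            f"cortical thickness {ctth_mm} mm is below one voxel ({ph.voxel_mm} mm)")
    valid = shape.faces()
    for f in faces:
        if f not in valid:
            raise GeometryError(f"face {f!r} not valid for {shape.kind} "
                                f"(expected subset of {valid})")
    # nearest whole number of voxel layers, half-up
    t = int(ctth_mm / ph.voxel_mm + 0.5) * ph.voxel_mm
    nx, ny, nz = ph.labels.shape
    x = _center_coords(nx, ph.voxel_mm)[:, None, None]
    y = _center_coords(ny, ph.voxel_mm)[None, :, None]
    z = _center_coords(nz, ph.voxel_mm)[None, None, :]
    inner = _inside(shape, x, y, z, shrink={f: t for f in faces})
    out = ph.copy()
    interior = out.labels == MARROW
    if not (inner & interior).any():
        raise ShellExceedsExtentError("cortical shell leaves no spongiosa")
    out.labels[interior & ~inner] = CORTICAL
    out.meta.update(stage="shelled", ctth_mm=t, ctth_requested_mm=ctth_mm,
                    cortical_faces=tuple(faces))
    return out
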