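"""Numba kernels: rod-lattice rasterisation and local-thickness stamping.

Kept free of any project types so they stay trivially cacheable; all
coordinates are in mm in the grid frame (voxel centres at (i + 0.5) * vox).
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _fill_segment(mask, p0x, p0y, p0z, p1x, p1y, p1z, axis, half, vox):
    nx, ny, nz = mask.shape
    if axis == 0:
        a0, a1 = p0x, p1x
    elif axis == 1:
        a0, a1 = p0y, p1y
    else:
        a0, a1 = p0z, p1z
    if a1 < a0:  # displaced nodes may invert order
        p0x, p1x = p1x, p0x
        p0y, p1y = p1y, p0y
        p0z, p1z = p1z, p0z
        a0, a1 = a1, a0
    length = a1 - a0
    na = mask.shape[axis]
    m0 = int(np.ceil(a0 / vox - 0.5))
    m1 = int(np.floor(a1 / vox - 0.5))
    if m0 < 0:
        m0 = 0
    if m1 > na - 1:
        m1 = na - 1
    for m in range(m0, m1 + 1):
        c = (m + 0.5) * vox
        f = 0.5 if length <= 0.0 else (c - a0) / length
        cx = p0x + f * (p1x - p0x)
        cy = p0y + f * (p1y - p0y)
        cz = p0z + f * (p1z - p0z)
        if axis == 0:
            b0 = int(np.floor((cy - half) / vox - 0.5)) + 1
            b1 = int(np.ceil((cy + half) / vox - 0.5)) - 1
            c0 = int(np.floor((cz - half) / vox - 0.5)) + 1
            c1 = int(np.ceil((cz + half) / vox - 0.5)) - 1
            if b0 < 0:
                b0 = 0
            if b1 > ny - 1:
                b1 = ny - 1
            if c0 < 0:
                c0 = 0
            if c1 > nz - 1:
                c1 = nz - 1
            for jb in range(b0, b1 + 1):
                for kc in range(c0, c1 + 1):
                    mask[m, jb, kc] = 1
        elif axis == 1:
            b0 = int(np.floor((cx - half) / vox - 0.5)) + 1
            b1 = int(np.ceil((cx + half) / vox - 0.5)) - 1
            c0 = int(np.floor((cz - half) / vox - 0.5)) + 1
            c1 = int(np.ceil((cz + half) / vox - 0.5)) - 1
            if b0 < 0:
                b0 = 0
            if b1 > nx - 1:
                b1 = nx - 1
            if c0 < 0:
                c0 = 0
            if c1 > nz - 1:
                c1 = nz - 1
            for ib in range(b0, b1 + 1):
                for kc in range(c0, c1 + 1):
                    mask[ib, m, kc] = 1
        else:
            b0 = int(np.floor((cx - half) / vox - 0.5)) + 1
            b1 = int(np.ceil((cx + half) / vox - 0.5)) - 1
            c0 = int(np.floor((cy - half) / vox - 0.5)) + 1
            c1 = int(np.ceil((cy + half) / vox - 0.5)) - 1
            if b0 < 0:
                b0 = 0
            if b1 > nx - 1:
                b1 = nx - 1
            if c0 < 0:
                c0 = 0
            if c1 > ny - 1:
                c1 = ny - 1
            for ib in range(b0, b1 + 1):
                for jc in range(c0, c1 + 1):
                    mask[ib, jc, m] = 1


@njit(cache=True)
def rasterize_lattice(mask, pos, widths, vox):
    """Rasterise rods between neighbouring lattice nodes.

    mask    : (nx, ny, nz) uint8, set to 1 inside any rod (never cleared)
    pos     : (n0, n1, n2, 3) node positions in mm
    widths  : (3, n0, n1, n2) full rod width (mm) of the rod leaving node
              (i, j, k) in +axis direction
    vox     : voxel edge (mm)

    A voxel centre belongs to a rod when its transverse distances to the
    (linearly interpolated) rod axis are strictly below width/2.
    """
    n0, n1, n2 = pos.shape[0], pos.shape[1], pos.shape[2]
    for i in range(n0):
        for j in range(n1):
            for k in range(n2):
                p0x = pos[i, j, k, 0]
                p0y = pos[i, j, k, 1]
                p0z = pos[i, j, k, 2]
                if i + 1 < n0:
                    _fill_segment(mask, p0x, p0y, p0z,
                                  pos[i + 1, j, k, 0], pos[i + 1, j, k, 1],
                                  pos[i + 1, j, k, 2], 0,
                                  widths[0, i, j, k] * 0.5, vox)
                if j + 1 < n1:
                    _fill_segment(mask, p0x, p0y, p0z,
                                  pos[i, j + 1, k, 0], pos[i, j + 1, k, 1],
                                  pos[i, j + 1, k, 2], 1,
                                  widths[1, i, j, k] * 0.5, vox)
                if k + 1 < n2:
                    _fill_segment(mask, p0x, p0y, p0z,
                                  pos[i, j, k + 1, 0], pos[i, j, k + 1, 1],
                                  pos[i, j, k + 1, 2], 2,
                                  widths[2, i, j, k] * 0.5, vox)


@njit(cache=True)
def local_thickness(mask, edt, out):
    """Hildebrand-style local thickness by sphere stamping.

    For every foreground voxel c the maximal inscribed sphere centred at c
    has radius edt[c] (voxel units, distance to nearest background centre);
    every voxel strictly inside that sphere is covered by a structure of
    diameter 2 * edt[c].  ``out`` receives the maximum such diameter in
    voxel units.
    """
    nx, ny, nz = mask.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if mask[x, y, z] == 0:
                    continue
                r = edt[x, y, z]
                d = 2.0 * r
                r2 = r * r - 1e-9
                ir = int(r)
                for dx in range(-ir, ir + 1):
                    xx = x + dx
                    if xx < 0 or xx >= nx:
                        continue
                    for dy in range(-ir, ir + 1):
                        yy = y + dy
                        if yy < 0 or yy >= ny:
                            continue
                        rem = r2 - dx * dx - dy * dy
                        if rem < 0:
                            continue
                        for dz in range(-ir, ir + 1):
                            zz = z + dz
                            if zz < 0 or zz >= nz:
                                continue
                            if dz * dz < rem and out[xx, yy, zz] < d:
                                out[xx, yy, zz] = d
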