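"""Numba kernels for cone-beam forward projection and voxel-driven backprojection.

Geometry convention (right-handed, z = rotation axis):
  source at angle beta:     S = SAD * (cos b, sin b, 0)
  in-plane detector axis:   u_hat = (-sin b, cos b, 0)
  detector row axis:        z_hat
  detector plane through (SAD - SDD)*(cos b, sin b, 0); pixel (iu, iv) sits at
  u = (iu - (nu-1)/2)*pitch + lateral_offset from the piercing point
  (the orthogonal projection of the source), v = (iv - (nv-1)/2)*pitch.

Rigid superior-inferior phantom motion enters as a shift of the sampling
grid: a projection taken with the phantom displaced by dz samples the static
volume at z - dz, which is exact for rigid 1-D translation.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True, inline="always")
def _trilinear(vol, fx, fy, fz, nx, ny, nz):
    # zero outside the voxel-center hull in x/y; edge-clamped in z
    # (long-object convention: the phantom continues beyond the grid axially)
    if fx < 0.0 or fy < 0.0 or fx > nx - 1 or fy > ny - 1:
        return 0.0
    if fz < 0.0:
        fz = 0.0
    elif fz > nz - 1:
        fz = nz - 1.0
    ix = int(fx)
    iy = int(fy)
    iz = int(fz)
    if ix == nx - 1:
        ix -= 1
    if iy == ny - 1:
        iy -= 1
    if iz == nz - 1:
        iz -= 1
    dx = fx - ix
    dy = fy - iy
    dz = fz - iz
    c000 = vol[ix, iy, iz]
    c100 = vol[ix + 1, iy, iz]
    c010 = vol[ix, iy + 1, iz]
    c110 = vol[ix + 1, iy + 1, iz]
    c001 = vol[ix, iy, iz + 1]
    c101 = vol[ix + 1, iy, iz + 1]
    c011 = vol[ix, iy + 1, iz + 1]
    c111 = vol[ix + 1, iy + 1, iz + 1]
    c00 = c000 * (1 - dx) + c100 * dx
    c10 = c010 * (1 - dx) + c110 * dx
    c01 = c001 * (1 - dx) + c101 * dx
    c11 = c011 * (1 - dx) + c111 * dx
    c0 = c00 * (1 - dy) + c10 * dy
    c1 = c01 * (1 - dy) + c11 * dy
    return c0 * (1 - dz) + c1 * dz


@njit(cache=True, fastmath=True)
def forward_project_kernel(
    vol,          # (nx, ny, nz) float64
    spacing,      # float, mm
    ox, oy, oz,   # origin: center of voxel (0,0,0), mm
    angles,       # (np,) rad
    dzs,          # (np,) phantom displacement per projection, mm
    sad, sdd,     # mm
    nu, nv,       # detector pixel counts
    pitch,        # detector pixel pitch, mm
    offset,       # lateral detector offset, mm
    step,         # ray-march step, mm
):
    nproj = angles.shape[0]
    nx, ny, nz = vol.shape
    out = np.zeros((nproj, nv, nu), dtype=np.float64)
    # bounding box of voxel centers (samples outside are zero)
    x0, x1 = ox, ox + spacing * (nx - 1)
    y0, y1 = oy, oy + spacing * (ny - 1)
    z0, z1 = oz, oz + spacing * (nz - 1)
    inv_sp = 1.0 / spacing
    for p in range(nproj):
        cb = math.cos(angles[p])
        sb = math.sin(angles[p])
        sx = sad * cb
        sy = sad * sb
        dzp = dzs[p]
        cxd = (sad - sdd) * cb
        cyd = (sad - sdd) * sb
        for iv in range(nv):
            v = (iv - (nv - 1) / 2.0) * pitch
            for iu in range(nu):
                u = (iu - (nu - 1) / 2.0) * pitch + offset
                px = cxd - u * sb
                py = cyd + u * cb
                pz = v
                dx = px - sx
                dy = py - sy
                dzr = pz - 0.0
                norm = math.sqrt(dx * dx + dy * dy + dzr * dzr)
                dx /= norm
                dy /= norm
                dzr /= norm
                # slab-clip against the voxel-center box in x/y only;
                # z is edge-clamped in the sampler (long-object convention)
                tmin = 0.0
                tmax = norm
                ok = True
                for ax in range(2):
                    if ax == 0:
                        o = sx
                        d = dx
                        lo = x0
                        hi = x1
                    else:
                        o = sy
                        d = dy
                        lo = y0
                        hi = y1
                    if abs(d) < 1e-12:
                        if o < lo or o > hi:
                            ok = False
                            break
                    else:
                        t1 = (lo - o) / d
                        t2 = (hi - o) / d
                        if t1 > t2:
                            t1, t2 = t2, t1
                        if t1 > tmin:
                            tmin = t1
                        if t2 < tmax:
                            tmax = t2
                if not ok or tmax <= tmin:
                    continue
                length = tmax - tmin
                nstep = int(length / step) + 1
                dt = length / nstep
                acc = 0.0
                for k in range(nstep):
                    t = tmin + (k + 0.5) * dt
                    fx = (sx + t * dx - x0) * inv_sp
                    fy = (sy + t * dy - y0) * inv_sp
                    fz = (t * dzr - dzp - z0) * inv_sp
                    acc += _trilinear(vol, fx, fy, fz, nx, ny, nz)
                out[p, iv, iu] = acc * dt
    return out


@njit(cache=True, fastmath=True)
def backproject_kernel(
    filtered,     # (np, nv, nu) redundancy-weighted ramp-filtered projections
    angles,       # (np,) rad
    sad,          # mm
    pitch_iso,    # virtual (isocenter-plane) detector pitch, mm
    offset_iso,   # virtual lateral offset, mm
    nxo, nyo, nzo,
    spacing, ox, oy, oz,
    dbeta,        # angular step, rad
):
    nproj, nv, nu = filtered.shape
    vol = np.zeros((nxo, nyo, nzo), dtype=np.float64)
    for p in range(nproj):
        cb = math.cos(angles[p])
        sb = math.sin(angles[p])
        proj = filtered[p]
        for ix in range(nxo):
            x = ox + ix * spacing
            for iy in range(nyo):
                y = oy + iy * spacing
                s = x * cb + y * sb          # toward the source
                t = -x * sb + y * cb         # along u_hat
                U = sad - s
                if U < 1e-6:
                    continue
                ratio = sad / U
                w2 = ratio * ratio * dbeta
                fu = (t * ratio - offset_iso) / pitch_iso + (nu - 1) / 2.0
                if fu < 0.0 or fu > nu - 1:
                    continue
                iu0 = int(fu)
                if iu0 == nu - 1:
                    iu0 -= 1
                du = fu - iu0
                zfac = ratio / pitch_iso
                for iz in range(nzo):
                    z = oz + iz * spacing
                    fv = z * zfac + (nv - 1) / 2.0
                    if fv < 0.0 or fv > nv - 1:
                        continue
                    iv0 = int(fv)
                    if iv0 == nv - 1:
                        iv0 -= 1
                    dv = fv - iv0
                    val = (
                        proj[iv0, iu0] * (1 - dv) * (1 - du)
                        + proj[iv0, iu0 + 1] * (1 - dv) * du
                        + proj[iv0 + 1, iu0] * dv * (1 - du)
                        + proj[iv0 + 1, iu0 + 1] * dv * du
                    )
                    vol[ix, iy, iz] += w2 * val
    return vol
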