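"""Independent brute-force oracles for projector geometry tests."""

import math

import numpy as np


def ray_sum_oracle(volume, src, dst, step=0.05):
    """Brute-force fine-step line integral with the projector's conventions:
    trilinear sampling, zero outside the x/y voxel-center hull, z edge-clamped."""
    src, dst = np.asarray(src, float), np.asarray(dst, float)
    length = np.linalg.norm(dst - src)
    n = int(length / step)
    ts = (np.arange(n) + 0.5) * (length / n)
    pts = src + np.outer(ts, (dst - src) / length)
    fx = (pts[:, 0] - volume.origin[0]) / volume.spacing
    fy = (pts[:, 1] - volume.origin[1]) / volume.spacing
    fz = (pts[:, 2] - volume.origin[2]) / volume.spacing
    nx, ny, nz = volume.shape
    inside = (fx >= 0) & (fx <= nx - 1) & (fy >= 0) & (fy <= ny - 1)
    fz = np.clip(fz, 0, nz - 1)
    acc = np.zeros(n)
    v = volume.values
    x0 = np.clip(np.floor(fx).astype(int), 0, nx - 2)
    y0 = np.clip(np.floor(fy).astype(int), 0, ny - 2)
    z0 = np.clip(np.floor(fz).astype(int), 0, nz - 2)
    dx, dy, dz = fx - x0, fy - y0, fz - z0
    for cx in (0, 1):
        for cy in (0, 1):
            for cz in (0, 1):
                w = (
                    (dx if cx else 1 - dx)
                    * (dy if cy else 1 - dy)
                    * (dz if cz else 1 - dz)
                )
                acc += w * v[x0 + cx, y0 + cy, z0 + cz]
    acc[~inside] = 0.0
    return acc.sum() * (length / n)


def pixel_position(protocol, beta, iu, iv):
    """World position of detector pixel (iu, iv) at gantry angle beta."""
    cb, sb = math.cos(beta), math.sin(beta)
    u = (iu - (protocol.nu - 1) / 2) * protocol.pitch + protocol.lateral_offset_mm
    v = (iv - (protocol.nv - 1) / 2) * protocol.pitch
    cx = (protocol.sad - protocol.sdd) * cb
    cy = (protocol.sad - protocol.sdd) * sb
    return np.array([cx - u * sb, cy + u * cb, v])
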