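"""Numba-compiled exact point-to-triangle nearest queries.

The closest-point-on-triangle routine follows the standard Voronoi-region
case analysis; the mesh query is an exhaustive scan with a
centroid-plus-bounding-radius prune, so it is exact for every input
(including sliver triangles produced by plane cuts).
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True, inline="always")
def _closest_on_triangle(px, py, pz, tri):
    ax, ay, az = tri[0, 0], tri[0, 1], tri[0, 2]
    bx, by, bz = tri[1, 0], tri[1, 1], tri[1, 2]
    cx, cy, cz = tri[2, 0], tri[2, 1], tri[2, 2]

    abx, aby, abz = bx - ax, by - ay, bz - az
    acx, acy, acz = cx - ax, cy - ay, cz - az
    apx, apy, apz = px - ax, py - ay, pz - az

    d1 = abx * apx + aby * apy + abz * apz
    d2 = acx * apx + acy * apy + acz * apz
    if d1 <= 0.0 and d2 <= 0.0:
        return ax, ay, az

    bpx, bpy, bpz = px - bx, py - by, pz - bz
    d3 = abx * bpx + aby * bpy + abz * bpz
    d4 = acx * bpx + acy * bpy + acz * bpz
    if d3 >= 0.0 and d4 <= d3:
        return bx, by, bz

    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        denom = d1 - d3
        v = d1 / denom if denom != 0.0 else 0.0
        return ax + v * abx, ay + v * aby, az + v * abz

    cpx, cpy, cpz = px - cx, py - cy, pz - cz
    d5 = abx * cpx + aby * cpy + abz * cpz
    d6 = acx * cpx + acy * cpy + acz * cpz
    if d6 >= 0.0 and d5 <= d6:
        return cx, cy, cz

    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        denom = d2 - d6
        w = d2 / denom if denom != 0.0 else 0.0
        return ax + w * acx, ay + w * acy, az + w * acz

    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        denom = (d4 - d3) + (d5 - d6)
        w = (d4 - d3) / denom if denom != 0.0 else 0.0
        return (
            bx + w * (cx - bx),
            by + w * (cy - by),
            bz + w * (cz - bz),
        )

    denom = va + vb + vc
    if denom != 0.0:
        v = vb / denom
        w = vc / denom
        return (
            ax + v * abx + w * acx,
            ay + v * aby + w * acy,
            az + v * abz + w * acz,
        )
    return ax, ay, az


@numba.njit(cache=True, parallel=False)
def nearest_on_mesh(points, triangles, centroids, radii):
    """Exact nearest point on a triangle soup for each query point.

    Returns ``(distances, closest_points, triangle_indices)``.
    """
    n = points.shape[0]
    m = triangles.shape[0]
    out_d = np.empty(n)
    out_cp = np.empty((n, 3))
    out_tri = np.empty(n, dtype=np.int64)
    cd2 = np.empty(m)
    for i in range(n):
        px, py, pz = points[i, 0], points[i, 1], points[i, 2]
        # squared centroid distances and the nearest-centroid seed triangle
        best_j = 0
        best_cd = 1e300
        for j in range(m):
            dx = px - centroids[j, 0]
            dy = py - centroids[j, 1]
            dz = pz - centroids[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            cd2[j] = d2
            if d2 < best_cd:
                best_cd = d2
                best_j = j
        qx, qy, qz = _closest_on_triangle(px, py, pz, triangles[best_j])
        dx, dy, dz = px - qx, py - qy, pz - qz
        best_d2 = dx * dx + dy * dy + dz * dz
        best_d = np.sqrt(best_d2)
        bx, by, bz = qx, qy, qz
        bt = best_j
        for j in range(m):
            # triangle j can win only if |p - c_j| < best_d + r_j
            bound = best_d + radii[j]
            if cd2[j] >= bound * bound or j == best_j:
                continue
            qx, qy, qz = _closest_on_triangle(px, py, pz, triangles[j])
            dx, dy, dz = px - qx, py - qy, pz - qz
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < best_d2:
                best_d2 = d2
                best_d = np.sqrt(d2)
                bx, by, bz = qx, qy, qz
                bt = j
        out_d[i] = best_d
        out_cp[i, 0] = bx
        out_cp[i, 1] = by
        out_cp[i, 2] = bz
        out_tri[i] = bt
    return out_d, out_cp, out_tri
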