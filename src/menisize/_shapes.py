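"""Parametric meniscus and proximal-tibia mesh construction.

The shapes are procedural, not statistical: a meniscus is a triangular
wedge cross-section (tall peripheral rim tapering to a thin central edge)
swept along a C-shaped elliptical arc, and a proximal tibia is a tapered
extrusion of an asymmetric elliptical cross-section whose top surface
carries two gently concave condylar dishes and a central intercondylar
eminence with medial and lateral tubercles.  All dimensions are in mm and
the canonical frame is +x anterior, +y medial (right knee), +z proximal.
"""

from __future__ import annotations

import numpy as np

__all__ = ["build_meniscus", "build_tibia", "TIBIA_LENGTH_MM"]

#: Proximal tibia segment length along z (the template is 3.5 cm long).
TIBIA_LENGTH_MM = 35.0


def _close_ring_sweep(rings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate a swept closed ring (n_arc, n_ring, 3) with end caps."""
    n_arc, n_ring, _ = rings.shape
    vertices = rings.reshape(-1, 3)
    faces = []
    for i in range(n_arc - 1):
        for j in range(n_ring):
            a = i * n_ring + j
            b = i * n_ring + (j + 1) % n_ring
            c = (i + 1) * n_ring + j
            d = (i + 1) * n_ring + (j + 1) % n_ring
            faces.append((a, b, d))
            faces.append((a, d, c))
    # end caps: fan triangulation of the (convex) profile polygon
    for j in range(1, n_ring - 1):
        faces.append((0, j + 1, j))  # start cap
        base = (n_arc - 1) * n_ring
        faces.append((base, base + j, base + j + 1))  # end cap
    return vertices, np.asarray(faces, dtype=np.int64)


def _wedge_profile() -> np.ndarray:
    """Closed 2D profile ring (f, z_frac): f is the radial fraction of the
    local ellipse, z_frac the height fraction.

    Thin inner edge, tall outer rim, flat bottom.  The top carries a flat
    band parallel to the bottom over the outer part of the body, so the
    minimal-extent direction of the swept solid is exactly the
    construction z-axis and "height" means slab thickness.
    """
    pts = [
        (0.0, 0.10),   # inner edge, thin
        (0.0, 0.0),    # inner bottom
        (0.5, 0.0),    # bottom mid
        (1.0, 0.0),    # outer bottom
        (1.0, 0.5),    # outer wall
        (1.0, 1.0),    # outer top (rim)
        (0.8, 1.0),    # flat top band,
        (0.55, 1.0),   # parallel to the bottom
    ]
    # taper from the top band down to the thin inner edge
    for f in (0.4, 0.25, 0.12):
        pts.append((f, 0.10 + 0.90 * (f / 0.55) ** 1.2))
    return np.asarray(pts, dtype=float)


def build_meniscus(
    width: float,
    length: float,
    height: float,
    span_deg: float,
    n_arc: int = 96,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Build a C-shaped meniscus wedge.

    Returns ``(vertices, faces, anterior_root, posterior_root)``.  The body
    opens toward -y (the intercondylar side); the root chord runs along x.
    Extents in the construction frame match ``length``/``width``/``height``
    exactly (the swept shape is affinely rescaled per axis).
    """
    delta = np.radians((360.0 - span_deg) / 2.0)
    a = length / 2.0
    b = width / (1.0 + np.cos(delta))
    thetas = np.linspace(-np.pi / 2 + delta, 3 * np.pi / 2 - delta, n_arc)
    s = np.linspace(0.0, 1.0, n_arc)  # normalized arc position

    taper = np.sin(np.pi * s) ** 0.5
    thickness = 0.45 * (0.30 + 0.70 * taper)       # radial fraction
    h = height * (0.30 + 0.70 * np.sin(np.pi * s) ** 0.6)

    profile = _wedge_profile()
    rings = np.empty((n_arc, len(profile), 3))
    for i, th in enumerate(thetas):
        f_in = 1.0 - thickness[i]
        f = f_in + profile[:, 0] * thickness[i]
        rings[i, :, 0] = f * a * np.cos(th)
        rings[i, :, 1] = f * b * np.sin(th)
        rings[i, :, 2] = profile[:, 1] * h[i]

    vertices, faces = _close_ring_sweep(rings)
    faces = faces[:, ::-1]  # outward normals
    anterior = rings[0].mean(axis=0)
    posterior = rings[-1].mean(axis=0)
    if anterior[0] < posterior[0]:
        anterior, posterior = posterior, anterior

    # rescale each axis so the extents are exact
    lo = vertices.min(axis=0)
    hi = vertices.max(axis=0)
    scale = np.array([length, width, height]) / (hi - lo)
    center = (hi + lo) / 2.0
    vertices = (vertices - center) * scale
    anterior = (anterior - center) * scale
    posterior = (posterior - center) * scale
    return vertices, faces, anterior, posterior


def _blend(lat: float, med: float, sin_theta: np.ndarray) -> np.ndarray:
    """Smoothly interpolate a per-side parameter across the midline."""
    t = np.clip((sin_theta + 0.3) / 0.6, 0.0, 1.0)
    w = t * t * (3.0 - 2.0 * t)  # smoothstep
    return lat + (med - lat) * w


#: Default intercondylar eminence geometry: a raised ridge spanning the
#: region between the tubercle planes (|y| <= half_width) with a sharp
#: lateral falloff, topped by the medial and lateral tubercle spines whose
#: apexes sit on the tubercle planes.  All values in mm.
DEFAULT_EMINENCE = {
    "ridge_height": 5.0,     # ridge above condylar level
    "half_width": 3.5,       # tubercle-plane distance from the midline
    "ridge_margin": 1.5,     # ridge crest ends this far inside those planes
    "falloff": 1.0,          # lateral decay length of the ridge crest
    "ap_sigma_frac": 0.32,   # AP footprint as a fraction of plateau depth
    "tubercle_medial": {"x": -2.0, "height": 4.0, "sigma_x": 2.5,
                        "sigma_y": 1.2},
    "tubercle_lateral": {"x": 2.0, "height": 4.0, "sigma_x": 2.5,
                         "sigma_y": 1.2},
}


def build_tibia(
    width_medial: float,
    width_lateral: float,
    depth_medial: float,
    depth_lateral: float,
    eminence: dict | None = None,
    dish_depth: float = 2.0,
    n_theta: int = 120,
    n_r: int = 16,
    n_z: int = 8,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Build a proximal tibia segment of :data:`TIBIA_LENGTH_MM` length.

    ``width_*`` are compartment half-widths measured from the midline
    (so the compartment's y-extent), ``depth_*`` the AP extents per side;
    ``eminence`` optionally overrides :data:`DEFAULT_EMINENCE`.
    Returns ``(vertices, faces, landmarks)`` with analytic landmark points
    for the tubercles, the plateau center and the plateau level.
    """
    em = eminence or DEFAULT_EMINENCE
    y_t = em["half_width"]
    w = em["falloff"]
    ap_sigma = em["ap_sigma_frac"] * (depth_medial + depth_lateral) / 2.0
    tub_m = em["tubercle_medial"]
    tub_l = em["tubercle_lateral"]

    def z_top(x, y):
        cy_m, cy_l = width_medial * 0.55, -width_lateral * 0.55
        sx_m, sy_m = depth_medial * 0.30, width_medial * 0.32
        sx_l, sy_l = depth_lateral * 0.30, width_lateral * 0.32
        z = -dish_depth * np.exp(-(((x) / sx_m) ** 2 + ((y - cy_m) / sy_m) ** 2))
        z = z - dish_depth * np.exp(-(((x) / sx_l) ** 2 + ((y - cy_l) / sy_l) ** 2))
        # intercondylar ridge: crest confined inside the tubercle planes
        # (beyond the tubercles lies articular surface)
        crest = max(y_t - em["ridge_margin"], 0.0)
        lateral = np.exp(-(np.maximum(np.abs(y) - crest, 0.0) / w) ** 2)
        z = z + em["ridge_height"] * np.exp(-((x / ap_sigma) ** 2)) * lateral
        # narrow tubercle spines, apexes on the tubercle planes (y = +/- y_t)
        for t, yc in ((tub_m, y_t), (tub_l, -y_t)):
            z = z + t["height"] * np.exp(
                -((x - t["x"]) ** 2) / (2.0 * t["sigma_x"] ** 2)
                - ((y - yc) ** 2) / (2.0 * t["sigma_y"] ** 2)
            )
        return z

    thetas = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    st, ct = np.sin(thetas), np.cos(thetas)
    a_b = _blend(depth_lateral / 2.0, depth_medial / 2.0, st)
    b_b = _blend(width_lateral, width_medial, st)

    vertices = [np.array([0.0, 0.0, z_top(0.0, 0.0)])]  # top center
    # concentric top rings out to the rim, denser toward the center so the
    # sharp eminence falloff is resolved
    for fr in np.linspace(0.0, 1.0, n_r + 1)[1:] ** 1.3:
        x = fr * a_b * ct
        y = fr * b_b * st
        vertices.append(np.column_stack([x, y, z_top(x, y)]))
    rim_z = vertices[-1][:, 2]
    # total segment length (eminence apex to cut bottom) is exactly 35 mm
    apex_z = max(float(vertices[0][2]), *(float(r[:, 2].max()) for r in vertices[1:]))
    bottom_z = apex_z - TIBIA_LENGTH_MM
    # tapered wall rings down the shaft
    for t in np.linspace(0.0, 1.0, n_z + 1)[1:]:
        s = 1.0 - 0.45 * t**1.5
        x = s * a_b * ct
        y = s * b_b * st
        z = rim_z * (1.0 - t) + bottom_z * t
        vertices.append(np.column_stack([x, y, z]))
    bottom_center = np.array([0.0, 0.0, bottom_z])
    ring_list = vertices[1:]
    verts = np.concatenate(
        [vertices[0][None, :]] + ring_list + [bottom_center[None, :]]
    )
    n_rings = len(ring_list)
    bottom_idx = 1 + n_rings * n_theta

    def ring(i, j):
        return 1 + i * n_theta + (j % n_theta)

    faces = []
    for j in range(n_theta):  # top center fan
        faces.append((0, ring(0, j), ring(0, j + 1)))
    for i in range(n_rings - 1):  # ring bands (top surface then wall)
        for j in range(n_theta):
            a = ring(i, j)
            b = ring(i, j + 1)
            c = ring(i + 1, j)
            d = ring(i + 1, j + 1)
            faces.append((a, c, d))
            faces.append((a, d, b))
    for j in range(n_theta):  # bottom fan
        faces.append((bottom_idx, ring(n_rings - 1, j + 1), ring(n_rings - 1, j)))
    faces = np.asarray(faces, dtype=np.int64)

    landmarks = {
        "medial_tubercle": np.array(
            [tub_m["x"], y_t, float(z_top(tub_m["x"], y_t))]
        ),
        "lateral_tubercle": np.array(
            [tub_l["x"], -y_t, float(z_top(tub_l["x"], -y_t))]
        ),
        "plateau_center": np.array([0.0, 0.0, float(z_top(0.0, 0.0))]),
        "plateau_level_z": float(verts[:, 2].max()),
    }
    return verts, faces, landmarks


def random_wave_field(rng: np.random.Generator, sd: float):
    """Smooth low-frequency random displacement field with std ~= ``sd``.

    Returns a callable ``points -> displacements``: a sum of three random
    cosine waves per coordinate with wavelengths of a few centimetres, so
    the perturbed meshes stay valid (no folds at mm scale) and the same
    field can be applied consistently to meshes and landmark points of one
    specimen.
    """
    waves = [
        (rng.normal(scale=0.12, size=3), rng.uniform(0.0, 2.0 * np.pi),
         rng.normal(size=3))
        for _ in range(3)
    ]

    def field(points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if sd <= 0:
            return np.zeros_like(points)
        disp = np.zeros_like(points)
        for k, phase, amp in waves:
            disp += amp[None, :] * np.cos(points @ k + phase)[:, None]
        return disp * (sd / np.sqrt(1.5))

    return field
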