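"""Shared fixtures: procedural meshes, a small prepared cohort, and an
independent brute-force point-to-triangle oracle."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

import menisize as mz


# ---------------------------------------------------------------------------
# independent closest-point-on-triangle reference (interior critical point
# plus clamped edge minimizers; no shared code with the package kernel)
# ---------------------------------------------------------------------------
def closest_point_triangle_ref(p, a, b, c):
    p, a, b, c = (np.asarray(x, dtype=float) for x in (p, a, b, c))
    candidates = []
    ab, ac = b - a, c - a
    G = np.array([[ab @ ab, ab @ ac], [ab @ ac, ac @ ac]])
    rhs = np.array([ab @ (p - a), ac @ (p - a)])
    det = np.linalg.det(G)
    if abs(det) > 1e-300:
        s, t = np.linalg.solve(G, rhs)
        if s >= 0 and t >= 0 and s + t <= 1:
            candidates.append(a + s * ab + t * ac)
    for u, v in ((a, b), (b, c), (a, c)):
        e = v - u
        ee = e @ e
        lam = 0.0 if ee == 0 else np.clip((p - u) @ e / ee, 0.0, 1.0)
        candidates.append(u + lam * e)
    dists = [np.linalg.norm(p - q) for q in candidates]
    i = int(np.argmin(dists))
    return dists[i], candidates[i]


def brute_force_nearest(points, vertices, faces):
    """Exhaustive exact nearest-surface distances (test oracle)."""
    vertices = np.asarray(vertices, dtype=float)
    out = np.empty(len(points))
    for i, p in enumerate(np.atleast_2d(points)):
        best = np.inf
        for f in faces:
            d, _ = closest_point_triangle_ref(p, *vertices[f])
            best = min(best, d)
        out[i] = best
    return out


def surface_mesh_from_trimesh(tm, name=""):
    return mz.SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), name)


def random_valid_mesh(n_faces, seed):
    """Connected random triangle soup (valid, not necessarily closed)."""
    rng = np.random.default_rng(seed)
    tm = trimesh.creation.icosphere(subdivisions=2)
    v = np.asarray(tm.vertices) * (10.0 + 3.0 * rng.random())
    v = v + rng.normal(scale=0.5, size=v.shape)
    f = np.asarray(tm.faces)[: n_faces]
    used = np.unique(f)
    remap = -np.ones(len(v), dtype=int)
    remap[used] = np.arange(len(used))
    return mz.SurfaceMesh(v[used], remap[f], name=f"rand{seed}")


@pytest.fixture(scope="session")
def template():
    return mz.build_default_template()


@pytest.fixture(scope="session")
def fast_icp():
    return mz.IcpParams(
        seed=1, n_sample_points=400, max_iterations=60, rel_tolerance=1e-6
    )


@pytest.fixture(scope="session")
def single_start_icp():
    return mz.IcpParams(
        seed=1,
        n_sample_points=300,
        max_iterations=60,
        rel_tolerance=1e-6,
        multistart_rotations=(np.eye(3),),
    )


@pytest.fixture(scope="session")
def cohort6():
    """Raw (unprepared) cohort of 6 with ground truth."""
    return mz.generate_cohort(mz.CohortParams(n=6, seed=3))


@pytest.fixture(scope="session")
def prepared6(template, fast_icp):
    """Prepared cohort of 6 (template frame, cuts, dimensions)."""
    specimens, truths = mz.generate_cohort(mz.CohortParams(n=6, seed=17))
    mz.prepare_cohort(specimens, template, fast_icp)
    return specimens, truths
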