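"""Oriented-bounding-box meniscus morphometry and radiographic sizing.

Meniscus width/length/height are read off an oriented bounding box whose
vertical axis is the minimal-extent axis of the initial OBB (a meniscus is
a flat structure, so this is its height direction) and whose in-plane
orientation is re-aligned to the anterior–posterior meniscus root axis.
Radiographic (Pollard) sizing converts plateau measurements to meniscus
width/length: width passes through, length is the lateral-view plateau
depth multiplied by 0.8 (medial) or 0.7 (lateral).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .mesh_core import AnatomicalFrame, Compartment, SurfaceMesh

__all__ = [
    "MeniscusDimensions",
    "RootLandmarks",
    "RadiographMeasurement",
    "POLLARD_FACTORS",
    "meniscus_dimensions",
    "pollard_dimensions",
]

#: Pollard plateau-depth-to-meniscus-length factors per compartment.
POLLARD_FACTORS = {Compartment.MEDIAL: 0.8, Compartment.LATERAL: 0.7}


@dataclass(frozen=True)
class MeniscusDimensions:
    """Meniscus extents (mm): length along x, width along y, height along z
    of the root-aligned box frame."""

    width: float
    length: float
    height: float
    box_frame: AnatomicalFrame

    def __post_init__(self):
        if not (self.width > 0 and self.length > 0 and self.height > 0):
            raise ValidationError("meniscus dimensions must be positive")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.width, self.length, self.height)


@dataclass(frozen=True)
class RootLandmarks:
    """Anterior and posterior meniscus root insertion points (mm)."""

    anterior_root: np.ndarray
    posterior_root: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.anterior_root, float).reshape(3)
        p = np.asarray(self.posterior_root, float).reshape(3)
        if np.allclose(a, p):
            raise ValidationError("root landmarks must be distinct points")
        object.__setattr__(self, "anterior_root", a)
        object.__setattr__(self, "posterior_root", p)

    def check_on_surface(self, mesh: SurfaceMesh, tol_mm: float = 5.0) -> None:
        d, _, _ = mesh.nearest.query(
            np.vstack([self.anterior_root, self.posterior_root])
        )
        if d.max() > tol_mm:
            raise ValidationError(
                f"root landmark is {d.max():.1f} mm from the meniscus surface"
            )

    def transformed(self, transform) -> "RootLandmarks":
        return RootLandmarks(
            transform.apply(self.anterior_root),
            transform.apply(self.posterior_root),
        )


@dataclass(frozen=True)
class RadiographMeasurement:
    """Plain-radiograph plateau measurements for one compartment (mm)."""

    ap_width: float
    lateral_plateau_depth: float
    compartment: Compartment

    def __post_init__(self):
        if not (self.ap_width > 0 and self.lateral_plateau_depth > 0):
            raise ValidationError("radiograph measurements must be positive")
        if not isinstance(self.compartment, Compartment):
            raise ValidationError(f"unknown compartment: {self.compartment!r}")


def _signed_axis(axis: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Orient ``axis`` toward ``reference`` (deterministic for ties)."""
    d = float(axis @ reference)
    if d < 0:
        return -axis
    if d == 0:
        nz = np.flatnonzero(axis)
        if len(nz) and axis[nz[0]] < 0:
            return -axis
    return axis


def _height_axis(vertices: np.ndarray) -> np.ndarray:
    """Minimal-extent direction of the model points.

    The smallest principal axis of the vertex cloud, refined by a
    0.5-degree grid search about the two in-plane principal axes to
    minimize the extent.  Every step is rigid-equivariant, so the
    resulting measurements are exactly invariant under rigid motion.
    """
    X = vertices - vertices.mean(axis=0)
    _, V = np.linalg.eigh(X.T @ X)
    z = V[:, 0]  # smallest-variance direction (eigh sorts ascending)
    from .geometry import rotation_about_axis

    angles = np.arange(-45.0, 45.0 + 1e-9, 0.5)
    for _ in range(2):
        for axis in (V[:, 1], V[:, 2]):
            cands = np.array(
                [rotation_about_axis(axis, a) @ z for a in angles]
            )
            extents = np.ptp(X @ cands.T, axis=0)
            z = cands[int(np.argmin(extents))]
    return z


def meniscus_dimensions(
    mesh: SurfaceMesh, roots: RootLandmarks
) -> MeniscusDimensions:
    """Measure width/length/height from a root-aligned oriented box.

    The minimal-extent axis of the model points supplies the height (z)
    direction (a meniscus is flat, so this is its thickness direction);
    the box is then rotated about z until its x-axis is parallel to the
    anterior–posterior root axis, and the extents re-measured so the box
    fully encloses the meniscus.
    """
    z_axis = _signed_axis(
        _height_axis(mesh.vertices), np.array([0.0, 0.0, 1.0])
    )

    chord = roots.posterior_root - roots.anterior_root
    x_axis = chord - (chord @ z_axis) * z_axis
    nx = np.linalg.norm(x_axis)
    if nx < 1e-9:
        raise ValidationError(
            "root axis is parallel to the height axis (roots coincide "
            "after projection)"
        )
    x_axis = x_axis / nx
    y_axis = np.cross(z_axis, x_axis)

    R = np.column_stack([x_axis, y_axis, z_axis])
    proj = mesh.vertices @ R
    lo = proj.min(axis=0)
    hi = proj.max(axis=0)
    center = R @ ((lo + hi) / 2.0)
    frame = AnatomicalFrame(center, x_axis, y_axis, z_axis)
    return MeniscusDimensions(
        width=float(hi[1] - lo[1]),
        length=float(hi[0] - lo[0]),
        height=float(hi[2] - lo[2]),
        box_frame=frame,
    )


def pollard_dimensions(
    measurement: RadiographMeasurement,
) -> tuple[float, float]:
    """Radiographic meniscus ``(width, length)`` from plateau measurements."""
    factor = POLLARD_FACTORS.get(measurement.compartment)
    if factor is None:
        raise ValidationError(f"unknown compartment: {measurement.compartment!r}")
    return measurement.ap_width, measurement.lateral_plateau_depth * factor
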