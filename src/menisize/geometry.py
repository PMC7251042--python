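"""Low-level geometric primitives shared across the package.

Provides rigid transforms and an exact nearest-point-on-surface query for
triangle meshes.  The query is the workhorse behind ICP correspondence and
the mean/maximum surface-distance score, so it is exact (point-to-triangle,
not point-to-vertex): a compiled exhaustive scan with a sound
centroid-plus-bounding-radius prune that can never discard the true
nearest triangle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ValidationError

__all__ = ["RigidTransform", "NearestSurface", "rotation_about_axis"]


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """3x3 rotation matrix about ``axis`` by ``angle_deg`` degrees."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValidationError("rotation axis must be non-zero")
    return Rotation.from_rotvec(np.radians(angle_deg) * axis / n).as_matrix()


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` in millimetres.

    ``rotation`` must be orthonormal with determinant +1 (tolerance 1e-9).
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not (np.isfinite(R).all() and np.isfinite(t).all()):
            raise ValidationError("rigid transform must be finite")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-9:
            raise ValidationError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValidationError("rotation matrix must have determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix) -> "RigidTransform":
        m = np.asarray(matrix, dtype=float)
        return cls(m[:3, :3], m[:3, 3])

    def to_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


class NearestSurface:
    """Exact closest-point-on-surface queries against a triangle mesh.

    An exhaustive compiled scan with a centroid-plus-bounding-radius prune:
    exact for every input (point-to-triangle, never point-to-vertex), with
    no acceleration structure that could miss the true nearest triangle.
    """

    def __init__(self, vertices, faces):
        vertices = np.asarray(vertices, dtype=float)
        faces = np.asarray(faces, dtype=np.int64)
        if len(faces) == 0:
            raise ValidationError("mesh has no faces")
        self.triangles = np.ascontiguousarray(vertices[faces])
        self.centroids = np.ascontiguousarray(self.triangles.mean(axis=1))
        self.radii = np.ascontiguousarray(
            np.linalg.norm(
                self.triangles - self.centroids[:, None, :], axis=2
            ).max(axis=1)
        )

    def query(self, points) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(distances, closest_points, triangle_indices)``."""
        from ._kernels import nearest_on_mesh

        points = np.ascontiguousarray(
            np.atleast_2d(np.asarray(points, dtype=float))
        )
        return nearest_on_mesh(
            points, self.triangles, self.centroids, self.radii
        )
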