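"""Template alignment and standardized tibia-plateau cuts.

Every proximal tibia is ICP-superimposed onto an average right tibia
template (3.5 cm long) carrying preconfigured cutting planes: an axial
plane 10 mm distal and parallel to the plateau, and sagittal planes
perpendicular to it — one centered on the plateau and one through each
intercondylar tubercle.  Three plateau configurations are produced:

* ``ENTIRE`` — the full proximal surface above the axial plane (100%),
* ``HALF_WITH_EMINENCE`` — one compartment including the intercondylar
  area, split at the centered sagittal plane (50%),
* ``HALF_WITHOUT_EMINENCE`` — one compartment excluding the intercondylar
  region, split at the tubercle plane of that side (< 50%).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import trimesh

from ._shapes import build_tibia
from .errors import ValidationError
from .geometry import RigidTransform
from .mesh_core import AnatomicalFrame, Compartment, SurfaceMesh, load_mesh, save_mesh
from .registration import IcpParams, icp_register, surface_distance

__all__ = [
    "PlateauConfig",
    "CuttingPlaneSet",
    "TibiaTemplate",
    "AlignmentResult",
    "align_to_template",
    "cut_plateau",
    "build_default_template",
    "save_template",
    "load_template",
]

#: Distance from the plateau level to the axial cutting plane (1 cm).
AXIAL_OFFSET_MM = 10.0


class PlateauConfig(enum.Enum):
    ENTIRE = "entire"
    HALF_WITH_EMINENCE = "half_with_eminence"
    HALF_WITHOUT_EMINENCE = "half_without_eminence"


Plane = tuple[np.ndarray, np.ndarray]  # (point, unit normal)


def _as_plane(plane) -> Plane:
    point = np.asarray(plane[0], dtype=float).reshape(3)
    normal = np.asarray(plane[1], dtype=float).reshape(3)
    n = np.linalg.norm(normal)
    if n == 0:
        raise ValidationError("plane normal must be non-zero")
    return point, normal / n


@dataclass(frozen=True)
class CuttingPlaneSet:
    """The preconfigured cutting planes, in the template frame."""

    axial_plane: Plane
    central_sagittal_plane: Plane
    medial_tubercle_plane: Plane
    lateral_tubercle_plane: Plane

    def __post_init__(self):
        for name in (
            "axial_plane",
            "central_sagittal_plane",
            "medial_tubercle_plane",
            "lateral_tubercle_plane",
        ):
            object.__setattr__(self, name, _as_plane(getattr(self, name)))
        axial_n = self.axial_plane[1]
        for plane in (
            self.central_sagittal_plane,
            self.medial_tubercle_plane,
            self.lateral_tubercle_plane,
        ):
            if abs(float(axial_n @ plane[1])) > 1e-9:
                raise ValidationError(
                    "sagittal plane normals must be perpendicular to the axial plane"
                )


@dataclass
class TibiaTemplate:
    """Average right proximal tibia with landmarks and cutting planes."""

    mesh: SurfaceMesh
    plateau_level_z: float
    medial_tubercle: np.ndarray
    lateral_tubercle: np.ndarray
    plateau_center: np.ndarray
    frame: AnatomicalFrame
    planes: CuttingPlaneSet

    def __post_init__(self):
        self.medial_tubercle = np.asarray(self.medial_tubercle, float).reshape(3)
        self.lateral_tubercle = np.asarray(self.lateral_tubercle, float).reshape(3)
        self.plateau_center = np.asarray(self.plateau_center, float).reshape(3)
        if not (
            self.medial_tubercle[1]
            > self.plateau_center[1]
            > self.lateral_tubercle[1]
        ):
            raise ValidationError(
                "landmarks must satisfy medial.y > center.y > lateral.y"
            )
        for name in ("medial_tubercle", "lateral_tubercle", "plateau_center"):
            d, _, _ = self.mesh.nearest.query(getattr(self, name))
            if float(d[0]) > 1.0:
                raise ValidationError(f"landmark {name} is > 1 mm off the surface")


class AlignmentResult(NamedTuple):
    transform: RigidTransform
    residual_mesd: float
    converged: bool


def build_default_template(
    width_medial: float = 31.9,
    width_lateral: float = 32.0,
    depth_medial: float = 58.0,
    depth_lateral: float = 50.4,
) -> TibiaTemplate:
    """Deterministic synthetic average right tibia template.

    Default plateau dimensions follow the mean meniscus dimensions scaled
    by the radiographic plateau-to-meniscus factors (0.8 medial /
    0.7 lateral); repeated calls are bit-identical.
    """
    vertices, faces, lm = build_tibia(
        width_medial, width_lateral, depth_medial, depth_lateral
    )
    mesh = SurfaceMesh(vertices, faces, name="tibia_template", is_closed=True)
    level = lm["plateau_level_z"]
    ez = np.array([0.0, 0.0, 1.0])
    ey = np.array([0.0, 1.0, 0.0])
    planes = CuttingPlaneSet(
        axial_plane=(np.array([0.0, 0.0, level - AXIAL_OFFSET_MM]), ez),
        central_sagittal_plane=(lm["plateau_center"], ey),
        medial_tubercle_plane=(lm["medial_tubercle"], ey),
        lateral_tubercle_plane=(lm["lateral_tubercle"], ey),
    )
    return TibiaTemplate(
        mesh=mesh,
        plateau_level_z=level,
        medial_tubercle=lm["medial_tubercle"],
        lateral_tubercle=lm["lateral_tubercle"],
        plateau_center=lm["plateau_center"],
        frame=AnatomicalFrame.canonical(),
        planes=planes,
    )


def align_to_template(
    tibia: SurfaceMesh, template: TibiaTemplate, params: IcpParams | None = None
) -> AlignmentResult:
    """ICP-superimpose a (right-sided) tibia onto the template mesh."""
    params = params or IcpParams()
    transform, _, converged = icp_register(tibia, template.mesh, params)
    residual = surface_distance(
        template.mesh,
        tibia.transformed(transform),
        n_sample_points=params.n_sample_points,
        seed=params.seed,
    ).mesd
    return AlignmentResult(transform, residual, converged)


def cut_plateau(
    tibia_aligned: SurfaceMesh,
    planes: CuttingPlaneSet,
    config: PlateauConfig,
    compartment: Compartment | None = None,
) -> SurfaceMesh:
    """Cut a template-aligned tibia into one of the plateau configurations.

    The result is the open surface on the kept side of each plane (no
    capping along the cut boundary).
    """
    if config is not PlateauConfig.ENTIRE and compartment is None:
        raise ValidationError(f"config {config.value} requires a compartment")
    cuts: list[Plane] = [planes.axial_plane]
    sign = 1.0 if compartment is Compartment.MEDIAL else -1.0
    if config is PlateauConfig.HALF_WITH_EMINENCE:
        point, normal = planes.central_sagittal_plane
        cuts.append((point, sign * normal))
    elif config is PlateauConfig.HALF_WITHOUT_EMINENCE:
        point, normal = (
            planes.medial_tubercle_plane
            if compartment is Compartment.MEDIAL
            else planes.lateral_tubercle_plane
        )
        cuts.append((point, sign * normal))

    tm = tibia_aligned.to_trimesh()
    for point, normal in cuts:
        tm = trimesh.intersections.slice_mesh_plane(
            tm, plane_normal=normal, plane_origin=point, cap=False
        )
        if tm is None or len(tm.faces) == 0:
            raise ValidationError(
                f"cut {config.value} produced an empty mesh for "
                f"{tibia_aligned.name!r} (planes miss the surface)"
            )
    name = f"{tibia_aligned.name}_{config.value}" + (
        f"_{compartment.value}" if compartment else ""
    )
    return SurfaceMesh(
        np.asarray(tm.vertices), np.asarray(tm.faces), name=name, is_closed=False
    )


def save_template(template: TibiaTemplate, directory) -> None:
    """Serialize the template as PLY mesh + JSON landmarks."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_mesh(template.mesh, directory / "template.ply")
    meta = {
        "plateau_level_z": template.plateau_level_z,
        "medial_tubercle": template.medial_tubercle.tolist(),
        "lateral_tubercle": template.lateral_tubercle.tolist(),
        "plateau_center": template.plateau_center.tolist(),
        "planes": {
            name: [p.tolist(), n.tolist()]
            for name, (p, n) in {
                "axial_plane": template.planes.axial_plane,
                "central_sagittal_plane": template.planes.central_sagittal_plane,
                "medial_tubercle_plane": template.planes.medial_tubercle_plane,
                "lateral_tubercle_plane": template.planes.lateral_tubercle_plane,
            }.items()
        },
    }
    (directory / "template.json").write_text(json.dumps(meta, indent=2))


def load_template(directory) -> TibiaTemplate:
    directory = Path(directory)
    mesh = load_mesh(directory / "template.ply")
    mesh.name = "tibia_template"
    meta = json.loads((directory / "template.json").read_text())
    planes = CuttingPlaneSet(**{k: tuple(v) for k, v in meta["planes"].items()})
    return TibiaTemplate(
        mesh=mesh,
        plateau_level_z=meta["plateau_level_z"],
        medial_tubercle=np.array(meta["medial_tubercle"]),
        lateral_tubercle=np.array(meta["lateral_tubercle"]),
        plateau_center=np.array(meta["plateau_center"]),
        frame=AnatomicalFrame.canonical(),
        planes=planes,
    )
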