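"""Cohort serialization: mesh files plus a JSON manifest.

The manifest lists per specimen the side, the paths of the three meshes,
the meniscus root landmarks and the (optional) radiographic plateau
measurements; the generator's ground truth goes to a separate, clearly
test-only file.
"""

from __future__ import annotations

import json
from pathlib import Path

from .mesh_core import Compartment, Side, load_mesh, save_mesh
from .morphometry import RadiographMeasurement, RootLandmarks
from .sizing_bank import Specimen
from .synthetic_cohort import GroundTruth

__all__ = ["save_cohort", "load_cohort"]


def save_cohort(
    directory,
    specimens: list[Specimen],
    truths: list[GroundTruth] | None = None,
    mesh_format: str = "stl",
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in specimens:
        paths = {}
        for key, mesh in (
            ("medial_meniscus", s.medial_meniscus),
            ("lateral_meniscus", s.lateral_meniscus),
            ("tibia", s.tibia),
        ):
            rel = f"{s.id}_{key}.{mesh_format}"
            save_mesh(mesh, directory / rel)
            paths[key] = rel
        entry = {
            "id": s.id,
            "side": s.side.value,
            "meshes": paths,
            "roots": {
                c.value: {
                    "anterior": r.anterior_root.tolist(),
                    "posterior": r.posterior_root.tolist(),
                }
                for c, r in s.roots.items()
            },
        }
        if s.radiograph:
            entry["radiograph"] = {
                c.value: {
                    "ap_width": m.ap_width,
                    "lateral_plateau_depth": m.lateral_plateau_depth,
                }
                for c, m in s.radiograph.items()
            }
        entries.append(entry)
    (directory / "manifest.json").write_text(
        json.dumps({"specimens": entries}, indent=2)
    )
    if truths is not None:
        payload = {
            "note": "generator ground truth - for testing only, never an input "
                    "to the selectors",
            "specimens": [
                {
                    "id": t.specimen_id,
                    "side": t.side.value,
                    "dims": {c.value: list(v) for c, v in t.dims.items()},
                    "plateau_width": {c.value: v for c, v in t.plateau_width.items()},
                    "plateau_depth": {c.value: v for c, v in t.plateau_depth.items()},
                    "eminence": t.eminence,
                    "plateau_level_z": t.plateau_level_z,
                    "pose": t.pose.to_matrix().tolist(),
                }
                for t in truths
            ],
        }
        (directory / "truth.json").write_text(json.dumps(payload, indent=2))
    return directory / "manifest.json"


def load_cohort(manifest_path) -> list[Specimen]:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    data = json.loads(manifest_path.read_text())
    specimens = []
    for entry in data["specimens"]:
        roots = {
            Compartment(c): RootLandmarks(v["anterior"], v["posterior"])
            for c, v in entry["roots"].items()
        }
        radiograph = None
        if "radiograph" in entry:
            radiograph = {
                Compartment(c): RadiographMeasurement(
                    ap_width=v["ap_width"],
                    lateral_plateau_depth=v["lateral_plateau_depth"],
                    compartment=Compartment(c),
                )
                for c, v in entry["radiograph"].items()
            }
        specimens.append(
            Specimen(
                id=entry["id"],
                side=Side(entry["side"]),
                medial_meniscus=load_mesh(base / entry["meshes"]["medial_meniscus"]),
                lateral_meniscus=load_mesh(base / entry["meshes"]["lateral_meniscus"]),
                tibia=load_mesh(base / entry["meshes"]["tibia"]),
                roots=roots,
                radiograph=radiograph,
            )
        )
    return specimens
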