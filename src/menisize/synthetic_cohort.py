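"""Seeded generator of synthetic meniscus + tibia-plateau cohorts.

Emulates a cohort of unilateral knee joints: per-compartment meniscus
width/length/height are drawn from the cohort statistics (defaults below),
the plateau compartment dimensions follow the meniscus dimensions through
the radiographic plateau-to-meniscus factors with a controllable
plateau–meniscus correlation ``rho``, and medial/lateral compartment sizes
are mixed between a shared knee-size factor and independent draws by
``compartment_independence``.  Each specimen is emitted in a random rigid
pose (scan pose variability) and a configurable fraction are left knees.
Ground truth (true dimensions, plateau sizes, pose) is stored alongside
every specimen for testing only — selectors never consume it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._shapes import (
    DEFAULT_EMINENCE,
    build_meniscus,
    build_tibia,
    random_wave_field,
)
from .errors import ValidationError
from .geometry import RigidTransform, rotation_about_axis
from .mesh_core import Compartment, Side, SurfaceMesh, mirror_to_right
from .morphometry import POLLARD_FACTORS, RadiographMeasurement, RootLandmarks
from .sizing_bank import Specimen

__all__ = [
    "CompartmentDims",
    "CohortParams",
    "GroundTruth",
    "generate_cohort",
    "simulate_radiograph",
    "cohort_with_twin",
]

#: Arc span (degrees) of the C-shape per compartment: the medial meniscus
#: is a more open C, the lateral nearly a closed ring.
_SPAN_DEG = {Compartment.MEDIAL: 240.0, Compartment.LATERAL: 290.0}

#: Inter-individual variation of the intercondylar eminence (SDs in mm
#: around the template values, scaled by ``eminence_variation``).  The
#: eminence carries cruciate-ligament insertions, not meniscus size
#: information, so its variation is independent of the compartment sizes.
_RIDGE_HEIGHT_SD = 1.5
_RIDGE_HALF_WIDTH_SD = 0.5
_TUBERCLE_HEIGHT_SD = 1.0
_TUBERCLE_X_SD = 1.5
_TUBERCLE_SIGMA_SD = 0.4

#: Within-compartment share of variance carried by the common compartment
#: size factor (the remainder is per-dimension scatter).
_DIM_COMMONALITY = 0.8


@dataclass(frozen=True)
class CompartmentDims:
    """Mean and SD of width/length/height for one compartment (mm)."""

    width_mean: float
    width_sd: float
    length_mean: float
    length_sd: float
    height_mean: float
    height_sd: float

    def __post_init__(self):
        if min(self.width_sd, self.length_sd, self.height_sd) <= 0:
            raise ValidationError("dimension SDs must be positive")

    @property
    def means(self) -> np.ndarray:
        return np.array([self.width_mean, self.length_mean, self.height_mean])

    @property
    def sds(self) -> np.ndarray:
        return np.array([self.width_sd, self.length_sd, self.height_sd])


# Cohort meniscus dimension statistics (mm).  The medial length SD equals
# the lateral one: the printed medial value repeats the mean and is treated
# as a typographical slip.
_MEDIAL_DEFAULT = CompartmentDims(31.9, 3.14, 46.4, 3.01, 8.9, 1.51)
_LATERAL_DEFAULT = CompartmentDims(32.0, 3.52, 35.3, 3.01, 9.7, 1.37)


@dataclass(frozen=True)
class CohortParams:
    """Study conditions for one synthetic cohort."""

    n: int = 50
    seed: int = 0
    medial: CompartmentDims = _MEDIAL_DEFAULT
    lateral: CompartmentDims = _LATERAL_DEFAULT
    rho: float = 0.8
    compartment_independence: float = 0.5
    shape_noise_sd: float = 0.2
    rx_noise_sd: float = 1.0
    left_fraction: float = 0.36
    eminence_variation: float = 1.0
    meniscus_arc_segments: int = 96
    tibia_theta_segments: int = 120

    def __post_init__(self):
        if self.n < 2:
            raise ValidationError("cohort size must be >= 2")
        for name in ("rho", "compartment_independence", "left_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.shape_noise_sd < 0 or self.rx_noise_sd < 0:
            raise ValidationError("noise SDs must be non-negative")
        if self.eminence_variation < 0:
            raise ValidationError("eminence_variation must be non-negative")

    def dims(self, compartment: Compartment) -> CompartmentDims:
        return self.medial if compartment is Compartment.MEDIAL else self.lateral


@dataclass
class GroundTruth:
    """Generator-side truth for one specimen (test-only; never consumed by
    the selectors)."""

    specimen_id: str
    side: Side
    dims: dict[Compartment, tuple[float, float, float]]  # (W, L, H) mm
    plateau_width: dict[Compartment, float]
    plateau_depth: dict[Compartment, float]
    eminence: dict
    plateau_level_z: float  # pre-pose apex height
    plateau_apex_posed: np.ndarray  # apex point after posing/mirroring
    pose: RigidTransform
    roots: dict[Compartment, RootLandmarks]  # posed, same as the specimen's


def _specimen_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), 7919, index]))


def _draw_dims(
    rng: np.random.Generator, stats: CompartmentDims, z_comp: float
) -> np.ndarray:
    w = np.sqrt(_DIM_COMMONALITY)
    z = w * z_comp + np.sqrt(1.0 - _DIM_COMMONALITY) * rng.normal(size=3)
    vals = stats.means + stats.sds * z
    return np.clip(vals, stats.means - 3 * stats.sds, stats.means + 3 * stats.sds)


def generate_cohort(
    params: CohortParams,
) -> tuple[list[Specimen], list[GroundTruth]]:
    """Generate ``params.n`` specimens with ground truth (deterministic
    per seed)."""
    rng_cohort = np.random.default_rng(np.random.SeedSequence([params.seed, 104729]))
    n_left = int(round(params.left_fraction * params.n))
    left_ids = set(
        rng_cohort.choice(params.n, size=n_left, replace=False).tolist()
    )

    specimens: list[Specimen] = []
    truths: list[GroundTruth] = []
    ci = params.compartment_independence
    for i in range(params.n):
        rng = _specimen_rng(params.seed, i)
        sid = f"S{i:03d}"
        g = rng.normal()
        dims: dict[Compartment, np.ndarray] = {}
        plateau_w: dict[Compartment, float] = {}
        plateau_d: dict[Compartment, float] = {}
        for comp in Compartment:
            stats = params.dims(comp)
            z_comp = np.sqrt(1.0 - ci) * g + np.sqrt(ci) * rng.normal()
            men = _draw_dims(rng, stats, z_comp)
            indep = _draw_dims(rng, stats, rng.normal())
            blended = params.rho * men + (1.0 - params.rho) * indep
            dims[comp] = men
            plateau_w[comp] = float(blended[0])
            plateau_d[comp] = float(blended[1] / POLLARD_FACTORS[comp])
        ev = params.eminence_variation
        eminence = {
            "ridge_height": float(
                np.clip(
                    rng.normal(DEFAULT_EMINENCE["ridge_height"],
                               ev * _RIDGE_HEIGHT_SD),
                    2.0, 9.0,
                )
            ),
            "half_width": float(
                np.clip(
                    rng.normal(DEFAULT_EMINENCE["half_width"],
                               ev * _RIDGE_HALF_WIDTH_SD),
                    2.0, 5.5,
                )
            ),
            "ridge_margin": DEFAULT_EMINENCE["ridge_margin"],
            "falloff": DEFAULT_EMINENCE["falloff"],
            "ap_sigma_frac": DEFAULT_EMINENCE["ap_sigma_frac"],
        }
        for key in ("tubercle_medial", "tubercle_lateral"):
            base = DEFAULT_EMINENCE[key]
            eminence[key] = {
                "x": float(rng.normal(base["x"], ev * _TUBERCLE_X_SD)),
                "height": float(
                    np.clip(rng.normal(base["height"], ev * _TUBERCLE_HEIGHT_SD),
                            0.5, 7.0)
                ),
                "sigma_x": float(
                    np.clip(rng.normal(base["sigma_x"], ev * _TUBERCLE_SIGMA_SD),
                            1.5, 3.5)
                ),
                "sigma_y": float(
                    np.clip(rng.normal(base["sigma_y"], ev * 0.5 * _TUBERCLE_SIGMA_SD),
                            0.9, 1.8)
                ),
            }

        meshes: dict[str, SurfaceMesh] = {}
        roots: dict[Compartment, RootLandmarks] = {}
        for comp in Compartment:
            w, l, h = dims[comp]
            v, f, ant, post = build_meniscus(
                w, l, h, _SPAN_DEG[comp], n_arc=params.meniscus_arc_segments
            )
            if comp is Compartment.MEDIAL:
                ty = 2.0 - v[:, 1].min()
            else:
                v[:, :2] = -v[:, :2]  # rotate 180 deg about z: opens toward +y
                ant, post = post.copy(), ant.copy()
                ant[:2], post[:2] = -ant[:2], -post[:2]
                ty = -2.0 - v[:, 1].max()
            tz = -1.0 - v[:, 2].min()
            shift = np.array([0.0, ty, tz])
            v = v + shift
            meshes[comp.value] = SurfaceMesh(
                v, f, name=f"{sid}_{comp.value}_meniscus", is_closed=True
            )
            roots[comp] = RootLandmarks(ant + shift, post + shift)

        tv, tf, _ = build_tibia(
            plateau_w[Compartment.MEDIAL],
            plateau_w[Compartment.LATERAL],
            plateau_d[Compartment.MEDIAL],
            plateau_d[Compartment.LATERAL],
            eminence=eminence,
            n_theta=params.tibia_theta_segments,
        )
        meshes["tibia"] = SurfaceMesh(tv, tf, name=f"{sid}_tibia", is_closed=True)

        # one smooth deformation field per specimen (anatomy variation)
        fld = random_wave_field(rng, params.shape_noise_sd)
        for key, mesh in meshes.items():
            mesh.vertices = mesh.vertices + fld(mesh.vertices)
            meshes[key] = SurfaceMesh(
                mesh.vertices, mesh.faces, mesh.name, mesh.is_closed
            )
        roots = {
            c: RootLandmarks(
                r.anterior_root + fld(r.anterior_root)[0],
                r.posterior_root + fld(r.posterior_root)[0],
            )
            for c, r in roots.items()
        }

        side = Side.LEFT if i in left_ids else Side.RIGHT
        if side is Side.LEFT:
            for key in list(meshes):
                meshes[key] = mirror_to_right(meshes[key], Side.LEFT)
            roots = {
                c: RootLandmarks(
                    r.anterior_root * [1, -1, 1], r.posterior_root * [1, -1, 1]
                )
                for c, r in roots.items()
            }

        apex_pre = meshes["tibia"].vertices[
            int(np.argmax(meshes["tibia"].vertices[:, 2]))
        ].copy()

        angle = rng.uniform(0.0, 25.0)
        axis = rng.normal(size=3)
        pose = RigidTransform(
            rotation_about_axis(axis, angle), rng.uniform(-20.0, 20.0, size=3)
        )
        for key in list(meshes):
            meshes[key] = meshes[key].transformed(pose)
        roots = {c: r.transformed(pose) for c, r in roots.items()}

        truth = GroundTruth(
            specimen_id=sid,
            side=side,
            dims={c: tuple(map(float, dims[c])) for c in Compartment},
            plateau_width=plateau_w,
            plateau_depth=plateau_d,
            eminence=eminence,
            plateau_level_z=float(apex_pre[2]),
            plateau_apex_posed=pose.apply(apex_pre),
            pose=pose,
            roots=roots,
        )
        specimen = Specimen(
            id=sid,
            side=side,
            medial_meniscus=meshes[Compartment.MEDIAL.value],
            lateral_meniscus=meshes[Compartment.LATERAL.value],
            tibia=meshes["tibia"],
            roots=roots,
        )
        specimen.radiograph = simulate_radiograph(
            specimen, truth, params.rx_noise_sd, params.seed
        )
        specimens.append(specimen)
        truths.append(truth)
    return specimens, truths


def simulate_radiograph(
    specimen: Specimen,
    truth: GroundTruth,
    rx_noise_sd: float,
    seed: int,
) -> dict[Compartment, RadiographMeasurement]:
    """Per-compartment radiographic plateau measurements with Gaussian
    measurement noise.

    Noise-free measurements equal the true plateau dimensions, so the
    Pollard conversion recovers the true meniscus dimensions exactly when
    the plateau tracks the meniscus (``rho = 1``) and ``rx_noise_sd = 0``.
    """
    idx = int(truth.specimen_id.lstrip("S")) if truth.specimen_id[0] == "S" else 0
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 15485863, idx]))
    out = {}
    for comp in Compartment:
        noise = rng.normal(scale=rx_noise_sd, size=2) if rx_noise_sd > 0 else (0.0, 0.0)
        out[comp] = RadiographMeasurement(
            ap_width=max(1.0, truth.plateau_width[comp] + noise[0]),
            lateral_plateau_depth=max(1.0, truth.plateau_depth[comp] + noise[1]),
            compartment=comp,
        )
    return out


def cohort_with_twin(
    params: CohortParams, twin_of: int = 0, twin_id: str = "TWIN"
) -> tuple[list[Specimen], list[GroundTruth], str, str]:
    """Cohort plus one exact duplicate of specimen ``twin_of``.

    The twin is a bit-identical copy under a new id (same pose), used by
    the selector recovery tests: every selector must pick the twin when
    its original is the query.  Returns
    ``(specimens, truths, twin_id, original_id)``.
    """
    specimens, truths = generate_cohort(params)
    src = specimens[twin_of]
    twin = Specimen(
        id=twin_id,
        side=src.side,
        medial_meniscus=src.medial_meniscus.copy(),
        lateral_meniscus=src.lateral_meniscus.copy(),
        tibia=src.tibia.copy(),
        roots={
            c: RootLandmarks(r.anterior_root.copy(), r.posterior_root.copy())
            for c, r in src.roots.items()
        },
        radiograph=dict(src.radiograph) if src.radiograph else None,
    )
    truth = replace_truth_id(truths[twin_of], twin_id)
    return specimens + [twin], truths + [truth], twin_id, src.id


def replace_truth_id(truth: GroundTruth, new_id: str) -> GroundTruth:
    return GroundTruth(
        specimen_id=new_id,
        side=truth.side,
        dims=dict(truth.dims),
        plateau_width=dict(truth.plateau_width),
        plateau_depth=dict(truth.plateau_depth),
        eminence=dict(truth.eminence),
        plateau_level_z=truth.plateau_level_z,
        plateau_apex_posed=truth.plateau_apex_posed.copy(),
        pose=truth.pose,
        roots=dict(truth.roots),
    )
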