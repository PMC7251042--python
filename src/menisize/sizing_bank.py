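"""Allograft selectors over a bank of candidate specimens.

Three selection methods, mirroring how a recipient would be matched
against a tissue bank:

* ``3d_mri`` — direct meniscus matching: the candidate meniscus with the
  lowest combined MeSD after ICP superimposition (the best available
  allograft, used as gold standard);
* ``3d_ct`` — indirect matching by the ipsilateral tibia plateau: the
  standardized plateau cuts are compared by MeSD and the selected
  specimen's meniscus of the same compartment is returned;
* ``2d_rx`` — radiographic Pollard matching: lowest error sum of squares
  ``(W_sized - W_allograft)^2 + (L_sized - L_allograft)^2`` against the
  3D-measured candidate dimensions.

Ranking for the 3D selectors is by combined MeSD with MaSD as tie-break,
then lexicographic id; all candidate scores are retained in the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError
from .mesh_core import Compartment, Side, SurfaceMesh, mirror_to_right
from .morphometry import (
    MeniscusDimensions,
    RadiographMeasurement,
    RootLandmarks,
    meniscus_dimensions,
)
from .plateau_prep import (
    AlignmentResult,
    PlateauConfig,
    TibiaTemplate,
    align_to_template,
    cut_plateau,
)
from .registration import IcpParams, SurfaceDistanceResult, match_score, pair_seed

__all__ = [
    "Specimen",
    "MatchResult",
    "prepare_specimen",
    "prepare_cohort",
    "select_by_meniscus_3d",
    "select_by_tibia_3d",
    "select_by_pollard_2d",
    "count_pairings",
]


@dataclass
class Specimen:
    """One knee: both menisci, the proximal tibia, and per-compartment
    metadata.  After ingestion all meshes are right-sided and (when
    prepared) expressed in the template frame."""

    id: str
    side: Side
    medial_meniscus: SurfaceMesh
    lateral_meniscus: SurfaceMesh
    tibia: SurfaceMesh
    roots: dict[Compartment, RootLandmarks]
    radiograph: dict[Compartment, RadiographMeasurement] | None = None
    dims_3d: dict[Compartment, MeniscusDimensions] = field(default_factory=dict)
    plateau_cuts: dict[tuple[PlateauConfig, Compartment | None], SurfaceMesh] = field(
        default_factory=dict
    )
    alignment: AlignmentResult | None = None

    def meniscus(self, compartment: Compartment) -> SurfaceMesh:
        return (
            self.medial_meniscus
            if compartment is Compartment.MEDIAL
            else self.lateral_meniscus
        )


@dataclass(frozen=True)
class MatchResult:
    """One selector decision with the full candidate ranking."""

    query_id: str
    compartment: Compartment | None
    method: str
    selected_id: str
    criterion_value: float
    ranking: tuple  # ordered (candidate_id, criterion) pairs, best first
    config: PlateauConfig | None = None

    def __post_init__(self):
        if self.selected_id == self.query_id:
            raise ValidationError("selected candidate equals the query")


def count_pairings(n: int) -> int:
    """Ordered (query, candidate) evaluations in a full leave-one-out run."""
    if n < 2:
        raise ValidationError("cohort size must be >= 2")
    return n * (n - 1)


def _reflect_roots(roots: RootLandmarks) -> RootLandmarks:
    a = roots.anterior_root.copy()
    p = roots.posterior_root.copy()
    a[1] = -a[1]
    p[1] = -p[1]
    return RootLandmarks(a, p)


_ALL_CUT_KEYS = (
    (PlateauConfig.ENTIRE, None),
    (PlateauConfig.HALF_WITH_EMINENCE, Compartment.MEDIAL),
    (PlateauConfig.HALF_WITH_EMINENCE, Compartment.LATERAL),
    (PlateauConfig.HALF_WITHOUT_EMINENCE, Compartment.MEDIAL),
    (PlateauConfig.HALF_WITHOUT_EMINENCE, Compartment.LATERAL),
)


def prepare_specimen(
    specimen: Specimen,
    template: TibiaTemplate,
    params: IcpParams | None = None,
    with_cuts: bool = True,
) -> Specimen:
    """Ingest one specimen: mirror left knees to the right side, align the
    tibia to the template, carry all meshes and landmarks into the template
    frame, precompute the plateau cuts and the 3D meniscus dimensions."""
    params = params or IcpParams()
    if specimen.side is Side.LEFT:
        specimen.medial_meniscus = mirror_to_right(specimen.medial_meniscus, Side.LEFT)
        specimen.lateral_meniscus = mirror_to_right(
            specimen.lateral_meniscus, Side.LEFT
        )
        specimen.tibia = mirror_to_right(specimen.tibia, Side.LEFT)
        specimen.roots = {c: _reflect_roots(r) for c, r in specimen.roots.items()}

    alignment = align_to_template(
        specimen.tibia,
        template,
        params.with_seed(pair_seed(params.seed, specimen.id, "align")),
    )
    specimen.alignment = alignment
    T = alignment.transform
    specimen.tibia = specimen.tibia.transformed(T)
    specimen.medial_meniscus = specimen.medial_meniscus.transformed(T)
    specimen.lateral_meniscus = specimen.lateral_meniscus.transformed(T)
    specimen.roots = {c: r.transformed(T) for c, r in specimen.roots.items()}

    if with_cuts:
        for config, comp in _ALL_CUT_KEYS:
            specimen.plateau_cuts[(config, comp)] = cut_plateau(
                specimen.tibia, template.planes, config, comp
            )
    for comp in Compartment:
        specimen.dims_3d[comp] = meniscus_dimensions(
            specimen.meniscus(comp), specimen.roots[comp]
        )
    return specimen


def prepare_cohort(
    specimens: list[Specimen],
    template: TibiaTemplate,
    params: IcpParams | None = None,
    with_cuts: bool = True,
) -> list[Specimen]:
    return [
        prepare_specimen(s, template, params, with_cuts=with_cuts)
        for s in specimens
    ]


def _check_bank(query_id: str, bank) -> None:
    if not bank:
        raise ValidationError("candidate bank is empty")
    ids = [getattr(b, "id", b[0] if isinstance(b, tuple) else None) for b in bank]
    if query_id in ids:
        raise ValidationError("bank must exclude the query specimen")
    if len(set(ids)) != len(ids):
        raise ValidationError("bank contains duplicate specimen ids")


def _rank_3d(
    entries: list[tuple[str, SurfaceDistanceResult]],
) -> tuple[str, float, tuple]:
    """Order by (MeSD, MaSD, id); return best id, criterion and ranking."""
    ordered = sorted(entries, key=lambda e: (e[1].mesd, e[1].masd, e[0]))
    ranking = tuple((cid, res.mesd) for cid, res in ordered)
    return ordered[0][0], ordered[0][1].mesd, ranking


def select_by_meniscus_3d(
    query: Specimen,
    bank: list[Specimen],
    compartment: Compartment,
    params: IcpParams | None = None,
) -> MatchResult:
    """Direct 3D meniscus sizing: lowest combined MeSD after registration."""
    params = params or IcpParams()
    _check_bank(query.id, bank)
    q_mesh = query.meniscus(compartment)
    entries = []
    for cand in bank:
        seed = pair_seed(
            params.seed, "meniscus", compartment.value, query.id, cand.id
        )
        entries.append(
            (cand.id, match_score(q_mesh, cand.meniscus(compartment),
                                  params.with_seed(seed)))
        )
    selected, criterion, ranking = _rank_3d(entries)
    return MatchResult(
        query_id=query.id,
        compartment=compartment,
        method="3d_mri",
        selected_id=selected,
        criterion_value=criterion,
        ranking=ranking,
    )


def select_by_tibia_3d(
    query: Specimen,
    bank: list[Specimen],
    compartment: Compartment,
    config: PlateauConfig,
    params: IcpParams | None = None,
) -> MatchResult:
    """Indirect sizing by the tibia plateau: the standardized cuts are
    matched by MeSD and the selected specimen's meniscus (same
    compartment) is the returned allograft."""
    params = params or IcpParams()
    _check_bank(query.id, bank)
    key = (config, None if config is PlateauConfig.ENTIRE else compartment)
    q_cut = query.plateau_cuts.get(key)
    if q_cut is None:
        raise ValidationError(
            f"plateau cut {key} missing on query {query.id!r}; "
            "run prepare_specimen first"
        )
    entries = []
    for cand in bank:
        c_cut = cand.plateau_cuts.get(key)
        if c_cut is None:
            raise ValidationError(f"plateau cut {key} missing on {cand.id!r}")
        seed = pair_seed(
            params.seed, "plateau", config.value,
            "both" if key[1] is None else key[1].value, query.id, cand.id,
        )
        entries.append((cand.id, match_score(q_cut, c_cut, params.with_seed(seed))))
    selected, criterion, ranking = _rank_3d(entries)
    return MatchResult(
        query_id=query.id,
        compartment=compartment,
        method="3d_ct",
        selected_id=selected,
        criterion_value=criterion,
        ranking=ranking,
        config=config,
    )


def select_by_pollard_2d(
    query_dims: tuple[float, float],
    bank_dims: list[tuple[str, MeniscusDimensions]],
    query_id: str = "query",
    compartment: Compartment | None = None,
) -> MatchResult:
    """Radiographic sizing: equally weighted width/length error sum of
    squares against the 3D-measured candidate dimensions (mm^2)."""
    _check_bank(query_id, bank_dims)
    wq, lq = float(query_dims[0]), float(query_dims[1])
    entries = []
    for cid, dims in bank_dims:
        sse = (wq - dims.width) ** 2 + (lq - dims.length) ** 2
        entries.append((cid, sse))
    ordered = sorted(entries, key=lambda e: (e[1], e[0]))
    return MatchResult(
        query_id=query_id,
        compartment=compartment,
        method="2d_rx",
        selected_id=ordered[0][0],
        criterion_value=ordered[0][1],
        ranking=tuple(ordered),
    )
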