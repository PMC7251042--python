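"""Leave-one-out validation experiment and the statistics battery.

Each specimen in turn acts as the recipient while the remaining specimens
form the imaginary tissue bank; the selected allograft meniscus is
registered back onto the original meniscus and compared by MeSD, MaSD and
the absolute width/length/height differences.  Sizing mismatches count as
outliers above > 5 mm width, > 5 mm length, > 4 mm height or > 5 mm MaSD.
Method comparisons use a one-way repeated-measures ANOVA with
Greenhouse–Geisser correction, paired t-tests, the classic (mean-centered)
Levene test and the variance-ratio F test, with Bonferroni-corrected
significance levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, ValidationError
from .mesh_core import Compartment
from .plateau_prep import PlateauConfig
from .registration import IcpParams, match_score, pair_seed, score_calls
from .sizing_bank import (
    MatchResult,
    Specimen,
    count_pairings,
    select_by_meniscus_3d,
    select_by_pollard_2d,
    select_by_tibia_3d,
)
from .morphometry import pollard_dimensions

__all__ = [
    "CoupleMetrics",
    "OutlierCriteria",
    "MethodSummary",
    "StatTestResult",
    "LeaveOneOutResult",
    "evaluate_couple",
    "run_leave_one_out",
    "summarize",
    "rm_anova_gg",
    "pairwise_battery",
]

METRIC_NAMES = ("mesd", "masd", "d_width", "d_length", "d_height")


@dataclass(frozen=True)
class CoupleMetrics:
    """Agreement between an original meniscus and its selected allograft."""

    query_id: str
    selected_id: str
    mesd: float
    masd: float
    d_width: float
    d_length: float
    d_height: float
    # signed differences (original - selected) are retained alongside the
    # unsigned table values
    signed_d_width: float = 0.0
    signed_d_length: float = 0.0
    signed_d_height: float = 0.0

    def __post_init__(self):
        if self.mesd < 0 or self.masd < 0:
            raise ValidationError("surface distances must be non-negative")
        if self.masd < self.mesd:
            raise ValidationError("MaSD cannot be smaller than MeSD")

    def value(self, metric: str) -> float:
        return getattr(self, metric)


@dataclass(frozen=True)
class OutlierCriteria:
    """Sizing-mismatch thresholds (strict >, mm)."""

    width_mm: float = 5.0
    length_mm: float = 5.0
    height_mm: float = 4.0
    masd_mm: float = 5.0

    def __post_init__(self):
        if min(self.width_mm, self.length_mm, self.height_mm, self.masd_mm) <= 0:
            raise ValidationError("outlier thresholds must be positive")


@dataclass
class MethodSummary:
    """Per-method cohort summary (layout of the sizing-results tables)."""

    method: str
    compartment: Compartment | None
    config: PlateauConfig | None
    n: int
    stats: dict[str, dict[str, float]]  # metric -> mean/min/max/sd
    outliers: dict[str, int]  # W, L, H, MaSD, total


@dataclass(frozen=True)
class StatTestResult:
    test: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    alpha_corrected: float | None = None
    degenerate: bool = False
    extra: dict = field(default_factory=dict)


@dataclass
class LeaveOneOutResult:
    method: str
    compartment: Compartment
    config: PlateauConfig | None
    matches: list[MatchResult]
    couples: list[CoupleMetrics]
    n_scoring_evaluations: int


def evaluate_couple(
    original: Specimen,
    match: MatchResult,
    bank: list[Specimen],
    params: IcpParams | None = None,
) -> CoupleMetrics:
    """Register the selected allograft meniscus onto the original meniscus
    and compute the per-couple metrics.

    Uses the same deterministic per-pair seed as the direct 3D selector,
    so the gold-standard selection is by construction at least as good as
    any other method's selection on this metric.
    """
    params = params or IcpParams()
    selected = next((s for s in bank if s.id == match.selected_id), None)
    if selected is None:
        raise ValidationError(f"selected specimen {match.selected_id!r} not in bank")
    comp = match.compartment
    if comp is None:
        raise ValidationError("match has no compartment")
    seed = pair_seed(params.seed, "meniscus", comp.value, original.id, selected.id)
    res = match_score(
        original.meniscus(comp), selected.meniscus(comp), params.with_seed(seed)
    )
    if comp not in original.dims_3d or comp not in selected.dims_3d:
        raise ValidationError("3D dimensions missing; run prepare_specimen first")
    od = original.dims_3d[comp]
    sd = selected.dims_3d[comp]
    dw = od.width - sd.width
    dl = od.length - sd.length
    dh = od.height - sd.height
    return CoupleMetrics(
        query_id=original.id,
        selected_id=selected.id,
        mesd=res.mesd,
        masd=res.masd,
        d_width=abs(dw),
        d_length=abs(dl),
        d_height=abs(dh),
        signed_d_width=dw,
        signed_d_length=dl,
        signed_d_height=dh,
    )


def run_leave_one_out(
    cohort: list[Specimen],
    method: str,
    compartment: Compartment,
    config: PlateauConfig | None = None,
    params: IcpParams | None = None,
) -> LeaveOneOutResult:
    """Full bank simulation: every specimen is sized against the others.

    Performs exactly ``count_pairings(n)`` scoring evaluations and returns
    one couple per specimen; results are independent of cohort ordering.
    """
    params = params or IcpParams()
    if len(cohort) < 2:
        raise ValidationError("cohort size must be >= 2")
    if method == "3d_ct" and config is None:
        raise ValidationError("3d_ct requires a plateau config")
    ordered = sorted(cohort, key=lambda s: s.id)
    calls_before = score_calls.count
    matches: list[MatchResult] = []
    for query in ordered:
        bank = [s for s in ordered if s.id != query.id]
        if method == "3d_mri":
            match = select_by_meniscus_3d(query, bank, compartment, params)
        elif method == "3d_ct":
            match = select_by_tibia_3d(query, bank, compartment, config, params)
        elif method == "2d_rx":
            if not query.radiograph:
                raise ValidationError(f"specimen {query.id!r} has no radiograph")
            qdims = pollard_dimensions(query.radiograph[compartment])
            bank_dims = [(s.id, s.dims_3d[compartment]) for s in bank]
            match = select_by_pollard_2d(
                qdims, bank_dims, query_id=query.id, compartment=compartment
            )
        else:
            raise ValidationError(f"unknown method: {method!r}")
        matches.append(match)

    n_eval = sum(len(m.ranking) for m in matches)
    expected = count_pairings(len(cohort))
    if n_eval != expected:
        raise ValidationError(
            f"performed {n_eval} scoring evaluations, expected {expected}"
        )
    if method in ("3d_mri", "3d_ct"):
        icp_calls = score_calls.count - calls_before
        if icp_calls != expected:
            raise ValidationError(
                f"performed {icp_calls} registrations, expected {expected}"
            )

    by_id = {s.id: s for s in ordered}
    couples = [
        evaluate_couple(by_id[m.query_id], m, ordered, params) for m in matches
    ]
    return LeaveOneOutResult(
        method=method,
        compartment=compartment,
        config=config,
        matches=matches,
        couples=couples,
        n_scoring_evaluations=n_eval,
    )


def summarize(
    metrics: list[CoupleMetrics],
    criteria: OutlierCriteria | None = None,
    method: str = "",
    compartment: Compartment | None = None,
    config: PlateauConfig | None = None,
) -> MethodSummary:
    """Mean/min/max/SD per metric and strict-threshold outlier counts.

    A couple counts once in every category it exceeds; ``total`` is the
    number of couples exceeding at least one category.
    """
    if not metrics:
        raise ValidationError("cannot summarize an empty metric list")
    criteria = criteria or OutlierCriteria()
    stats: dict[str, dict[str, float]] = {}
    for name in METRIC_NAMES:
        vals = np.array([m.value(name) for m in metrics], dtype=float)
        stats[name] = {
            "mean": float(vals.mean()),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        }
    flags = {
        "W": [m.d_width > criteria.width_mm for m in metrics],
        "L": [m.d_length > criteria.length_mm for m in metrics],
        "H": [m.d_height > criteria.height_mm for m in metrics],
        "MaSD": [m.masd > criteria.masd_mm for m in metrics],
    }
    outliers = {k: int(sum(v)) for k, v in flags.items()}
    outliers["total"] = int(sum(any(col) for col in zip(*flags.values())))
    return MethodSummary(
        method=method,
        compartment=compartment,
        config=config,
        n=len(metrics),
        stats=stats,
        outliers=outliers,
    )


def rm_anova_gg(data) -> StatTestResult:
    """One-way within-subjects ANOVA with Greenhouse–Geisser correction.

    ``data`` is an (n subjects) x (k conditions) matrix.  The F statistic
    uses the standard repeated-measures partition of sums of squares; the
    Greenhouse–Geisser epsilon is computed from the doubly-centered
    condition covariance matrix and deflates both degrees of freedom.
    For k = 2 the epsilon is exactly 1 (sphericity trivially holds).
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValidationError("data must be a 2D subjects x conditions matrix")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValidationError("need at least 2 subjects and 2 conditions")
    if not np.isfinite(X).all():
        raise ValidationError("data matrix must be complete and finite")

    grand = X.mean()
    subj = X.mean(axis=1)
    cond = X.mean(axis=0)
    ss_cond = n * np.sum((cond - grand) ** 2)
    ss_subj = k * np.sum((subj - grand) ** 2)
    ss_tot = np.sum((X - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    if ss_err <= 0 or np.isclose(ss_err, 0.0):
        raise DegenerateDataError("zero residual variance in RM-ANOVA")
    F = (ss_cond / df1) / (ss_err / df2)

    if k == 2:
        eps = 1.0
    else:
        S = np.cov(X, rowvar=False, ddof=1)
        C = S - S.mean(axis=0)[None, :] - S.mean(axis=1)[:, None] + S.mean()
        denom = (k - 1) * np.sum(C * C)
        if denom <= 0:
            raise DegenerateDataError("degenerate condition covariance")
        eps = float(np.trace(C) ** 2 / denom)
        eps = min(1.0, eps)
    df1c = eps * df1
    df2c = eps * df2
    p = float(sps.f.sf(F, df1c, df2c))
    return StatTestResult(
        test="rm_anova_gg",
        statistic=float(F),
        df=(df1c, df2c),
        p_value=p,
        extra={"epsilon": eps, "df_uncorrected": (df1, df2)},
    )


def pairwise_battery(
    metrics_a,
    metrics_b,
    alpha: float = 0.05,
    m_comparisons: int = 6,
) -> list[StatTestResult]:
    """Pairwise method comparison: paired t-test on means, variance-ratio
    F test and classic Levene test on spreads.

    Each result carries ``alpha_corrected = alpha / m_comparisons``
    (0.0083 for the family-wise 0.05 over 6 comparisons).  Identical
    pairings make the t-test degenerate; it is flagged rather than
    reported as p = 1.
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValidationError("need two equal-length samples of length >= 3")
    if m_comparisons < 1 or alpha <= 0:
        raise ValidationError("invalid alpha or comparison count")
    alpha_c = alpha / m_comparisons
    results = []

    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1)
    if var_a == 0 and var_b == 0:
        raise DegenerateDataError("both samples have zero variance")

    d = a - b
    if d.var(ddof=1) == 0:
        results.append(
            StatTestResult(
                test="paired_t", statistic=float("nan"), df=(float(len(a) - 1),),
                p_value=float("nan"), alpha_corrected=alpha_c, degenerate=True,
            )
        )
    else:
        t = sps.ttest_rel(a, b)
        results.append(
            StatTestResult(
                test="paired_t", statistic=float(t.statistic),
                df=(float(len(a) - 1),), p_value=float(t.pvalue),
                alpha_corrected=alpha_c,
            )
        )

    if var_a == 0 or var_b == 0:
        results.append(
            StatTestResult(
                test="f_variance", statistic=float("inf") if var_b == 0 else 0.0,
                df=(float(len(a) - 1), float(len(b) - 1)), p_value=0.0,
                alpha_corrected=alpha_c, degenerate=True,
            )
        )
    else:
        F = float(var_a / var_b)
        dfn, dfd = len(a) - 1, len(b) - 1
        cdf = sps.f.cdf(F, dfn, dfd)
        p = float(2.0 * min(cdf, 1.0 - cdf))
        results.append(
            StatTestResult(
                test="f_variance", statistic=F, df=(float(dfn), float(dfd)),
                p_value=min(1.0, p), alpha_corrected=alpha_c,
            )
        )

    lev = sps.levene(a, b, center="mean")
    results.append(
        StatTestResult(
            test="levene", statistic=float(lev.statistic),
            df=(1.0, float(len(a) + len(b) - 2)), p_value=float(lev.pvalue),
            alpha_corrected=alpha_c,
        )
    )
    return results
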