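"""Per-couple evaluation, summaries, and the statistics battery."""

import numpy as np
import pytest
import scipy.stats as sps

import menisize as mz
from menisize.errors import DegenerateDataError, ValidationError
from menisize.registration import pair_seed


def _couple(qid="q", sid="s", mesd=0.5, masd=2.0, dw=1.0, dl=1.0, dh=0.5):
    return mz.CoupleMetrics(
        query_id=qid, selected_id=sid, mesd=mesd, masd=masd,
        d_width=dw, d_length=dl, d_height=dh,
    )


class TestSummarize:
    def test_hand_computed_mean_and_sd(self):
        rows = [_couple(mesd=m, masd=m + 1) for m in (0.2, 0.4, 0.6, 0.8, 1.0)]
        s = mz.summarize(rows)
        assert s.stats["mesd"]["mean"] == pytest.approx(0.6, abs=1e-12)
        assert s.stats["mesd"]["min"] == pytest.approx(0.2, abs=1e-12)
        assert s.stats["mesd"]["max"] == pytest.approx(1.0, abs=1e-12)
        vals = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        assert s.stats["mesd"]["sd"] == pytest.approx(vals.std(ddof=1), abs=1e-12)

    def test_strict_width_threshold(self):
        """The 5.0 mm boundary itself is not an outlier (strict >)."""
        rows = [_couple(dw=w) for w in (4.9, 5.0, 5.1)]
        s = mz.summarize(rows)
        assert s.outliers["W"] == 1

    def test_couple_counts_in_every_exceeded_category(self):
        rows = [_couple(masd=5.2, dh=4.3)]
        s = mz.summarize(rows)
        assert s.outliers["MaSD"] == 1
        assert s.outliers["H"] == 1
        assert s.outliers["total"] == 1

    def test_matches_brute_force_filter_and_permutation(self):
        rng = np.random.default_rng(3)
        rows = [
            _couple(
                qid=f"q{i}", mesd=rng.uniform(0, 2), masd=rng.uniform(2, 8),
                dw=rng.uniform(0, 8), dl=rng.uniform(0, 8), dh=rng.uniform(0, 6),
            )
            for i in range(30)
        ]
        s = mz.summarize(rows)
        assert s.outliers["W"] == sum(1 for r in rows if r.d_width > 5)
        assert s.outliers["MaSD"] == sum(1 for r in rows if r.masd > 5)
        assert s.outliers["total"] == sum(
            1 for r in rows
            if r.d_width > 5 or r.d_length > 5 or r.d_height > 4 or r.masd > 5
        )
        shuffled = list(reversed(rows))
        s2 = mz.summarize(shuffled)
        for metric in s.stats:
            for k in s.stats[metric]:
                assert s2.stats[metric][k] == pytest.approx(
                    s.stats[metric][k], abs=1e-12
                )
        assert s2.outliers == s.outliers

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            mz.summarize([])


class TestEvaluateCouple:
    def test_exact_copy_has_near_zero_metrics(self, prepared6, single_start_icp):
        specimens, _ = prepared6
        orig, twin = specimens[0], specimens[1]
        match = mz.MatchResult(
            query_id=orig.id, compartment=mz.Compartment.MEDIAL,
            method="3d_mri", selected_id=twin.id, criterion_value=0.0,
            ranking=((twin.id, 0.0),),
        )
        # plant the twin: same meshes and dimensions under the other id
        twin.medial_meniscus = orig.medial_meniscus
        twin.dims_3d[mz.Compartment.MEDIAL] = orig.dims_3d[mz.Compartment.MEDIAL]
        m = mz.evaluate_couple(orig, match, specimens, single_start_icp)
        assert m.mesd < 0.05
        assert m.d_width == 0.0 and m.d_length == 0.0 and m.d_height == 0.0

    def test_scaled_copy_width_difference(self, template, single_start_icp):
        """A 1.2x scaled copy of a ~30 mm wide meniscus differs by ~6 mm
        in width."""
        specimens, _ = mz.generate_cohort(
            mz.CohortParams(n=2, seed=31, shape_noise_sd=0.0)
        )
        mz.prepare_cohort(specimens, template, single_start_icp)
        orig, other = specimens
        scale = 1.2
        other.medial_meniscus = mz.SurfaceMesh(
            orig.medial_meniscus.vertices * scale, orig.medial_meniscus.faces,
            "scaled",
        )
        roots = orig.roots[mz.Compartment.MEDIAL]
        other.roots = dict(other.roots)
        other.roots[mz.Compartment.MEDIAL] = mz.RootLandmarks(
            roots.anterior_root * scale, roots.posterior_root * scale
        )
        other.dims_3d[mz.Compartment.MEDIAL] = mz.meniscus_dimensions(
            other.medial_meniscus, other.roots[mz.Compartment.MEDIAL]
        )
        match = mz.MatchResult(
            query_id=orig.id, compartment=mz.Compartment.MEDIAL,
            method="3d_mri", selected_id=other.id, criterion_value=0.0,
            ranking=((other.id, 0.0),),
        )
        m = mz.evaluate_couple(orig, match, specimens, single_start_icp)
        expected = orig.dims_3d[mz.Compartment.MEDIAL].width * 0.2
        assert m.d_width == pytest.approx(expected, abs=0.3)

    def test_equals_independent_recomputation(self, prepared6, single_start_icp):
        """No hidden caching: the metrics equal a from-scratch rebuild."""
        specimens, _ = prepared6
        orig, sel = specimens[2], specimens[3]
        match = mz.MatchResult(
            query_id=orig.id, compartment=mz.Compartment.LATERAL,
            method="3d_mri", selected_id=sel.id, criterion_value=0.0,
            ranking=((sel.id, 0.0),),
        )
        m1 = mz.evaluate_couple(orig, match, specimens, single_start_icp)
        seed = pair_seed(
            single_start_icp.seed, "meniscus", "lateral", orig.id, sel.id
        )
        res = mz.match_score(
            orig.lateral_meniscus, sel.lateral_meniscus,
            single_start_icp.with_seed(seed),
        )
        assert m1.mesd == res.mesd and m1.masd == res.masd
        od = orig.dims_3d[mz.Compartment.LATERAL]
        sd = sel.dims_3d[mz.Compartment.LATERAL]
        assert m1.d_width == abs(od.width - sd.width)

    def test_missing_selection_rejected(self, prepared6, single_start_icp):
        specimens, _ = prepared6
        match = mz.MatchResult(
            query_id=specimens[0].id, compartment=mz.Compartment.MEDIAL,
            method="3d_mri", selected_id="GHOST", criterion_value=0.0,
            ranking=(("GHOST", 0.0),),
        )
        with pytest.raises(ValidationError):
            mz.evaluate_couple(specimens[0], match, specimens, single_start_icp)


class TestRunLeaveOneOut:
    def test_two_specimens_select_each_other(self, template, single_start_icp):
        specimens, _ = mz.generate_cohort(mz.CohortParams(n=2, seed=13))
        mz.prepare_cohort(specimens, template, single_start_icp)
        res = mz.run_leave_one_out(
            specimens, "2d_rx", mz.Compartment.MEDIAL, None, single_start_icp
        )
        assert {m.query_id: m.selected_id for m in res.matches} == {
            specimens[0].id: specimens[1].id,
            specimens[1].id: specimens[0].id,
        }
        assert res.n_scoring_evaluations == 2

    def test_order_invariance(self, prepared6, single_start_icp):
        specimens, _ = prepared6
        r1 = mz.run_leave_one_out(
            specimens, "2d_rx", mz.Compartment.LATERAL, None, single_start_icp
        )
        r2 = mz.run_leave_one_out(
            list(reversed(specimens)), "2d_rx", mz.Compartment.LATERAL, None,
            single_start_icp,
        )
        assert [m.selected_id for m in r1.matches] == [
            m.selected_id for m in r2.matches
        ]
        assert [c.mesd for c in r1.couples] == [c.mesd for c in r2.couples]

    def test_evaluation_count_matches_pairings(self, prepared6, single_start_icp):
        specimens, _ = prepared6
        res = mz.run_leave_one_out(
            specimens, "3d_mri", mz.Compartment.MEDIAL, None, single_start_icp
        )
        assert res.n_scoring_evaluations == mz.count_pairings(len(specimens))
        assert len(res.couples) == len(specimens)

    def test_gold_standard_dominates_per_query(self, prepared6, single_start_icp):
        """The direct meniscus selector attains the lowest per-query MeSD
        among all methods (it is the argmin of that very criterion)."""
        specimens, _ = prepared6
        gold = mz.run_leave_one_out(
            specimens, "3d_mri", mz.Compartment.MEDIAL, None, single_start_icp
        )
        ct = mz.run_leave_one_out(
            specimens, "3d_ct", mz.Compartment.MEDIAL,
            mz.PlateauConfig.HALF_WITHOUT_EMINENCE, single_start_icp,
        )
        rx = mz.run_leave_one_out(
            specimens, "2d_rx", mz.Compartment.MEDIAL, None, single_start_icp
        )
        gold_by_q = {c.query_id: c.mesd for c in gold.couples}
        for other in (ct, rx):
            for c in other.couples:
                assert gold_by_q[c.query_id] <= c.mesd + 1e-12


class TestRmAnovaGG:
    def test_two_conditions_have_epsilon_one(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(12, 2)) + [0.0, 0.5]
        res = mz.rm_anova_gg(data)
        assert res.extra["epsilon"] == 1.0
        assert res.df == (1.0, 11.0)

    def test_compound_symmetry_gives_epsilon_near_one(self):
        rng = np.random.default_rng(1)
        subj = rng.normal(size=(400, 1))
        data = subj + rng.normal(scale=1.0, size=(400, 4))
        res = mz.rm_anova_gg(data)
        assert res.extra["epsilon"] > 0.95

    def test_matches_reference_implementation(self):
        """F, epsilon and p agree with pingouin to 1e-8 on a small
        integer matrix."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        data = np.array(
            [
                [8, 7, 6],
                [5, 8, 5],
                [7, 7, 3],
                [9, 6, 4],
                [6, 5, 5],
                [8, 9, 6],
            ],
            dtype=float,
        )
        res = mz.rm_anova_gg(data)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(6), 3),
                "condition": np.tile(np.arange(3), 6),
                "y": data.ravel(),
            }
        )
        ref = pingouin.rm_anova(
            data=df, dv="y", within="condition", subject="subject",
            correction=True,
        )
        assert res.statistic == pytest.approx(float(ref["F"][0]), abs=1e-8)
        assert res.extra["epsilon"] == pytest.approx(float(ref["eps"][0]), abs=1e-8)
        assert res.p_value == pytest.approx(float(ref["p_GG_corr"][0]), abs=1e-8)

    def test_constant_data_rejected(self):
        with pytest.raises(DegenerateDataError):
            mz.rm_anova_gg(np.ones((5, 3)))


class TestPairwiseBattery:
    def test_bonferroni_threshold_printed_value(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        results = mz.pairwise_battery(a, b, alpha=0.05, m_comparisons=6)
        for r in results:
            assert round(r.alpha_corrected, 4) == 0.0083

    def test_identical_samples_flagged_degenerate(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        results = mz.pairwise_battery(a, a.copy())
        t = next(r for r in results if r.test == "paired_t")
        assert t.degenerate
        assert np.isnan(t.p_value)

    def test_matches_hand_formula_oracles(self):
        """Paired t, variance-ratio F and classic Levene agree with
        textbook formulas to 1e-8 on seeded samples."""
        rng = np.random.default_rng(5)
        a = rng.normal(loc=1.0, scale=1.2, size=25)
        b = rng.normal(loc=0.6, scale=0.8, size=25)
        results = {r.test: r for r in mz.pairwise_battery(a, b)}

        d = a - b
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_t = 2 * sps.t.sf(abs(t_ref), len(d) - 1)
        assert results["paired_t"].statistic == pytest.approx(t_ref, abs=1e-8)
        assert results["paired_t"].p_value == pytest.approx(p_t, abs=1e-8)

        F_ref = a.var(ddof=1) / b.var(ddof=1)
        cdf = sps.f.cdf(F_ref, len(a) - 1, len(b) - 1)
        p_f = 2 * min(cdf, 1 - cdf)
        assert results["f_variance"].statistic == pytest.approx(F_ref, abs=1e-8)
        assert results["f_variance"].p_value == pytest.approx(p_f, abs=1e-8)

        # classic Levene: one-way ANOVA on |x - group mean|
        za = np.abs(a - a.mean())
        zb = np.abs(b - b.mean())
        zbar = np.concatenate([za, zb]).mean()
        num = len(a) * (za.mean() - zbar) ** 2 + len(b) * (zb.mean() - zbar) ** 2
        den = ((za - za.mean()) ** 2).sum() + ((zb - zb.mean()) ** 2).sum()
        W_ref = (len(a) + len(b) - 2) * num / den
        p_w = sps.f.sf(W_ref, 1, len(a) + len(b) - 2)
        assert results["levene"].statistic == pytest.approx(W_ref, abs=1e-8)
        assert results["levene"].p_value == pytest.approx(p_w, abs=1e-8)

    def test_zero_variance_everywhere_rejected(self):
        with pytest.raises(DegenerateDataError):
            mz.pairwise_battery(np.ones(5), np.ones(5))
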