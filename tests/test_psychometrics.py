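"""ICC, MCID interpretation and the two-rater diff workflow."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitool.psychometrics import (MCID_CHRONIC, MCID_SUBACUTE_RANGE,
                                   PsychometricsError, RaterMatrix, icc,
                                   interpret_change, rater_diff)
from gaitool.rubric import ItemScore, ScoreSheet, SheetMetadata

RATINGS_3x4 = np.array([  # 4 targets x 3 raters, hand-checkable
    [9.0, 2.0, 5.0],
    [6.0, 1.0, 3.0],
    [8.0, 4.0, 6.0],
    [7.0, 1.0, 2.0],
])


def _mean_squares_brute(x):
    """Independent two-way ANOVA mean squares by direct summation."""
    n, k = x.shape
    grand = x.sum() / (n * k)
    msr = sum(k * (row.mean() - grand) ** 2 for row in x) / (n - 1)
    msc = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum((x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
              for i in range(n) for j in range(k))
    return msr, msc, sse / ((n - 1) * (k - 1))


class TestICC:
    def test_identical_columns_give_one(self):
        x = np.tile(np.array([[3.0], [7.0], [11.0], [5.0]]), (1, 3))
        res = icc(RaterMatrix(x))
        assert res.estimate == pytest.approx(1.0)

    def test_matches_brute_force_mean_squares_3x4(self):
        res = icc(RaterMatrix(RATINGS_3x4))
        msr, msc, mse = _mean_squares_brute(RATINGS_3x4)
        assert res.msr == pytest.approx(msr)
        assert res.msc == pytest.approx(msc)
        assert res.mse == pytest.approx(mse)
        n, k = RATINGS_3x4.shape
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert res.estimate == pytest.approx(expected)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        n, k = RATINGS_3x4.shape
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(n), k),
            "raters": np.tile(np.arange(k), n),
            "ratings": RATINGS_3x4.ravel(),
        })
        table = pg.intraclass_corr(df, targets="targets", raters="raters",
                                   ratings="ratings")
        # absolute-agreement single-measure row (labelled ICC2 or ICC(A,1)
        # depending on pingouin version)
        ref = table[table.Type.isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
        res = icc(RaterMatrix(RATINGS_3x4))
        assert res.estimate == pytest.approx(ref.ICC, abs=1e-9)
        assert res.ci95[0] == pytest.approx(ref[ci_col][0], abs=5e-3)
        assert res.ci95[1] == pytest.approx(ref[ci_col][1], abs=5e-3)

    def test_constant_offset_penalized(self):
        base = np.array([[2.0], [5.0], [9.0], [13.0]])
        x = np.hstack([base, base + 4.0])
        res = icc(RaterMatrix(x))
        assert res.estimate < 1.0
        assert -1.0 <= res.estimate <= 1.0

    def test_zero_variance_degenerate(self):
        with pytest.warns(UserWarning, match="undefined"):
            res = icc(RaterMatrix(np.full((4, 3), 5.0)))
        assert res.degenerate and res.estimate == 0.0

    def test_listwise_removal_with_warning(self):
        x = RATINGS_3x4.copy()
        x[1, 2] = np.nan
        with pytest.warns(UserWarning, match="listwise"):
            m = RaterMatrix(x)
        assert m.ratings.shape == (3, 3)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(PsychometricsError):
            RaterMatrix(np.array([[1.0, 2.0]]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.permutations(list(range(4))))
    def test_invariant_to_target_relabeling(self, perm):
        a = icc(RaterMatrix(RATINGS_3x4)).estimate
        b = icc(RaterMatrix(RATINGS_3x4[perm])).estimate
        assert a == pytest.approx(b)


class TestMCID:
    def test_chronic_fac3_threshold(self):
        res = interpret_change(40, 28, "chronic_stroke", "FAC3_household")
        assert res.meets_mcid and res.change == 12
        assert not interpret_change(40, 30, "chronic_stroke",
                                    "FAC3_household").meets_mcid

    def test_chronic_fac45_threshold(self):
        assert interpret_change(20, 14, "chronic_stroke",
                                "FAC45_community").meets_mcid
        assert not interpret_change(20, 15.5, "chronic_stroke",
                                    "FAC45_community").meets_mcid

    def test_subacute_band_reported_as_range(self):
        lo, hi = MCID_SUBACUTE_RANGE
        below = interpret_change(10, 9, "subacute_stroke")
        within = interpret_change(10, 7, "subacute_stroke")
        above = interpret_change(10, 3, "subacute_stroke")
        assert not below.meets_mcid and "below" in below.band
        assert within.meets_mcid and "within" in within.band
        assert above.meets_mcid and "above" in above.band
        assert f"{lo}" in within.band and f"{hi}" in within.band

    def test_zero_change_never_meets(self):
        assert not interpret_change(10, 10, "subacute_stroke").meets_mcid
        assert not interpret_change(10, 10, "chronic_stroke",
                                    "FAC45_community").meets_mcid

    def test_chronic_without_anchor_errors(self):
        with pytest.raises(PsychometricsError, match="anchor"):
            interpret_change(10, 0, "chronic_stroke")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0, 62), st.floats(0, 62))
    def test_symmetric_and_monotone(self, pre, post):
        a = interpret_change(pre, post, "chronic_stroke", "FAC45_community")
        b = interpret_change(post, pre, "chronic_stroke", "FAC45_community")
        assert a.meets_mcid == b.meets_mcid and a.change == b.change
        bigger = interpret_change(0, a.change + 1.0, "chronic_stroke",
                                  "FAC45_community")
        if a.meets_mcid:
            assert bigger.meets_mcid

    def test_published_thresholds_exact(self):
        assert MCID_CHRONIC == {"FAC3_household": 11.8, "FAC45_community": 5.19}
        assert MCID_SUBACUTE_RANGE == (1.5, 4.0)


def _sheet(scores: dict, cycle="step-4") -> ScoreSheet:
    items = [ItemScore(i, "default", scores.get(i, 0),
                       "normal" if scores.get(i, 0) == 0 else f"code{scores[i]}")
             for i in range(1, 32)]
    s = ScoreSheet(metadata=SheetMetadata(cycle_id=cycle), item_scores=items)
    s.recompute_totals()
    return s


class TestRaterDiff:
    def test_identical_sheets_empty_report(self):
        a, b = _sheet({5: 1}), _sheet({5: 1})
        rep = rater_diff(a, b)
        assert rep.in_agreement and not rep.warnings

    def test_score_and_descriptor_discrepancies(self):
        a, b = _sheet({5: 1, 9: 2}), _sheet({5: 2, 9: 2})
        b.item(24).descriptor_code = "circumduction"
        a.item(24).descriptor_code = "scissoring"
        rep = rater_diff(a, b)
        kinds = {(d.item_id, d.kind) for d in rep.discrepancies}
        assert (5, "score") in kinds and (24, "descriptor") in kinds

    def test_different_cycles_warn(self):
        rep = rater_diff(_sheet({}, cycle="step-3"), _sheet({}, cycle="step-5"))
        assert any("same exact gait cycle" in w for w in rep.warnings)

    def test_mismatched_exclusions_reported_not_fatal(self):
        a, b = _sheet({}), _sheet({})
        a.item(18).excluded = True
        a.item(18).exclusion_reason = "footwear"
        rep = rater_diff(a, b)
        assert any(d.kind == "exclusion" for d in rep.discrepancies)
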