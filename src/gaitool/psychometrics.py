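"""Rater-agreement statistics and clinically-important-change interpretation.

The reliability statistic is the intraclass correlation coefficient,
two-way random effects, absolute agreement, single measures -- ICC(2,1) in
the Shrout-Fleiss taxonomy -- the usual choice for clinical test-retest and
inter-rater designs.  It is computed from the two-way ANOVA mean squares

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

with the standard F-based 95% confidence interval.  Published reliability
for the instrument on stroke survivors is high (intra-rater ICC 0.98,
inter-rater 0.83); those values come from patient recordings and are not
re-estimated here -- this module provides the routine for the rater-training
workflow.

Published minimal clinically important difference (MCID) bands for the total
score: subacute stroke, 1.5-4 points (a range, reported as such); chronic
stroke, 11.8 points anchored to Functional Ambulation Category (FAC) level 3
/ household ambulation, or 5.19 points anchored to FAC levels 4-5 /
community ambulation.  The chronic values were derived from bilaterally
averaged scores, which may have inflated them; the caveat is repeated in the
interpretation whenever a bilateral average is used.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .rubric import ScoreSheet

MCID_SUBACUTE_RANGE = (1.5, 4.0)
MCID_CHRONIC = {"FAC3_household": 11.8, "FAC45_community": 5.19}

BILATERAL_CAVEAT = ("bilaterally averaged total: the published chronic MCID was "
                    "derived from bilaterally averaged scores, which may have "
                    "inflated it by averaging out paretic-limb change")


class PsychometricsError(ValueError):
    pass


@dataclass
class RaterMatrix:
    """targets x raters (or sessions) matrix of scores."""

    ratings: np.ndarray
    design: str = "inter_rater"  # or intra_rater (columns = sessions)

    def __post_init__(self):
        r = np.asarray(self.ratings, dtype=float)
        if r.ndim != 2:
            raise PsychometricsError("ratings must be 2-D (targets x raters)")
        if r.shape[1] < 2 or r.shape[0] < 2:
            raise PsychometricsError(">= 2 targets and >= 2 raters/sessions required")
        if np.isnan(r).any():
            keep = ~np.isnan(r).any(axis=1)
            warnings.warn(f"dropping {int((~keep).sum())} target(s) with missing "
                          f"cells (listwise)", stacklevel=2)
            r = r[keep]
            if r.shape[0] < 2:
                raise PsychometricsError("fewer than 2 complete targets remain")
        self.ratings = r

    @classmethod
    def from_csv(cls, path, design: str = "inter_rater") -> "RaterMatrix":
        df = pd.read_csv(path)
        num = df.select_dtypes("number")
        return cls(num.to_numpy(), design=design)


@dataclass
class ICCResult:
    estimate: float
    ci95: tuple[float, float]
    form: str
    n_targets: int
    n_raters: int
    msr: float
    msc: float
    mse: float
    p_value: float
    degenerate: bool = False

    def __str__(self) -> str:
        lo, hi = self.ci95
        return (f"ICC(2,1) = {self.estimate:.3f} (95% CI {lo:.3f}-{hi:.3f}), "
                f"n={self.n_targets} targets x {self.n_raters} raters")


def icc(matrix: RaterMatrix, alpha: float = 0.05) -> ICCResult:
    """Two-way random-effects, absolute-agreement, single-measure ICC with
    its F-based confidence interval and the underlying ANOVA mean squares."""
    x = matrix.ratings
    n, k = x.shape
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ssr = k * np.sum((row_m - grand) ** 2)
    ssc = n * np.sum((col_m - grand) ** 2)
    sse = np.sum((x - row_m[:, None] - col_m[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or np.isclose(msr + msc + mse, 0):
        warnings.warn("zero between-target variance: ICC undefined, reported as "
                      "0 by convention", stacklevel=2)
        return ICCResult(0.0, (0.0, 0.0), "ICC(2,1)", n, k, msr, msc, mse,
                         p_value=1.0, degenerate=True)
    est = (msr - mse) / denom

    if mse <= 0:  # perfect agreement: no residual variance
        p = 0.0 if est > 0 else 1.0
        return ICCResult(float(est), (float(est), float(est)), "ICC(2,1)",
                         n, k, msr, msc, mse, p_value=p,
                         degenerate=False)

    # F test of H0: ICC = 0 and the Satterthwaite-df confidence bounds
    fv = msr / mse
    p_value = float(1.0 - f_dist.cdf(fv, n - 1, (n - 1) * (k - 1)))
    fc = msc / mse
    est_c = min(max(est, 1e-12), 1 - 1e-12)
    vn = (k - 1) * (n - 1) * (k * est_c * fc + n * (1 + (k - 1) * est_c) - k * est_c) ** 2
    vd = ((n - 1) * k ** 2 * est_c ** 2 * fc ** 2
          + (n * (1 + (k - 1) * est_c) - k * est_c) ** 2)
    v = vn / vd
    f2u = f_dist.ppf(1 - alpha / 2, n - 1, v)
    f2l = f_dist.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f2u * mse) / (f2u * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f2l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2l * msr)
    lower, upper = float(max(-1.0, lower)), float(min(1.0, upper))
    return ICCResult(float(est), (lower, upper), "ICC(2,1)", n, k,
                     float(msr), float(msc), float(mse), p_value=p_value)


@dataclass
class ChangeInterpretation:
    population: str                # subacute_stroke | chronic_stroke
    anchor: Optional[str]          # FAC3_household | FAC45_community
    change: float                  # |post - pre| in points
    band: str
    meets_mcid: bool
    notes: list[str] = field(default_factory=list)

    def __str__(self) -> str:
        verdict = "meets" if self.meets_mcid else "does not meet"
        s = (f"change of {self.change:g} points ({self.population}"
             f"{', ' + self.anchor if self.anchor else ''}): {self.band}; "
             f"{verdict} the published MCID")
        for note in self.notes:
            s += f"\n  note: {note}"
        return s


def interpret_change(pre: float, post: float, population: str,
                     anchor: Optional[str] = None,
                     bilateral_average: bool = False) -> ChangeInterpretation:
    """Compare an absolute total-score change against the published MCID
    band for the population (direction of improvement: lower = better)."""
    change = abs(post - pre)
    notes = ["direction of improvement: lower total = more normal gait"]
    if bilateral_average:
        notes.append(BILATERAL_CAVEAT)
    if population == "subacute_stroke":
        lo, hi = MCID_SUBACUTE_RANGE
        if change < lo:
            band = f"below the published {lo}-{hi} point MCID range"
            meets = False
        elif change <= hi:
            band = f"within the published {lo}-{hi} point MCID range"
            meets = True
        else:
            band = f"above the published {lo}-{hi} point MCID range"
            meets = True
        return ChangeInterpretation(population, None, change, band, meets, notes)
    if population == "chronic_stroke":
        if anchor not in MCID_CHRONIC:
            raise PsychometricsError(
                "chronic-stroke interpretation requires an anchor: one of "
                + ", ".join(MCID_CHRONIC))
        thr = MCID_CHRONIC[anchor]
        meets = change >= thr
        band = (f"{'at or above' if meets else 'below'} the published "
                f"{thr}-point MCID ({anchor})")
        return ChangeInterpretation(population, anchor, change, band, meets, notes)
    raise PsychometricsError(f"unknown population {population!r}")


@dataclass
class ItemDiscrepancy:
    item_id: int
    score_a: int
    score_b: int
    code_a: str
    code_b: str
    kind: str  # "score" | "descriptor" | "exclusion"


@dataclass
class RaterDiffReport:
    discrepancies: list[ItemDiscrepancy]
    warnings: list[str]

    @property
    def in_agreement(self) -> bool:
        return not self.discrepancies


def rater_diff(sheet_a: ScoreSheet, sheet_b: ScoreSheet) -> RaterDiffReport:
    """Per-item discrepancy report for the two-rater consensus workflow:
    items where score, descriptor or exclusion status differ.  Warns when
    the sheets reference different gait cycles -- each evaluator must score
    the same exact gait cycle."""
    warns = []
    ca, cb = sheet_a.metadata.cycle_id, sheet_b.metadata.cycle_id
    if ca and cb and ca != cb:
        warns.append(f"sheets reference different gait cycles ({ca!r} vs {cb!r}); "
                     "raters must score the same exact gait cycle")
    out = []
    for sa in sheet_a.item_scores:
        try:
            sb = sheet_b.item(sa.item_id)
        except KeyError:
            warns.append(f"item {sa.item_id} missing from second sheet")
            continue
        if sa.excluded != sb.excluded:
            out.append(ItemDiscrepancy(sa.item_id, sa.score, sb.score,
                                       sa.descriptor_code, sb.descriptor_code,
                                       "exclusion"))
        elif sa.score != sb.score:
            out.append(ItemDiscrepancy(sa.item_id, sa.score, sb.score,
                                       sa.descriptor_code, sb.descriptor_code,
                                       "score"))
        elif (sa.descriptor_code != sb.descriptor_code
              or tuple(sa.checkboxes) != tuple(sb.checkboxes)):
            out.append(ItemDiscrepancy(sa.item_id, sa.score, sb.score,
                                       sa.descriptor_code, sb.descriptor_code,
                                       "descriptor"))
    return RaterDiffReport(out, warns)


def bilateral_average(sheet_left: ScoreSheet, sheet_right: ScoreSheet) -> dict:
    """Optional bilaterally-averaged summary (never the default): one MCID
    study scored both sides and averaged.  Labelled with its caveat."""
    return {
        "left_total": sheet_left.total,
        "right_total": sheet_right.total,
        "bilateral_average_total": (sheet_left.total + sheet_right.total) / 2.0,
        "caveat": BILATERAL_CAVEAT,
    }
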