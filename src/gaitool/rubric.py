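"""The 31-item gait-coordination rubric and the item-level scoring engine.

The instrument is an ordinal observational measure of gait coordination:
each item scores one joint-movement component at a named temporal event of
the gait cycle, 0 (normal) up to the item's maximum, the 31 maxima summing
to 62.  Items are scored either from a rater's descriptor selection
(*observed* mode) or from kinematic measurements (*measured* mode); measured
mode resolves each printed threshold through the realized intervals shipped
in the packaged rubric (see ``data/rubric.yaml`` for the boundary
convention).

Values that are abnormal but fall in a gap the printed levels do not cover
never score 0: they map to the nearest abnormal level and are flagged for
review.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Optional

import yaml

from .config import DEFAULT_CONFIG, EngineConfig

RUBRIC_VERSION = "1.0"
SECTIONS = ("stance_and_swing", "stance", "swing")
TOTAL_MAX_SCORE = 62
N_ITEMS = 31


class RubricError(Exception):
    """Corrupt or inconsistent packaged rubric."""


class ScoringError(ValueError):
    """Invalid input to the scoring engine."""


class MissingMeasurementError(ScoringError):
    def __init__(self, item_id: int, names: Iterable[str]):
        self.item_id = item_id
        self.names = sorted(names)
        super().__init__(
            f"item {item_id}: missing required measurement(s): {', '.join(self.names)}"
        )


@dataclass(frozen=True)
class Interval:
    """Realized half-open/closed interval predicate on one measurement."""

    measurement: str
    lo: float = -math.inf
    hi: float = math.inf
    lo_open: bool = False
    hi_open: bool = False
    absolute: bool = False

    def contains(self, value: float) -> bool:
        v = abs(value) if self.absolute else value
        lo_ok = v > self.lo if self.lo_open else v >= self.lo
        hi_ok = v < self.hi if self.hi_open else v <= self.hi
        return lo_ok and hi_ok

    def distance(self, value: float) -> float:
        """Distance from value to the interval (0 when inside)."""
        v = abs(value) if self.absolute else value
        if v < self.lo:
            return self.lo - v
        if v > self.hi:
            return v - self.hi
        return 0.0


@dataclass(frozen=True)
class ScoreLevel:
    score: int
    code: str
    text: str
    interval: Optional[Interval] = None
    checkboxes: tuple[str, ...] = ()


@dataclass(frozen=True)
class Branch:
    label: str
    levels: tuple[ScoreLevel, ...]
    title: Optional[str] = None

    @property
    def level0(self) -> ScoreLevel:
        return next(lv for lv in self.levels if lv.score == 0)

    def level(self, code: str) -> ScoreLevel:
        for lv in self.levels:
            if lv.code == code:
                return lv
        raise ScoringError(f"branch {self.label!r} has no level {code!r}")


@dataclass(frozen=True)
class ItemDefinition:
    id: int
    name: str
    section: str
    plane: str
    view: str
    branches: tuple[Branch, ...]
    required_inputs: tuple[str, ...]
    primary_measurement: Optional[str] = None

    @property
    def max_score(self) -> int:
        return max(lv.score for br in self.branches for lv in br.levels)

    @property
    def abnormal_scores(self) -> tuple[int, ...]:
        """Distinct nonzero score values across all branches, ascending."""
        return tuple(sorted({lv.score for br in self.branches for lv in br.levels
                             if lv.score > 0}))

    def branch(self, label: str) -> Branch:
        for br in self.branches:
            if br.label == label:
                return br
        raise ScoringError(f"item {self.id} has no branch {label!r}")

    def find_level(self, code: str,
                   branch_label: Optional[str] = None) -> tuple[Branch, ScoreLevel]:
        candidates = ([self.branch(branch_label)] if branch_label
                      else list(self.branches))
        for br in candidates:
            for lv in br.levels:
                if lv.code == code:
                    return br, lv
        raise ScoringError(f"item {self.id}: descriptor {code!r} not in item")


@dataclass(frozen=True)
class ItemInput:
    """One item's worth of input: either an observed descriptor selection or
    a mapping of named measurements (exactly one of the two)."""

    item_id: int
    mode: str  # "observed" | "measured"
    observed_code: Optional[str] = None
    branch_label: Optional[str] = None
    checkboxes: tuple[str, ...] = ()
    measurements: Optional[Mapping[str, float]] = None

    def __post_init__(self):
        if self.mode not in ("observed", "measured"):
            raise ScoringError(f"unknown mode {self.mode!r}")
        if (self.mode == "observed") != (self.observed_code is not None):
            raise ScoringError("observed mode requires observed_code (and only then)")
        if (self.mode == "measured") != (self.measurements is not None):
            raise ScoringError("measured mode requires measurements (and only then)")


@dataclass
class ItemScore:
    item_id: int
    branch_label: str
    score: int
    descriptor_code: str
    checkboxes: tuple[str, ...] = ()
    excluded: bool = False
    exclusion_reason: Optional[str] = None
    adjusted: bool = False
    adjustment_reason: Optional[str] = None
    flagged_for_review: bool = False
    raw_score: Optional[int] = None  # pre-adjustment score, kept for audit

    def to_dict(self) -> dict:
        return {
            "item_id": self.item_id,
            "branch": self.branch_label,
            "score": self.score,
            "code": self.descriptor_code,
            "checkboxes": list(self.checkboxes),
            "excluded": self.excluded,
            "exclusion_reason": self.exclusion_reason,
            "adjusted": self.adjusted,
            "adjustment_reason": self.adjustment_reason,
            "flagged_for_review": self.flagged_for_review,
            "raw_score": self.raw_score,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ItemScore":
        return cls(
            item_id=d["item_id"], branch_label=d["branch"], score=d["score"],
            descriptor_code=d["code"], checkboxes=tuple(d.get("checkboxes") or ()),
            excluded=d.get("excluded", False),
            exclusion_reason=d.get("exclusion_reason"),
            adjusted=d.get("adjusted", False),
            adjustment_reason=d.get("adjustment_reason"),
            flagged_for_review=d.get("flagged_for_review", False),
            raw_score=d.get("raw_score"),
        )


@dataclass
class SheetMetadata:
    """Mirrors the printed form header."""

    name: str = ""
    date: str = ""
    examiner: str = ""
    diagnosis: str = ""
    limb_assessed: str = ""
    device: str = "none"
    orthosis: str = "none"
    assist: str = "none"
    footwear: str = "barefoot"
    cycle_id: str = ""
    comments: str = ""
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("name", "date", "examiner", "diagnosis", "limb_assessed",
                 "device", "orthosis", "assist", "footwear", "cycle_id",
                 "comments")} | {"notes": list(self.notes)}

    @classmethod
    def from_dict(cls, d: dict) -> "SheetMetadata":
        kw = {k: d.get(k, "") for k in
              ("name", "date", "examiner", "diagnosis", "limb_assessed",
               "cycle_id", "comments")}
        kw |= {k: d.get(k, dflt) for k, dflt in
               (("device", "none"), ("orthosis", "none"),
                ("assist", "none"), ("footwear", "barefoot"))}
        return cls(notes=list(d.get("notes") or []), **kw)


@dataclass
class ScoreSheet:
    metadata: SheetMetadata
    item_scores: list[ItemScore]
    total: int = 0
    max_possible: int = TOTAL_MAX_SCORE

    @property
    def normalized(self) -> float:
        return self.total / self.max_possible if self.max_possible else 0.0

    def item(self, item_id: int) -> ItemScore:
        for sc in self.item_scores:
            if sc.item_id == item_id:
                return sc
        raise KeyError(f"no score for item {item_id}")

    def recompute_totals(self, rubric: Optional[list[ItemDefinition]] = None) -> None:
        rubric = rubric if rubric is not None else load_rubric()
        by_id = {it.id: it for it in rubric}
        self.total = sum(sc.score for sc in self.item_scores if not sc.excluded)
        self.max_possible = TOTAL_MAX_SCORE - sum(
            by_id[sc.item_id].max_score for sc in self.item_scores if sc.excluded)

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata.to_dict(),
            "items": [sc.to_dict() for sc in self.item_scores],
            "total": self.total,
            "max_possible": self.max_possible,
            "normalized": self.normalized,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreSheet":
        return cls(
            metadata=SheetMetadata.from_dict(d.get("metadata", {})),
            item_scores=[ItemScore.from_dict(x) for x in d["items"]],
            total=d.get("total", 0),
            max_possible=d.get("max_possible", TOTAL_MAX_SCORE),
        )


# ---------------------------------------------------------------------------
# rubric loading

_RUBRIC_CACHE: Optional[tuple[ItemDefinition, ...]] = None


def _parse_interval(d: dict) -> Interval:
    return Interval(
        measurement=d["measurement"],
        lo=float(d.get("lo", -math.inf)),
        hi=float(d.get("hi", math.inf)),
        lo_open=bool(d.get("lo_open", False)),
        hi_open=bool(d.get("hi_open", False)),
        absolute=bool(d.get("abs", False)),
    )


def _parse_item(d: dict) -> ItemDefinition:
    branches = []
    for bd in d["branches"]:
        levels = []
        for ld in bd["levels"]:
            levels.append(ScoreLevel(
                score=int(ld["score"]),
                code=str(ld["code"]),
                text=str(ld["text"]),
                interval=_parse_interval(ld["interval"]) if "interval" in ld else None,
                checkboxes=tuple(ld.get("checkboxes") or ()),
            ))
        branches.append(Branch(label=str(bd.get("label", "default")),
                               title=bd.get("title"),
                               levels=tuple(levels)))
    return ItemDefinition(
        id=int(d["id"]), name=str(d["name"]), section=str(d["section"]),
        plane=str(d.get("plane", "none")), view=str(d.get("view", "none")),
        branches=tuple(branches),
        required_inputs=tuple(d.get("required_inputs") or ()),
        primary_measurement=d.get("primary_measurement"),
    )


def _validate_rubric(items: tuple[ItemDefinition, ...]) -> None:
    if len(items) != N_ITEMS:
        raise RubricError(f"expected {N_ITEMS} items, found {len(items)}")
    if [it.id for it in items] != list(range(1, N_ITEMS + 1)):
        raise RubricError("item ids are not 1..31 in order")
    total = sum(it.max_score for it in items)
    if total != TOTAL_MAX_SCORE:
        raise RubricError(f"per-item maxima sum to {total}, expected {TOTAL_MAX_SCORE}")
    for it in items:
        want = ("stance_and_swing" if it.id <= 4 else
                "stance" if it.id <= 18 else "swing")
        if it.section != want:
            raise RubricError(f"item {it.id}: section {it.section!r}, expected {want!r}")
        for br in it.branches:
            n0 = sum(1 for lv in br.levels if lv.score == 0)
            if n0 != 1:
                raise RubricError(f"item {it.id} branch {br.label}: {n0} level-0 entries")
        codes = [(br.label, lv.code) for br in it.branches for lv in br.levels]
        if len(codes) != len(set(codes)):
            raise RubricError(f"item {it.id}: duplicate descriptor codes")


def load_rubric() -> list[ItemDefinition]:
    """Load the packaged rubric: all 31 items with every printed level,
    threshold and branch.  Hard failure (naming the item) on corruption."""
    global _RUBRIC_CACHE
    if _RUBRIC_CACHE is None:
        text = resources.files("gaitool.data").joinpath("rubric.yaml").read_text()
        raw = yaml.safe_load(text)
        items = tuple(_parse_item(d) for d in raw["items"])
        _validate_rubric(items)
        _RUBRIC_CACHE = items
    return list(_RUBRIC_CACHE)


def rubric_by_id() -> dict[int, ItemDefinition]:
    return {it.id: it for it in load_rubric()}


# ---------------------------------------------------------------------------
# scoring

def score_item(item: ItemDefinition, inp: ItemInput,
               config: EngineConfig = DEFAULT_CONFIG,
               side: str = "right") -> ItemScore:
    """Score a single item.  Deterministic; observed descriptors are looked
    up verbatim, measured values are resolved through the item's realized
    intervals and pattern classifiers (branch inferred from the sign/pattern
    of the dominant deviation)."""
    if inp.item_id != item.id:
        raise ScoringError(f"input is for item {inp.item_id}, not {item.id}")
    if inp.mode == "observed":
        br, lv = item.find_level(inp.observed_code, inp.branch_label)
        bad = [c for c in inp.checkboxes if c not in lv.checkboxes]
        if bad:
            raise ScoringError(
                f"item {item.id}: checkbox(es) {bad} not defined for level {lv.code!r}")
        return ItemScore(item.id, br.label, lv.score, lv.code,
                         checkboxes=tuple(inp.checkboxes), raw_score=lv.score)
    from . import measured  # local import to avoid a cycle
    missing = [n for n in item.required_inputs if n not in inp.measurements]
    if missing:
        raise MissingMeasurementError(item.id, missing)
    return measured.classify(item, dict(inp.measurements), config, side)


def score_sheet(inputs: list[ItemInput], context=None,
                config: EngineConfig = DEFAULT_CONFIG,
                side: str = "right",
                metadata: Optional[SheetMetadata] = None,
                exclusions: Optional[dict[int, str]] = None) -> ScoreSheet:
    """Score a full sheet: one input per non-excluded item, then the
    administration adjustments (orthosis midpoint, assistive-device minimums,
    physical-assist escalation, footwear exclusions), then totals."""
    from .adjustments import ContextFlags, apply_adjustments

    context = context if context is not None else ContextFlags()
    rubric = load_rubric()
    by_id = {i.id: i for i in rubric}
    seen = [i.item_id for i in inputs]
    dupes = {x for x in seen if seen.count(x) > 1}
    if dupes:
        raise ScoringError(f"duplicate inputs for item(s) {sorted(dupes)}")

    exclusions = dict(exclusions or {})
    if context.footwear == "shoes":
        for iid in (18, 31):
            exclusions.setdefault(iid, "not scored - footwear (toe position not visible)")
    missing = [i for i in range(1, N_ITEMS + 1) if i not in seen and i not in exclusions]
    if missing:
        raise ScoringError(
            f"no input for item(s) {missing} and no exclusion justifies their absence")

    scores: list[ItemScore] = []
    for iid in range(1, N_ITEMS + 1):
        if iid in exclusions and iid not in seen:
            lv0 = by_id[iid].branches[0].level0
            scores.append(ItemScore(iid, by_id[iid].branches[0].label, 0, lv0.code,
                                    excluded=True, exclusion_reason=exclusions[iid],
                                    raw_score=None))
        else:
            inp = next(i for i in inputs if i.item_id == iid)
            sc = score_item(by_id[iid], inp, config, side)
            if iid in exclusions:
                sc.excluded = True
                sc.exclusion_reason = exclusions[iid]
            scores.append(sc)

    md = metadata if metadata is not None else SheetMetadata()
    md.limb_assessed = md.limb_assessed or side
    sheet = ScoreSheet(metadata=md, item_scores=scores)
    return apply_adjustments(sheet, context, rubric)
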