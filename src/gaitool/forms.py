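"""Score-sheet rendering and parsing.

Two text surfaces:

* a printable **markdown form** mirroring the instrument's printed layout
  (header fields, the three phase sections, one line per item with the
  selected level's descriptor and checked sub-descriptors, the comments
  section and the total over the adjusted maximum).  Each item line carries
  a machine-readable bracket so that rendering and re-parsing a sheet is an
  identity;
* an **observed-mode YAML form** keyed by item id and descriptor code (a
  blank template comes from ``blank_form``), the unambiguous way for a
  rater to enter scores.
"""
from __future__ import annotations

import re
import warnings
from typing import Optional

import yaml

from .adjustments import ContextFlags
from .config import DEFAULT_CONFIG, EngineConfig
from .rubric import (ItemInput, ItemScore, ScoreSheet, ScoringError,
                     SheetMetadata, load_rubric, score_sheet)

_SECTION_TITLES = {"stance_and_swing": "Stance and Swing Phases",
                   "stance": "Stance Phase",
                   "swing": "Swing Phase"}

_DEVICE_VOCAB = ("none", "cane", "walker", "other")
_ORTHOSIS_VOCAB = ("none", "AFO", "KAFO", "other")
_ASSIST_VOCAB = ("none", "standby", "minimal_1", "moderate_or_2plus")
_FOOTWEAR_VOCAB = ("barefoot", "shoes")


def _clean(s: str) -> str:
    return (s or "").replace("\n", "; ").replace("|", "/").strip()


def render_form(sheet: ScoreSheet) -> str:
    """Markdown form mirroring the printed instrument layout."""
    by_id = {it.id: it for it in load_rubric()}
    md = sheet.metadata
    lines = ["# G.A.I.T. Score Sheet", ""]
    lines.append(f"Name: {_clean(md.name)} | Date: {_clean(md.date)} | "
                 f"Examiner: {_clean(md.examiner)}")
    lines.append(f"Diagnosis: {_clean(md.diagnosis)} | "
                 f"Limb assessed: {_clean(md.limb_assessed)} | "
                 f"Cycle: {_clean(md.cycle_id)}")
    lines.append(f"Device: {md.device} | Orthosis: {md.orthosis} | "
                 f"Assist: {md.assist} | Footwear: {md.footwear}")
    lines.append("")
    section = None
    for sc in sheet.item_scores:
        item = by_id[sc.item_id]
        if item.section != section:
            section = item.section
            lines.append(f"## {_SECTION_TITLES[section]}")
            lines.append("")
        if sc.excluded:
            raw = "-" if sc.raw_score is None else str(sc.raw_score)
            bracket = (f"[excluded: {_clean(sc.exclusion_reason) or 'excluded'} | "
                       f"branch: {sc.branch_label} | code: {sc.descriptor_code} | "
                       f"raw: {raw}]")
            lines.append(f"{sc.item_id}. {item.name} — not scored {bracket}")
            continue
        br = item.branch(sc.branch_label)
        lv = br.level(sc.descriptor_code)
        checks = ",".join(sc.checkboxes) if sc.checkboxes else "-"
        raw = "-" if sc.raw_score is None else str(sc.raw_score)
        adj = _clean(sc.adjustment_reason) if sc.adjusted else "-"
        flag = "yes" if sc.flagged_for_review else "no"
        bracket = (f"[score: {sc.score} | branch: {sc.branch_label} | "
                   f"code: {sc.descriptor_code} | checks: {checks} | "
                   f"raw: {raw} | adjusted: {adj} | flagged: {flag}]")
        desc = lv.text
        if sc.checkboxes:
            desc += " (" + ", ".join(f"[x] {c}" for c in sc.checkboxes) + ")"
        lines.append(f"{sc.item_id}. {item.name} — {sc.score} = {desc} {bracket}")
    lines.append("")
    lines.append(f"**Total Score: {sheet.total} / {sheet.max_possible}**")
    lines.append("")
    lines.append(f"Comments: {_clean(md.comments)}")
    for note in md.notes:
        lines.append(f"Note: {_clean(note)}")
    lines.append("")
    return "\n".join(lines)


_ITEM_RE = re.compile(r"^(\d+)\.\s+.*\[(.+)\]\s*$")
_HEADER_RES = {
    "name": re.compile(r"Name:\s*([^|]*)"),
    "date": re.compile(r"Date:\s*([^|]*)"),
    "examiner": re.compile(r"Examiner:\s*([^|]*)"),
    "diagnosis": re.compile(r"Diagnosis:\s*([^|]*)"),
    "limb_assessed": re.compile(r"Limb assessed:\s*([^|]*)"),
    "cycle_id": re.compile(r"Cycle:\s*([^|]*)"),
    "device": re.compile(r"Device:\s*([^|]*)"),
    "orthosis": re.compile(r"Orthosis:\s*([^|]*)"),
    "assist": re.compile(r"Assist:\s*([^|]*)"),
    "footwear": re.compile(r"Footwear:\s*([^|]*)"),
    "comments": re.compile(r"Comments:\s*(.*)$"),
}


def parse_form(text: str) -> ScoreSheet:
    """Parse a rendered markdown form back into an identical ScoreSheet."""
    md = SheetMetadata()
    seen_keys: set[str] = set()
    notes: list[str] = []
    items: list[ItemScore] = []
    for line in text.splitlines():
        m = _ITEM_RE.match(line.strip())
        if m:
            iid = int(m.group(1))
            fields = {}
            for part in m.group(2).split(" | "):
                key, _, val = part.partition(":")
                fields[key.strip()] = val.strip()
            if "excluded" in fields:
                raw = fields.get("raw", "-")
                items.append(ItemScore(
                    iid, fields.get("branch", "default"), 0,
                    fields.get("code", "normal"), excluded=True,
                    exclusion_reason=fields["excluded"],
                    raw_score=None if raw == "-" else int(raw)))
            else:
                checks = fields.get("checks", "-")
                raw = fields.get("raw", "-")
                adj = fields.get("adjusted", "-")
                items.append(ItemScore(
                    iid, fields["branch"], int(fields["score"]), fields["code"],
                    checkboxes=tuple(c for c in checks.split(",") if c and c != "-"),
                    adjusted=adj != "-",
                    adjustment_reason=None if adj == "-" else adj,
                    flagged_for_review=fields.get("flagged") == "yes",
                    raw_score=None if raw == "-" else int(raw)))
            continue
        if line.startswith("Note: "):
            notes.append(line[len("Note: "):])
            continue
        for key, rx in _HEADER_RES.items():
            mm = rx.search(line)
            if mm and key not in seen_keys:
                setattr(md, key, mm.group(1).strip())
                seen_keys.add(key)
    md.notes = notes
    if not items:
        raise ScoringError("no item lines found in form text")
    sheet = ScoreSheet(metadata=md, item_scores=sorted(items, key=lambda s: s.item_id))
    sheet.recompute_totals()
    return sheet


# ---------------------------------------------------------------------------
# observed-mode YAML form

def blank_form() -> str:
    """A blank observed-mode form: every item at its level-0 descriptor,
    available descriptor codes listed alongside."""
    lines = ["# Observed-mode score entry: set `code` (and `branch` for the",
             "# branched items) per item; checkboxes where the level offers them.",
             "metadata:",
             '  name: ""', '  date: ""', '  examiner: ""', '  diagnosis: ""',
             '  limb_assessed: right', '  device: none', '  orthosis: none',
             '  assist: none', '  footwear: barefoot', '  cycle_id: ""',
             '  comments: ""',
             "items:"]
    for item in load_rubric():
        opts = "; ".join(
            f"{br.label}/{lv.code}={lv.score}" for br in item.branches
            for lv in br.levels)
        lines.append(f"# {item.id}. {item.name}  [{opts}]")
        lines.append(f"- item: {item.id}")
        lines.append(f"  branch: {item.branches[0].label}")
        lines.append("  code: normal")
        lines.append("  checkboxes: []")
    return "\n".join(lines) + "\n"


def context_from_metadata(md: SheetMetadata) -> ContextFlags:
    """Parse the header's device/orthosis/assist/footwear free text against
    the controlled vocabulary; unparseable text warns and applies no
    adjustment."""
    def pick(value: str, vocab: tuple, label: str) -> str:
        v = (value or "").strip()
        for option in vocab:
            if v.lower() == option.lower():
                return option
        if v:
            warnings.warn(f"unrecognised {label} {value!r}; no adjustment applied "
                          f"(expected one of {', '.join(vocab)})", stacklevel=3)
        return vocab[0]

    side = md.limb_assessed if md.limb_assessed in ("left", "right") else "right"
    return ContextFlags(
        assistive_device=pick(md.device, _DEVICE_VOCAB, "assistive device"),
        orthosis=pick(md.orthosis, _ORTHOSIS_VOCAB, "orthosis"),
        footwear=pick(md.footwear, _FOOTWEAR_VOCAB, "footwear"),
        assist=pick(md.assist, _ASSIST_VOCAB, "assist level"),
        side=side)


def read_observed_form(text: str):
    """Read an observed-mode form (YAML, or a rendered markdown form) into
    (inputs, exclusions, metadata, context)."""
    if text.lstrip().startswith("# G.A.I.T."):
        sheet = parse_form(text)
        inputs = [ItemInput(item_id=sc.item_id, mode="observed",
                            observed_code=sc.descriptor_code,
                            branch_label=sc.branch_label,
                            checkboxes=tuple(sc.checkboxes))
                  for sc in sheet.item_scores if not sc.excluded]
        exclusions = {sc.item_id: sc.exclusion_reason or "excluded"
                      for sc in sheet.item_scores if sc.excluded}
        return inputs, exclusions, sheet.metadata, context_from_metadata(sheet.metadata)
    raw = yaml.safe_load(text)
    md = SheetMetadata.from_dict(raw.get("metadata") or {})
    inputs, exclusions = [], {}
    for entry in raw.get("items") or []:
        iid = int(entry["item"])
        if entry.get("excluded"):
            exclusions[iid] = str(entry["excluded"])
            continue
        inputs.append(ItemInput(
            item_id=iid, mode="observed", observed_code=str(entry["code"]),
            branch_label=str(entry.get("branch") or "default") or None,
            checkboxes=tuple(entry.get("checkboxes") or ())))
    return inputs, exclusions, md, context_from_metadata(md)


def score_observed_form(text: str,
                        config: EngineConfig = DEFAULT_CONFIG) -> ScoreSheet:
    inputs, exclusions, md, context = read_observed_form(text)
    return score_sheet(inputs, context, config, side=context.side,
                       metadata=md, exclusions=exclusions)
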