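"""Score candidate conditions against a point allocation.

A disease profile selects exactly one criterion option per evaluation item
(subcategory).  Its scorecard awards the selected option's points per
item, sums them into category subtotals and a total, and reports them
against the "full marks" (the per-item maxima).  With the published
allocation the model's total ranges from 114 (every lowest option) to 620
(every highest option).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

from .ahp import SchemaError
from .hierarchy import CoverageError, Hierarchy, ScoreAllocation

__all__ = [
    "DiseaseProfile",
    "ScorecardRow",
    "Scorecard",
    "load_profile",
    "bundled_profile",
    "score_disease",
    "score_range",
    "deduction_report",
    "render_scorecard",
]

_DATA = resources.files("nbsahp") / "data"


@dataclass(frozen=True)
class DiseaseProfile:
    """One selected criterion option per subcategory for one condition."""

    disease: str
    selections: Mapping[str, str]  # subcategory id -> option id
    evidence: Mapping[str, str] = field(default_factory=dict)

    def validate_against(self, h: Hierarchy) -> None:
        for c in h.categories:
            for s in c.subcategories:
                sel = self.selections.get(s.id)
                if sel is None:
                    raise CoverageError(
                        f"profile {self.disease!r} has no selection for "
                        f"subcategory {s.id!r}"
                    )
                if sel not in {o.id for o in s.options}:
                    raise SchemaError(
                        f"profile {self.disease!r}: option {sel!r} does not "
                        f"belong to subcategory {s.id!r}"
                    )
        extra = set(self.selections) - {
            s.id for c in h.categories for s in c.subcategories
        }
        if extra:
            raise SchemaError(f"profile selects unknown subcategories: {sorted(extra)}")


def load_profile(source) -> DiseaseProfile:
    """Load a disease profile from a YAML path, stream, or dict."""
    if isinstance(source, Mapping):
        doc = source
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    try:
        return DiseaseProfile(
            disease=str(doc["disease"]),
            selections={str(k): str(v) for k, v in doc["selections"].items()},
            evidence={str(k): str(v) for k, v in doc.get("evidence", {}).items()},
        )
    except (KeyError, TypeError, AttributeError) as exc:
        raise SchemaError(f"malformed profile: {exc}") from exc


def bundled_profile(name: str) -> DiseaseProfile:
    """Bundled validation profiles: ``pku``, ``mcad``, or ``ch``."""
    with (_DATA / "profiles" / f"{name}.yaml").open(encoding="utf-8") as fh:
        return load_profile(fh)


@dataclass(frozen=True)
class ScorecardRow:
    category_id: str
    category_label: str
    subcategory_id: str
    subcategory_label: str
    option_id: str
    option_label: str
    rating: int
    full_marks: int


@dataclass(frozen=True)
class Scorecard:
    disease: str
    rows: tuple[ScorecardRow, ...]

    def category_subtotals(self) -> dict[str, tuple[int, int]]:
        """category id -> (subtotal, full-marks subtotal), in hierarchy order."""
        out: dict[str, tuple[int, int]] = {}
        for r in self.rows:
            sub, full = out.get(r.category_id, (0, 0))
            out[r.category_id] = (sub + r.rating, full + r.full_marks)
        return out

    @property
    def total(self) -> int:
        return sum(r.rating for r in self.rows)

    @property
    def full_marks_total(self) -> int:
        return sum(r.full_marks for r in self.rows)


def _subcat_max(a: ScoreAllocation, h: Hierarchy, sid: str) -> int:
    return max(a.subcategory_points(h, sid).values())


def score_disease(p: DiseaseProfile, a: ScoreAllocation, h: Hierarchy) -> Scorecard:
    """Rate a profile: selected option's points per item, summed up the tree."""
    p.validate_against(h)
    rows = []
    for c in h.categories:
        for s in c.subcategories:
            oid = p.selections[s.id]
            opt = next(o for o in s.options if o.id == oid)
            rows.append(
                ScorecardRow(
                    category_id=c.id,
                    category_label=c.label,
                    subcategory_id=s.id,
                    subcategory_label=s.label,
                    option_id=oid,
                    option_label=opt.label,
                    rating=a[f"{c.id}/{s.id}/{oid}"],
                    full_marks=_subcat_max(a, h, s.id),
                )
            )
    return Scorecard(disease=p.disease, rows=tuple(rows))


def score_range(a: ScoreAllocation, h: Hierarchy) -> tuple[int, int]:
    """(lowest, highest) achievable total: per-item minima/maxima summed."""
    lo = hi = 0
    for c in h.categories:
        for s in c.subcategories:
            pts = a.subcategory_points(h, s.id).values()
            lo += min(pts)
            hi += max(pts)
    return lo, hi


def deduction_report(
    p: DiseaseProfile, a: ScoreAllocation, h: Hierarchy
) -> list[tuple[str, int]]:
    """Points lost per subcategory (full marks minus rating), largest first.

    Only items with a nonzero loss are listed; the losses sum to
    ``max_total - total``.
    """
    card = score_disease(p, a, h)
    losses = [
        (r.subcategory_id, r.full_marks - r.rating)
        for r in card.rows
        if r.full_marks > r.rating
    ]
    losses.sort(key=lambda t: (-t[1], t[0]))
    return losses


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _scorecard_dict(s: Scorecard) -> dict:
    return {
        "disease": s.disease,
        "rows": [
            {
                "category_id": r.category_id,
                "category_label": r.category_label,
                "subcategory_id": r.subcategory_id,
                "subcategory_label": r.subcategory_label,
                "option_id": r.option_id,
                "option_label": r.option_label,
                "rating": r.rating,
                "full_marks": r.full_marks,
            }
            for r in s.rows
        ],
        "category_subtotals": {
            cid: {"rating": sub, "full_marks": full}
            for cid, (sub, full) in s.category_subtotals().items()
        },
        "total": s.total,
        "full_marks_total": s.full_marks_total,
    }


def scorecard_from_json(text: str) -> Scorecard:
    doc = json.loads(text)
    rows = tuple(
        ScorecardRow(
            category_id=r["category_id"],
            category_label=r["category_label"],
            subcategory_id=r["subcategory_id"],
            subcategory_label=r["subcategory_label"],
            option_id=r["option_id"],
            option_label=r["option_label"],
            rating=int(r["rating"]),
            full_marks=int(r["full_marks"]),
        )
        for r in doc["rows"]
    )
    return Scorecard(disease=doc["disease"], rows=rows)


def render_scorecard(s: Scorecard, fmt: str = "text") -> str:
    """Render a scorecard as ``csv``, ``json``, or aligned ``text``.

    All formats mirror the published table layout: one row per evaluation
    item with its selected criterion, rating and full marks, a subtotal row
    per category and a final total row.
    """
    if fmt == "json":
        return json.dumps(_scorecard_dict(s), indent=2, ensure_ascii=False)
    subtotals = s.category_subtotals()
    if fmt == "csv":
        import csv as _csv

        buf = io.StringIO()
        w = _csv.writer(buf)
        w.writerow(["row_type", "category", "subcategory", "criteria", "rating_score", "full_marks"])
        for cid, (sub, full) in subtotals.items():
            for r in s.rows:
                if r.category_id == cid:
                    w.writerow(["criterion", r.category_label, r.subcategory_label,
                                r.option_label, r.rating, r.full_marks])
            w.writerow(["subtotal", next(r.category_label for r in s.rows
                                         if r.category_id == cid), "", "", sub, full])
        w.writerow(["total", "", "", "", s.total, s.full_marks_total])
        return buf.getvalue()
    if fmt == "text":
        lines = [f"Scoring results: {s.disease}", ""]
        widths = (34, 44, 8, 10)
        header = f"{'Subcategory':<{widths[0]}}  {'Criteria':<{widths[1]}}  {'Rating':>{widths[2]}}  {'Full marks':>{widths[3]}}"
        for cid, (sub, full) in subtotals.items():
            label = next(r.category_label for r in s.rows if r.category_id == cid)
            lines.append(f"[{label}]")
            lines.append(header)
            for r in s.rows:
                if r.category_id == cid:
                    lines.append(
                        f"{r.subcategory_label[:widths[0]]:<{widths[0]}}  "
                        f"{r.option_label[:widths[1]]:<{widths[1]}}  "
                        f"{r.rating:>{widths[2]}}  {r.full_marks:>{widths[3]}}"
                    )
            lines.append(f"{'Subtotal':<{widths[0] + widths[1] + 2}}  {sub:>{widths[2]}}  {full:>{widths[3]}}")
            lines.append("")
        lines.append(f"{'Total':<{widths[0] + widths[1] + 2}}  {s.total:>{widths[2]}}  {s.full_marks_total:>{widths[3]}}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {fmt!r}; use csv, json, or text")
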