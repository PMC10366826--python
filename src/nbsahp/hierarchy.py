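"""Assessment hierarchy, weight composition, and point allocation.

The assessment instrument is a three-level hierarchy: five categories
(disease/condition, screening test, intervention, follow-up setting,
economic evaluation), sixteen subcategories (the evaluation items), and
fifty criterion options (the ordinal levels a candidate condition can be
rated at).  Local priority vectors — one per internal node, obtained from
pairwise comparisons — are composed multiplicatively down the tree into
global option weights, which are converted into an integer point
allocation by multiplying by 1000 and rounding to whole numbers.

The canonical hierarchy, the published point allocation, and the published
category weights ship as bundled fixtures (``nbsahp/data``).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Mapping, Sequence

import yaml

from .ahp import (
    CI_THRESHOLD,
    DEFAULT_SCALE,
    AggregationPolicy,
    ConsistencyReport,
    JudgmentScale,
    PairwiseMatrix,
    PriorityVector,
    SchemaError,
    aggregate_matrices,
    consistency_index,
    geometric_mean_weights,
    group_matrices,
)

__all__ = [
    "Option",
    "Subcategory",
    "Category",
    "Hierarchy",
    "LocalWeights",
    "GlobalWeights",
    "ScoreAllocation",
    "CoverageError",
    "load_hierarchy",
    "save_hierarchy",
    "canonical_hierarchy",
    "published_allocation",
    "published_category_weights",
    "enumerate_questions",
    "compose_global_weights",
    "allocate_scores",
    "weights_from_survey",
    "load_allocation",
    "save_allocation",
    "uniform_local_weights",
]

#: node path of the category-level comparison matrix
ROOT = "root"

_DATA = resources.files("nbsahp") / "data"


class CoverageError(ValueError):
    """A required node/selection is absent."""


@dataclass(frozen=True)
class Option:
    id: str
    label: str


@dataclass(frozen=True)
class Subcategory:
    id: str
    label: str
    description: str = ""
    options: tuple[Option, ...] = ()

    def __post_init__(self) -> None:
        if len(self.options) < 2:
            raise SchemaError(f"subcategory {self.id!r} needs >= 2 options")
        ids = [o.id for o in self.options]
        if len(set(ids)) != len(ids):
            raise SchemaError(f"duplicate option ids under subcategory {self.id!r}")


@dataclass(frozen=True)
class Category:
    id: str
    label: str
    subcategories: tuple[Subcategory, ...] = ()

    def __post_init__(self) -> None:
        if not self.subcategories:
            raise SchemaError(f"category {self.id!r} has no subcategories")
        ids = [s.id for s in self.subcategories]
        if len(set(ids)) != len(ids):
            raise SchemaError(f"duplicate subcategory ids under category {self.id!r}")


@dataclass(frozen=True)
class Hierarchy:
    """Category -> subcategory -> criterion-option tree."""

    categories: tuple[Category, ...]

    def __post_init__(self) -> None:
        cids = [c.id for c in self.categories]
        if len(set(cids)) != len(cids):
            raise SchemaError("duplicate category ids")
        # subcategory ids must be globally unique: disease profiles key on them
        sids = [s.id for c in self.categories for s in c.subcategories]
        if len(set(sids)) != len(sids):
            raise SchemaError("subcategory ids must be unique across the hierarchy")

    # -- structure queries ------------------------------------------------

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    @property
    def n_subcategories(self) -> int:
        return sum(len(c.subcategories) for c in self.categories)

    @property
    def n_options(self) -> int:
        return sum(len(s.options) for c in self.categories for s in c.subcategories)

    def category(self, cid: str) -> Category:
        for c in self.categories:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def subcategory(self, sid: str) -> tuple[Category, Subcategory]:
        for c in self.categories:
            for s in c.subcategories:
                if s.id == sid:
                    return c, s
        raise KeyError(sid)

    def internal_nodes(self) -> list[tuple[str, tuple[str, ...]]]:
        """(node path, ordered child ids) for every internal node.

        The root (comparing categories) has path ``root``; a category node
        ``<cat>``; a subcategory node ``<cat>/<sub>``.
        """
        nodes = [(ROOT, tuple(c.id for c in self.categories))]
        for c in self.categories:
            nodes.append((c.id, tuple(s.id for s in c.subcategories)))
            for s in c.subcategories:
                nodes.append((f"{c.id}/{s.id}", tuple(o.id for o in s.options)))
        return nodes

    def option_paths(self) -> list[str]:
        """``cat/sub/opt`` paths in canonical (table) order."""
        return [
            f"{c.id}/{s.id}/{o.id}"
            for c in self.categories
            for s in c.subcategories
            for o in s.options
        ]


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------


def _hierarchy_from_dict(doc: Mapping) -> Hierarchy:
    try:
        cats = []
        for c in doc["categories"]:
            subs = []
            for s in c["subcategories"]:
                opts = tuple(Option(id=o["id"], label=o["label"]) for o in s["options"])
                subs.append(
                    Subcategory(
                        id=s["id"],
                        label=s["label"],
                        description=s.get("description", ""),
                        options=opts,
                    )
                )
            cats.append(Category(id=c["id"], label=c["label"], subcategories=tuple(subs)))
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed hierarchy config: {exc}") from exc
    return Hierarchy(categories=tuple(cats))


def _hierarchy_to_dict(h: Hierarchy) -> dict:
    return {
        "categories": [
            {
                "id": c.id,
                "label": c.label,
                "subcategories": [
                    {
                        "id": s.id,
                        "label": s.label,
                        "description": s.description,
                        "options": [{"id": o.id, "label": o.label} for o in s.options],
                    }
                    for s in c.subcategories
                ],
            }
            for c in h.categories
        ]
    }


def load_hierarchy(source) -> Hierarchy:
    """Load and validate a hierarchy from a YAML path, stream, or dict."""
    if isinstance(source, Mapping):
        return _hierarchy_from_dict(source)
    if hasattr(source, "read"):
        return _hierarchy_from_dict(yaml.safe_load(source))
    with open(source, encoding="utf-8") as fh:
        return _hierarchy_from_dict(yaml.safe_load(fh))


def save_hierarchy(h: Hierarchy, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_hierarchy_to_dict(h), fh, sort_keys=False, allow_unicode=True)


def canonical_hierarchy() -> Hierarchy:
    """The bundled canonical assessment hierarchy (5/16/50 nodes)."""
    with (_DATA / "hierarchy.yaml").open(encoding="utf-8") as fh:
        return load_hierarchy(fh)


def enumerate_questions(h: Hierarchy) -> dict[str, list[tuple[str, str, str]]]:
    """Full pairwise question sets per level: (node, item_a, item_b).

    Every internal node with k >= 2 children contributes C(k, 2) pairs.
    For the canonical hierarchy this yields 10 category, 25 subcategory and
    57 criterion pairs.  The published survey instrument asked 10/22/56; the
    reduced design for the 3 missing pairs was never disclosed, so full
    enumeration is used and the discrepancy documented rather than
    reverse-engineered.
    """
    out: dict[str, list[tuple[str, str, str]]] = {
        "category": [],
        "subcategory": [],
        "criterion": [],
    }
    level_of = {0: "category", 1: "subcategory", 2: "criterion"}
    for node, children in h.internal_nodes():
        depth = 0 if node == ROOT else node.count("/") + 1
        level = level_of[depth]
        for i in range(len(children)):
            for j in range(i + 1, len(children)):
                out[level].append((node, children[i], children[j]))
    return out


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocalWeights:
    """One priority vector per internal node, keyed by node path."""

    vectors: Mapping[str, PriorityVector]

    def validate_against(self, h: Hierarchy) -> None:
        for node, children in h.internal_nodes():
            v = self.vectors.get(node)
            if v is None:
                raise CoverageError(f"no priority vector for node {node!r}")
            if v.items != children:
                raise SchemaError(
                    f"node {node!r}: vector items {v.items} != children {children}"
                )

    def __getitem__(self, node: str) -> PriorityVector:
        return self.vectors[node]


@dataclass(frozen=True)
class GlobalWeights:
    """Global weight per criterion option, keyed by ``cat/sub/opt`` path."""

    weights: Mapping[str, float]

    def total(self) -> float:
        return float(sum(self.weights.values()))

    def __getitem__(self, path: str) -> float:
        return self.weights[path]


def uniform_local_weights(h: Hierarchy) -> LocalWeights:
    """Equal weights at every node (useful baseline and test input)."""
    import numpy as np

    vecs = {}
    for node, children in h.internal_nodes():
        n = len(children)
        vecs[node] = PriorityVector(children, np.full(n, 1.0 / n))
    return LocalWeights(vecs)


def compose_global_weights(h: Hierarchy, lw: LocalWeights) -> GlobalWeights:
    """Multiply local weights along each root -> option path.

    Categories with a single subcategory (economic evaluation) carry
    subcategory weight 1, passing the category weight straight through.
    """
    lw.validate_against(h)
    cat_w = lw[ROOT].as_dict()
    out: dict[str, float] = {}
    for c in h.categories:
        sub_w = lw[c.id].as_dict()
        for s in c.subcategories:
            opt_w = lw[f"{c.id}/{s.id}"].as_dict()
            for o in s.options:
                out[f"{c.id}/{s.id}/{o.id}"] = cat_w[c.id] * sub_w[s.id] * opt_w[o.id]
    return GlobalWeights(out)


# ---------------------------------------------------------------------------
# Point allocation
# ---------------------------------------------------------------------------

RoundingRule = Literal["half_up", "bankers"]


def _round(x: float, rule: RoundingRule) -> int:
    if rule == "half_up":
        return int(math.floor(x + 0.5))
    if rule == "bankers":
        return round(x)
    raise ValueError(f"unknown rounding rule {rule!r}")


@dataclass(frozen=True)
class ScoreAllocation:
    """Integer points per criterion option (``cat/sub/opt`` path keys)."""

    points: Mapping[str, int]
    provenance: str = "computed"

    def __getitem__(self, path: str) -> int:
        return self.points[path]

    def grand_total(self) -> int:
        return sum(self.points.values())

    def subcategory_points(self, h: Hierarchy, sid: str) -> dict[str, int]:
        c, s = h.subcategory(sid)
        return {o.id: self.points[f"{c.id}/{s.id}/{o.id}"] for o in s.options}

    def category_total(self, h: Hierarchy, cid: str) -> int:
        c = h.category(cid)
        return sum(
            self.points[f"{c.id}/{s.id}/{o.id}"]
            for s in c.subcategories
            for o in s.options
        )


def allocate_scores(
    gw: GlobalWeights,
    rounding: RoundingRule = "half_up",
    provenance: str = "computed",
) -> ScoreAllocation:
    """points = round(1000 * weight); grand total within 1000 +/- #options."""
    if abs(gw.total() - 1.0) > 1e-6:
        raise ValueError(f"global weights sum to {gw.total()}, not 1")
    pts = {path: _round(1000.0 * w, rounding) for path, w in gw.weights.items()}
    alloc = ScoreAllocation(points=pts, provenance=provenance)
    n = len(pts)
    if not (1000 - n <= alloc.grand_total() <= 1000 + n):
        raise AssertionError("rounding bound violated; weights not normalised?")
    return alloc


def load_allocation(path) -> ScoreAllocation:
    """Read an allocation CSV (category_id, subcategory_id, option_id, points, provenance)."""
    pts: dict[str, int] = {}
    provs: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            key = f"{row['category_id']}/{row['subcategory_id']}/{row['option_id']}"
            if key in pts:
                raise SchemaError(f"duplicate allocation row for {key}")
            pts[key] = int(row["points"])
            provs.add(row["provenance"])
    prov = provs.pop() if len(provs) == 1 else "mixed"
    return ScoreAllocation(points=pts, provenance=prov)


def save_allocation(a: ScoreAllocation, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["category_id", "subcategory_id", "option_id", "points", "provenance"])
        for key, pts in a.points.items():
            cid, sid, oid = key.split("/")
            writer.writerow([cid, sid, oid, pts, a.provenance])


def published_allocation() -> ScoreAllocation:
    """The published point allocation, bundled as an immutable fixture."""
    with resources.as_file(_DATA / "table3_allocation.csv") as p:
        return load_allocation(p)


def published_category_weights() -> dict[str, float]:
    """Published category-level weights (sum to 0.999 due to printing)."""
    with (_DATA / "category_weights.yaml").open(encoding="utf-8") as fh:
        return {str(k): float(v) for k, v in yaml.safe_load(fh).items()}


def load_local_weights(source) -> LocalWeights:
    """Read local weights from YAML: ``{node_path: {child_id: weight}}``."""
    import numpy as np

    if isinstance(source, Mapping):
        doc = source
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    vecs = {}
    for node, mapping in doc.items():
        items = tuple(str(k) for k in mapping)
        vecs[str(node)] = PriorityVector(items, np.array([float(mapping[k]) for k in mapping]))
    return LocalWeights(vecs)


def save_local_weights(lw: LocalWeights, path) -> None:
    doc = {node: {k: float(v) for k, v in vec.as_dict().items()}
           for node, vec in lw.vectors.items()}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


# ---------------------------------------------------------------------------
# Survey -> weights pipeline
# ---------------------------------------------------------------------------


def weights_from_survey(
    h: Hierarchy,
    rows: Sequence[Mapping[str, str]],
    scale: JudgmentScale = DEFAULT_SCALE,
    policy: AggregationPolicy = "aij",
    ci_threshold: float = CI_THRESHOLD,
) -> tuple[LocalWeights, dict[str, ConsistencyReport]]:
    """Aggregate respondent judgments node by node and solve for weights.

    For every internal node with >= 2 children the respondents' complete
    matrices are aggregated (AIJ by default), solved by row geometric
    means, and the aggregated matrix's consistency reported.  Single-child
    nodes get weight 1 and CI 0 without any comparisons.  Respondents who
    skipped a node entirely are excluded from that node only; a node with
    zero usable matrices is a coverage error.
    """
    import numpy as np

    vecs: dict[str, PriorityVector] = {}
    reports: dict[str, ConsistencyReport] = {}
    for node, children in h.internal_nodes():
        if len(children) == 1:
            vecs[node] = PriorityVector(children, np.array([1.0]))
            reports[node] = ConsistencyReport(lambda_max=1.0, ci=0.0, n=1, consistent=True)
            continue
        mats = group_matrices(rows, node, children, scale)
        if not mats:
            raise CoverageError(f"no usable respondent matrices for node {node!r}")
        agg = aggregate_matrices(mats, policy)
        if isinstance(agg, PairwiseMatrix):
            w = geometric_mean_weights(agg)
            reports[node] = consistency_index(agg, w, ci_threshold)
        else:  # AIP: consistency assessed on the AIJ matrix as a summary
            w = agg
            aij = aggregate_matrices(mats, "aij")
            assert isinstance(aij, PairwiseMatrix)
            reports[node] = consistency_index(aij, geometric_mean_weights(aij), ci_threshold)
        vecs[node] = w
    return LocalWeights(vecs), reports
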