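"""Pairwise-comparison core of the analytic hierarchy process (AHP).

Verbal judgments from a panel of respondents are turned into positive
reciprocal comparison matrices, aggregated across the panel, and solved
for priority weights by the row geometric-mean method.  Consistency of
each (aggregated) matrix is summarised by the consistency index
CI = (lambda_max - n) / (n - 1), with CI = 0 for perfectly consistent
judgments; following common practice for coarse verbal scales, a matrix
with CI <= 0.15 is treated as acceptably consistent.

A power-iteration principal-eigenvector solver is included as an
independent cross-check of the geometric-mean method; for n <= 3 the two
coincide analytically.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "STRENGTH_LEVELS",
    "DEFAULT_SCALE",
    "CI_THRESHOLD",
    "VerbalJudgment",
    "JudgmentScale",
    "PairwiseMatrix",
    "PriorityVector",
    "ConsistencyReport",
    "SchemaError",
    "ConflictError",
    "build_matrix",
    "geometric_mean_weights",
    "eigenvector_weights",
    "consistency_index",
    "aggregate_matrices",
    "read_responses",
    "write_responses",
    "RESPONSE_COLUMNS",
]

# Verbal response levels, weakest to strongest.
STRENGTH_LEVELS = ("equal", "moderate", "strong", "very_strong")

#: CI above this value flags the judgments as inconsistent.
CI_THRESHOLD = 0.15

#: Normalisation tolerance for priority vectors.
NORM_TOL = 1e-12

#: Power-iteration convergence tolerance and iteration cap.
POWER_TOL = 1e-10
POWER_MAXITER = 10_000


class SchemaError(ValueError):
    """Input refers to unknown items or is structurally malformed."""


class ConflictError(ValueError):
    """Mutually contradictory inputs (e.g. the same pair judged twice)."""


@dataclass(frozen=True)
class JudgmentScale:
    """Mapping from verbal strength levels to importance ratios.

    The four verbal levels map by default onto the odd Saaty values
    1, 3, 5, 7 ("extreme", 9, has no verbal counterpart here).  ``equal``
    must map to exactly 1 and values must increase strictly with strength.
    """

    values: Mapping[str, float] = field(
        default_factory=lambda: {
            "equal": 1.0,
            "moderate": 3.0,
            "strong": 5.0,
            "very_strong": 7.0,
        }
    )

    def __post_init__(self) -> None:
        missing = [s for s in STRENGTH_LEVELS if s not in self.values]
        if missing:
            raise SchemaError(f"scale is missing strength levels: {missing}")
        if self.values["equal"] != 1:
            raise SchemaError("'equal' must map to exactly 1")
        seq = [float(self.values[s]) for s in STRENGTH_LEVELS]
        if any(v < 1 for v in seq) or any(b <= a for a, b in zip(seq, seq[1:])):
            raise SchemaError(
                "scale values must be >= 1 and strictly increasing with strength"
            )

    def __getitem__(self, strength: str) -> float:
        return float(self.values[strength])

    def lattice(self) -> np.ndarray:
        """All representable ratio values: scale values and their reciprocals."""
        vals = {float(v) for v in self.values.values()}
        vals |= {1.0 / v for v in vals}
        return np.array(sorted(vals))


DEFAULT_SCALE = JudgmentScale()


@dataclass(frozen=True)
class VerbalJudgment:
    """One pairwise comparison: how much more important is one item?

    ``direction`` names the more important item ('a' or 'b'); it is
    ignored when strength is 'equal' (record 'none' there).
    """

    item_a: str
    item_b: str
    strength: str
    direction: Literal["a", "b", "none"] = "none"

    def __post_init__(self) -> None:
        if self.item_a == self.item_b:
            raise SchemaError(f"self-comparison of item {self.item_a!r}")
        if self.strength not in STRENGTH_LEVELS:
            raise SchemaError(f"unknown strength {self.strength!r}")
        if self.direction not in ("a", "b", "none"):
            raise SchemaError(f"unknown direction {self.direction!r}")
        if self.strength != "equal" and self.direction == "none":
            raise SchemaError("non-equal judgment requires a direction")

    def ratio(self, scale: JudgmentScale = DEFAULT_SCALE) -> float:
        """Importance of item_a relative to item_b."""
        if self.strength == "equal":
            return 1.0
        v = scale[self.strength]
        return v if self.direction == "a" else 1.0 / v


@dataclass(frozen=True)
class PairwiseMatrix:
    """Positive reciprocal matrix of judged importance ratios.

    ``values[i, j]`` is the importance of ``items[i]`` relative to
    ``items[j]``.  Cells never answered are NaN and ``is_complete`` is
    False; solvers require complete matrices.
    """

    items: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.values, dtype=float)
        n = len(self.items)
        if a.shape != (n, n):
            raise SchemaError(f"matrix shape {a.shape} does not match {n} items")
        if len(set(self.items)) != n:
            raise SchemaError("duplicate item labels")
        if not np.allclose(np.diag(a), 1.0, equal_nan=False):
            raise SchemaError("diagonal entries must equal 1")
        known = ~np.isnan(a)
        if np.any(a[known] <= 0) or np.any(np.isinf(a[known])):
            raise SchemaError("entries must be strictly positive and finite")
        if np.any(known != known.T):
            raise SchemaError("missing cells must be missing symmetrically")
        both = known & known.T
        if not np.allclose((a * a.T)[both], 1.0, rtol=1e-9):
            raise SchemaError("reciprocity violated: a_ij * a_ji != 1")
        object.__setattr__(self, "values", a)

    @property
    def n(self) -> int:
        return len(self.items)

    @property
    def is_complete(self) -> bool:
        return not np.any(np.isnan(self.values))

    def permuted(self, order: Sequence[int]) -> "PairwiseMatrix":
        """Same matrix under a simultaneous row/column/item permutation."""
        idx = np.asarray(order)
        return PairwiseMatrix(
            tuple(self.items[i] for i in idx), self.values[np.ix_(idx, idx)]
        )


@dataclass(frozen=True)
class PriorityVector:
    """Nonnegative weights over the items of one node, summing to 1."""

    items: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.items),):
            raise SchemaError("weights length does not match items")
        if np.any(w < 0):
            raise SchemaError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise SchemaError(f"weights sum to {w.sum()}, not 1")
        object.__setattr__(self, "weights", w)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.items, self.weights.tolist()))


@dataclass(frozen=True)
class ConsistencyReport:
    """Consistency summary of one comparison matrix."""

    lambda_max: float
    ci: float
    n: int
    consistent: bool


def build_matrix(
    judgments: Iterable[VerbalJudgment],
    items: Sequence[str],
    scale: JudgmentScale = DEFAULT_SCALE,
) -> PairwiseMatrix:
    """Assemble a reciprocal comparison matrix from verbal judgments.

    Each unordered pair may appear at most once; judging the same pair
    twice raises :class:`ConflictError` even if the two judgments agree.
    Pairs never judged are left NaN and flag the matrix incomplete.
    """
    items = tuple(items)
    index = {it: i for i, it in enumerate(items)}
    n = len(items)
    a = np.full((n, n), np.nan)
    np.fill_diagonal(a, 1.0)
    seen: set[frozenset[str]] = set()
    for j in judgments:
        if j.item_a not in index or j.item_b not in index:
            raise SchemaError(
                f"judgment on ({j.item_a!r}, {j.item_b!r}) references an "
                f"item outside {list(items)}"
            )
        key = frozenset((j.item_a, j.item_b))
        if key in seen:
            raise ConflictError(f"pair ({j.item_a!r}, {j.item_b!r}) judged twice")
        seen.add(key)
        r = j.ratio(scale)
        ia, ib = index[j.item_a], index[j.item_b]
        a[ia, ib] = r
        a[ib, ia] = 1.0 / r
    return PairwiseMatrix(items, a)


def _require_complete(m: PairwiseMatrix) -> None:
    if not m.is_complete:
        missing = [
            (m.items[i], m.items[j])
            for i in range(m.n)
            for j in range(i + 1, m.n)
            if math.isnan(m.values[i, j])
        ]
        raise ValueError(f"matrix incomplete; missing pairs: {missing}")


def geometric_mean_weights(m: PairwiseMatrix) -> PriorityVector:
    """Row geometric-mean priority vector, normalised to sum to 1.

    w_i proportional to (prod_j a_ij)^(1/n); exact for consistent
    matrices (a_ij = w_i / w_j).
    """
    _require_complete(m)
    if m.n == 1:
        return PriorityVector(m.items, np.array([1.0]))
    g = np.exp(np.log(m.values).mean(axis=1))
    return PriorityVector(m.items, g / g.sum())


def eigenvector_weights(
    m: PairwiseMatrix,
    tol: float = POWER_TOL,
    maxiter: int = POWER_MAXITER,
) -> PriorityVector:
    """Principal right eigenvector by power iteration (independent oracle)."""
    _require_complete(m)
    if m.n == 1:
        return PriorityVector(m.items, np.array([1.0]))
    w = np.full(m.n, 1.0 / m.n)
    for _ in range(maxiter):
        nxt = m.values @ w
        nxt /= nxt.sum()
        if np.abs(nxt - w).max() < tol:
            return PriorityVector(m.items, nxt)
        w = nxt
    raise ArithmeticError(f"power iteration failed to converge in {maxiter} steps")


def consistency_index(
    m: PairwiseMatrix,
    w: PriorityVector,
    threshold: float = CI_THRESHOLD,
) -> ConsistencyReport:
    """CI = (lambda_max - n)/(n - 1) with lambda_max from Rayleigh ratios.

    lambda_max is estimated as the mean of (A w)_i / w_i, which equals the
    principal eigenvalue when ``w`` is the exact eigenvector (in particular
    for consistent matrices).  Complete reciprocal matrices of order <= 2
    are consistent by construction, so CI = 0 there.
    """
    if m.items != w.items:
        raise SchemaError("matrix and priority vector items differ in order")
    _require_complete(m)
    if m.n <= 2:
        lam = float(m.n)
        ci = 0.0
    else:
        ratios = (m.values @ w.weights) / w.weights
        lam = float(ratios.mean())
        ci = (lam - m.n) / (m.n - 1)
        if abs(ci) < 1e-12:  # clip numerical noise in the consistent case
            ci = 0.0
    return ConsistencyReport(lambda_max=lam, ci=ci, n=m.n, consistent=ci <= threshold)


AggregationPolicy = Literal["aij", "aip"]


def aggregate_matrices(
    group: Sequence[PairwiseMatrix],
    policy: AggregationPolicy = "aij",
) -> PairwiseMatrix | PriorityVector:
    """Combine one comparison matrix per respondent into a group judgment.

    ``aij`` (aggregation of individual judgments, the default) takes the
    element-wise geometric mean of the respondents' matrices, which
    preserves reciprocity exactly, and returns a matrix to be solved once.
    ``aip`` (aggregation of individual priorities) solves each respondent's
    matrix first and returns the geometric mean of the priority vectors,
    renormalised.  Respondents who skipped a block are simply absent from
    ``group``; partially filled matrices are rejected.
    """
    if not group:
        raise ValueError("cannot aggregate an empty group")
    items = group[0].items
    for m in group:
        if m.items != items:
            raise SchemaError(f"item mismatch: {m.items} vs {items}")
        _require_complete(m)
    if policy == "aij":
        logs = np.stack([np.log(m.values) for m in group])
        mean_log = logs.mean(axis=0)
        # symmetrise so reciprocity holds exactly despite fp rounding
        mean_log = (mean_log - mean_log.T) / 2.0
        return PairwiseMatrix(items, np.exp(mean_log))
    if policy == "aip":
        ws = np.stack([geometric_mean_weights(m).weights for m in group])
        g = np.exp(np.log(ws).mean(axis=0))
        return PriorityVector(items, g / g.sum())
    raise ValueError(f"unknown aggregation policy {policy!r}")


# ---------------------------------------------------------------------------
# Survey response CSV schema
# ---------------------------------------------------------------------------

RESPONSE_COLUMNS = (
    "respondent_id",
    "level",
    "matrix_id",
    "item_a",
    "item_b",
    "judgment",
    "direction",
)

_LEVELS = ("category", "subcategory", "criterion")


def read_responses(path) -> list[dict[str, str]]:
    """Read survey responses from CSV (UTF-8, header required).

    Columns: respondent_id, level (category|subcategory|criterion),
    matrix_id (node path, e.g. ``screening_test`` or
    ``screening_test/cost``), item_a, item_b,
    judgment (equal|moderate|strong|very_strong), direction (a|b|none).
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != RESPONSE_COLUMNS:
            raise SchemaError(
                f"expected header {list(RESPONSE_COLUMNS)}, got {reader.fieldnames}"
            )
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if row["level"] not in _LEVELS:
                raise SchemaError(f"line {lineno}: unknown level {row['level']!r}")
            if row["judgment"] not in STRENGTH_LEVELS:
                raise SchemaError(f"line {lineno}: unknown judgment {row['judgment']!r}")
            if row["direction"] not in ("a", "b", "none"):
                raise SchemaError(f"line {lineno}: unknown direction {row['direction']!r}")
            rows.append(dict(row))
    return rows


def write_responses(rows: Iterable[Mapping[str, str]], path) -> None:
    """Write survey responses in the CSV schema of :func:`read_responses`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=RESPONSE_COLUMNS)
        writer.writeheader()
        for row in rows:
            writer.writerow({c: row[c] for c in RESPONSE_COLUMNS})


def group_matrices(
    rows: Sequence[Mapping[str, str]],
    matrix_id: str,
    items: Sequence[str],
    scale: JudgmentScale = DEFAULT_SCALE,
) -> list[PairwiseMatrix]:
    """Per-respondent complete matrices for one node of the hierarchy.

    A respondent with no records for the node is skipped (allowed for the
    technical criterion block); a respondent with some but not all pairs
    answered is a schema violation.
    """
    per_resp: dict[str, list[VerbalJudgment]] = {}
    for row in rows:
        if row["matrix_id"] != matrix_id:
            continue
        per_resp.setdefault(row["respondent_id"], []).append(
            VerbalJudgment(
                item_a=row["item_a"],
                item_b=row["item_b"],
                strength=row["judgment"],
                direction=row["direction"],
            )
        )
    out = []
    for rid in sorted(per_resp):
        m = build_matrix(per_resp[rid], items, scale)
        if not m.is_complete:
            raise SchemaError(
                f"respondent {rid!r} answered node {matrix_id!r} only partially"
            )
        out.append(m)
    return out
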