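"""Fuzzy extension of the AHP weighting step.

Crisp Saaty judgments are fuzzified to triangular fuzzy numbers (TFNs)
with a ±1 spread around the mode, saturated at the scale ends, and
propagated through Buckley's row-geometric-mean construction to yield
fuzzy criterion weights.  The fuzzy weights carry the variability of the
relative-importance judgments into the priority weights; they are
collapsed back to crisp values by the centroid and renormalized.

TFN arithmetic follows the standard interval approximation: products and
powers are taken componentwise, and a quotient of positive TFNs pairs the
numerator's lower bound with the denominator's upper bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ahp import PairwiseComparisonMatrix, WeightVector, consistency

__all__ = [
    "TriangularFuzzyNumber",
    "FuzzyWeightVector",
    "tfn_scale",
    "fuzzify_matrix",
    "buckley_fuzzy_weights",
    "group_buckley_fuzzy_weights",
    "defuzzify",
    "group_weight_table",
    "normalize_defuzzified",
    "weight_table",
    "round_display",
]

_SCALE_INTEGERS = (1, 2, 3, 4, 5, 6, 7, 8, 9)
_MATCH_TOL = 1e-9


@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """Triangular fuzzy number (l, m, u): membership rises linearly from
    ``l`` to a peak at the mode ``m`` and falls to zero at ``u``."""

    l: float
    m: float
    u: float

    def __post_init__(self):
        if not (self.l <= self.m <= self.u):
            raise ValueError(f"TFN requires l <= m <= u, got ({self.l}, {self.m}, {self.u})")
        if self.l <= 0:
            raise ValueError("TFNs here represent positive ratios; l must be > 0")

    def __mul__(self, other: "TriangularFuzzyNumber") -> "TriangularFuzzyNumber":
        return TriangularFuzzyNumber(self.l * other.l, self.m * other.m, self.u * other.u)

    def __add__(self, other: "TriangularFuzzyNumber") -> "TriangularFuzzyNumber":
        return TriangularFuzzyNumber(self.l + other.l, self.m + other.m, self.u + other.u)

    def reciprocal(self) -> "TriangularFuzzyNumber":
        return TriangularFuzzyNumber(1.0 / self.u, 1.0 / self.m, 1.0 / self.l)

    def root(self, n: int) -> "TriangularFuzzyNumber":
        return TriangularFuzzyNumber(self.l ** (1.0 / n), self.m ** (1.0 / n), self.u ** (1.0 / n))

    def centroid(self) -> float:
        return (self.l + self.m + self.u) / 3.0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.l, self.m, self.u)


@dataclass(frozen=True)
class FuzzyWeightVector:
    """One triangular fuzzy weight per criterion of a set.

    Buckley's construction guarantees that the modes coincide with the
    crisp geometric-mean weights and therefore sum to 1.
    """

    set_id: str
    criteria: tuple[str, ...]
    weights: tuple[TriangularFuzzyNumber, ...]

    def __post_init__(self):
        if len(self.weights) != len(self.criteria):
            raise ValueError("one fuzzy weight per criterion required")
        if abs(sum(w.m for w in self.weights) - 1.0) > 1e-9:
            raise ValueError("fuzzy weight modes must sum to 1")

    def modes(self) -> WeightVector:
        return WeightVector(
            self.set_id, self.criteria, np.array([w.m for w in self.weights])
        )

    def __getitem__(self, criterion: str) -> TriangularFuzzyNumber:
        return self.weights[self.criteria.index(criterion)]


def tfn_scale(intensity: float) -> TriangularFuzzyNumber:
    """Fuzzify a Saaty intensity with a ±1 spread saturated at the scale ends.

    1 → (1, 1, 1); an integer x in 2..8 → (x−1, x, x+1); 9 → (8, 9, 9);
    a reciprocal 1/x maps to the fuzzy reciprocal.  Even intermediate
    intensities are supported for interoperability; anything off the
    1/9..9 grid is rejected.
    """
    for x in _SCALE_INTEGERS:
        if abs(intensity - x) <= _MATCH_TOL:
            if x == 1:
                return TriangularFuzzyNumber(1.0, 1.0, 1.0)
            return TriangularFuzzyNumber(float(x - 1), float(x), float(min(x + 1, 9)))
        if abs(intensity - 1.0 / x) <= _MATCH_TOL / x:
            return tfn_scale(float(x)).reciprocal()
    raise ValueError(f"intensity {intensity!r} is not on the supported 1/9..9 scale")


def fuzzify_matrix(matrix: PairwiseComparisonMatrix) -> list[list[TriangularFuzzyNumber]]:
    """Elementwise fuzzification of a crisp pairwise matrix."""
    return [[tfn_scale(x) for x in row] for row in matrix.values]


def _buckley_from_fuzzy(
    fuzzy: Sequence[Sequence[TriangularFuzzyNumber]],
    set_id: str,
    criteria: tuple[str, ...],
) -> FuzzyWeightVector:
    n = len(fuzzy)
    row_means = []
    for row in fuzzy:
        prod = TriangularFuzzyNumber(1.0, 1.0, 1.0)
        for cell in row:
            prod = prod * cell
        row_means.append(prod.root(n))
    sum_l = sum(r.l for r in row_means)
    sum_m = sum(r.m for r in row_means)
    sum_u = sum(r.u for r in row_means)
    weights = tuple(
        TriangularFuzzyNumber(r.l / sum_u, r.m / sum_m, r.u / sum_l) for r in row_means
    )
    return FuzzyWeightVector(set_id, criteria, weights)


def buckley_fuzzy_weights(matrix: PairwiseComparisonMatrix) -> FuzzyWeightVector:
    """Buckley fuzzy weights of one pairwise matrix.

    Row fuzzy geometric means ``r_i = (∏_j ã_ij)^(1/n)`` are computed
    componentwise; the weight divides each row mean by the total,
    pairing bounds conservatively:
    ``w̃_i = (l_ri / Σu, m_ri / Σm, u_ri / Σl)``.
    """
    return _buckley_from_fuzzy(fuzzify_matrix(matrix), matrix.set_id, matrix.criteria)


def group_buckley_fuzzy_weights(
    matrices: Sequence[PairwiseComparisonMatrix],
) -> FuzzyWeightVector:
    """Group fuzzy weights across participants.

    Each participant's crisp matrix is fuzzified on the judgment scale,
    the fuzzy matrices are combined componentwise by the geometric mean
    (mirroring the crisp group path), and Buckley's construction is
    applied to the combined fuzzy matrix.  The modes of the result equal
    the crisp geometric-mean weights of the crisp group matrix.
    """
    if not matrices:
        raise ValueError("at least one matrix is required")
    first = matrices[0]
    for m in matrices[1:]:
        if m.set_id != first.set_id or m.criteria != first.criteria:
            raise ValueError("all matrices must share set_id, order, and criterion ordering")
    k = len(matrices)
    fuzzified = [fuzzify_matrix(m) for m in matrices]
    n = first.order
    combined: list[list[TriangularFuzzyNumber]] = []
    for i in range(n):
        row = []
        for j in range(n):
            prod = TriangularFuzzyNumber(1.0, 1.0, 1.0)
            for f in fuzzified:
                prod = prod * f[i][j]
            row.append(prod.root(k))
        combined.append(row)
    return _buckley_from_fuzzy(combined, first.set_id, first.criteria)


def defuzzify(w: TriangularFuzzyNumber) -> float:
    """Centroid defuzzification: (l + m + u) / 3."""
    return w.centroid()


def normalize_defuzzified(values: Sequence[float]) -> np.ndarray:
    """Normalize positive crisp values to sum 1."""
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        raise ValueError("defuzzified values must be positive to normalize")
    return v / v.sum()


def round_display(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, as in printed weight tables."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def weight_table(
    matrix: PairwiseComparisonMatrix,
    labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Full weighting report for one criterion set.

    One row per criterion with crisp geometric-mean weight, Buckley fuzzy
    weight (l, m, u), centroid-defuzzified value and normalized
    defuzzified weight at full precision, plus 2-dp display columns; the
    consistency diagnostics are attached as ``DataFrame.attrs``.
    """
    return _weight_table_from_fuzzy(buckley_fuzzy_weights(matrix), matrix, labels)


def group_weight_table(
    matrices: Sequence[PairwiseComparisonMatrix],
    labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Group weighting report: fuzzy group weights with crisp group
    consistency diagnostics attached."""
    from .ahp import aggregate_group

    fuzzy = group_buckley_fuzzy_weights(matrices)
    group_matrix = aggregate_group(matrices)
    return _weight_table_from_fuzzy(fuzzy, group_matrix, labels)


def _weight_table_from_fuzzy(
    fuzzy: FuzzyWeightVector,
    matrix: PairwiseComparisonMatrix,
    labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    crisp = fuzzy.modes()
    defuzz = np.array([defuzzify(w) for w in fuzzy.weights])
    norm = normalize_defuzzified(defuzz)
    df = pd.DataFrame(
        {
            "criterion": list(matrix.criteria),
            "label": [
                (labels or {}).get(c, c) for c in matrix.criteria
            ],
            "weight": crisp.weights,
            "fuzzy_l": [w.l for w in fuzzy.weights],
            "fuzzy_m": [w.m for w in fuzzy.weights],
            "fuzzy_u": [w.u for w in fuzzy.weights],
            "defuzzified": defuzz,
            "normalized_defuzzified": norm,
        }
    )
    for col in ("weight", "fuzzy_l", "fuzzy_m", "fuzzy_u", "defuzzified", "normalized_defuzzified"):
        df[f"{col}_2dp"] = df[col].map(round_display)
    report = consistency(matrix, crisp)
    df.attrs["set_id"] = matrix.set_id
    df.attrs["consistency"] = report.as_dict()
    return df
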