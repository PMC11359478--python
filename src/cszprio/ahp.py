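"""Crisp analytic hierarchy process (AHP).

Reciprocal pairwise-comparison matrices, priority-weight derivation by the
row geometric mean (default) or the principal eigenvector, Saaty's
consistency index/ratio with the CR < 0.10 acceptance gate, and group
aggregation by the element-wise geometric mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .elicitation import format_intensity

__all__ = [
    "SAATY_RANDOM_INDEX",
    "CR_THRESHOLD",
    "PairwiseComparisonMatrix",
    "WeightVector",
    "ConsistencyReport",
    "matrix_from_judgments",
    "geometric_mean_weights",
    "eigenvector_weights",
    "consistency",
    "aggregate_group",
    "read_matrix_csv",
    "write_matrix_csv",
]

#: Saaty's random consistency index by matrix order (expected CI of random
#: reciprocal matrices).  Classic values through n=10; 11-15 follow the
#: commonly published continuation.  Swappable via the ``random_index``
#: argument of :func:`consistency`.
SAATY_RANDOM_INDEX: dict[int, float] = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32,
    8: 1.41, 9: 1.45, 10: 1.49, 11: 1.51, 12: 1.54, 13: 1.56,
    14: 1.57, 15: 1.59,
}

#: Acceptance gate on the consistency ratio.
CR_THRESHOLD = 0.10

_RECIP_TOL = 1e-9


@dataclass(frozen=True)
class PairwiseComparisonMatrix:
    """One expert's reciprocal judgments over an ordered criterion set.

    ``values[i, j]`` is how many times more important criterion ``i`` is
    than criterion ``j``; the diagonal is 1 and ``a_ij * a_ji = 1``.
    """

    set_id: str
    criteria: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", a)
        n = len(self.criteria)
        if a.shape != (n, n):
            raise ValueError(f"matrix shape {a.shape} does not match {n} criteria")
        if not np.all(a > 0):
            raise ValueError("all pairwise entries must be positive")
        if not np.allclose(np.diag(a), 1.0, atol=_RECIP_TOL):
            raise ValueError("diagonal entries must equal 1")
        if not np.allclose(a * a.T, 1.0, atol=1e-7):
            i, j = np.unravel_index(np.argmax(np.abs(a * a.T - 1.0)), a.shape)
            raise ValueError(
                f"matrix is not reciprocal: a[{i},{j}]*a[{j},{i}] = {a[i, j] * a[j, i]:.6g}"
            )

    @property
    def order(self) -> int:
        return len(self.criteria)

    def is_consistent(self, tol: float = 1e-9) -> bool:
        """Exact (cardinal) consistency: a_ik = a_ij * a_jk for all triples."""
        a = self.values
        return bool(
            np.allclose(a[:, None, :], a[:, :, None] * a[None, :, :], rtol=tol, atol=tol)
        )


@dataclass(frozen=True)
class WeightVector:
    """Normalized priority weights over an ordered criterion set."""

    set_id: str
    criteria: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != (len(self.criteria),):
            raise ValueError("one weight per criterion required")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > _RECIP_TOL:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.criteria, self.weights.tolist()))

    def __getitem__(self, criterion: str) -> float:
        return self.weights[self.criteria.index(criterion)]


@dataclass(frozen=True)
class ConsistencyReport:
    """Saaty consistency diagnostics for one pairwise matrix."""

    lambda_max: float
    ci: float
    ri: float
    cr: float
    acceptable: bool = field(default=False)

    def as_dict(self) -> dict[str, float | bool]:
        return {
            "lambda_max": self.lambda_max,
            "ci": self.ci,
            "ri": self.ri,
            "cr": self.cr,
            "acceptable": self.acceptable,
        }


def matrix_from_judgments(
    judgments: Iterable[tuple[str, str, float]],
    criteria: Sequence[str],
    set_id: str = "hazard",
) -> PairwiseComparisonMatrix:
    """Assemble a full reciprocal matrix from one judgment per unordered pair.

    Each judgment ``(a, b, x)`` states that criterion ``a`` is ``x`` times
    as important as criterion ``b``; the mirror entry ``1/x`` and the unit
    diagonal are filled in automatically.  Row/column order follows
    ``criteria``.
    """
    criteria = tuple(criteria)
    index = {c: i for i, c in enumerate(criteria)}
    n = len(criteria)
    a = np.full((n, n), np.nan)
    np.fill_diagonal(a, 1.0)
    for ca, cb, x in judgments:
        if ca not in index or cb not in index:
            unknown = ca if ca not in index else cb
            raise ValueError(f"judgment references unknown criterion {unknown!r}")
        if ca == cb:
            raise ValueError(f"self-comparison of criterion {ca!r}")
        if x <= 0:
            raise ValueError(f"non-positive intensity {x!r} for pair ({ca!r}, {cb!r})")
        i, j = index[ca], index[cb]
        if not np.isnan(a[i, j]):
            raise ValueError(f"duplicate judgment for pair ({ca!r}, {cb!r})")
        a[i, j] = x
        a[j, i] = 1.0 / x
    if np.isnan(a).any():
        i, j = map(int, np.argwhere(np.isnan(a))[0])
        raise ValueError(f"missing judgment for pair ({criteria[i]!r}, {criteria[j]!r})")
    return PairwiseComparisonMatrix(set_id=set_id, criteria=criteria, values=a)


def geometric_mean_weights(matrix: PairwiseComparisonMatrix) -> WeightVector:
    """Row-geometric-mean priority weights, normalized to sum 1.

    ``w_i ∝ (∏_j a_ij)^(1/n)``.  Exact on consistent matrices and the
    basis of the fuzzy weighting pipeline.
    """
    gm = np.exp(np.mean(np.log(matrix.values), axis=1))
    return WeightVector(matrix.set_id, matrix.criteria, gm / gm.sum())


def eigenvector_weights(
    matrix: PairwiseComparisonMatrix,
    tolerance: float = 1e-12,
    max_iterations: int = 10_000,
) -> WeightVector:
    """Principal right eigenvector weights by power iteration.

    Converges for every positive matrix (Perron-Frobenius); raises if the
    iteration budget is exhausted before the L1 change drops below
    ``tolerance``.
    """
    a = matrix.values
    w = np.full(matrix.order, 1.0 / matrix.order)
    for _ in range(max_iterations):
        nxt = a @ w
        nxt /= nxt.sum()
        if np.abs(nxt - w).sum() < tolerance:
            return WeightVector(matrix.set_id, matrix.criteria, nxt)
        w = nxt
    raise RuntimeError(
        f"power iteration did not converge to {tolerance:g} within {max_iterations} iterations"
    )


def consistency(
    matrix: PairwiseComparisonMatrix,
    weights: WeightVector | None = None,
    random_index: dict[int, float] = SAATY_RANDOM_INDEX,
    threshold: float = CR_THRESHOLD,
) -> ConsistencyReport:
    """Saaty consistency ratio of a pairwise matrix.

    ``lambda_max`` is the mean over rows of ``(A w)_i / w_i`` for the
    supplied weight vector (geometric-mean weights by default), so the
    ratio is well defined for either weighting method;
    ``CI = (lambda_max - n) / (n - 1)`` and ``CR = CI / RI``.  Matrices of
    order 1 or 2 are always consistent (CR = 0).
    """
    if weights is None:
        weights = geometric_mean_weights(matrix)
    w = weights.weights
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive for consistency assessment")
    n = matrix.order
    if n <= 2:
        return ConsistencyReport(lambda_max=float(n), ci=0.0, ri=0.0, cr=0.0, acceptable=True)
    lambda_max = float(np.mean((matrix.values @ w) / w))
    ci = (lambda_max - n) / (n - 1)
    try:
        ri = random_index[n]
    except KeyError:
        raise ValueError(
            f"no random index for matrix order {n}; table covers n <= {max(random_index)}"
        ) from None
    cr = ci / ri
    return ConsistencyReport(
        lambda_max=lambda_max, ci=ci, ri=ri, cr=cr, acceptable=cr < threshold
    )


def eigen_lambda_max(matrix: PairwiseComparisonMatrix) -> float:
    """Principal eigenvalue by dense eigen-decomposition (cross-check path)."""
    return float(np.max(np.linalg.eigvals(matrix.values).real))


def aggregate_group(
    matrices: Sequence[PairwiseComparisonMatrix],
) -> PairwiseComparisonMatrix:
    """Combine per-participant matrices by the element-wise geometric mean.

    The geometric mean is the only reciprocal-preserving group aggregation
    of judgment ratios, so the result is again a valid pairwise matrix.
    """
    if not matrices:
        raise ValueError("at least one matrix is required for group aggregation")
    first = matrices[0]
    for m in matrices[1:]:
        if m.set_id != first.set_id:
            raise ValueError(f"mixed criterion sets: {m.set_id!r} vs {first.set_id!r}")
        if m.criteria != first.criteria:
            raise ValueError("all matrices must share order and criterion ordering")
    logs = np.mean([np.log(m.values) for m in matrices], axis=0)
    # antisymmetrize in log space so reciprocity survives float drift
    logs = (logs - logs.T) / 2.0
    combined = np.exp(logs)
    np.fill_diagonal(combined, 1.0)
    return PairwiseComparisonMatrix(first.set_id, first.criteria, combined)


def read_matrix_csv(path: str | Path, set_id: str | None = None) -> PairwiseComparisonMatrix:
    """Read a square pairwise matrix with criterion ids as header row/column.

    Entries may be decimals or '1/7'-style fractions.
    """
    df = pd.read_csv(path, index_col=0, dtype=str)
    criteria = tuple(df.columns)
    if tuple(df.index) != criteria:
        raise ValueError(f"{path}: row labels must match column labels in order")
    values = np.array(
        [[float(Fraction(str(x).strip())) for x in row] for row in df.to_numpy()]
    )
    return PairwiseComparisonMatrix(set_id or Path(path).stem, criteria, values)


def write_matrix_csv(matrix: PairwiseComparisonMatrix, path: str | Path) -> None:
    """Write a matrix CSV, rendering reciprocal entries as '1/x' fractions."""
    rows = [
        [format_intensity(x) for x in row]
        for row in matrix.values
    ]
    pd.DataFrame(rows, index=list(matrix.criteria), columns=list(matrix.criteria)).to_csv(path)
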