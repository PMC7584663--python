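"""Stability statistics for strategy labels and model parameters.

Covers the analyses used to ask whether a population's mix of reciprocity
motives is stable: test-retest Pearson correlations of model parameters and
of inter-participant distances in parameter space, the Stuart-Maxwell test
of marginal homogeneity on paired strategy labels, chi-square comparisons
of strategy prevalence between samples (overall and pairwise with
Bonferroni correction), and OLS residualization of phi on theta for trait
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist

__all__ = [
    "TransitionTable",
    "StuartMaxwellResult",
    "pearson_test",
    "interparticipant_distances",
    "stuart_maxwell",
    "chi_square_independence",
    "pairwise_prevalence_tests",
    "residualize",
    "transition_table",
    "prevalence_table",
]


def pearson_test(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("pearson_test needs equal-length 1-D vectors, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def interparticipant_distances(params: Sequence[Sequence[float]]) -> np.ndarray:
    """Euclidean distances between all unordered participant pairs.

    Uses the canonical condensed ordering (pairs (0,1), (0,2), ..., (n-2,
    n-1)), so distance vectors from two blocks with participants in the same
    order are directly comparable.
    """
    arr = np.asarray(params, dtype=float)
    if arr.ndim != 2 or len(arr) < 2:
        raise ValueError("need a 2-D array with at least two participants")
    return pdist(arr, metric="euclidean")


@dataclass(frozen=True)
class TransitionTable:
    """Paired strategy counts: participants labelled i in block A, j in block B."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("transition table must be square")
        if counts.shape[0] != len(self.labels):
            raise ValueError("label order must match the table dimension")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def percent_stable(self) -> float:
        """Percentage of participants keeping their label across blocks."""
        return 100.0 * np.trace(self.counts) / self.n

    def row_percentages(self) -> np.ndarray:
        """Each cell as a percentage of its block-A (row) strategy count."""
        rows = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = 100.0 * self.counts / rows
        return np.where(rows > 0, out, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels),
                            columns=list(self.labels))


def transition_table(labels_a: Sequence[str], labels_b: Sequence[str],
                     label_order: Sequence[str]) -> TransitionTable:
    """Cross-tabulate paired labels from two blocks of the same participants."""
    labels_a = list(labels_a)
    labels_b = list(labels_b)
    if not labels_a or len(labels_a) != len(labels_b):
        raise ValueError("need nonempty, equal-length paired label vectors")
    order = list(label_order)
    index = {lab: i for i, lab in enumerate(order)}
    unknown = (set(labels_a) | set(labels_b)) - set(order)
    if unknown:
        raise ValueError(f"labels outside label_order: {sorted(unknown)}")
    counts = np.zeros((len(order), len(order)), dtype=int)
    for a, b in zip(labels_a, labels_b):
        counts[index[a], index[b]] += 1
    return TransitionTable(counts, tuple(order))


@dataclass(frozen=True)
class StuartMaxwellResult:
    statistic: float
    df: int
    pvalue: float
    used_generalized_inverse: bool = False


def stuart_maxwell(table: TransitionTable | np.ndarray) -> StuartMaxwellResult:
    """Stuart-Maxwell test of marginal homogeneity for paired categories.

    With k categories, drops the last one and tests ``d' S^-1 d`` against
    chi-square(k-1), where d holds the first k-1 row-minus-column marginal
    differences and ``S_ii = row_i + col_i - 2 n_ii``, ``S_ij = -(n_ij +
    n_ji)``.  For k=2 the statistic reduces exactly to McNemar's
    ``(b - c)^2 / (b + c)``.  A singular covariance (e.g. an unused
    category) falls back to the Moore-Penrose inverse with rank-based
    degrees of freedom, flagged in the result.
    """
    counts = table.counts if isinstance(table, TransitionTable) else np.asarray(table)
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1] or counts.shape[0] < 2:
        raise ValueError("need a square table with k >= 2 categories")
    k = counts.shape[0]
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    d = (row - col)[: k - 1]
    sub = counts[: k - 1, : k - 1]
    S = -(sub + sub.T)
    np.fill_diagonal(S, (row + col - 2 * np.diag(counts))[: k - 1])
    if np.allclose(d, 0):
        return StuartMaxwellResult(0.0, k - 1, 1.0)
    rank = np.linalg.matrix_rank(S)
    if rank < k - 1:
        stat = float(d @ np.linalg.pinv(S) @ d)
        df = int(rank)
        generalized = True
    else:
        stat = float(d @ np.linalg.solve(S, d))
        df = k - 1
        generalized = False
    p = float(sps.chi2.sf(stat, df)) if df > 0 else 1.0
    return StuartMaxwellResult(stat, df, p, generalized)


def prevalence_table(labels_by_study: dict[str, Sequence[str]],
                     label_order: Sequence[str]) -> pd.DataFrame:
    """Study x strategy count table from per-study label vectors."""
    order = list(label_order)
    rows = {}
    for study, labels in labels_by_study.items():
        series = pd.Series(list(labels))
        rows[study] = series.value_counts().reindex(order, fill_value=0)
    return pd.DataFrame(rows).T[order]


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square of independence on a counts table (no Yates).

    Returns ``(X2, df, p)`` with ``df = (r - 1)(c - 1)``.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(counts.sum(axis=1) == 0) or np.any(counts.sum(axis=0) == 0):
        raise ValueError("zero marginal: expected counts undefined")
    stat, p, df, _ = sps.chi2_contingency(counts, correction=False)
    return float(stat), int(df), float(p)


def pairwise_prevalence_tests(table: pd.DataFrame) -> pd.DataFrame:
    """2x2 prevalence chi-squares for every pair of strategies.

    ``table`` is a 2-study x k-strategy count table.  Each of the C(k, 2)
    sub-tables is tested for independence; Bonferroni correction multiplies
    p by the number of pairs (capped at 1).  Pairs whose sub-table has a
    zero marginal are flagged as degenerate and skipped.
    """
    counts = pd.DataFrame(table)
    if counts.shape[0] != 2 or counts.shape[1] < 2:
        raise ValueError("need a 2-study x k-strategy table, k >= 2")
    pairs = list(combinations(counts.columns, 2))
    rows = []
    for a, b in pairs:
        sub = counts[[a, b]].to_numpy(dtype=float)
        degenerate = np.any(sub.sum(axis=0) == 0) or np.any(sub.sum(axis=1) == 0)
        if degenerate:
            rows.append((a, b, np.nan, np.nan, np.nan, True))
            continue
        stat, _, p = chi_square_independence(sub)
        rows.append((a, b, stat, p, min(1.0, p * len(pairs)), False))
    return pd.DataFrame(
        rows,
        columns=["strategy_a", "strategy_b", "chi2", "p_uncorrected",
                 "p_bonferroni", "degenerate"],
    )


def residualize(y, x) -> np.ndarray:
    """Residuals of the OLS regression of y on (intercept, x).

    The output is mean-zero and orthogonal to x to machine precision.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1 or len(y) < 3:
        raise ValueError("residualize needs equal-length 1-D vectors, n >= 3")
    if np.std(x) == 0:
        raise ValueError("regressor is constant; slope undefined")
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef
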