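"""Frequency comparisons of segmentation and grading outcomes.

Segmentation counts across acquisition groups are compared with the
Pearson chi-square test (R x C, no continuity correction) and pairs of
groups with the two-sided Fisher exact test.  The two-sided Fisher
convention is the point-probability rule: sum the hypergeometric
probabilities of every table (margins fixed) whose probability does not
exceed the observed table's.  Significance is reported at the 5% level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


class ShapeError(ValueError):
    pass


class DegenerateTableError(ValueError):
    pass


class PairingError(ValueError):
    pass


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
            raise ShapeError(f"need an RxC table with R,C >= 2, got shape {c.shape}")
        if (c < 0).any() or not np.allclose(c, np.round(c)):
            raise ValueError("counts must be non-negative integers")
        self.counts = c.astype(np.int64)
        if not self.row_labels:
            self.row_labels = [f"row{i}" for i in range(c.shape[0])]
        if not self.col_labels:
            self.col_labels = [f"col{j}" for j in range(c.shape[1])]

    @classmethod
    def from_csv(cls, path) -> "ContingencyTable":
        df = pd.read_csv(path, index_col=0)
        return cls(counts=df.to_numpy(), row_labels=list(df.index.astype(str)),
                   col_labels=list(df.columns.astype(str)))


def fisher_exact_2x2(table: ContingencyTable | np.ndarray) -> float:
    """Two-sided Fisher exact p-value of a 2x2 table."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if counts.shape != (2, 2):
        raise ShapeError(f"Fisher exact needs a 2x2 table, got {counts.shape}")
    return float(sps.fisher_exact(counts, alternative="two-sided").pvalue)


def fisher_null_distribution(table: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All feasible 2x2 tables' first cells and their hypergeometric mass.

    Convenience for auditing the exact test: with the margins of
    ``table`` fixed, returns (values of the top-left cell, probability of
    each corresponding table).  The masses sum to 1.
    """
    t = np.asarray(table, dtype=np.int64)
    r1, r2 = t.sum(axis=1)
    c1 = t[:, 0].sum()
    n = t.sum()
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(ks, n, r1, c1)
    return ks, pmf


def chi_square_test(table: ContingencyTable | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on an RxC table: (statistic, df, p-value)."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    rowsum = counts.sum(axis=1, keepdims=True)
    colsum = counts.sum(axis=0, keepdims=True)
    expected = rowsum * colsum / counts.sum()
    if (expected <= 0).any():
        raise DegenerateTableError("every expected count must be > 0")
    res = sps.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def agreement_rate(predictions: Sequence, reference: Sequence) -> tuple[float, int, int]:
    """Exact-match agreement as (proportion, n_matches, n_total)."""
    predictions = list(predictions)
    reference = list(reference)
    if len(predictions) != len(reference):
        raise PairingError(
            f"length mismatch: {len(predictions)} predictions vs {len(reference)} references")
    if not predictions:
        return 0.0, 0, 0
    matches = sum(int(p == r) for p, r in zip(predictions, reference))
    return matches / len(predictions), matches, len(predictions)


def test_result_json(method: str, statistic: float | None, df: int | None,
                     p_value: float) -> str:
    return json.dumps({
        "method": method, "statistic": statistic, "df": df,
        "p_value": p_value, "significant_at_5pct": bool(p_value < ALPHA),
    })
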