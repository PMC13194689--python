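"""Exact and classical statistics used across the pipeline.

The workhorse test is the two-sided Fisher's exact test on 2x2 contingency
tables of division-phenotype counts (e.g. preprophase-band category vs rest,
by genotype), with Bonferroni control over the family of category tests.
Chi-square independence, Welch's t and the Wilcoxon rank-sum test cover the
remaining comparisons.

Two-sided Fisher p-values follow the sum-of-small-probabilities convention:
the p-value sums hypergeometric probabilities of all tables with the observed
margins whose probability does not exceed that of the observed table, up to a
relative tolerance of 1e-7 (the convention of mainstream implementations).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _ss

__all__ = [
    "ContingencyTable",
    "TestResult",
    "DegenerateInputError",
    "fisher_exact_two_sided",
    "bonferroni",
    "chi_square_independence",
    "welch_t_two_sided",
    "wilcoxon_rank_sum",
]

#: smallest p-value ever reported; exact zeros are floored here
P_FLOOR = 1e-300


class DegenerateInputError(ValueError):
    """Raised when an input is syntactically valid but statistically empty."""


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c table of non-negative integer counts with labelled margins."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        if not self.row_labels:
            object.__setattr__(
                self, "row_labels", tuple(f"row{i}" for i in range(counts.shape[0]))
            )
        if not self.col_labels:
            object.__setattr__(
                self, "col_labels", tuple(f"col{j}" for j in range(counts.shape[1]))
            )
        if len(self.row_labels) != counts.shape[0] or len(self.col_labels) != counts.shape[1]:
            raise ValueError("label lengths must match table shape")

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_csv(cls, path) -> "ContingencyTable":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(
            df.to_numpy(),
            row_labels=tuple(str(r) for r in df.index),
            col_labels=tuple(str(c) for c in df.columns),
        )

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.counts, index=list(self.row_labels), columns=list(self.col_labels)
        ).to_csv(path)


@dataclass
class TestResult:
    """Outcome of a hypothesis test, JSON-serialisable."""

    method: str
    p_value: float
    statistic: float | None = None
    df: float | None = None
    threshold: float | None = None  # per-test alpha when Bonferroni applied
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")

    def to_json(self) -> str:
        rec = {"method": self.method, "statistic": self.statistic,
               "p_value": self.p_value, "df": self.df}
        if self.threshold is not None:
            rec["threshold"] = self.threshold
        rec.update(self.extra)
        return json.dumps(rec, sort_keys=True)


def _clip_p(p: float) -> float:
    return float(min(1.0, max(P_FLOOR, p)))


def _as_2x2(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        counts = table.counts
    else:
        counts = np.asarray(table)
        if counts.ndim != 2:
            raise ValueError("expected a 2x2 table")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
    if counts.shape != (2, 2):
        raise ValueError("Fisher's exact test requires a 2x2 table")
    return counts


def fisher_exact_two_sided(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The p-value is the total hypergeometric probability of all tables sharing
    the observed margins that are no more probable than the observed table
    (within relative tolerance 1e-7).
    """
    counts = _as_2x2(table)
    if counts.sum() == 0:
        raise DegenerateInputError("all-zero contingency table")
    odds, p = _ss.fisher_exact(counts, alternative="two-sided")
    return TestResult(
        method="fisher_exact_two_sided",
        p_value=_clip_p(p),
        statistic=float(odds) if np.isfinite(odds) else None,
    )


def bonferroni(p_values, alpha: float = 0.05) -> list[tuple[float, bool]]:
    """Bonferroni adjustment: adjusted_p = min(1, m*p); significant iff p < alpha/m."""
    p_values = list(p_values)
    if not p_values:
        raise ValueError("empty p-value list")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    m = len(p_values)
    out = []
    for p in p_values:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-value {p} outside (0, 1]")
        out.append((min(1.0, m * p), p < alpha / m))
    return out


def chi_square_independence(table) -> TestResult:
    """Pearson chi-square test of independence with (r-1)(c-1) df, no continuity correction."""
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    counts = table.counts
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise DegenerateInputError("zero margin gives zero expected counts")
    stat, p, dof, _ = _ss.chi2_contingency(counts, correction=False)
    return TestResult(
        method="chi_square_independence",
        p_value=_clip_p(p),
        statistic=float(stat),
        df=float(dof),
    )


def welch_t_two_sided(a, b) -> TestResult:
    """Welch's unequal-variance two-sample t-test (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch's t-test needs at least 2 values per group")
    if np.var(a) == 0 and np.var(b) == 0:
        # no within-group variability: equal means are indistinguishable
        if np.mean(a) == np.mean(b):
            return TestResult(method="welch_t_two_sided", p_value=1.0, statistic=0.0)
        raise DegenerateInputError("zero variance in both groups with unequal means")
    res = _ss.ttest_ind(a, b, equal_var=False)
    return TestResult(
        method="welch_t_two_sided",
        p_value=_clip_p(res.pvalue),
        statistic=float(res.statistic),
        df=float(res.df),
    )


# exact enumeration is tractable and tie-free convention is unambiguous
_WILCOXON_EXACT_MAX_N = 25


def wilcoxon_rank_sum(a, b) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test, two-sided, midranks for ties.

    Exact null enumeration when both groups have <= 25 observations and no
    ties are present; otherwise the normal approximation with tie-corrected
    variance and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least one value")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.unique(pooled).size == 1:
        # every observation identical: no evidence either way
        return TestResult(method="wilcoxon_rank_sum", p_value=1.0, statistic=float(a.size * b.size / 2))
    exact = (not has_ties) and a.size <= _WILCOXON_EXACT_MAX_N and b.size <= _WILCOXON_EXACT_MAX_N
    res = _ss.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        method="wilcoxon_rank_sum",
        p_value=_clip_p(res.pvalue),
        statistic=float(res.statistic),
        extra={"engine": "exact" if exact else "normal_approximation"},
    )
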