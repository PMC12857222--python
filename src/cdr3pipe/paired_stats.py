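"""Exact paired Wilcoxon signed-rank tests and mean +/- SEM summaries.

The exact two-sided p-value is computed by full enumeration of the
2^n sign assignments over the observed absolute-difference ranks
(midranks for ties, zeros dropped), as

    p = P(|W - E[W]| >= |w_plus - E[W]|)

which for tie-free data equals the classical tail-doubling construction.
Sample sizes here are small (planned longitudinal contrasts over at most
a handful of subjects), so enumeration is instantaneous.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

#: Planned timepoint contrasts, as (day A, day B) pairs.
DEFAULT_CONTRASTS = ((0, 2), (0, 42), (42, 56), (56, 90), (90, 285), (0, 285))

SIGNIFICANCE_LEVEL = 0.05
TENDENCY_LEVEL = 0.10

_MAX_EXACT_N = 30  # 2^30 sign vectors still enumerable through the rank-sum DP


@dataclass(frozen=True)
class PairedSample:
    """Aligned measurements for the same subjects at two timepoints."""

    subject_ids: tuple[str, ...]
    values_a: tuple[float, ...]
    values_b: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.subject_ids) == len(self.values_a) == len(self.values_b)):
            raise ValueError("subject_ids, values_a and values_b must have equal length")
        if len(self.subject_ids) == 0:
            raise ValueError("at least one pair is required")

    @classmethod
    def from_arrays(
        cls,
        values_a: Sequence[float],
        values_b: Sequence[float],
        subject_ids: Sequence[str] | None = None,
    ) -> "PairedSample":
        if subject_ids is None:
            subject_ids = [f"s{i}" for i in range(len(values_a))]
        return cls(tuple(subject_ids), tuple(values_a), tuple(values_b))


@dataclass(frozen=True)
class ComparisonResult:
    label: str
    n_effective: int
    w_plus: float
    p_two_sided: float
    direction: int  # sign of the median nonzero difference

    @property
    def significant(self) -> bool:
        return self.p_two_sided <= SIGNIFICANCE_LEVEL

    @property
    def tendency(self) -> bool:
        return SIGNIFICANCE_LEVEL < self.p_two_sided < TENDENCY_LEVEL

    @property
    def flag(self) -> str:
        if self.significant:
            return "significant"
        if self.tendency:
            return "tendency"
        return ""


def _rank_sum_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Counts of subset sums of the (doubled, integer) ranks.

    Equivalent to enumerating all 2^n sign vectors; counts fit exactly in
    float64 for the sample sizes accepted here.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def signed_rank_exact(pairs: PairedSample, label: str = "") -> ComparisonResult:
    """Exact two-sided paired Wilcoxon signed-rank test.

    Differences are ``b - a``; zero differences are dropped before ranking;
    ties receive midranks.  With no nonzero differences, p = 1.
    """
    a = np.asarray(pairs.values_a, dtype=float)
    b = np.asarray(pairs.values_b, dtype=float)
    d = b - a
    d = d[d != 0]
    n = d.size
    if n == 0:
        return ComparisonResult(label=label, n_effective=0, w_plus=0.0,
                                p_two_sided=1.0, direction=0)
    if n > _MAX_EXACT_N:
        raise ValueError(f"exact enumeration limited to n <= {_MAX_EXACT_N} pairs")

    ranks = rankdata(np.abs(d))  # midranks for ties
    w_plus = float(ranks[d > 0].sum())
    ranks2 = np.round(2 * ranks).astype(np.int64)
    counts = _rank_sum_distribution(ranks2)
    total = int(ranks2.sum())
    w2 = int(round(2 * w_plus))
    sums = np.arange(total + 1)
    # |W - E[W]| on the doubled scale: |2W - total| vs |2w_plus - total|
    deviation = abs(2 * w2 - total)
    tail = counts[np.abs(2 * sums - total) >= deviation].sum()
    p = float(tail / counts.sum())
    direction = int(np.sign(np.median(d)))
    return ComparisonResult(
        label=label, n_effective=n, w_plus=w_plus, p_two_sided=p, direction=direction
    )


def planned_comparisons(
    data: pd.DataFrame,
    contrasts: Iterable[tuple[int, int]] = DEFAULT_CONTRASTS,
    value_column: str = "value",
    min_pairs: int = 2,
) -> list[ComparisonResult]:
    """Run the planned signed-rank contrasts on long-format data.

    ``data`` needs columns ``subject``, ``timepoint`` and ``value_column``.
    Subjects missing either timepoint of a contrast are excluded pairwise.
    Contrasts with fewer than ``min_pairs`` complete pairs are skipped with
    a warning.  Unknown timepoints raise ``ValueError``.
    """
    wide = data.pivot_table(
        index="subject", columns="timepoint", values=value_column, aggfunc="first"
    )
    known = set(wide.columns)
    results: list[ComparisonResult] = []
    for t_a, t_b in contrasts:
        if t_a not in known or t_b not in known:
            raise ValueError(f"unknown timepoint in contrast ({t_a}, {t_b})")
        sub = wide[[t_a, t_b]].dropna()
        label = f"day {t_a} vs day {t_b}"
        if len(sub) < min_pairs:
            warnings.warn(f"contrast {label!r} skipped: only {len(sub)} complete pair(s)")
            continue
        pairs = PairedSample.from_arrays(
            sub[t_a].tolist(), sub[t_b].tolist(), [str(s) for s in sub.index]
        )
        results.append(signed_rank_exact(pairs, label=label))
    return results


@dataclass(frozen=True)
class SummaryRow:
    timepoint: object
    mean: float
    sem: float | None
    n: int


def mean_sem(values: Sequence[float], timepoint: object = None) -> SummaryRow:
    """Arithmetic mean and standard error (sample sd over sqrt(n)).

    SEM is None for a single observation.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("mean_sem requires at least one value")
    mean = float(v.mean())
    sem = None if v.size == 1 else float(v.std(ddof=1) / math.sqrt(v.size))
    return SummaryRow(timepoint=timepoint, mean=mean, sem=sem, n=int(v.size))


def format_p(p: float) -> str:
    """Two-decimal presentation used in report tables."""
    return f"{p:.2f}"


def format_mean_sem(row: SummaryRow, decimals: int = 2) -> str:
    if row.sem is None:
        return f"{row.mean:.{decimals}f} (NA)"
    return f"{row.mean:.{decimals}f} ({row.sem:.{decimals}f})"
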