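"""Class-stratified descriptor distributions and two-sample tests.

Distributions are summarised as binned percentage matrices: one row per
selectivity class, one column per bin, cells holding the percentage of that
class's compounds falling in the bin (rows sum to 100).  Bins are half-open
``(lo, hi]`` and labeled by their upper bound — a bin labeled "350" holds
values in (300, 350] — with an underflow bin at the low end and an
overflow ``">hi"`` bin at the high end.

Class pairs are compared with the two-sided Wilcoxon rank-sum
(Mann–Whitney U) test and the two-sample Kolmogorov–Smirnov test.  No
multiple-testing correction is applied; the result table carries the sample
sizes needed to apply one downstream.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinningScheme:
    """Half-open ``(lo, hi]`` bins labeled by upper bound, with tail bins.

    ``edges`` are the interior boundaries: the first bin is
    ``(-inf, edges[0]]`` labeled ``edges[0]``, subsequent bins are
    ``(edges[i-1], edges[i]]`` labeled ``edges[i]``, and values above
    ``edges[-1]`` land in an overflow bin labeled ``">edges[-1]"``.
    """

    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.edges) < 1:
            raise ValueError("need at least one bin edge")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def labels(self) -> list[str]:
        def fmt(e: float) -> str:
            return str(int(e)) if float(e).is_integer() else str(e)

        return [fmt(e) for e in self.edges] + [f">{fmt(self.edges[-1])}"]

    def bin_index(self, value: float) -> int:
        """Index of the bin holding ``value`` (NaN is the caller's problem)."""
        for i, edge in enumerate(self.edges):
            if value <= edge:
                return i
        return len(self.edges)

    @classmethod
    def from_range(cls, lo: float, hi: float, width: float) -> "BinningScheme":
        n = int(round((hi - lo) / width))
        return cls(tuple(lo + width * (i + 1) for i in range(n)))

    @classmethod
    def integer_counts(cls, max_value: int) -> "BinningScheme":
        """Bins at 0, 1, ..., max_value plus an overflow ``">max_value"``."""
        return cls(tuple(float(i) for i in range(max_value + 1)))


#: Bin schemes mirroring the figures the analysis reproduces: 50-Da MW bins,
#: unit-width logS/SlogP bins, integer bins with a ">4" overflow for counts.
DEFAULT_SCHEMES: dict[str, BinningScheme] = {
    "mw50": BinningScheme.from_range(100.0, 700.0, 50.0),
    "logs_unit": BinningScheme.from_range(-10.0, 0.0, 1.0),
    "logp_unit": BinningScheme.from_range(-4.0, 10.0, 1.0),
    "counts": BinningScheme.integer_counts(4),
}


def percentage_matrix(
    values_by_class: Mapping[str, Sequence[float]],
    scheme: BinningScheme,
) -> pd.DataFrame:
    """Binned percentage matrix, one row per class.

    Percentages are ``100 * count_in_bin / class_size``; null values are
    excluded from both numerator and denominator (with a logged count); an
    empty class yields a row of NaN and a warning.
    """
    labels = scheme.labels
    rows = {}
    for cls, values in values_by_class.items():
        arr = np.asarray(
            [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))],
            dtype=float,
        )
        n_null = len(values) - arr.size
        if n_null:
            logger.info("class %s: %d null values excluded", cls, n_null)
        if arr.size == 0:
            logger.warning("class %s is empty; emitting null row", cls)
            rows[cls] = [np.nan] * len(labels)
            continue
        counts = np.zeros(len(labels))
        for v in arr:
            counts[scheme.bin_index(v)] += 1
        rows[cls] = 100.0 * counts / arr.size
    return pd.DataFrame.from_dict(rows, orient="index", columns=labels)


@dataclass(frozen=True)
class TestResult:
    method: str  # "wilcoxon_rank_sum" | "ks_two_sample"
    statistic: float
    p_value: float
    n1: int
    n2: int
    note: str = ""


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 12
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    The exact null distribution is used when the combined sample size is at
    most ``exact_max_n`` and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.  Ties force the
    approximate path even at small n (noted in the result).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    small = x.size + y.size <= exact_max_n
    if small and not has_ties:
        method, note = "exact", ""
    else:
        method = "asymptotic"
        note = "ties forced asymptotic path" if small and has_ties else ""
        if note:
            logger.info("wilcoxon_rank_sum: %s (n1=%d, n2=%d)", note, x.size, y.size)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return TestResult(
        "wilcoxon_rank_sum",
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        x.size,
        y.size,
        note or method,
    )


def ks_two_sample(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 12
) -> TestResult:
    """Two-sample Kolmogorov–Smirnov test.

    The statistic is ``D = sup |ECDF_x - ECDF_y|``; the two-sided p-value is
    exact for combined sample sizes up to ``exact_max_n`` and otherwise from
    the asymptotic Kolmogorov distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if x.size + y.size <= exact_max_n else "asymp"
    res = stats.ks_2samp(x, y, alternative="two-sided", method=method)
    return TestResult(
        "ks_two_sample",
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        x.size,
        y.size,
        method,
    )


_METHODS = {"wilcoxon_rank_sum": wilcoxon_rank_sum, "ks_two_sample": ks_two_sample}


def pairwise_class_tests(
    values_by_class: Mapping[str, Sequence[float]],
    method: str = "wilcoxon_rank_sum",
    pooled: bool = False,
) -> pd.DataFrame:
    """Run a two-sample test between classes for one descriptor.

    With ``pooled=False`` (default) every unordered pair of classes is
    tested; with ``pooled=True`` each class is tested against the pooled
    remainder.  Per-pair failures are recorded in the ``error`` column, not
    raised.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}")
    if len(values_by_class) < 2:
        raise ValueError("need at least two classes")
    test = _METHODS[method]

    clean = {
        cls: [v for v in vals if v is not None and not (isinstance(v, float) and math.isnan(v))]
        for cls, vals in values_by_class.items()
    }

    if pooled:
        pairs = [
            (cls, "rest", clean[cls], list(itertools.chain.from_iterable(
                v for c, v in clean.items() if c != cls)))
            for cls in clean
        ]
    else:
        pairs = [
            (a, b, clean[a], clean[b])
            for a, b in itertools.combinations(clean, 2)
        ]

    rows = []
    for name1, name2, v1, v2 in pairs:
        row = {"class1": name1, "class2": name2, "method": method,
               "n1": len(v1), "n2": len(v2)}
        try:
            res = test(v1, v2)
            row.update(statistic=res.statistic, p_value=res.p_value, error="")
        except Exception as exc:
            row.update(statistic=np.nan, p_value=np.nan, error=str(exc))
            logger.warning("test %s vs %s failed: %s", name1, name2, exc)
        rows.append(row)
    return pd.DataFrame(rows)
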