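"""Count-table statistics: low-count filtering (arbitrary cutoff or
percentile of the count distribution) and correction-factor fold-change.

Low read counts often carry no real biological signal — they can arise
from sequencing errors or cross-mapping — and they produce unstable
fold-changes (10 vs 5 reads is "2-fold" but hardly meaningful).  Two
remedies are provided: filtering features below a cutoff, and an additive
correction factor k (by default the median of the nonzero read-count
distribution of the samples being compared) applied to both counts before
forming the ratio, which damps low-count fold-changes while leaving
well-expressed features essentially untouched: with k = 30,
(10+30)/(5+30) = 1.14 instead of 2.0, while (4000+30)/(2000+30) = 1.99.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .core_io import CountTable


@dataclass
class FilterParams:
    """Either an arbitrary minimum count or a percentile-derived cutoff."""

    min_count: int | None = None
    percentile: float | None = None

    def __post_init__(self) -> None:
        if self.min_count is None and self.percentile is None:
            raise ValueError("set min_count and/or percentile")
        if self.min_count is not None and self.min_count < 0:
            raise ValueError("min_count must be >= 0")
        if self.percentile is not None and not 0 <= self.percentile <= 100:
            raise ValueError("percentile must be in [0, 100]")


@dataclass
class CorrectionFactor:
    k: float
    source: str = "auto_median"  # or "user"

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("correction factor must be >= 0")


def min_count_filter(table: CountTable, min_count: int) -> CountTable:
    """Drop feature rows that are below the cutoff in every sample.

    The cutoff is inclusive: a feature counts as expressed in a sample iff
    its count there is >= min_count.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    keep = np.any(table.counts >= min_count, axis=1)
    return CountTable(
        features=[f for f, k in zip(table.features, keep) if k],
        samples=list(table.samples),
        counts=table.counts[keep],
    )


def percentile_cutoff(counts: np.ndarray, q: float, include_zeros: bool = False) -> float:
    """Nearest-rank percentile of a sample's count distribution.

    By default zeros are excluded: a feature absent from a sample is "not
    detected" rather than "count 0", so it should not drag the cutoff down.
    Filtering keeps counts >= the returned cutoff.
    """
    counts = np.asarray(counts, dtype=float)
    if not include_zeros:
        counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("no (nonzero) counts to take a percentile of")
    if not 0 <= q <= 100:
        raise ValueError("percentile must be in [0, 100]")
    ordered = np.sort(counts)
    rank = max(1, ceil(q / 100 * ordered.size))  # nearest-rank; q=0 -> minimum
    return float(ordered[rank - 1])


def percentile_filter(table: CountTable, q: float, include_zeros: bool = False) -> CountTable:
    """Per-sample percentile filtering: a feature is expressed in a sample
    iff its count reaches that sample's percentile cutoff; rows expressed
    nowhere are dropped."""
    cutoffs = np.array(
        [percentile_cutoff(table.counts[:, j], q, include_zeros) for j in range(len(table.samples))]
    )
    keep = np.any(table.counts >= cutoffs, axis=1)
    return CountTable(
        features=[f for f, k in zip(table.features, keep) if k],
        samples=list(table.samples),
        counts=table.counts[keep],
    )


def correction_factor(table: CountTable, include_zeros: bool = False) -> CorrectionFactor:
    """Median of the read-count distribution pooled over the table's samples.

    Zeros are excluded by default (absent features are not observations of
    zero); with an even number of values the mean of the two middle values
    is used.
    """
    vals = table.counts.ravel()
    if not include_zeros:
        vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError("cannot compute correction factor of an empty table")
    return CorrectionFactor(k=float(np.median(vals)), source="auto_median")


def corrected_fold_change(test: float, control: float, k: float = 0.0) -> float:
    """Signed fold-change of test vs control with additive correction k.

    The ratio r = (test+k)/(control+k) is reported as r when r >= 1 and as
    -1/r otherwise, so a symmetric threshold reads |FC| >= t. Rounding to
    two decimals is left to the reporting layer.
    """
    if test < 0 or control < 0 or k < 0:
        raise ValueError("counts and correction factor must be >= 0")
    if control + k == 0:
        raise ZeroDivisionError("fold-change undefined: control + k == 0")
    r = (test + k) / (control + k)
    if r == 0:
        return float("-inf")
    return r if r >= 1 else -1.0 / r
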