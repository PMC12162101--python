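"""Run-level QC: conversion efficiency from CHH context, assembly Nx
statistics, and read-subsampling coverage curves."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .capture import base_coverage
from .io import CytosineRecord, GenomicInterval
from .matrix import CountMatrix

__all__ = [
    "ConversionEstimate",
    "NxResult",
    "conversion_estimate",
    "chh_totals",
    "nx_stat",
    "thin_counts",
    "thin_fragments",
    "coverage_curve",
]


@dataclass
class ConversionEstimate:
    """Percent CHH methylation: a proxy for failed conversion of
    unmethylated cytosines. Mammalian CHH is essentially unmethylated, so
    anything observed is (mostly) conversion error. Status thresholds
    follow the common guide lines: <1% pass, 1-5% warn, >=5% fail."""

    percent_chh: float
    status: str

    @property
    def conversion_rate(self) -> float:
        return 1.0 - self.percent_chh / 100.0


def conversion_estimate(
    chh_m: int, chh_total: int, warn_at: float = 1.0, fail_at: float = 5.0
) -> ConversionEstimate:
    if chh_total <= 0:
        raise ValueError("chh_total must be > 0")
    if not 0 <= chh_m <= chh_total:
        raise ValueError("need 0 <= chh_m <= chh_total")
    pct = 100.0 * chh_m / chh_total
    status = "pass" if pct < warn_at else ("warn" if pct < fail_at else "fail")
    return ConversionEstimate(pct, status)


def chh_totals(records: Iterable[CytosineRecord]) -> tuple[int, int]:
    """(methylated CHH reads, total CHH reads) over a cytosine report."""
    m = tot = 0
    for r in records:
        if r.context == "CHH":
            m += r.M
            tot += r.M + r.U
    return m, tot


@dataclass
class NxResult:
    x: float
    value: int


def nx_stat(lengths: Sequence[int], x: float) -> NxResult:
    """Assembly Nx: sort lengths descending; the first length at which
    the cumulative sum reaches >= x of the total. N50 is x=0.5."""
    lengths = np.asarray(lengths, dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("empty length set")
    if not 0.0 < x < 1.0:
        raise ValueError("x must be in (0, 1)")
    if (lengths <= 0).any():
        raise ValueError("lengths must be positive")
    desc = np.sort(lengths)[::-1]
    csum = np.cumsum(desc)
    idx = int(np.searchsorted(csum, x * csum[-1]))
    return NxResult(x, int(desc[idx]))


def thin_counts(matrix: CountMatrix, fraction: float, seed: int = 0) -> CountMatrix:
    """Random read-level subsampling of a count matrix.

    Each cell's retained coverage is Binomial(c, f); the methylated
    share of the retained reads is hypergeometric, so thinned matrices
    stay valid integer count matrices with E[coverage] = f * c.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    c = matrix.coverage
    c_new = rng.binomial(c, fraction)
    m_new = np.zeros_like(c_new)
    ok = c_new > 0
    m_new[ok] = rng.hypergeometric(matrix.M[ok], matrix.U[ok], c_new[ok])
    return CountMatrix(list(matrix.sites), list(matrix.samples), m_new, c_new - m_new, matrix.meta)


def thin_fragments(
    fragments: Sequence[GenomicInterval], fraction: float, seed: int = 0
) -> list[GenomicInterval]:
    """Keep each fragment independently with probability ``fraction``."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    keep = rng.random(len(fragments)) < fraction
    return [f for f, k in zip(fragments, keep) if k]


def coverage_curve(
    fragments: Sequence[GenomicInterval],
    target: Sequence[GenomicInterval],
    fractions: Sequence[float] = (0.25, 0.5, 0.75, 1.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, float, float]:
    """Mean/median target depth after thinning to each fraction, plus the
    fitted line (slope, intercept) of mean depth against fraction —
    linear through ~0 when subsampling behaves."""
    if not target:
        raise ValueError("empty target")
    rows = []
    for i, f in enumerate(fractions):
        sub = list(fragments) if f >= 1.0 else thin_fragments(fragments, f, seed=seed + i)
        mean_d, med_d = base_coverage(sub, target)
        rows.append({"fraction": f, "mean_depth": mean_d, "median_depth": med_d})
    df = pd.DataFrame(rows)
    slope, intercept = np.polyfit(df["fraction"], df["mean_depth"], deg=1)
    return df, float(slope), float(intercept)
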