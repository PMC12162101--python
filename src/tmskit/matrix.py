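"""Multi-sample methylation count matrices and the study-style filters.

The central object is :class:`CountMatrix`: sites x samples matrices of
methylated (M) and unmethylated (U) read counts with per-sample metadata
(group, tissue, technology), assembled from per-sample strand-collapsed
cytosine reports by union of sites. Filtering follows the common
coverage/missingness rule "covered at >=min_cov in >=min_frac of
samples", optionally restricted to a capture target, with both
comparators explicitly configurable (inclusive by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import capture
from .io import CpGSite, GenomicInterval

__all__ = [
    "CountMatrix",
    "FilterSpec",
    "MethLevels",
    "assemble_matrix",
    "filter_matrix",
    "methylation_levels",
    "site_summary",
    "annotation_summary",
    "promoters_from_tss",
]

_CMP = {"ge": np.greater_equal, "gt": np.greater}


@dataclass
class CountMatrix:
    """Sites x samples methylated/unmethylated count matrices."""

    sites: list[CpGSite]
    samples: list[str]
    M: np.ndarray
    U: np.ndarray
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.int64)
        self.U = np.asarray(self.U, dtype=np.int64)
        shape = (len(self.sites), len(self.samples))
        if self.M.shape != shape or self.U.shape != shape:
            raise ValueError(f"count matrices must be {shape}")
        if (self.M < 0).any() or (self.U < 0).any():
            raise ValueError("negative counts")
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("duplicate sites")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")

    @property
    def coverage(self) -> np.ndarray:
        return self.M + self.U

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.sites), len(self.samples)

    def subset_sites(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return CountMatrix(
            sites=[self.sites[i] for i in idx],
            samples=list(self.samples),
            M=self.M[idx],
            U=self.U[idx],
            meta=self.meta,
        )

    def subset_samples(self, names: Sequence[str]) -> "CountMatrix":
        idx = [self.samples.index(n) for n in names]
        meta = self.meta.loc[list(names)] if self.meta is not None else None
        return CountMatrix(list(self.sites), list(names), self.M[:, idx], self.U[:, idx], meta)

    def to_tsv(self, m_path: str | Path, u_path: str | Path) -> None:
        index = pd.MultiIndex.from_tuples(
            [(s.chrom, s.pos0) for s in self.sites], names=["chrom", "pos0"]
        )
        pd.DataFrame(self.M, index=index, columns=self.samples).to_csv(m_path, sep="\t")
        pd.DataFrame(self.U, index=index, columns=self.samples).to_csv(u_path, sep="\t")

    @classmethod
    def from_tsv(
        cls, m_path: str | Path, u_path: str | Path, meta: pd.DataFrame | None = None
    ) -> "CountMatrix":
        m = pd.read_csv(m_path, sep="\t", index_col=[0, 1])
        u = pd.read_csv(u_path, sep="\t", index_col=[0, 1])
        if not m.index.equals(u.index) or list(m.columns) != list(u.columns):
            raise ValueError("M and U tables disagree on sites or samples")
        sites = [CpGSite(str(c), int(p)) for c, p in m.index]
        return cls(sites, list(m.columns), m.to_numpy(), u.to_numpy(), meta)


@dataclass
class FilterSpec:
    """Coverage/missingness filter: keep a site iff the fraction of samples
    with coverage `cov_cmp` min_cov satisfies `frac_cmp` min_frac, and the
    site lies within `tol` bp of the target (when a target is given)."""

    min_cov: int = 5
    min_frac: float = 0.75
    cov_cmp: str = "ge"
    frac_cmp: str = "ge"
    target: list[GenomicInterval] | None = None
    tol: int = 0

    def __post_init__(self) -> None:
        if self.min_cov < 0 or not (0.0 <= self.min_frac <= 1.0):
            raise ValueError("min_cov must be >=0 and min_frac in [0,1]")
        if self.cov_cmp not in _CMP or self.frac_cmp not in _CMP:
            raise ValueError("comparators must be 'ge' or 'gt'")


@dataclass
class MethLevels:
    """Per-cell methylation proportions M/(M+U), NaN where coverage is 0."""

    sites: list[CpGSite]
    samples: list[str]
    m: np.ndarray  # float, NaN = unobserved


def assemble_matrix(
    reports: Mapping[str, Mapping[CpGSite, tuple[int, int]]],
    sheet: pd.DataFrame | None = None,
) -> CountMatrix:
    """Union-of-sites assembly; cells absent from a sample's report get
    (0, 0), so downstream missingness filtering is meaningful."""
    samples = list(reports)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample IDs")
    if sheet is not None:
        missing = [s for s in samples if s not in sheet.index]
        if missing:
            raise ValueError(f"samples absent from sheet: {missing}")
        sheet = sheet.loc[samples]
    sites = sorted({site for rep in reports.values() for site in rep})
    index = {s: i for i, s in enumerate(sites)}
    M = np.zeros((len(sites), len(samples)), dtype=np.int64)
    U = np.zeros_like(M)
    for j, name in enumerate(samples):
        for site, (m, u) in reports[name].items():
            M[index[site], j] = m
            U[index[site], j] = u
    return CountMatrix(sites, samples, M, U, meta=sheet)


def filter_matrix(matrix: CountMatrix, spec: FilterSpec) -> tuple[CountMatrix, dict]:
    """Apply target and coverage/missingness filters; returns the filtered
    matrix (site order preserved) and a report of drops per rule."""
    n_sites, n_samples = matrix.shape
    keep = np.ones(n_sites, dtype=bool)
    report = {"n_input": n_sites, "dropped_off_target": 0, "dropped_coverage": 0}
    if spec.target is not None:
        on, _ = capture.proximity_mask(matrix.sites, spec.target, tol=spec.tol)
        report["dropped_off_target"] = int((~on).sum())
        keep &= on
    if n_samples > 0:
        covered = _CMP[spec.cov_cmp](matrix.coverage, spec.min_cov)
        frac = covered.sum(axis=1) / n_samples
        cov_ok = _CMP[spec.frac_cmp](frac, spec.min_frac)
    else:
        cov_ok = np.zeros(n_sites, dtype=bool)
    report["dropped_coverage"] = int((keep & ~cov_ok).sum())
    keep &= cov_ok
    report["n_kept"] = int(keep.sum())
    return matrix.subset_sites(keep), report


def methylation_levels(matrix: CountMatrix) -> MethLevels:
    c = matrix.coverage
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(c > 0, matrix.M / np.maximum(c, 1), np.nan)
    return MethLevels(list(matrix.sites), list(matrix.samples), m)


def site_summary(levels: MethLevels, lo: float = 0.1, hi: float = 0.9) -> pd.DataFrame:
    """Per-site mean/median methylation over observed cells, with the
    variable (strictly between lo and hi) and hypo/hyper (<0.5 / >0.5
    mean) flags used for subset analyses."""
    if not lo < hi:
        raise ValueError("lo must be < hi")
    m = levels.m
    n_obs = np.sum(~np.isnan(m), axis=1)
    obs = n_obs > 0
    mean = np.full(len(levels.sites), np.nan)
    median = np.full(len(levels.sites), np.nan)
    if obs.any():
        mean[obs] = np.nanmean(m[obs], axis=1)
        median[obs] = np.nanmedian(m[obs], axis=1)
    variable = obs & (mean > lo) & (mean < hi)
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in levels.sites],
            "pos0": [s.pos0 for s in levels.sites],
            "mean": mean,
            "median": median,
            "n_observed": n_obs,
            "variable": variable,
            "hypo": obs & (mean < 0.5),
            "hyper": obs & (mean > 0.5),
        }
    )


def annotation_summary(
    sites: Sequence[CpGSite],
    site_medians: np.ndarray,
    annotations: Mapping[str, Sequence[GenomicInterval]],
) -> pd.DataFrame:
    """Per-annotation site counts and the median of per-site medians.

    A site overlapping k labels contributes to all k; sites overlapping
    no annotation are summarized under "unannotated". NaN medians
    (never-observed sites) are excluded from the median but counted.
    """
    site_medians = np.asarray(site_medians, dtype=float)
    if len(site_medians) != len(sites):
        raise ValueError("site_medians must align with sites")
    hit_any = np.zeros(len(sites), dtype=bool)
    rows = []
    for label, intervals in annotations.items():
        mask, _ = capture.proximity_mask(list(sites), list(intervals), tol=0)
        hit_any |= mask
        vals = site_medians[mask]
        rows.append((label, int(mask.sum()), float(np.nanmedian(vals)) if mask.any() else np.nan))
    un = ~hit_any
    vals = site_medians[un]
    rows.append(("unannotated", int(un.sum()), float(np.nanmedian(vals)) if un.any() else np.nan))
    return pd.DataFrame(rows, columns=["label", "n_sites", "median_methylation"]).set_index("label")


def promoters_from_tss(
    tss: Sequence[GenomicInterval], upstream: int = 2000
) -> list[GenomicInterval]:
    """Promoter intervals as the ``upstream`` bp region upstream of each
    TSS, strand-aware (minus-strand promoters extend rightwards), clipped
    at 0 and merged."""
    raw = []
    for t in tss:
        if t.strand == "-":
            raw.append(GenomicInterval(t.chrom, t.end, t.end + upstream))
        else:
            start = max(t.start - upstream, 0)
            if start < t.start:
                raw.append(GenomicInterval(t.chrom, start, t.start))
    return capture.expand_merge(raw, 0)
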