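"""Cross-technology concordance: OLS fits of methylation levels, array
beta-value emulation, per-sample matched-vs-permuted R2, and the Welch
test comparing those distributions.

Axes follow the field's plotting convention: the comparison technology
on x, the sequencing assay under evaluation on y; R2 comes from the
simple y-on-x regression, so for a simple linear fit R2 equals the
squared Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import t as t_dist

from .matrix import MethLevels

__all__ = [
    "ConcordFit",
    "BetaParams",
    "ols_fit",
    "beta_values",
    "paired_sample_r2",
    "welch_t",
    "subset_compare",
    "derangement",
]


@dataclass
class ConcordFit:
    """Simple-OLS summary; ``defined`` is False when the fit is
    degenerate (fewer than 3 points or zero variance on either axis)."""

    r2: float
    slope: float
    intercept: float
    pearson_r: float
    n_points: int
    defined: bool = True

    @classmethod
    def undefined(cls, n_points: int = 0) -> "ConcordFit":
        nan = float("nan")
        return cls(nan, nan, nan, nan, n_points, defined=False)


@dataclass
class BetaParams:
    """Array beta-value offset (added to the total intensity)."""

    offset: float = 100.0

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("offset must be >= 0")


def ols_fit(x: np.ndarray, y: np.ndarray) -> ConcordFit:
    """Least-squares y-on-x fit after pairwise-complete filtering.

    Degenerate inputs (n < 3 or zero variance) yield an undefined fit,
    never an exception.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        return ConcordFit.undefined(n)
    sxx = np.sum((x - x.mean()) ** 2)
    syy = np.sum((y - y.mean()) ** 2)
    if sxx == 0.0 or syy == 0.0:
        return ConcordFit.undefined(n)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    ss_res = syy - slope * sxy
    r2 = 1.0 - ss_res / syy
    r = sxy / np.sqrt(sxx * syy)
    return ConcordFit(float(r2), float(slope), float(intercept), float(r), n)


def beta_values(
    M: np.ndarray, U: np.ndarray, params: BetaParams | None = None
) -> np.ndarray:
    """Array-style beta: M / (M + U + offset); with a positive offset,
    beta < 1 always. M = U = 0 with offset 0 gives NaN."""
    p = params or BetaParams()
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if (M < 0).any() or (U < 0).any():
        raise ValueError("counts must be >= 0")
    denom = M + U + p.offset
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, M / denom, np.nan)


def derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random permutation of range(n) with no fixed points (n >= 2)."""
    if n < 2:
        raise ValueError("derangement needs n >= 2")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def paired_sample_r2(
    levels_a: MethLevels,
    levels_b: MethLevels,
    pairing: Mapping[str, str],
    permute: bool = False,
    seed: int = 0,
) -> dict[str, float]:
    """Per-sample R2 between two technologies over shared sites.

    ``pairing`` maps each sample of A to its partner in B (bijective).
    Each R2 uses only sites present in both site sets and observed in
    both members of the pair. With ``permute=True`` the B side is
    reassigned by a seeded derangement — every sample is compared
    against a different individual, the null for shared canonical
    methylation structure. Pairs without a defined fit get NaN.
    """
    a_samples = list(pairing)
    b_targets = [pairing[s] for s in a_samples]
    if len(set(b_targets)) != len(b_targets):
        raise ValueError("pairing must be bijective")
    if permute:
        perm = derangement(len(a_samples), np.random.default_rng(seed))
        b_targets = [b_targets[i] for i in perm]
    site_idx_b = {s: i for i, s in enumerate(levels_b.sites)}
    shared = [(i, site_idx_b[s]) for i, s in enumerate(levels_a.sites) if s in site_idx_b]
    if not shared:
        raise ValueError("no shared sites between the two level sets")
    ia = np.array([i for i, _ in shared])
    ib = np.array([j for _, j in shared])
    col_a = {s: j for j, s in enumerate(levels_a.samples)}
    col_b = {s: j for j, s in enumerate(levels_b.samples)}
    out: dict[str, float] = {}
    for sa, sb in zip(a_samples, b_targets):
        x = levels_b.m[ib, col_b[sb]]
        y = levels_a.m[ia, col_a[sa]]
        fit = ols_fit(x, y)
        out[sa] = fit.r2 if fit.defined else float("nan")
    return out


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Unequal-variance t test: (t, Welch-Satterthwaite df, two-sided p).

    Degenerate variance is handled explicitly: both samples constant and
    equal means -> t = 0, p = 1; both constant and unequal means -> p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    dm = x.mean() - y.mean()
    if vx == 0.0 and vy == 0.0:
        if dm == 0.0:
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return float(np.sign(dm) * np.inf), float(len(x) + len(y) - 2), 0.0
    se2 = vx / len(x) + vy / len(y)
    t = dm / np.sqrt(se2)
    df = se2**2 / (
        (vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1)
    )
    p = 2.0 * t_dist.sf(abs(t), df)
    return float(t), float(df), float(p)


def subset_compare(
    mean_a: np.ndarray,
    mean_b: np.ndarray,
    masks: Mapping[str, np.ndarray],
) -> dict[str, ConcordFit]:
    """One OLS fit per named boolean mask over the shared site vector
    (region subsets, variable sites, probe types — all uniform here)."""
    mean_a = np.asarray(mean_a, dtype=float)
    mean_b = np.asarray(mean_b, dtype=float)
    out: dict[str, ConcordFit] = {}
    for name, mask in masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != mean_a.shape:
            raise ValueError(f"mask {name!r} not aligned to site vector")
        out[name] = ols_fit(mean_b[mask], mean_a[mask])
    return out
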