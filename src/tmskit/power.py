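"""Coverage-conditioned power simulation for two-group methylation tests.

The simulator resamples an empirical per-cell coverage distribution with
replacement, assigns each sample a binary group label, draws methylated
counts from Binomial(coverage, p0 + delta * group), tests each simulated
site for a group effect, and reports power as the fraction of sites
significant at a nominal threshold — across a grid of sample sizes,
effect sizes, and coverage multipliers (doubling/quadrupling every
site's total counts emulates deeper sequencing).

The default per-site test is the binomial-GLM likelihood-ratio test.
For a single binary predictor the GLM maximum likelihood is attained at
the group-pooled proportions, so the deviance has a closed form; this is
computed vectorized across sites and is immune to separation (0/1
fitted proportions contribute zero terms via x*log(x) -> 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import chi2, fisher_exact

from .matrix import CountMatrix

__all__ = [
    "CoveragePool",
    "PowerConfig",
    "draw_coverage",
    "simulate_counts",
    "site_pvalue",
    "grouped_lrt",
    "estimate_power",
]

_TESTS = ("binomial-glm-lrt", "pooled-fisher")


@dataclass
class CoveragePool:
    """Multiset of observed per-cell coverages, resampled with
    replacement during simulation."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64).ravel()
        if self.values.size == 0:
            raise ValueError("coverage pool is empty")
        if (self.values < 0).any():
            raise ValueError("coverages must be >= 0")

    @classmethod
    def from_matrix(cls, matrix: CountMatrix, n_sites: int = 1000, seed: int = 0) -> "CoveragePool":
        """Pool the per-cell coverages of ``n_sites`` randomly chosen
        sites of a real count matrix (all sites if fewer)."""
        rng = np.random.default_rng(seed)
        cov = matrix.coverage
        if len(matrix.sites) > n_sites:
            idx = rng.choice(len(matrix.sites), size=n_sites, replace=False)
            cov = cov[idx]
        return cls(cov.ravel())

    @classmethod
    def negbin(cls, mean: float = 20.0, dispersion: float = 5.0, n: int = 10_000, seed: int = 0) -> "CoveragePool":
        rng = np.random.default_rng(seed)
        return cls(rng.negative_binomial(dispersion, dispersion / (dispersion + mean), size=n))

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass
class PowerConfig:
    """Simulation grid and test settings.

    ``baseline`` sets the no-effect methylation level p0: "symmetric"
    uses p0 = 0.5 - delta/2 (groups straddle 0.5, comparable across
    deltas); a float fixes p0 directly.
    """

    n_sites: int = 1000
    sample_sizes: Sequence[int] = (100, 200, 400)
    deltas: Sequence[float] = (0.0, 0.05, 0.10, 0.15, 0.20)
    multipliers: Sequence[int] = (1, 2, 4)
    a_sig: float = 0.001
    baseline: str | float = "symmetric"
    test: str = "binomial-glm-lrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.a_sig < 1.0:
            raise ValueError("a_sig must be in (0, 1)")
        if any(d < 0 for d in self.deltas):
            raise ValueError("deltas must be >= 0")
        if any(k < 1 or int(k) != k for k in self.multipliers):
            raise ValueError("multipliers must be positive integers")
        if self.test not in _TESTS:
            raise ValueError(f"test must be one of {_TESTS}")
        for d in self.deltas:
            p0 = self.p0(d)
            if p0 < 0 or p0 + d > 1:
                raise ValueError(f"baseline gives p0={p0} with delta={d} outside [0,1]")

    def p0(self, delta: float) -> float:
        if self.baseline == "symmetric":
            return 0.5 - delta / 2.0
        return float(self.baseline)


def draw_coverage(
    pool: CoveragePool, n: int, k: int = 1, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """n i.i.d. draws with replacement from the pool, each multiplied by
    the coverage multiplier k. The same seed yields the same base draw,
    so k=2 doubles every value of the k=1 vector."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.choice(pool.values, size=n, replace=True) * int(k)


def simulate_counts(
    coverages: np.ndarray,
    groups: np.ndarray,
    p0: float,
    delta: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Methylated counts M_i ~ Binomial(c_i, p0 + delta * group_i)."""
    if p0 < 0 or p0 + delta > 1:
        raise ValueError(f"p0={p0} with delta={delta} leaves [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = p0 + delta * np.asarray(groups)
    return rng.binomial(np.asarray(coverages), p)


def grouped_lrt(
    M: np.ndarray, C: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized binomial-GLM likelihood-ratio test, one test per row.

    M, C are (sites, samples); returns (deviance, p). Rows where either
    group has zero total coverage get NaN.
    """
    M = np.atleast_2d(M)
    C = np.atleast_2d(C)
    g = np.asarray(groups).astype(bool)
    m1, c1 = M[:, g].sum(axis=1), C[:, g].sum(axis=1)
    m0, c0 = M[:, ~g].sum(axis=1), C[:, ~g].sum(axis=1)
    valid = (c0 > 0) & (c1 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(c1 > 0, m1 / np.maximum(c1, 1), 0.0)
        p0_ = np.where(c0 > 0, m0 / np.maximum(c0, 1), 0.0)
        pp = (m0 + m1) / np.maximum(c0 + c1, 1)
        ll_full = (
            xlogy(m1, p1) + xlogy(c1 - m1, 1 - p1) + xlogy(m0, p0_) + xlogy(c0 - m0, 1 - p0_)
        )
        ll_null = xlogy(m0 + m1, pp) + xlogy(c0 + c1 - m0 - m1, 1 - pp)
    stat = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    p = chi2.sf(stat, df=1)
    stat = np.where(valid, stat, np.nan)
    p = np.where(valid, p, np.nan)
    return stat, p


def site_pvalue(
    M: np.ndarray, c: np.ndarray, groups: np.ndarray, test: str = "binomial-glm-lrt"
) -> float:
    """P-value for a group effect at one site.

    Default: likelihood-ratio test comparing logistic-binomial models
    with/without the group term (chi-square, 1 df). "pooled-fisher"
    collapses counts per group into a 2x2 table and applies the
    two-sided exact test.
    """
    if test not in _TESTS:
        raise ValueError(f"test must be one of {_TESTS}")
    M = np.asarray(M)
    c = np.asarray(c)
    g = np.asarray(groups).astype(bool)
    if test == "binomial-glm-lrt":
        _, p = grouped_lrt(M[None, :], c[None, :], g)
        return float(p[0])
    m1, c1 = M[g].sum(), c[g].sum()
    m0, c0 = M[~g].sum(), c[~g].sum()
    if c0 == 0 or c1 == 0:
        return float("nan")
    table = [[int(m1), int(c1 - m1)], [int(m0), int(c0 - m0)]]
    return float(fisher_exact(table, alternative="two-sided")[1])


def estimate_power(config: PowerConfig, pool: CoveragePool) -> pd.DataFrame:
    """Power over the (sample size, effect size, multiplier) grid.

    Each grid cell simulates ``n_sites`` independent sites (fresh
    coverage and count draws per site); power is the fraction of testable
    sites significant at ``a_sig``. Coverage base draws are shared across
    multipliers within a (n, delta) cell so deeper sequencing is compared
    on the same resampled cells. Fully seed-deterministic.
    """
    rows = []
    for ni, n in enumerate(config.sample_sizes):
        groups = np.zeros(n, dtype=np.int64)
        groups[n // 2 :] = 1
        for di, delta in enumerate(config.deltas):
            p0 = config.p0(delta)
            rng_cov = np.random.default_rng(
                np.random.SeedSequence((config.seed, 101, ni, di))
            )
            base = rng_cov.choice(pool.values, size=(config.n_sites, n), replace=True)
            for ki, k in enumerate(config.multipliers):
                c = base * int(k)
                rng_cnt = np.random.default_rng(
                    np.random.SeedSequence((config.seed, 202, ni, di, ki))
                )
                p = p0 + delta * groups
                M = rng_cnt.binomial(c, p[None, :])
                if config.test == "binomial-glm-lrt":
                    _, pvals = grouped_lrt(M, c, groups)
                else:
                    pvals = np.array(
                        [site_pvalue(M[s], c[s], groups, test=config.test) for s in range(config.n_sites)]
                    )
                tested = ~np.isnan(pvals)
                n_tested = int(tested.sum())
                power = float((pvals[tested] < config.a_sig).sum() / n_tested) if n_tested else float("nan")
                rows.append(
                    {
                        "n": n,
                        "delta": delta,
                        "k": k,
                        "mean_coverage": float(c.mean()),
                        "power": power,
                        "n_sites": config.n_sites,
                        "n_tested": n_tested,
                        "a_sig": config.a_sig,
                        "seed": config.seed,
                    }
                )
    return pd.DataFrame(rows)
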