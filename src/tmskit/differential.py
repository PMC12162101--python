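"""Beta-binomial tissue-specificity testing.

Each variable CpG site is tested for a focal-tissue effect by maximum-
likelihood beta-binomial regression: the methylated count M_i out of
coverage c_i follows BetaBinomial(c_i, mu_i, rho) with
logit(mu_i) = b0 + b1 * focal_i and a single overdispersion rho (the
intra-class correlation of the latent per-sample methylation
proportion) shared across arms. Significance comes from the likelihood
ratio against b1 = 0 (chi-square, 1 df), the standardized effect is
z = b1 / se(b1) from the observed information, and q-values are
Benjamini-Hochberg. Cross-technology agreement of significant-site sets
is quantified by Fisher's exact test with a Haldane-corrected odds
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, expit, gammaln, xlogy
from scipy.stats import chi2, fisher_exact
from statsmodels.stats.multitest import multipletests

from .matrix import CountMatrix, methylation_levels, site_summary

__all__ = [
    "BetaBinFit",
    "EnrichmentResult",
    "betabinom_loglik",
    "fit_betabinom_site",
    "bh_fdr",
    "tissue_scan",
    "overlap_enrichment",
]

_RHO_FLOOR = 1e-8


@dataclass
class BetaBinFit:
    b0: float
    b1: float
    rho: float
    z: float
    p: float
    q: float | None = None
    converged: bool = True


@dataclass
class EnrichmentResult:
    table: tuple[int, int, int, int]  # a=both, b=A only, c=B only, d=neither
    odds_ratio: float
    log2_or: float
    ci95: tuple[float, float]
    p: float


def betabinom_loglik(M: np.ndarray, c: np.ndarray, mu: np.ndarray | float, rho: float) -> float:
    """Sum of beta-binomial log-pmfs with mean mu and ICC rho.

    Uses the (alpha, beta) = (mu, 1-mu) * (1-rho)/rho parameterization;
    rho below a small floor reduces exactly to the binomial likelihood
    (the continuous limit), keeping the optimization well-behaved at the
    boundary.
    """
    M = np.asarray(M, dtype=float)
    c = np.asarray(c, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), M.shape)
    comb = gammaln(c + 1) - gammaln(M + 1) - gammaln(c - M + 1)
    if rho < _RHO_FLOOR:
        return float(np.sum(comb + xlogy(M, mu) + xlogy(c - M, 1.0 - mu)))
    s = (1.0 - rho) / rho
    a = np.clip(mu * s, 1e-12, None)
    b = np.clip((1.0 - mu) * s, 1e-12, None)
    return float(np.sum(comb + betaln(M + a, c - M + b) - betaln(a, b)))


def _nll(theta: np.ndarray, M: np.ndarray, c: np.ndarray, focal: np.ndarray, with_b1: bool) -> float:
    if with_b1:
        b0, b1, lrho = theta
    else:
        b0, lrho = theta
        b1 = 0.0
    mu = expit(b0 + b1 * focal)
    rho = expit(lrho)
    return -betabinom_loglik(M, c, mu, rho)


def _fd_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h * h)
    return H


def fit_betabinom_site(
    M: np.ndarray, c: np.ndarray, focal_indicator: np.ndarray
) -> BetaBinFit:
    """ML beta-binomial fit of one site's counts on a focal-vs-rest
    contrast; returns effect, overdispersion, z, and the LRT p-value.

    Cells with zero coverage are dropped; each arm needs >= 2 covered
    samples. If the optimizer pushes rho to its floor the model reduces
    to the binomial GLM, whose closed-form solution is used as a
    fallback candidate for both hypotheses.
    """
    M = np.asarray(M, dtype=float)
    c = np.asarray(c, dtype=float)
    f = np.asarray(focal_indicator, dtype=float)
    keep = c > 0
    M, c, f = M[keep], c[keep], f[keep]
    if (f == 1).sum() < 2 or (f == 0).sum() < 2:
        raise ValueError("need >= 2 covered samples per arm")

    def logit_prop(m_sum: float, c_sum: float) -> float:
        p = (m_sum + 0.5) / (c_sum + 1.0)
        return float(np.log(p / (1.0 - p)))

    b0_start = logit_prop(M[f == 0].sum(), c[f == 0].sum())
    b1_start = logit_prop(M[f == 1].sum(), c[f == 1].sum()) - b0_start
    lrho_start = np.log(0.02 / 0.98)
    bounds_full = [(-20, 20), (-20, 20), (-18, 5)]
    bounds_null = [(-20, 20), (-18, 5)]

    res_full = minimize(
        _nll, x0=np.array([b0_start, b1_start, lrho_start]),
        args=(M, c, f, True), method="L-BFGS-B", bounds=bounds_full,
    )
    res_null = minimize(
        _nll, x0=np.array([logit_prop(M.sum(), c.sum()), lrho_start]),
        args=(M, c, f, False), method="L-BFGS-B", bounds=bounds_null,
    )
    ll_full, ll_null = -res_full.fun, -res_null.fun

    # profile down to the binomial model when rho hits the floor
    binom_full = -_nll(np.array([b0_start, b1_start, -30.0]), M, c, f, True)
    # closed-form binomial MLE equals group proportions, so b*_start is the optimum
    if binom_full > ll_full:
        ll_full = binom_full
        res_full.x = np.array([b0_start, b1_start, -18.0])
    binom_null = -_nll(np.array([logit_prop(M.sum(), c.sum()), -30.0]), M, c, f, False)
    if binom_null > ll_null:
        ll_null = binom_null

    stat = max(0.0, 2.0 * (ll_full - ll_null))
    p = float(chi2.sf(stat, df=1))
    b0, b1, lrho = res_full.x
    rho = float(expit(lrho))
    se = float("nan")
    try:
        H = _fd_hessian(lambda th: _nll(th, M, c, f, True), res_full.x)
        cov = np.linalg.inv(H)
        if cov[1, 1] > 0:
            se = float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        pass
    z = float(b1 / se) if np.isfinite(se) and se > 0 else float("nan")
    converged = bool(res_full.success and res_null.success and np.isfinite(p))
    return BetaBinFit(float(b0), float(b1), rho, z, p, converged=converged)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs propagate unchanged."""
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def tissue_scan(
    matrix: CountMatrix,
    tissue_labels: Sequence[str],
    focal: str,
    fdr: float = 0.05,
    lo: float = 0.1,
    hi: float = 0.9,
) -> pd.DataFrame:
    """Per-site focal-tissue-vs-rest beta-binomial scan with BH FDR.

    Only variable sites (per-site median methylation strictly between
    ``lo`` and ``hi``) are tested; untested and non-converged sites carry
    NaN p/q. Returns one row per site of the input matrix.
    """
    labels = np.asarray(tissue_labels)
    if len(labels) != len(matrix.samples):
        raise ValueError("one tissue label per sample required")
    if focal not in set(labels):
        raise ValueError(f"focal tissue {focal!r} absent")
    f = (labels == focal).astype(float)
    levels = methylation_levels(matrix)
    summ = site_summary(levels, lo=lo, hi=hi)
    variable = summ["median"].between(lo, hi, inclusive="neither").fillna(False).to_numpy()
    n_sites = len(matrix.sites)
    cols = {k: np.full(n_sites, np.nan) for k in ("b0", "b1", "rho", "z", "p")}
    tested = np.zeros(n_sites, dtype=bool)
    C = matrix.coverage
    for i in np.flatnonzero(variable):
        try:
            fit = fit_betabinom_site(matrix.M[i], C[i], f)
        except ValueError:
            continue
        if not fit.converged:
            continue
        tested[i] = True
        cols["b0"][i], cols["b1"][i] = fit.b0, fit.b1
        cols["rho"][i], cols["z"][i], cols["p"][i] = fit.rho, fit.z, fit.p
    q = bh_fdr(np.where(tested, cols["p"], np.nan))
    out = pd.DataFrame(
        {
            "chrom": [s.chrom for s in matrix.sites],
            "pos0": [s.pos0 for s in matrix.sites],
            "variable": variable,
            "tested": tested,
            **cols,
            "q": q,
        }
    )
    out["significant"] = out["q"] < fdr
    return out


def overlap_enrichment(
    sig_a: set, sig_b: set, universe: set
) -> EnrichmentResult:
    """Enrichment of the overlap of two significant-site sets over a
    shared universe: 2x2 Fisher exact test, odds ratio with Haldane +0.5
    correction when any cell is zero, Wald 95% CI on the log2 scale."""
    if not universe:
        raise ValueError("empty universe")
    if not (sig_a <= universe and sig_b <= universe):
        raise ValueError("significant sets must be subsets of the universe")
    a = len(sig_a & sig_b)
    b = len(sig_a - sig_b)
    c = len(sig_b - sig_a)
    d = len(universe) - a - b - c
    cells = np.array([a, b, c, d], dtype=float)
    corr = cells + 0.5 if (cells == 0).any() else cells
    odds = (corr[0] * corr[3]) / (corr[1] * corr[2])
    log2_or = float(np.log2(odds))
    se_ln = float(np.sqrt((1.0 / corr).sum()))
    half = 1.959963984540054 * se_ln / np.log(2.0)
    p = float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return EnrichmentResult(
        (a, b, c, d), float(odds), log2_or, (log2_or - half, log2_or + half), p
    )
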