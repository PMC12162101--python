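"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive (per-base scans, double loops,
closed-form products) and shares no code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np

from tmskit.io import CpGSite, GenomicInterval


def covered_bases(intervals) -> dict[str, set[int]]:
    out: dict[str, set[int]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, set()).update(range(iv.start, iv.end))
    return out


def expand_merge_bases(intervals, flank, chrom_lengths=None) -> dict[str, set[int]]:
    """Per-base union of flank-expanded intervals."""
    out: dict[str, set[int]] = {}
    for iv in intervals:
        lo = max(iv.start - flank, 0)
        hi = iv.end + flank
        if chrom_lengths is not None:
            hi = min(hi, chrom_lengths[iv.chrom])
        out.setdefault(iv.chrom, set()).update(range(lo, hi))
    return out


def pair_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Number of integer positions strictly between two half-open
    intervals; 0 when they overlap or are adjacent."""
    if a_start < b_end and b_start < a_end:
        return 0
    if b_start >= a_end:
        return b_start - a_end
    return a_start - b_end


def on_target_brute(query, reference, tol: int) -> list[bool]:
    """Per-query on-target flag by exhaustive pairwise gap computation."""
    out = []
    for q in query:
        if isinstance(q, CpGSite):
            qs, qe, qc = q.pos0, q.pos0 + 1, q.chrom
        else:
            qs, qe, qc = q.start, q.end, q.chrom
        hit = False
        for r in reference:
            if r.chrom != qc:
                continue
            if pair_gap(qs, qe, r.start, r.end) <= tol:
                hit = True
                break
        out.append(hit)
    return out


def depth_brute(fragments, target) -> list[int]:
    """Per-base depth over the target, position by position."""
    depths = []
    for t in target:
        for pos in range(t.start, t.end):
            depths.append(
                sum(1 for f in fragments if f.chrom == t.chrom and f.start <= pos < f.end)
            )
    return depths


def shore_shelf_label_brute(islands, pos: int, chrom: str, shore_bp=2000, shelf_bp=4000):
    """Label of a single base under island > shore > shelf precedence."""
    dists = []
    for iv in islands:
        if iv.chrom != chrom:
            continue
        if iv.start <= pos < iv.end:
            return "island"
        dists.append(pos - iv.end + 1 if pos >= iv.end else iv.start - pos)
    if not dists:
        return None
    d = min(dists)
    if d <= shore_bp:
        return "shore"
    if d <= shelf_bp:
        return "shelf"
    return None


def filter_brute(M, U, min_cov, min_frac, cov_cmp, frac_cmp) -> list[bool]:
    """Double-loop coverage/missingness filter."""
    n_sites, n_samples = M.shape
    keep = []
    for i in range(n_sites):
        n_cov = 0
        for j in range(n_samples):
            c = M[i, j] + U[i, j]
            ok = c >= min_cov if cov_cmp == "ge" else c > min_cov
            n_cov += ok
        frac = n_cov / n_samples
        keep.append(frac >= min_frac if frac_cmp == "ge" else frac > min_frac)
    return keep


def nx_brute(lengths, x: float) -> int:
    """Enumerate suffix sums of the descending sort."""
    desc = sorted(lengths, reverse=True)
    total = sum(desc)
    running = 0
    for length in desc:
        running += length
        if running >= x * total:
            return length
    raise AssertionError("unreachable")


def bh_brute(p: list[float]) -> list[float]:
    """Step-up BH by direct definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order, start=1):
        q[i] = min(
            min(p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)),
            1.0,
        )
    return q


def betabinom_logpmf_product(M: int, c: int, a: float, b: float) -> float:
    """Exact beta-binomial log-pmf via the rising-factorial product form:
    C(c, M) * prod(a+j, j<M) * prod(b+j, j<c-M) / prod(a+b+j, j<c)."""
    log_comb = math.lgamma(c + 1) - math.lgamma(M + 1) - math.lgamma(c - M + 1)
    num = sum(math.log(a + j) for j in range(M))
    num += sum(math.log(b + j) for j in range(c - M))
    den = sum(math.log(a + b + j) for j in range(c))
    return log_comb + num - den


def ols_normal_equations(x, y):
    """Slope/intercept/r2 from explicitly assembled normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    A = np.array([[len(x), x.sum()], [x.sum(), (x * x).sum()]])
    rhs = np.array([y.sum(), (x * y).sum()])
    intercept, slope = np.linalg.solve(A, rhs)
    resid = y - (intercept + slope * x)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return slope, intercept, 1.0 - ss_res / ss_tot


def random_intervals(rng, n, chroms=("chr1",), max_pos=10_000, max_len=400):
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, max_pos - 1))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, min(start + length, max_pos)))
    return out
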