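"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure of targeted enzymatic
methylation sequencing (TMS) data: a bimodal (beta-mixture) methylome,
negative-binomial per-cell coverage, incomplete-conversion background
(CHH methylation), group effect sites, between-sample overdispersion,
on/off-target capture fragment mixtures, microarray beta values with an
intensity offset, and MspI-digest (RRBS-style) site selection. Every
generator is seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import CpGSite, CytosineRecord, GenomicInterval
from .capture import ProbeSet, proximity_mask
from .matrix import CountMatrix

__all__ = [
    "DigestConfig",
    "DigestResult",
    "MethylomeTruth",
    "ReferenceSim",
    "gen_reference",
    "simulate_truth",
    "gen_methylome",
    "gen_count_matrix",
    "gen_tissue_matrix",
    "gen_array_betas",
    "gen_fragments",
    "msp1_digest",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class DigestConfig:
    """MspI-style in-silico digest: cut inside every motif occurrence at
    ``cut_offset`` (C^CGG for the defaults), retain fragments whose length
    falls in [size_min, size_max] (the RRBS size-selection window)."""

    motif: str = "CCGG"
    cut_offset: int = 1
    size_min: int = 180
    size_max: int = 2000

    def __post_init__(self) -> None:
        if not self.motif:
            raise ValueError("motif must be non-empty")
        if not 0 <= self.cut_offset <= len(self.motif):
            raise ValueError("cut_offset out of range")
        if not 0 < self.size_min <= self.size_max:
            raise ValueError("need 0 < size_min <= size_max")


@dataclass
class DigestResult:
    fragments: list[tuple[int, int]]
    retained: list[tuple[int, int]]
    covered_cpgs: list[CpGSite]


@dataclass
class ReferenceSim:
    fasta: str
    genome: dict[str, str]
    sites: list[CpGSite]
    probes: ProbeSet


@dataclass
class MethylomeTruth:
    """Ground-truth methylome: per-site, per-group true methylation
    proportions plus the noise/coverage model parameters."""

    sites: list[CpGSite]
    pi: np.ndarray  # (n_groups, n_sites)
    effect_sites: np.ndarray  # bool (n_sites,)
    delta: float = 0.0
    conversion_error: float = 0.005  # unmethylated C read as methylated
    inverse_error: float = 0.0  # methylated C read as unmethylated
    coverage_mean: float = 20.0
    coverage_dispersion: float = 5.0  # negative-binomial size; larger = tighter
    sample_rho: float = 0.02  # between-sample ICC of the true proportion

    def __post_init__(self) -> None:
        self.pi = np.atleast_2d(np.asarray(self.pi, dtype=float))
        self.effect_sites = np.asarray(self.effect_sites, dtype=bool)
        if self.pi.shape[1] != len(self.sites):
            raise ValueError("pi must have one column per site")
        if (self.pi < 0).any() or (self.pi > 1).any():
            raise ValueError("pi must lie in [0, 1]")
        if not 0 <= self.conversion_error <= 0.05:
            raise ValueError("conversion_error must be in [0, 0.05]")
        if self.pi.shape[0] > 1 and self.effect_sites.any():
            gap = self.pi[1, self.effect_sites] - self.pi[0, self.effect_sites]
            if not np.allclose(np.abs(gap), self.delta):
                raise ValueError("effect sites must differ by exactly delta")


def gen_reference(
    n_chroms: int = 1,
    chrom_length: int = 100_000,
    cpg_rate: float = 0.02,
    probe_length: int = 120,
    probe_fraction: float = 0.1,
    seed: int = 0,
) -> ReferenceSim:
    """Random reference with CG dinucleotides planted at ~``cpg_rate`` per
    bp, plus a probe set in which every probe overlaps at least one CpG.

    The background sequence is generated CG-free, so the returned CpG
    list is exactly the set of CG occurrences in the sequence.
    """
    if not 0.0 <= cpg_rate <= 0.2:
        raise ValueError("cpg_rate must be in [0, 0.2]")
    if chrom_length < 1000:
        raise ValueError("chrom_length must be >= 1000")
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    sites: list[CpGSite] = []
    probe_ivs: list[GenomicInterval] = []
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        seq = rng.choice(_BASES, size=chrom_length).copy()
        # scrub accidental CG: replacing the G with A/T cannot create a new CG
        for i in np.flatnonzero((seq[:-1] == b"C") & (seq[1:] == b"G")):
            seq[i + 1] = b"A" if rng.random() < 0.5 else b"T"
        n_plant = int(round(cpg_rate * chrom_length))
        if n_plant:
            cand = np.sort(rng.choice(chrom_length - 1, size=min(2 * n_plant, chrom_length // 2), replace=False))
            planted = []
            last = -2
            for p in cand:
                if p - last >= 2:
                    planted.append(p)
                    last = p
                if len(planted) >= n_plant:
                    break
            for p in planted:
                seq[p] = b"C"
                seq[p + 1] = b"G"
        s = seq.tobytes().decode()
        genome[chrom] = s
        cpg_pos = [i for i in range(len(s) - 1) if s[i] == "C" and s[i + 1] == "G"]
        chrom_sites = [CpGSite(chrom, p) for p in cpg_pos]
        sites.extend(chrom_sites)
        if chrom_sites:
            n_probes = max(1, int(probe_fraction * len(chrom_sites)))
            anchors = rng.choice(len(chrom_sites), size=n_probes, replace=False)
            for a in np.sort(anchors):
                center = chrom_sites[a].pos0
                start = min(max(center - probe_length // 2, 0), chrom_length - probe_length)
                probe_ivs.append(
                    GenomicInterval(chrom, start, start + probe_length, name=f"probe_{chrom}_{center}")
                )
    fasta_lines = []
    for chrom, s in genome.items():
        fasta_lines.append(f">{chrom}")
        fasta_lines.extend(s[i : i + 80] for i in range(0, len(s), 80))
    return ReferenceSim("\n".join(fasta_lines) + "\n", genome, sites, ProbeSet(probe_ivs))


def simulate_truth(
    sites: Sequence[CpGSite],
    delta: float = 0.1,
    frac_effect: float = 0.1,
    mixture_weight: float = 0.5,
    beta_low: tuple[float, float] = (1.0, 10.0),
    beta_high: tuple[float, float] = (10.0, 1.0),
    n_groups: int = 2,
    seed: int = 0,
    **kwargs,
) -> MethylomeTruth:
    """Draw a ground-truth methylome: bimodal baseline pi from a two-
    component beta mixture, with ``frac_effect`` of eligible sites given
    a +delta group-1 shift. Extra kwargs pass through to
    :class:`MethylomeTruth` (noise/coverage parameters)."""
    rng = np.random.default_rng(seed)
    n = len(sites)
    low = rng.random(n) < mixture_weight
    pi0 = np.where(
        low,
        rng.beta(*beta_low, size=n),
        rng.beta(*beta_high, size=n),
    )
    effect = np.zeros(n, dtype=bool)
    if delta > 0 and frac_effect > 0 and n_groups > 1:
        eligible = np.flatnonzero(pi0 + delta <= 1.0)
        n_eff = int(round(frac_effect * n))
        if len(eligible) < n_eff:
            raise ValueError("not enough sites with pi + delta <= 1 to plant effects")
        effect[rng.choice(eligible, size=n_eff, replace=False)] = True
    pi = np.tile(pi0, (n_groups, 1))
    if n_groups > 1:
        pi[1, effect] = pi0[effect] + delta
    return MethylomeTruth(list(sites), pi, effect, delta=delta, **kwargs)


def _cell_proportions(p: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Cell-level true proportions: Beta around p with ICC rho; degenerate
    p in {0,1} (or rho=0) passes through unchanged."""
    if rho <= 0:
        return p
    a = p * (1.0 - rho) / rho
    b = (1.0 - p) * (1.0 - rho) / rho
    inner = (p > 0) & (p < 1)
    out = p.astype(float).copy()
    out[inner] = rng.beta(a[inner], b[inner])
    return out


def _draw_counts(
    truth: MethylomeTruth, groups: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Coverage and methylated-count matrices (sites x cells)."""
    n_sites = len(truth.sites)
    n = len(groups)
    size = truth.coverage_dispersion
    mu = truth.coverage_mean
    c = rng.negative_binomial(size, size / (size + mu), size=(n_sites, n))
    p_true = truth.pi[np.minimum(groups, truth.pi.shape[0] - 1)].T  # (sites, cells)
    p_cell = _cell_proportions(p_true, truth.sample_rho, rng)
    e, eo = truth.conversion_error, truth.inverse_error
    p_obs = p_cell * (1.0 - eo) + (1.0 - p_cell) * e
    m = rng.binomial(c, p_obs)
    return c, m


def gen_count_matrix(
    truth: MethylomeTruth, n_per_group: int, seed: int = 0
) -> tuple[CountMatrix, np.ndarray]:
    """Fast path: draw one count matrix directly (no per-record plumbing).
    Returns the matrix and the group label per sample."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    n_groups = truth.pi.shape[0]
    groups = np.repeat(np.arange(n_groups), n_per_group)
    c, m = _draw_counts(truth, groups, rng)
    samples = [f"g{g}_s{i}" for g in range(n_groups) for i in range(n_per_group)]
    meta = pd.DataFrame({"group": groups.astype(str)}, index=samples)
    return CountMatrix(list(truth.sites), samples, m, c - m, meta), groups


def gen_methylome(
    truth: MethylomeTruth,
    n_per_group: int,
    seed: int = 0,
    n_chh: int = 500,
) -> tuple[dict[str, list[CytosineRecord]], pd.DataFrame, pd.DataFrame]:
    """Per-sample cytosine reports (both CpG strands, plus CHH background
    rows whose methylation probability is the conversion error), the
    sample sheet, and the ground-truth table."""
    rng = np.random.default_rng(seed)
    n_groups = truth.pi.shape[0]
    groups = np.repeat(np.arange(n_groups), n_per_group)
    c, m = _draw_counts(truth, groups, rng)
    # split dinucleotide counts across the two strands
    c_plus = rng.binomial(c, 0.5)
    m_plus = _hypergeom_split(m, c - m, c_plus, rng)
    chroms = sorted({s.chrom for s in truth.sites})
    extent = {ch: max(s.pos0 for s in truth.sites if s.chrom == ch) + 1000 for ch in chroms}
    taken = {(s.chrom, s.pos0) for s in truth.sites} | {(s.chrom, s.pos0 + 1) for s in truth.sites}
    chh_pos: list[tuple[str, int]] = []
    while len(chh_pos) < n_chh:
        ch = chroms[rng.integers(len(chroms))]
        p = int(rng.integers(1, extent[ch]))
        if (ch, p) not in taken:
            chh_pos.append((ch, p))
            taken.add((ch, p))
    size = truth.coverage_dispersion
    chh_c = rng.negative_binomial(
        size, size / (size + truth.coverage_mean), size=(n_chh, len(groups))
    )
    chh_m = rng.binomial(chh_c, truth.conversion_error)
    samples = [f"g{g}_s{i}" for g in range(n_groups) for i in range(n_per_group)]
    reports: dict[str, list[CytosineRecord]] = {}
    for j, name in enumerate(samples):
        recs: list[CytosineRecord] = []
        for i, site in enumerate(truth.sites):
            mp, cp = int(m_plus[i, j]), int(c_plus[i, j])
            mm, cm = int(m[i, j] - m_plus[i, j]), int(c[i, j] - c_plus[i, j])
            recs.append(CytosineRecord(site.chrom, site.pos0 + 1, "+", mp, cp - mp, "CpG"))
            recs.append(CytosineRecord(site.chrom, site.pos0 + 2, "-", mm, cm - mm, "CpG"))
        for i, (ch, p) in enumerate(chh_pos):
            mc, cc = int(chh_m[i, j]), int(chh_c[i, j])
            recs.append(CytosineRecord(ch, p, "+", mc, cc - mc, "CHH"))
        recs.sort(key=lambda r: (r.chrom, r.pos1))
        reports[name] = recs
    sheet = pd.DataFrame({"group": groups.astype(str)}, index=samples)
    sheet.index.name = "sample"
    truth_table = pd.DataFrame(
        {
            "chrom": [s.chrom for s in truth.sites],
            "pos0": [s.pos0 for s in truth.sites],
            "effect": truth.effect_sites,
            **{f"pi_group{g}": truth.pi[g] for g in range(n_groups)},
        }
    )
    return reports, sheet, truth_table


def _hypergeom_split(
    m: np.ndarray, u: np.ndarray, n_take: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Methylated reads among ``n_take`` drawn without replacement from a
    pool of m methylated + u unmethylated."""
    out = np.zeros_like(m)
    total = m + u
    ok = (total > 0) & (n_take > 0)
    out[ok] = rng.hypergeometric(m[ok], u[ok], n_take[ok])
    return out


def gen_tissue_matrix(
    n_sites: int = 500,
    tissues: Sequence[str] = ("adrenal", "heart", "kidney", "liver", "lung", "spleen"),
    n_per_tissue: int = 16,
    focal: str = "liver",
    frac_effect: float = 0.1,
    effect_logit: float = 2.0,
    rho: float = 0.02,
    baseline_beta: tuple[float, float] = (2.0, 2.0),
    coverage_mean: float = 20.0,
    coverage_dispersion: float = 5.0,
    seed: int = 0,
) -> tuple[CountMatrix, np.ndarray]:
    """Multi-tissue count matrix with a fraction of sites carrying a
    focal-tissue effect of ``effect_logit`` on the logit scale, plus
    beta-distributed between-sample overdispersion (ICC ``rho``).

    Baseline proportions are drawn from ``baseline_beta`` (default
    Beta(2,2), i.e., intermediate methylation, where tissue-specific
    sites live); returns the matrix and the planted-effect mask.
    """
    rng = np.random.default_rng(seed)
    tissues = list(tissues)
    if focal not in tissues:
        raise ValueError(f"focal tissue {focal!r} not in tissues")
    n_samples = n_per_tissue * len(tissues)
    labels = np.repeat(tissues, n_per_tissue)
    pi0 = rng.beta(*baseline_beta, size=n_sites)
    planted = np.zeros(n_sites, dtype=bool)
    n_eff = int(round(frac_effect * n_sites))
    planted[rng.choice(n_sites, size=n_eff, replace=False)] = True
    p = np.tile(pi0[:, None], (1, n_samples))
    is_focal = labels == focal
    shifted = expit(logit(pi0[planted]) + effect_logit)
    p[np.ix_(planted, is_focal)] = shifted[:, None]
    p_cell = _cell_proportions(p, rho, rng)
    size = coverage_dispersion
    c = rng.negative_binomial(size, size / (size + coverage_mean), size=(n_sites, n_samples))
    m = rng.binomial(c, p_cell)
    sites = [CpGSite("chr1", 100 + 2 * i) for i in range(n_sites)]
    samples = [f"{t}_{i}" for t in tissues for i in range(n_per_tissue)]
    meta = pd.DataFrame({"tissue": labels}, index=samples)
    return CountMatrix(sites, samples, m, c - m, meta), planted


def gen_paired_technologies(
    truth: MethylomeTruth, n_samples: int, seed: int = 0
) -> tuple[CountMatrix, CountMatrix]:
    """Two sequencing technologies measuring the same individuals.

    Each sample's latent per-site methylation proportion is drawn once
    (around the truth, ICC ``truth.sample_rho``) and shared by both
    technologies; coverage and count noise are independent between the
    two. Matched samples therefore share individual-specific signal —
    the structure behind matched-vs-permuted concordance tests.
    """
    rng = np.random.default_rng(seed)
    n_sites = len(truth.sites)
    p_true = np.tile(truth.pi[0][:, None], (1, n_samples))
    p_cell = _cell_proportions(p_true, truth.sample_rho, rng)
    size, mu = truth.coverage_dispersion, truth.coverage_mean
    e, eo = truth.conversion_error, truth.inverse_error
    p_obs = p_cell * (1.0 - eo) + (1.0 - p_cell) * e
    mats = []
    for tech in ("A", "B"):
        c = rng.negative_binomial(size, size / (size + mu), size=(n_sites, n_samples))
        m = rng.binomial(c, p_obs)
        samples = [f"ind{i}" for i in range(n_samples)]
        meta = pd.DataFrame({"technology": tech}, index=samples)
        mats.append(CountMatrix(list(truth.sites), samples, m, c - m, meta))
    return mats[0], mats[1]


def gen_array_betas(
    m: np.ndarray,
    offset: float = 100.0,
    noise_sd: float = 50.0,
    intensity_scale: float = 1000.0,
    seed: int = 0,
) -> np.ndarray:
    """Microarray-style beta values from true methylation proportions.

    Methylated/unmethylated intensities are proportional to m and 1-m
    (scaled by ``intensity_scale``) plus Gaussian noise, truncated at 0;
    beta = S_m / (S_m + S_u + offset). With a positive offset, beta
    never reaches 1 — the array's structural bias.
    """
    if offset < 0 or noise_sd < 0:
        raise ValueError("offset and noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    m = np.asarray(m, dtype=float)
    s_m = np.maximum(intensity_scale * m + rng.normal(0, noise_sd, m.shape) * (noise_sd > 0), 0.0)
    s_u = np.maximum(intensity_scale * (1.0 - m) + rng.normal(0, noise_sd, m.shape) * (noise_sd > 0), 0.0)
    denom = s_m + s_u + offset
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, s_m / denom, np.nan)
    return np.clip(beta, 0.0, 1.0)


def gen_fragments(
    probes: ProbeSet,
    n_fragments: int,
    on_target_prob: float = 0.785,
    length_mean: float = 180.0,
    length_sd: float = 40.0,
    genome_extent: Mapping[str, int] | None = None,
    tol: int = 200,
    seed: int = 0,
) -> list[GenomicInterval]:
    """On/off-target fragment mixture mirroring hybrid-capture output.

    With probability ``on_target_prob`` a fragment is placed entirely
    within ``tol`` bp of a uniformly chosen probe; otherwise it is placed
    uniformly on the genome, re-drawn if it happens to land within
    ``tol`` of a probe, so the realized on-target count is exactly
    Binomial(n, on_target_prob).
    """
    if not probes.intervals:
        raise ValueError("empty probe set")
    if not 0.0 <= on_target_prob <= 1.0:
        raise ValueError("on_target_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ivs = probes.intervals
    if genome_extent is None:
        genome_extent = {}
        for iv in ivs:
            genome_extent[iv.chrom] = max(genome_extent.get(iv.chrom, 0), iv.end + 10 * tol)
    chroms = sorted(genome_extent)
    weights = np.array([genome_extent[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    out: list[GenomicInterval] = []
    for _ in range(n_fragments):
        length = max(20, int(round(rng.normal(length_mean, length_sd))))
        if rng.random() < on_target_prob:
            probe = ivs[rng.integers(len(ivs))]
            chrom_len = genome_extent.get(probe.chrom, probe.end + 10 * tol)
            lo = max(probe.start - tol, 0)
            hi = max(min(probe.end + tol, chrom_len) - length, lo)
            start = int(rng.integers(lo, hi + 1))
            end = min(start + length, chrom_len)
            out.append(GenomicInterval(probe.chrom, start, end))
        else:
            for _attempt in range(1000):
                chrom = chroms[rng.choice(len(chroms), p=weights)]
                start = int(rng.integers(0, max(genome_extent[chrom] - length, 1)))
                cand = GenomicInterval(chrom, start, start + length)
                near, _ = proximity_mask([cand], ivs, tol=tol)
                if not near[0]:
                    out.append(cand)
                    break
            else:
                raise RuntimeError("could not place an off-target fragment; genome too small")
    return out


def msp1_digest(
    sequence: str, config: DigestConfig | None = None, chrom: str = "chr1"
) -> DigestResult:
    """In-silico MspI digest with RRBS-style size selection.

    Cuts at ``cut_offset`` inside every (possibly overlapping) motif
    occurrence; fragments partition [0, len). Retained fragments fall in
    the size-selection window; covered CpGs are all CG positions whose C
    lies on a retained fragment.
    """
    cfg = config or DigestConfig()
    seq = sequence.upper()
    cuts: set[int] = set()
    i = seq.find(cfg.motif)
    while i != -1:
        cut = i + cfg.cut_offset
        if 0 < cut < len(seq):
            cuts.add(cut)
        i = seq.find(cfg.motif, i + 1)
    bounds = [0, *sorted(cuts), len(seq)]
    fragments = [(s, e) for s, e in zip(bounds[:-1], bounds[1:]) if e > s]
    retained = [(s, e) for s, e in fragments if cfg.size_min <= e - s <= cfg.size_max]
    covered: list[CpGSite] = []
    for s, e in retained:
        for p in range(s, e):
            if seq[p : p + 2] == "CG":
                covered.append(CpGSite(chrom, p))
    return DigestResult(fragments, retained, covered)
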