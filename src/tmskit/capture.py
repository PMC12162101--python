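"""Capture-efficiency interval analytics.

Hybrid-capture panels are evaluated by how much of the sequenced material
lands on (or near) the probe footprint. The operations here are the
interval primitives those metrics reduce to: flank-expansion + merging of
probe sets, gap-tolerance classification of sites/fragments against a
reference set, per-base depth over a target, CpG counting in expanded
regions, and CpG island shore/shelf derivation.

All intervals are 0-based half-open; "within t bp" means the gap between
the query and the nearest reference interval on the same chromosome is
<= t, with overlap counting as gap 0 (the bedtools-style convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import CpGSite, GenomicInterval

__all__ = [
    "ProbeSet",
    "TargetSummary",
    "expand_merge",
    "proximity_mask",
    "expected_cpg_count",
    "base_coverage",
    "derive_shores_shelves",
    "subtract_intervals",
]


@dataclass
class ProbeSet:
    """Capture probes plus the flank (bp each side) defining the target."""

    intervals: list[GenomicInterval]
    flank: int = 200

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be >= 0")

    def target(self, chrom_lengths: Mapping[str, int] | None = None) -> list[GenomicInterval]:
        return expand_merge(self.intervals, self.flank, chrom_lengths)


@dataclass
class TargetSummary:
    n_query: int
    n_on_target: int
    empty_query: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.n_on_target > self.n_query:
            raise ValueError("n_on_target > n_query")
        self.empty_query = self.n_query == 0

    @property
    def fraction_on_target(self) -> float:
        return self.n_on_target / self.n_query if self.n_query else 0.0


def _by_chrom(intervals: Sequence[GenomicInterval]) -> dict[str, np.ndarray]:
    """chrom -> (k, 2) array of [start, end), input order."""
    out: dict[str, list[list[int]]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append([iv.start, iv.end])
    return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}


def _merge_sorted(arr: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent [start, end) rows; arr need not be sorted."""
    if len(arr) == 0:
        return arr.reshape(0, 2)
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    merged = [arr[0].tolist()]
    for s, e in arr[1:]:
        if s <= merged[-1][1]:  # adjacent (s == end) merges too
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def expand_merge(
    intervals: Sequence[GenomicInterval],
    flank: int,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[GenomicInterval]:
    """Grow every interval by ``flank`` bp each side, clip at 0 (and the
    chromosome end if lengths are given), and merge overlapping or
    adjacent results. Output is sorted and disjoint."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out: list[GenomicInterval] = []
    for chrom in sorted(_by_chrom(intervals)):
        arr = _by_chrom(intervals)[chrom]
        arr = arr.copy()
        arr[:, 0] = np.maximum(arr[:, 0] - flank, 0)
        arr[:, 1] = arr[:, 1] + flank
        if chrom_lengths is not None:
            if chrom not in chrom_lengths:
                raise KeyError(f"no length for chromosome {chrom!r}")
            arr[:, 1] = np.minimum(arr[:, 1], chrom_lengths[chrom])
            arr = arr[arr[:, 0] < arr[:, 1]]
        for s, e in _merge_sorted(arr):
            out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


def _as_query_arrays(
    query: Sequence[GenomicInterval] | Sequence[CpGSite],
) -> tuple[list[str], np.ndarray, np.ndarray]:
    chroms, starts, ends = [], [], []
    for q in query:
        if isinstance(q, CpGSite):
            chroms.append(q.chrom)
            starts.append(q.pos0)
            ends.append(q.pos0 + 1)
        else:
            chroms.append(q.chrom)
            starts.append(q.start)
            ends.append(q.end)
    return chroms, np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def proximity_mask(
    query: Sequence[GenomicInterval] | Sequence[CpGSite],
    reference: Sequence[GenomicInterval],
    tol: int = 200,
) -> tuple[np.ndarray, TargetSummary]:
    """Boolean on-target mask per query element, plus a summary.

    A query is on-target iff its gap to the nearest reference interval on
    the same chromosome is <= ``tol`` (overlap => gap 0). Point sites are
    treated as length-1 intervals. ``tol=0`` is plain overlap, used for
    the probe-covered-by-fragments metric.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    ref = {c: _merge_sorted(a) for c, a in _by_chrom(reference).items()}
    chroms, qs, qe = _as_query_arrays(query)
    mask = np.zeros(len(chroms), dtype=bool)
    order: dict[str, list[int]] = {}
    for i, c in enumerate(chroms):
        order.setdefault(c, []).append(i)
    for chrom, idx in order.items():
        if chrom not in ref:
            continue
        r = ref[chrom]
        rs, re = r[:, 0], r[:, 1]
        idx = np.asarray(idx)
        s, e = qs[idx], qe[idx]
        # nearest interval is either the last starting before the query end
        # or the first ending after the query start
        j = np.searchsorted(rs, e, side="right") - 1  # candidate on the left
        left_gap = np.full(len(idx), np.iinfo(np.int64).max, dtype=np.int64)
        ok = j >= 0
        left_gap[ok] = np.maximum(s[ok] - re[j[ok]], 0)
        k = np.searchsorted(re, s, side="right")  # candidate on the right
        right_gap = np.full(len(idx), np.iinfo(np.int64).max, dtype=np.int64)
        ok = k < len(rs)
        right_gap[ok] = np.maximum(rs[k[ok]] - e[ok], 0)
        mask[idx] = np.minimum(left_gap, right_gap) <= tol
    return mask, TargetSummary(n_query=len(chroms), n_on_target=int(mask.sum()))


def expected_cpg_count(
    probe_bed: Sequence[GenomicInterval],
    genome: Mapping[str, str] | str | Path,
    flank: int = 200,
) -> int:
    """Count CG dinucleotides in the merged, flank-expanded probe regions.

    Regions are expanded and merged first so a CG covered by two probes
    counts once; a CG straddling a region boundary counts iff its C (the
    plus-strand C of the dinucleotide) lies inside the region. ``genome``
    is a FASTA path or a chrom -> sequence mapping.
    """
    seqs = _load_genome(genome)
    lengths = {c: len(s) for c, s in seqs.items()}
    for iv in probe_bed:
        if iv.chrom not in seqs:
            raise KeyError(f"chromosome {iv.chrom!r} absent from genome")
    total = 0
    for region in expand_merge(probe_bed, flank, lengths):
        seq = seqs[region.chrom]
        # include one base past the end: a C at end-1 pairs with the G outside
        window = seq[region.start : min(region.end + 1, len(seq))].upper()
        total += sum(
            1
            for i in range(min(len(window) - 1, region.end - region.start))
            if window[i] == "C" and window[i + 1] == "G"
        )
    return total


def _load_genome(genome: Mapping[str, str] | str | Path) -> Mapping[str, str]:
    if isinstance(genome, (str, Path)):
        from pyfaidx import Fasta

        fa = Fasta(str(genome))
        return {name: str(fa[name][:]) for name in fa.keys()}
    return genome


def base_coverage(
    fragments: Sequence[GenomicInterval],
    target: Sequence[GenomicInterval],
) -> tuple[float, float]:
    """Mean and median per-base fragment depth over a merged target.

    Depth at a target base is the number of fragments covering it;
    bases outside the target are ignored. Raises on an empty target.
    """
    if not target:
        raise ValueError("empty target")
    frag = _by_chrom(fragments)
    depths: list[np.ndarray] = []
    for t in target:
        d = np.zeros(t.end - t.start, dtype=np.int64)
        arr = frag.get(t.chrom)
        if arr is not None:
            s = np.clip(arr[:, 0], t.start, t.end) - t.start
            e = np.clip(arr[:, 1], t.start, t.end) - t.start
            keep = e > s
            np.add.at(d, s[keep], 1)
            ends = e[keep]
            inside = ends < len(d)
            np.subtract.at(d, ends[inside], 1)
            d = np.cumsum(d)
        depths.append(d)
    all_d = np.concatenate(depths)
    return float(all_d.mean()), float(np.median(all_d))


def subtract_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Set difference a \\ b on merged interval sets, per chromosome."""
    a_m = {c: _merge_sorted(v) for c, v in _by_chrom(a).items()}
    b_m = {c: _merge_sorted(v) for c, v in _by_chrom(b).items()}
    out: list[GenomicInterval] = []
    for chrom in sorted(a_m):
        cuts = b_m.get(chrom, np.empty((0, 2), dtype=np.int64))
        for s, e in a_m[chrom]:
            pos = s
            for cs, ce in cuts:
                if ce <= pos or cs >= e:
                    continue
                if cs > pos:
                    out.append(GenomicInterval(chrom, int(pos), int(cs)))
                pos = max(pos, ce)
                if pos >= e:
                    break
            if pos < e:
                out.append(GenomicInterval(chrom, int(pos), int(e)))
    return out


def derive_shores_shelves(
    islands: Sequence[GenomicInterval],
    shore_bp: int = 2000,
    shelf_bp: int = 4000,
) -> dict[str, list[GenomicInterval]]:
    """Derive CpG shore and shelf annotations from island intervals.

    Shores are bases within ``shore_bp`` of an island boundary and not in
    any island; shelves are bases within (shore_bp, shelf_bp] and in
    neither island nor shore. Precedence island > shore > shelf resolves
    collisions between neighboring islands; everything clips at 0.
    """
    island_m = expand_merge(islands, 0)
    shore_zone = expand_merge(islands, shore_bp)
    shelf_zone = expand_merge(islands, shelf_bp)
    shores = subtract_intervals(shore_zone, island_m)
    shelves = subtract_intervals(subtract_intervals(shelf_zone, shore_zone), island_m)
    return {"island": island_m, "shore": shores, "shelf": shelves}
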