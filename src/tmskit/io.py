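"""Readers/writers for the text formats the pipeline touches.

Coordinate conventions, applied once here and nowhere else:

* BED intervals are 0-based, half-open ``[start, end)``.
* Cytosine reports (Bismark CpG-report dialect) are 1-based.
* Internal CpG site keys are 0-based positions of the **plus-strand C**
  of the CG dinucleotide; :func:`collapse_strands` is the single point
  where the per-strand 1-based records are folded onto that key.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import pandas as pd

__all__ = [
    "GenomicInterval",
    "CytosineRecord",
    "CpGSite",
    "MethParseError",
    "parse_cytosine_report",
    "write_cytosine_report",
    "parse_bed",
    "write_bed",
    "collapse_strands",
    "read_sample_sheet",
    "normalize_chrom",
]

_CONTEXTS = {"CG": "CpG", "CPG": "CpG", "CHG": "CHG", "CHH": "CHH"}
_STRANDS = {"+", "-"}


class MethParseError(ValueError):
    """Malformed input line; the message names the offending line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine-report line: per-cytosine counts, 1-based position."""

    chrom: str
    pos1: int
    strand: str
    M: int
    U: int
    context: str

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")
        if self.M < 0 or self.U < 0:
            raise ValueError("negative count")
        if self.context not in ("CpG", "CHG", "CHH"):
            raise ValueError(f"bad context {self.context!r}")


@dataclass(frozen=True, order=True)
class CpGSite:
    """Canonical site key: 0-based plus-strand C of a CG dinucleotide."""

    chrom: str
    pos0: int

    def __post_init__(self) -> None:
        if self.pos0 < 0:
            raise ValueError(f"negative position {self.pos0}")


def _open(source: str | Path | TextIO) -> tuple[TextIO, bool]:
    if isinstance(source, (str, Path)):
        return open(source, "rt"), True
    return source, False


def parse_cytosine_report(source: str | Path | TextIO) -> list[CytosineRecord]:
    """Parse a Bismark-style cytosine report (TSV, 1-based positions).

    Columns: chrom, position, strand, methylated count, unmethylated
    count, context; a 7th trinucleotide column is ignored. Raises
    :class:`MethParseError` naming the line number on malformed input.
    """
    fh, close = _open(source)
    records: list[CytosineRecord] = []
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise MethParseError(f"line {lineno}: expected >=6 columns, got {len(fields)}")
            chrom, pos_s, strand, m_s, u_s, ctx = fields[:6]
            try:
                pos1, m, u = int(pos_s), int(m_s), int(u_s)
            except ValueError:
                raise MethParseError(f"line {lineno}: non-integer position or count") from None
            if pos1 < 1:
                raise MethParseError(f"line {lineno}: position {pos1} < 1")
            if m < 0 or u < 0:
                raise MethParseError(f"line {lineno}: negative count")
            if strand not in _STRANDS:
                raise MethParseError(f"line {lineno}: unknown strand {strand!r}")
            ctx_norm = _CONTEXTS.get(ctx.upper())
            if ctx_norm is None:
                raise MethParseError(f"line {lineno}: unknown context {ctx!r}")
            records.append(CytosineRecord(chrom, pos1, strand, m, u, ctx_norm))
    finally:
        if close:
            fh.close()
    return records


def write_cytosine_report(records: Iterable[CytosineRecord], dest: str | Path | TextIO) -> None:
    """Write records in the same dialect :func:`parse_cytosine_report` reads."""
    fh, close = (open(dest, "wt"), True) if isinstance(dest, (str, Path)) else (dest, False)
    ctx_out = {"CpG": "CG", "CHG": "CHG", "CHH": "CHH"}
    try:
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos1}\t{r.strand}\t{r.M}\t{r.U}\t{ctx_out[r.context]}\n")
    finally:
        if close:
            fh.close()


_BED_SKIP = ("track", "browser", "#")


def parse_bed(source: str | Path | TextIO) -> list[GenomicInterval]:
    """Parse BED3/BED6; ``track``/``browser``/``#`` lines are skipped,
    columns beyond six ignored."""
    fh, close = _open(source)
    out: list[GenomicInterval] = []
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise MethParseError(f"line {lineno}: BED needs >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise MethParseError(f"line {lineno}: non-integer coordinate") from None
            if start < 0:
                raise MethParseError(f"line {lineno}: negative coordinate")
            if start >= end:
                raise MethParseError(f"line {lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else None
            out.append(GenomicInterval(chrom, start, end, name=name, strand=strand))
    finally:
        if close:
            fh.close()
    return out


def write_bed(intervals: Iterable[GenomicInterval], dest: str | Path | TextIO) -> None:
    fh, close = (open(dest, "wt"), True) if isinstance(dest, (str, Path)) else (dest, False)
    try:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand is not None:
                cols += [iv.name or ".", "0", iv.strand or "."]
            fh.write("\t".join(cols) + "\n")
    finally:
        if close:
            fh.close()


def collapse_strands(
    records: Iterable[CytosineRecord], collapse: bool = True
) -> dict[CpGSite, tuple[int, int]]:
    """Fold CpG-context records onto canonical dinucleotide site keys.

    CpG methylation is palindromically symmetric, so the minus-strand C at
    1-based position p reports on the dinucleotide whose plus-strand C sits
    at 1-based p-1; counts from the two strands are summed. Output is keyed
    by the 0-based plus-strand C position. Non-CpG-context records are
    dropped (they are QC substrate, not sites). With ``collapse=False``
    each strand keeps its own key (minus-strand key = its own 0-based
    position), for per-strand QC.
    """
    out: dict[CpGSite, tuple[int, int]] = {}
    for r in records:
        if r.context != "CpG":
            continue
        if r.strand == "+":
            pos0 = r.pos1 - 1
        elif collapse:
            if r.pos1 < 2:
                raise ValueError(
                    f"minus-strand CpG record at position {r.pos1} has no valid partner"
                )
            pos0 = r.pos1 - 2
        else:
            pos0 = r.pos1 - 1
        key = CpGSite(r.chrom, pos0)
        m, u = out.get(key, (0, 0))
        out[key] = (m + r.M, u + r.U)
    return out


def read_sample_sheet(source: str | Path | TextIO) -> pd.DataFrame:
    """Read a sample sheet TSV (columns: sample, file, group, tissue,
    technology; only ``sample`` is mandatory), indexed by sample ID."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    if "sample" not in df.columns:
        raise MethParseError("sample sheet must have a 'sample' column")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise MethParseError(f"duplicate sample IDs in sheet: {dups}")
    return df.set_index("sample")


def normalize_chrom(name: str) -> str:
    """Strip a leading 'chr' prefix. Off by default everywhere: chromosome
    matching is exact string equality unless a caller opts in."""
    return name[3:] if name.startswith("chr") else name
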