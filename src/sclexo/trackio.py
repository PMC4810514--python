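"""Core data types and file I/O for single-CpG signal pipelines.

Coordinate contract
-------------------
Everything in memory is **0-based, half-open** ``[start, end)``, BED-style.
The only place 1-based coordinates appear is wiggle text: ``write_wig``
emits ``internal position + 1`` and ``read_wig`` inverts that exactly, so
``read_wig(write_wig(t)) == t``.

A *canonical CpG position* is the 0-based position of the forward-strand C
of the palindromic CpG dinucleotide; reads from either strand that resolve
to the same CpG report the same canonical position.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file does not conform to its declared format."""


VALID_STRANDS = ("+", "-", ".")

_NON_ACGTN = re.compile(r"[^ACGTN]")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class ReferenceSequence:
    """A named chromosome sequence over the {A,C,G,T,N} alphabet."""

    chrom: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) == 0:
            raise ValueError("reference sequence must be non-empty")
        if _NON_ACGTN.search(self.seq):
            raise ValueError("reference sequence must be uppercase ACGTN")

    def __len__(self) -> int:
        return len(self.seq)

    def cpg_sites(self) -> np.ndarray:
        """0-based positions i with seq[i] == 'C' and seq[i+1] == 'G'."""
        arr = np.frombuffer(self.seq.encode("ascii"), dtype=np.uint8)
        hits = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
        return np.flatnonzero(hits)


@dataclass(frozen=True)
class AlignedRead:
    """A stranded aligned read; ``read_seq`` is 5'->3' of the sequenced strand."""

    interval: GenomicInterval
    read_seq: str
    replicate_id: str = "rep1"

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("aligned reads must be stranded (+ or -)")
        if len(self.read_seq) != len(self.interval):
            raise ValueError(
                f"read_seq length {len(self.read_seq)} does not match interval "
                f"length {len(self.interval)}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand


class CpGSignalTrack:
    """Sparse per-chromosome map of canonical CpG position -> integer coverage.

    Only strictly positive coverages are stored; setting a position to 0
    removes it.  Equality compares the full sparse content.
    """

    def __init__(self, data: Optional[Dict[str, Dict[int, int]]] = None) -> None:
        self._data: Dict[str, Dict[int, int]] = {}
        if data:
            for chrom, sub in data.items():
                for pos, cov in sub.items():
                    self.set(chrom, int(pos), int(cov))

    # -- mutation ----------------------------------------------------------
    def add(self, chrom: str, pos: int, count: int = 1) -> None:
        self.set(chrom, pos, self.get(chrom, pos) + count)

    def set(self, chrom: str, pos: int, coverage: int) -> None:
        if coverage < 0:
            raise ValueError("coverage must be non-negative")
        if coverage == 0:
            self._data.get(chrom, {}).pop(pos, None)
            if chrom in self._data and not self._data[chrom]:
                del self._data[chrom]
        else:
            self._data.setdefault(chrom, {})[pos] = coverage

    # -- access ------------------------------------------------------------
    def get(self, chrom: str, pos: int, default: int = 0) -> int:
        return self._data.get(chrom, {}).get(pos, default)

    def chroms(self) -> List[str]:
        return sorted(self._data)

    def positions(self, chrom: str) -> np.ndarray:
        return np.array(sorted(self._data.get(chrom, {})), dtype=np.int64)

    def items(self) -> Iterator[Tuple[str, int, int]]:
        for chrom in self.chroms():
            sub = self._data[chrom]
            for pos in sorted(sub):
                yield chrom, pos, sub[pos]

    def n_positions(self) -> int:
        return sum(len(sub) for sub in self._data.values())

    def total_coverage(self) -> int:
        return sum(cov for sub in self._data.values() for cov in sub.values())

    def to_dict(self) -> Dict[str, Dict[int, int]]:
        return {chrom: dict(sub) for chrom, sub in self._data.items()}

    def filter_coverage(self, min_coverage: int, strict: bool = False) -> "CpGSignalTrack":
        """Positions passing the coverage threshold (``>`` if strict, else ``>=``)."""
        out = CpGSignalTrack()
        for chrom, pos, cov in self.items():
            if (cov > min_coverage) if strict else (cov >= min_coverage):
                out.set(chrom, pos, cov)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CpGSignalTrack):
            return NotImplemented
        return self._data == other._data

    def __repr__(self) -> str:
        return f"CpGSignalTrack({self.n_positions()} positions on {len(self._data)} chroms)"


class ScoreTrack:
    """Sparse per-chromosome map of position -> finite real score."""

    def __init__(self, data: Optional[Dict[str, Dict[int, float]]] = None) -> None:
        self._data: Dict[str, Dict[int, float]] = {}
        if data:
            for chrom, sub in data.items():
                for pos, score in sub.items():
                    self.set(chrom, int(pos), float(score))

    def set(self, chrom: str, pos: int, score: float) -> None:
        if not np.isfinite(score):
            raise ValueError("scores must be finite")
        self._data.setdefault(chrom, {})[pos] = score

    def get(self, chrom: str, pos: int) -> Optional[float]:
        return self._data.get(chrom, {}).get(pos)

    def chroms(self) -> List[str]:
        return sorted(self._data)

    def items(self) -> Iterator[Tuple[str, int, float]]:
        for chrom in self.chroms():
            sub = self._data[chrom]
            for pos in sorted(sub):
                yield chrom, pos, sub[pos]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def xopen(path, mode: str = "rt"):
    """Open a text file, transparently handling ``.gz`` suffixes."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> List[ReferenceSequence]:
    """Read FASTA into reference sequences (uppercased, non-ACGTN -> N)."""
    seqs: List[ReferenceSequence] = []
    with xopen(path) as handle:
        first = handle.read(1)
        if first == "":
            raise FormatError(f"{path}: empty FASTA file")
        if first != ">":
            raise FormatError(f"{path}: FASTA must start with a '>' header")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            seq = _NON_ACGTN.sub("N", str(rec.seq).upper())
            if not rec.id:
                raise FormatError(f"{path}: FASTA record with empty header")
            if len(seq) == 0:
                raise FormatError(f"{path}: FASTA record {rec.id!r} has empty sequence")
            seqs.append(ReferenceSequence(chrom=rec.id, seq=seq))
    if not seqs:
        raise FormatError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: Iterable[ReferenceSequence], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.chrom, description="") for s in seqs]
    with xopen(path, "wt") as handle:
        SeqIO.write(records, handle, "fasta")
    del width  # Biopython wraps at its default; width kept for API stability


def read_bed(path) -> List[GenomicInterval]:
    """Read BED3+/BED6 into intervals, sorted by (chrom, start, end).

    Strand is honoured when a valid column 6 is present, else unstranded.
    ``track``/``browser``/comment lines are skipped.  A record with
    ``start >= end`` raises :class:`FormatError` naming the offending line.
    """
    intervals: List[GenomicInterval] = []
    with xopen(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise FormatError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            strand = "."
            if len(fields) >= 6 and fields[5] in ("+", "-"):
                strand = fields[5]
            intervals.append(GenomicInterval(chrom, start, end, strand))
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with xopen(path, "wt") as handle:
        for iv in intervals:
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def write_wig(track: CpGSignalTrack, path, name: Optional[str] = None) -> None:
    """Write a variableStep wiggle (1-based positions) for an integer track."""
    with xopen(path, "wt") as handle:
        if name:
            handle.write(f'track type=wiggle_0 name="{name}"\n')
        for chrom in track.chroms():
            handle.write(f"variableStep chrom={chrom}\n")
            sub = track.to_dict()[chrom]
            for pos in sorted(sub):
                handle.write(f"{pos + 1}\t{sub[pos]}\n")


_VSTEP = re.compile(r"^variableStep\s+chrom=(\S+)(?:\s+span=(\d+))?\s*$")
_FSTEP = re.compile(
    r"^fixedStep\s+chrom=(\S+)\s+start=(\d+)\s+step=(\d+)(?:\s+span=(\d+))?\s*$"
)


def _parse_wig(path, value_parser):
    """Shared variableStep/fixedStep wiggle parser; yields (chrom, pos0, value)."""
    with xopen(path) as handle:
        chrom: Optional[str] = None
        fixed: Optional[Tuple[int, int]] = None  # (next 1-based pos, step)
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            m = _VSTEP.match(line)
            if m:
                chrom, span = m.group(1), m.group(2)
                if span is not None and int(span) != 1:
                    raise FormatError(f"{path}: line {lineno}: only span=1 supported")
                fixed = None
                continue
            m = _FSTEP.match(line)
            if m:
                chrom = m.group(1)
                span = m.group(4)
                if span is not None and int(span) != 1:
                    raise FormatError(f"{path}: line {lineno}: only span=1 supported")
                fixed = (int(m.group(2)), int(m.group(3)))
                continue
            if chrom is None:
                raise FormatError(f"{path}: line {lineno}: data before step header")
            if fixed is not None:
                value = value_parser(line, path, lineno)
                pos1, step = fixed
                yield chrom, pos1 - 1, value
                fixed = (pos1 + step, step)
            else:
                parts = line.split()
                if len(parts) != 2:
                    raise FormatError(
                        f"{path}: line {lineno}: expected 'position value'"
                    )
                try:
                    pos1 = int(parts[0])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: non-integer position"
                    ) from exc
                yield chrom, pos1 - 1, value_parser(parts[1], path, lineno)


def _int_value(text: str, path, lineno: int) -> int:
    try:
        return int(text)
    except ValueError as exc:
        raise FormatError(
            f"{path}: line {lineno}: non-integer coverage {text!r}"
        ) from exc


def _float_value(text: str, path, lineno: int) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise FormatError(f"{path}: line {lineno}: non-numeric score {text!r}") from exc


def read_wig(path) -> CpGSignalTrack:
    """Read a (variable/fixed step) wiggle of integer coverages; inverse of write_wig."""
    track = CpGSignalTrack()
    for chrom, pos, value in _parse_wig(path, _int_value):
        if value != 0:
            track.set(chrom, pos, value)
    return track


def read_score_wig(path) -> ScoreTrack:
    """Read a wiggle of real-valued scores (e.g. per-base conservation)."""
    track = ScoreTrack()
    for chrom, pos, value in _parse_wig(path, _float_value):
        track.set(chrom, pos, value)
    return track


def read_bedgraph_scores(path) -> ScoreTrack:
    """Read a bedGraph, expanding each interval to per-position scores."""
    track = ScoreTrack()
    with xopen(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 bedGraph columns")
            chrom, start, end, score = (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                float(fields[3]),
            )
            if start >= end:
                raise FormatError(f"{path}: line {lineno}: start >= end")
            for pos in range(start, end):
                track.set(chrom, pos, score)
    return track


# ---------------------------------------------------------------------------
# Aligned-read TSV
# ---------------------------------------------------------------------------

READ_TSV_COLUMNS = ["chrom", "start", "end", "strand", "read_seq", "replicate_id"]


def read_aligned_reads(path) -> List[AlignedRead]:
    """Read the documented aligned-read TSV (header: chrom start end strand read_seq replicate_id)."""
    df = pd.read_csv(xopen(path), sep="\t", dtype={"chrom": str, "replicate_id": str})
    missing = [c for c in READ_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    reads = []
    for row in df.itertuples(index=False):
        reads.append(
            AlignedRead(
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
                read_seq=str(row.read_seq),
                replicate_id=str(row.replicate_id),
            )
        )
    return reads


def write_aligned_reads(reads: Sequence[AlignedRead], path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in reads],
            "start": [r.start for r in reads],
            "end": [r.end for r in reads],
            "strand": [r.strand for r in reads],
            "read_seq": [r.read_seq for r in reads],
            "replicate_id": [r.replicate_id for r in reads],
        }
    )
    with xopen(path, "wt") as handle:
        df.to_csv(handle, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Interval membership / blacklist filtering
# ---------------------------------------------------------------------------

class IntervalIndex:
    """Merged, sorted interval arrays per chromosome for O(log n) membership."""

    def __init__(self, intervals: Iterable[GenomicInterval]) -> None:
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._index: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: List[Tuple[int, int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            starts = np.array([s for s, _ in merged], dtype=np.int64)
            ends = np.array([e for _, e in merged], dtype=np.int64)
            self._index[chrom] = (starts, ends)

    def contains(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean membership for an array of positions on one chromosome."""
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in self._index or positions.size == 0:
            return np.zeros(positions.shape, dtype=bool)
        starts, ends = self._index[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(positions.shape, dtype=bool)
        inside[ok] = positions[ok] < ends[idx[ok]]
        return inside


def subtract_blacklist(
    track: CpGSignalTrack, blacklist: Sequence[GenomicInterval]
) -> CpGSignalTrack:
    """Remove every track position that falls inside any blacklist interval."""
    index = IntervalIndex(blacklist)
    out = CpGSignalTrack()
    for chrom in track.chroms():
        pos = track.positions(chrom)
        keep = ~index.contains(chrom, pos)
        sub = track.to_dict()[chrom]
        for p in pos[keep]:
            out.set(chrom, int(p), sub[int(p)])
    return out


def cap_coverage_quantile(track: CpGSignalTrack, quantile: float) -> CpGSignalTrack:
    """Drop positions whose coverage exceeds the given coverage quantile.

    Optional cleanup for extreme-signal positions that no curated blacklist
    covers; off by default in the CLI (no principled universal threshold
    exists, so the cutoff is user-supplied).
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    covs = np.array([cov for _, _, cov in track.items()])
    if covs.size == 0:
        return CpGSignalTrack()
    cutoff = float(np.quantile(covs, quantile))
    out = CpGSignalTrack()
    for chrom, pos, cov in track.items():
        if cov <= cutoff:
            out.set(chrom, pos, cov)
    return out
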