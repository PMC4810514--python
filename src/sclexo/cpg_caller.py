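"""Classify exonuclease-trimmed reads by the CpG content of their 5' window.

A read whose first ``window_len`` (default 10) bases contain exactly one
CpG identifies that CpG as hydroxymethylated (an *id CpG*): the exonuclease
stalls just upstream of the protected cytosine, so the read 5' end pins the
site at single-CpG resolution.  Reads with two or more window CpGs are
ambiguous (*probable CpG*) and are kept in a separate track that downstream
consensus calling ignores; reads with cytosines but no CpG in the window
(*CpH*) form a negative-control track; the remainder carry no window C.

The window test always runs on the read-oriented sequence (the 5' end is
the exonuclease-trimmed end of the sequenced strand), and id CpG positions
are reported canonically as the forward-strand C, so the two strands of a
palindromic CpG accumulate into the same track position.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Mapping, Optional, Sequence, Union

from .trackio import AlignedRead, CpGSignalTrack, ReferenceSequence

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class ReadClass(Enum):
    ID_CPG = "id_cpg"
    PROBABLE_CPG = "probable_cpg"
    CPH = "cph"
    NO_C = "no_c"


@dataclass
class CallerConfig:
    """Window length (bases from the 5' end) and reporting threshold."""

    window_len: int = 10
    min_coverage: int = 1

    def __post_init__(self) -> None:
        if self.window_len < 2:
            raise ValueError("window_len must be >= 2")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


@dataclass(frozen=True)
class ReadCall:
    """Classification outcome; ``position`` is canonical for CpG classes."""

    read_class: ReadClass
    chrom: str
    position: Optional[int] = None


ReferenceLike = Union[ReferenceSequence, Mapping[str, ReferenceSequence], None]


def _ref_base(reference: ReferenceLike, chrom: str, pos: int) -> Optional[str]:
    if reference is None:
        return None
    if isinstance(reference, ReferenceSequence):
        ref = reference if reference.chrom == chrom else None
    else:
        ref = reference.get(chrom)
    if ref is None or not 0 <= pos < len(ref):
        return None
    return ref.seq[pos]


def _genomic_pos(read: AlignedRead, read_index: int) -> int:
    """Genomic coordinate of read-oriented base ``read_index``."""
    if read.strand == "+":
        return read.start + read_index
    return read.end - 1 - read_index


def _next_base(read: AlignedRead, read_index: int, reference: ReferenceLike) -> Optional[str]:
    """Base following ``read_index`` in read orientation, via reference if off-read."""
    if read_index + 1 < len(read.read_seq):
        return read.read_seq[read_index + 1]
    # off the read 3' end: look one base further along the sequenced strand
    if read.strand == "+":
        base = _ref_base(reference, read.chrom, read.end)
        return base
    base = _ref_base(reference, read.chrom, read.start - 1)
    return _COMP.get(base) if base is not None else None


def classify_read(
    read: AlignedRead,
    cfg: Optional[CallerConfig] = None,
    reference: ReferenceLike = None,
) -> ReadCall:
    """Classify one read by its 5'-window CpG content.

    A window C whose following base would fall outside the read counts as a
    CpG only if a supplied reference confirms the G; without a reference it
    is treated as a CpH candidate (follower unknown, conservatively not a
    CpG).  The C of a CpG may sit on the window's last base with its G just
    outside the window: the C is the modifiable base the exonuclease stalls
    before, so it is in-window.
    """
    cfg = cfg or CallerConfig()
    seq = read.read_seq
    if len(seq) < 1:
        raise ValueError("read_seq must be non-empty")
    w = min(cfg.window_len, len(seq))

    cpg_hits: List[int] = []
    cph_hits: List[int] = []
    for i in range(w):
        if seq[i] != "C":
            continue
        nxt = _next_base(read, i, reference)
        if nxt == "G":
            cpg_hits.append(i)
        else:
            cph_hits.append(i)

    if len(cpg_hits) == 1:
        i = cpg_hits[0]
        g = _genomic_pos(read, i)
        canonical = g if read.strand == "+" else g - 1
        return ReadCall(ReadClass.ID_CPG, read.chrom, canonical)
    if len(cpg_hits) >= 2:
        i = cpg_hits[0]  # keyed by the 5'-most window CpG
        g = _genomic_pos(read, i)
        canonical = g if read.strand == "+" else g - 1
        return ReadCall(ReadClass.PROBABLE_CPG, read.chrom, canonical)
    if cph_hits:
        return ReadCall(ReadClass.CPH, read.chrom, _genomic_pos(read, cph_hits[0]))
    return ReadCall(ReadClass.NO_C, read.chrom, None)


@dataclass
class TrackBundle:
    """The three per-class signal tracks plus the class census."""

    id_track: CpGSignalTrack
    probable_track: CpGSignalTrack
    cph_track: CpGSignalTrack
    class_counts: Counter

    @property
    def n_reads(self) -> int:
        return sum(self.class_counts.values())


def build_tracks(
    reads: Sequence[AlignedRead],
    cfg: Optional[CallerConfig] = None,
    reference: ReferenceLike = None,
) -> TrackBundle:
    """Accumulate id / probable / CpH tracks from a read list.

    Coverage at an id CpG sums reads from both strands resolving to the same
    canonical position.  The four class counts always partition the input.
    """
    cfg = cfg or CallerConfig()
    id_track = CpGSignalTrack()
    probable_track = CpGSignalTrack()
    cph_track = CpGSignalTrack()
    counts: Counter = Counter({cls: 0 for cls in ReadClass})
    for read in reads:
        call = classify_read(read, cfg, reference)
        counts[call.read_class] += 1
        if call.read_class is ReadClass.ID_CPG:
            id_track.add(call.chrom, call.position)
        elif call.read_class is ReadClass.PROBABLE_CPG:
            probable_track.add(call.chrom, call.position)
        elif call.read_class is ReadClass.CPH:
            cph_track.add(call.chrom, call.position)
    return TrackBundle(id_track, probable_track, cph_track, counts)


def class_fractions(counts: Counter) -> Dict[str, float]:
    """Per-class fractions of all reads (sums to 1 over the four classes)."""
    total = sum(counts.values())
    if total == 0:
        return {cls.value: 0.0 for cls in ReadClass}
    return {cls.value: counts[cls] / total for cls in ReadClass}
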