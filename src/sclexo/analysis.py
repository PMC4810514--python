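"""Downstream analytics for single-CpG hydroxymethylation tracks.

Covers the validation toolkit around the caller: genome-wide Pearson
correlation of sparse coverage tracks, inclusion of called sites in
enrichment peaks, CpG-density stratification of signal, IUPAC motif
density metaprofiles around anchor sites (e.g. RCGY vs YCGR preference),
and conservation-score binning of called CpGs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .trackio import (
    CpGSignalTrack,
    GenomicInterval,
    IntervalIndex,
    ReferenceSequence,
    ScoreTrack,
    revcomp,
)


class UndefinedCorrelationError(ValueError):
    """Raised when Pearson r is undefined (too few pairs or zero variance)."""


IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


# ---------------------------------------------------------------------------
# Track correlation
# ---------------------------------------------------------------------------

def track_correlation(
    a: CpGSignalTrack,
    b: CpGSignalTrack,
    coverage_window: Optional[Tuple[int, int]] = None,
    mode: str = "union",
    dense_length: Optional[Dict[str, int]] = None,
) -> float:
    """Pearson r between two sparse coverage tracks.

    Positions are paired over the union of both tracks' positions with 0 for
    absent values (``mode="intersection"`` restricts to shared positions).
    ``mode="dense"`` pairs every position of the comparison domain, given as
    ``dense_length`` (chrom -> length): this is the genome-wide convention
    and is the statistically unbiased choice for near-disjoint tracks, where
    union pairing conditions on occupancy and anti-correlates singleton
    supports.  ``coverage_window=(lo, hi)`` keeps only positions whose
    coverage falls in ``[lo, hi]`` in at least one of the two tracks.
    """
    if mode not in ("union", "intersection", "dense"):
        raise ValueError("mode must be 'union', 'intersection' or 'dense'")
    if mode == "dense" and not dense_length:
        raise ValueError("mode='dense' requires dense_length (chrom -> length)")
    xs: List[int] = []
    ys: List[int] = []
    if mode == "dense":
        chroms = sorted(dense_length)
    else:
        chroms = sorted(set(a.chroms()) | set(b.chroms()))
    for chrom in chroms:
        pos_a = set(int(p) for p in a.positions(chrom))
        pos_b = set(int(p) for p in b.positions(chrom))
        if mode == "union":
            pos = pos_a | pos_b
        elif mode == "intersection":
            pos = pos_a & pos_b
        else:
            pos = range(dense_length[chrom])
        for p in pos:
            ca, cb = a.get(chrom, p), b.get(chrom, p)
            if coverage_window is not None:
                lo, hi = coverage_window
                if not (lo <= ca <= hi or lo <= cb <= hi):
                    continue
            xs.append(ca)
            ys.append(cb)
    if len(xs) < 2:
        raise UndefinedCorrelationError("fewer than 2 paired positions")
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.std() == 0.0 or y.std() == 0.0:
        raise UndefinedCorrelationError("zero variance in one of the tracks")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Peak inclusion
# ---------------------------------------------------------------------------

@dataclass
class InclusionResult:
    """How many thresholded track positions fall inside a peak set."""

    n_inside: int
    n_outside: int

    @property
    def n_total(self) -> int:
        return self.n_inside + self.n_outside

    @property
    def pct_inside(self) -> float:
        return 100.0 * self.n_inside / self.n_total if self.n_total else 0.0


def peak_inclusion(
    track: CpGSignalTrack,
    peaks: Sequence[GenomicInterval],
    min_coverage: int = 1,
) -> InclusionResult:
    """Fraction of track positions (coverage >= min_coverage) inside peaks."""
    filtered = track.filter_coverage(min_coverage)
    index = IntervalIndex(peaks)
    inside = outside = 0
    for chrom in filtered.chroms():
        pos = filtered.positions(chrom)
        hits = index.contains(chrom, pos)
        inside += int(hits.sum())
        outside += int((~hits).sum())
    return InclusionResult(n_inside=inside, n_outside=outside)


# ---------------------------------------------------------------------------
# CpG density stratification
# ---------------------------------------------------------------------------

def cpg_density_strata(
    track: CpGSignalTrack, ref: ReferenceSequence, window: int = 300
) -> pd.DataFrame:
    """Group track positions by local CpG density and average their signal.

    Density is the number of reference CpGs whose C lies inside the
    ``window``-base window centred on the position (the anchor CpG itself
    included; windows are clipped at chromosome ends).  Returns a frame
    indexed by density with columns ``n_positions`` and ``mean_signal``.
    """
    cpg = ref.cpg_sites()
    half = window // 2
    rows = []
    for chrom, pos, cov in track.items():
        if chrom != ref.chrom:
            continue
        lo = max(0, pos - half)
        hi = min(len(ref), pos + half)
        n = int(
            np.searchsorted(cpg, hi, side="left")
            - np.searchsorted(cpg, lo, side="left")
        )
        rows.append((n, cov))
    if not rows:
        return pd.DataFrame(columns=["n_positions", "mean_signal"]).rename_axis("density")
    df = pd.DataFrame(rows, columns=["density", "signal"])
    out = df.groupby("density")["signal"].agg(n_positions="size", mean_signal="mean")
    return out


# ---------------------------------------------------------------------------
# Motif metaprofiles
# ---------------------------------------------------------------------------

@dataclass
class MetaProfile:
    """Mean motif-occurrence indicator per signed offset around anchors."""

    offsets: np.ndarray
    density: np.ndarray
    n_anchors: int
    motif: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "density": self.density})


def _iupac_match_starts(seq: str, motif: str) -> np.ndarray:
    """Boolean array: does ``motif`` match ``seq`` starting at each position."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    L, k = len(seq), len(motif)
    out = np.zeros(L, dtype=bool)
    if L < k:
        return out
    hits = np.ones(L - k + 1, dtype=bool)
    for j, code in enumerate(motif):
        allowed = np.frombuffer(IUPAC[code.upper()].encode("ascii"), dtype=np.uint8)
        hits &= np.isin(arr[j : L - k + 1 + j], allowed)
    out[: L - k + 1] = hits
    return out


def motif_metaprofile(
    ref: ReferenceSequence,
    anchors: Iterable[int],
    motif: str = "RCGY",
    halfwidth: int = 50,
) -> MetaProfile:
    """Average motif density at each offset in [-halfwidth, +halfwidth].

    At each signed offset the profile holds the mean over anchors of the
    indicator that a motif instance *starts* there on either strand: forward
    instances start at their leftmost base; reverse-strand instances start
    at their 5' end, i.e. the rightmost genomic base of the reverse
    complement match.  Any IUPAC string is accepted (e.g. ``RCGY``,
    ``YCGR``, ``CG``).
    """
    anchors = [int(a) for a in anchors]
    if not anchors:
        raise ValueError("anchor set must be non-empty")
    motif = motif.upper()
    if any(c not in IUPAC for c in motif):
        raise ValueError(f"invalid IUPAC motif {motif!r}")
    L, k = len(ref), len(motif)
    if any(not 0 <= a < L for a in anchors):
        raise ValueError("anchors must lie within the reference")

    fwd = _iupac_match_starts(ref.seq, motif)
    rc_hits = _iupac_match_starts(ref.seq, revcomp(motif))
    rev = np.zeros(L, dtype=bool)
    # reverse-strand instance whose 5' end is at position q <=> rc match at q-k+1
    rev[k - 1 :] = rc_hits[: L - k + 1]
    either = fwd | rev

    offsets = np.arange(-halfwidth, halfwidth + 1)
    density = np.zeros(offsets.size, dtype=float)
    for a in anchors:
        idx = a + offsets
        ok = (idx >= 0) & (idx < L)
        density[ok] += either[idx[ok]]
    density /= len(anchors)
    return MetaProfile(offsets=offsets, density=density, n_anchors=len(anchors), motif=motif)


def signal_metaprofile(
    scores: ScoreTrack, chrom: str, anchors: Iterable[int], halfwidth: int = 50
) -> MetaProfile:
    """Mean of an arbitrary per-base score at each offset around anchors.

    Positions without a score contribute 0; generic companion to
    :func:`motif_metaprofile` for score tracks (conservation, ChIP signal).
    """
    anchors = [int(a) for a in anchors]
    if not anchors:
        raise ValueError("anchor set must be non-empty")
    offsets = np.arange(-halfwidth, halfwidth + 1)
    density = np.zeros(offsets.size, dtype=float)
    for a in anchors:
        for j, o in enumerate(offsets):
            val = scores.get(chrom, a + int(o))
            if val is not None:
                density[j] += val
    density /= len(anchors)
    return MetaProfile(offsets=offsets, density=density, n_anchors=len(anchors), motif="<score>")


# ---------------------------------------------------------------------------
# Score binning
# ---------------------------------------------------------------------------

@dataclass
class ScoreBinResult:
    """Partition of track positions into score bins (plus an unscored bin)."""

    table: pd.DataFrame  # indexed by bin label: n, fraction, mean_signal, mean_score
    positions: Dict[str, Set[Tuple[str, int]]]


def score_bin(
    track: CpGSignalTrack,
    scores: ScoreTrack,
    edges: Sequence[float] = (0.0, 0.075, 0.75, 1.0),
) -> ScoreBinResult:
    """Partition track positions by score into half-open bins.

    Bins are ``[e_i, e_{i+1})`` with the top bin closed (a score equal to
    the last edge belongs to the top bin).  Positions without a score go to
    a separate ``"unscored"`` bin; scores outside ``[edges[0], edges[-1]]``
    raise.
    """
    edges = list(edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing with >= 2 values")
    labels = [f"[{a:g}, {b:g})" for a, b in zip(edges, edges[1:])]
    labels[-1] = labels[-1][:-1] + "]"
    edge_arr = np.asarray(edges, dtype=float)

    members: Dict[str, List[Tuple[str, int, int, Optional[float]]]] = {
        lab: [] for lab in labels
    }
    members["unscored"] = []
    for chrom, pos, cov in track.items():
        s = scores.get(chrom, pos)
        if s is None:
            members["unscored"].append((chrom, pos, cov, None))
            continue
        if s < edges[0] or s > edges[-1]:
            raise ValueError(f"score {s} at {chrom}:{pos} outside bin range")
        i = int(np.searchsorted(edge_arr, s, side="right")) - 1
        i = min(i, len(labels) - 1)  # top edge belongs to the last bin
        members[labels[i]].append((chrom, pos, cov, s))

    n_scored = sum(len(v) for lab, v in members.items() if lab != "unscored")
    rows = []
    positions: Dict[str, Set[Tuple[str, int]]] = {}
    for lab in labels + ["unscored"]:
        entries = members[lab]
        positions[lab] = {(c, p) for c, p, _, _ in entries}
        covs = [cov for _, _, cov, _ in entries]
        svals = [s for _, _, _, s in entries if s is not None]
        rows.append(
            {
                "bin": lab,
                "n": len(entries),
                "fraction": (len(entries) / n_scored if n_scored and lab != "unscored" else np.nan),
                "mean_signal": float(np.mean(covs)) if covs else np.nan,
                "mean_score": float(np.mean(svals)) if svals else np.nan,
            }
        )
    table = pd.DataFrame(rows).set_index("bin")
    return ScoreBinResult(table=table, positions=positions)
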