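"""Replicate-consensus calling of hydroxymethylated CpGs.

A site is a *consensus id CpG* when it clears the coverage threshold in at
least ``min_replicates`` of the technical replicates (default: more than
8x coverage in at least two of three).  The consensus signal is the sum of
coverages over all replicates at kept positions, preserving the total read
evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .trackio import CpGSignalTrack


@dataclass
class ConsensusConfig:
    """Thresholds of the replicate-consensus rule.

    ``strict=True`` applies the coverage test as ``coverage > min_coverage``
    ("covered more than 8x"); set ``strict=False`` for the ``>=`` convention
    used by some other pipelines.
    """

    min_coverage: int = 8
    min_replicates: int = 2
    n_replicates: int = 3
    strict: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.min_replicates <= self.n_replicates:
            raise ValueError("need 1 <= min_replicates <= n_replicates")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


def call_consensus(
    tracks: Sequence[CpGSignalTrack], cfg: ConsensusConfig | None = None
) -> CpGSignalTrack:
    """Positions supported by >= min_replicates replicates at the coverage cut.

    The returned signal at a kept position is the sum of coverages across
    all replicates (including replicates below the per-replicate cut).
    """
    cfg = cfg or ConsensusConfig()
    if len(tracks) != cfg.n_replicates:
        raise ValueError(
            f"expected {cfg.n_replicates} replicate tracks, got {len(tracks)}"
        )
    out = CpGSignalTrack()
    chroms = sorted({c for t in tracks for c in t.chroms()})
    for chrom in chroms:
        positions = sorted({int(p) for t in tracks for p in t.positions(chrom)})
        for pos in positions:
            covs = [t.get(chrom, pos) for t in tracks]
            if cfg.strict:
                support = sum(1 for c in covs if c > cfg.min_coverage)
            else:
                support = sum(1 for c in covs if c >= cfg.min_coverage)
            if support >= cfg.min_replicates:
                out.set(chrom, pos, sum(covs))
    return out


@dataclass
class OverlapResult:
    """Venn counts and percentages for two replicate position sets."""

    n_both: int
    n_a_only: int
    n_b_only: int

    @property
    def n_union(self) -> int:
        return self.n_both + self.n_a_only + self.n_b_only

    @property
    def pct_overlap(self) -> float:
        """Jaccard-style percentage: shared positions over the union."""
        return 100.0 * self.n_both / self.n_union if self.n_union else 0.0

    @property
    def pct_a_in_b(self) -> float:
        n_a = self.n_both + self.n_a_only
        return 100.0 * self.n_both / n_a if n_a else 0.0

    @property
    def pct_b_in_a(self) -> float:
        n_b = self.n_both + self.n_b_only
        return 100.0 * self.n_both / n_b if n_b else 0.0


def replicate_overlap(
    track_a: CpGSignalTrack,
    track_b: CpGSignalTrack,
    min_coverage: int = 1,
    strict: bool = False,
) -> OverlapResult:
    """Venn decomposition of two replicates' positions at a coverage cut.

    Filtering uses ``>=`` by default (the convention of coverage-thresholded
    replicate comparisons); pass ``strict=True`` for ``>``.
    """
    a = {
        (chrom, int(p))
        for chrom in track_a.chroms()
        for p in track_a.filter_coverage(min_coverage, strict).positions(chrom)
    }
    b = {
        (chrom, int(p))
        for chrom in track_b.chroms()
        for p in track_b.filter_coverage(min_coverage, strict).positions(chrom)
    }
    return OverlapResult(
        n_both=len(a & b), n_a_only=len(a - b), n_b_only=len(b - a)
    )
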