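"""Synthetic read generation for selective-chemical-labeling exonuclease assays.

The generator emulates the SCL-exo library chemistry: sonicated fragments
are captured on beads when at least one CpG cytosine on a strand carries a
biotinylated glucosyl-5hmC, then a 5'->3' exonuclease trims the captured
strand until it stalls just upstream of the first bead-bound modified
cytosine.  Three failure modes are modelled per molecule:

``undigested``
    the exonuclease never engages; the read starts at the fragment 5' end.
``read-through``
    the first modified C is not protected (failed glucosylation /
    biotinylation / bead binding) and digestion proceeds past it, stalling
    at a later modified C if one exists.
``stall``
    digestion stops ``delta`` bases upstream of the first modified C, with
    ``delta`` drawn from a truncated geometric distribution (default mean
    3, support 0..10 — the empirically observed stall window).

Genomic capture additionally models a nonspecific background fraction
(``p_background``): fragments bound to the beads without any biotinylated
CpG.  Their reads start at the fragment 5' end (undigested) or at a
uniform exonuclease drop-off point, contributing the diffuse, replicate-
irreproducible CpH/no-C read mass seen in real libraries; the fraction
defaults to 0.5, which approximately reproduces the observed read-class
census (~42 % single-CpG, ~47 % CpH).  A specifically captured molecule
whose only protected cytosine fails (read-through) is destroyed by the
processive exonuclease and yields no read.

Defaults for the failure probabilities are the estimates obtained from the
fully hydroxymethylated 224-bp PCR standard: 12.38 % undigested and
51.04 % read-through.  The standard simulation itself takes no background
fraction: a uniformly hydroxymethylated template makes nonspecific and
specific capture indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.special import softmax

from .trackio import AlignedRead, GenomicInterval, ReferenceSequence, revcomp

#: Source locus of the 224-bp fully hydroxymethylated PCR standard
#: (mm8, 1-based inclusive chr3:93,697,590-93,697,813; stored 0-based half-open).
STANDARD_SOURCE_INTERVAL = GenomicInterval("chr3", 93_697_589, 93_697_813)

_UNDIGESTED, _READTHROUGH, _STALL = 0, 1, 2


# ---------------------------------------------------------------------------
# Configuration and ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Tunable knobs of the read generator.

    Probabilities are per sequenced molecule; ``p_undigested + p_nostall``
    must not exceed 1 (the remainder is the stall probability).
    """

    p_undigested: float = 0.1238
    p_nostall: float = 0.5104
    p_background: float = 0.5
    stall_offset_mean: float = 3.0
    stall_offset_max: int = 10
    read_length: int = 50
    n_reads: int = 100_000
    n_replicates: int = 3
    fragment_length_range: Tuple[int, int] = (200, 500)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_undigested", "p_nostall", "p_background"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.p_undigested + self.p_nostall > 1.0 + 1e-12:
            raise ValueError("p_undigested + p_nostall must be <= 1")
        if not 0 <= self.stall_offset_mean <= self.stall_offset_max:
            raise ValueError("need 0 <= stall_offset_mean <= stall_offset_max")
        if self.read_length < 1 or self.n_reads < 1 or self.n_replicates < 1:
            raise ValueError("read_length, n_reads, n_replicates must be >= 1")
        lo, hi = self.fragment_length_range
        if not 1 <= lo <= hi:
            raise ValueError("fragment_length_range must satisfy 1 <= lo <= hi")

    @property
    def p_stall(self) -> float:
        return 1.0 - self.p_undigested - self.p_nostall


class Hydroxymethylome:
    """Per-CpG, per-strand hydroxymethylation levels (simulator ground truth)."""

    def __init__(
        self,
        levels: Optional[Dict[str, Dict[int, Tuple[float, float]]]] = None,
        reference: Optional[ReferenceSequence] = None,
    ) -> None:
        self._levels: Dict[str, Dict[int, Tuple[float, float]]] = {}
        if levels:
            cpg: Optional[Set[int]] = None
            if reference is not None:
                cpg = set(int(p) for p in reference.cpg_sites())
            for chrom, sub in levels.items():
                for pos, (lf, lr) in sub.items():
                    if not (0.0 <= lf <= 1.0 and 0.0 <= lr <= 1.0):
                        raise ValueError("hydroxymethylation levels must be in [0, 1]")
                    if cpg is not None and (chrom != reference.chrom or pos not in cpg):
                        raise ValueError(
                            f"{chrom}:{pos} is not a CpG site of the reference"
                        )
                    self._levels.setdefault(chrom, {})[int(pos)] = (float(lf), float(lr))

    def level(self, chrom: str, pos: int) -> Tuple[float, float]:
        return self._levels.get(chrom, {}).get(pos, (0.0, 0.0))

    def positions(self, chrom: str) -> np.ndarray:
        return np.array(sorted(self._levels.get(chrom, {})), dtype=np.int64)

    def chroms(self) -> List[str]:
        return sorted(self._levels)

    def n_sites(self) -> int:
        return sum(len(sub) for sub in self._levels.values())

    def to_dict(self) -> Dict[str, Dict[int, Tuple[float, float]]]:
        return {chrom: dict(sub) for chrom, sub in self._levels.items()}


@dataclass(frozen=True)
class StandardTemplate:
    """A fully hydroxymethylated PCR standard with unmodified primer ends.

    ``hm_positions_forward`` are 0-based positions of hydroxymethylated Cs on
    the forward strand; ``hm_positions_reverse`` are forward-strand positions
    of Gs whose reverse-strand complement C is hydroxymethylated.
    """

    seq: str
    primer_len_5p: int
    primer_len_3p: int
    hm_positions_forward: Tuple[int, ...]
    hm_positions_reverse: Tuple[int, ...]
    name: str = "standard"

    def __len__(self) -> int:
        return len(self.seq)

    def first_hm(self, strand: str) -> int:
        """Forward-strand coordinate of the strand's 5'-most hydroxymethylated C."""
        if strand == "+":
            return min(self.hm_positions_forward)
        return max(self.hm_positions_reverse)

    def hm_local(self, strand: str) -> np.ndarray:
        """Hydroxymethylated-C positions in strand-local (5'->3') coordinates."""
        L = len(self.seq)
        if strand == "+":
            return np.array(sorted(self.hm_positions_forward), dtype=np.int64)
        return np.array(
            sorted(L - 1 - p for p in self.hm_positions_reverse), dtype=np.int64
        )


@dataclass
class SimulatedReadSet:
    """Reads plus the ground truth needed for recovery testing.

    ``captured_hm`` holds, per replicate, the canonical positions of every
    biotinylated CpG carried by a captured fragment; ``anchors`` holds, per
    read (same order as ``reads``), the canonical CpG the read's 5' end was
    anchored to, or ``None`` for unanchored (undigested / pass-through)
    molecules.
    """

    reads: Dict[str, List[AlignedRead]]
    captured_hm: Dict[str, Set[Tuple[str, int]]]
    anchors: Dict[str, List[Optional[Tuple[str, int]]]]

    def all_reads(self) -> List[AlignedRead]:
        return [r for rep in sorted(self.reads) for r in self.reads[rep]]


# ---------------------------------------------------------------------------
# Stall-offset distribution
# ---------------------------------------------------------------------------

def truncated_geometric_pmf(mean: float, max_offset: int) -> np.ndarray:
    """PMF proportional to ``q**k`` on ``k = 0..max_offset`` with the given mean.

    ``q`` is solved numerically; the family spans means in (0, max_offset),
    degenerating to a point mass at 0 (or max_offset) at the boundaries.
    """
    k = np.arange(max_offset + 1, dtype=float)
    if max_offset == 0 or mean <= 0:
        pmf = np.zeros(max_offset + 1)
        pmf[0] = 1.0
        return pmf
    if mean >= max_offset:
        pmf = np.zeros(max_offset + 1)
        pmf[-1] = 1.0
        return pmf

    def mean_at(t: float) -> float:
        return float(np.dot(k, softmax(t * k)))

    lo, hi = -60.0, 60.0
    if mean <= mean_at(lo):
        t = lo
    elif mean >= mean_at(hi):
        t = hi
    else:
        t = brentq(lambda x: mean_at(x) - mean, lo, hi, xtol=1e-12)
    return softmax(t * k)


def _sample_offsets(
    rng: np.random.Generator, mean: float, max_offset: int, size: int
) -> np.ndarray:
    pmf = truncated_geometric_pmf(mean, max_offset)
    return rng.choice(max_offset + 1, size=size, p=pmf)


# ---------------------------------------------------------------------------
# Standard template construction
# ---------------------------------------------------------------------------

def make_standard_template(
    seq_len: int = 224,
    seed: int = 0,
    primer_len: int = 24,
    first_hm_forward: Optional[int] = None,
) -> StandardTemplate:
    """Build a random fully hydroxymethylated standard with unmodified primers.

    Every interior C is hydroxymethylated on the forward strand and every
    interior G marks a hydroxymethylated C on the reverse strand; the two
    ``primer_len``-base ends are modification-free.  When
    ``first_hm_forward`` is given, the sequence is arranged so the forward
    strand's 5'-most modified C sits exactly there.
    """
    if seq_len < 60:
        raise ValueError("seq_len must be >= 60")
    if not 1 <= primer_len < seq_len // 2:
        raise ValueError("primer_len must leave a non-empty interior")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=seq_len).tolist()
    interior = range(primer_len, seq_len - primer_len)
    if first_hm_forward is not None:
        if not primer_len <= first_hm_forward < seq_len - primer_len:
            raise ValueError("first_hm_forward must fall in the interior")
        for i in range(primer_len, first_hm_forward):
            if seq[i] == "C":
                seq[i] = rng.choice(np.array(list("ATG")))
        seq[first_hm_forward] = "C"
    # guarantee >= 1 modified C per strand
    if not any(seq[i] == "C" for i in interior):
        seq[seq_len // 2] = "C"
    if not any(seq[i] == "G" for i in interior):
        seq[seq_len // 2 + 1] = "G"
    seq_str = "".join(seq)
    hm_fwd = tuple(i for i in interior if seq_str[i] == "C")
    hm_rev = tuple(i for i in interior if seq_str[i] == "G")
    return StandardTemplate(
        seq=seq_str,
        primer_len_5p=primer_len,
        primer_len_3p=primer_len,
        hm_positions_forward=hm_fwd,
        hm_positions_reverse=hm_rev,
    )


def standard_fixture(seed: int = 0) -> StandardTemplate:
    """The 224-bp standard with the first forward modified C pinned at 0-based 28."""
    return make_standard_template(seq_len=224, seed=seed, primer_len=24, first_hm_forward=28)


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------

def _local_to_interval(
    chrom: str, frag_start: int, frag_len: int, strand: str, s_local: int, e_local: int
) -> Tuple[int, int]:
    """Map a strand-local [s, e) span inside a fragment to genomic coordinates."""
    if strand == "+":
        return frag_start + s_local, frag_start + e_local
    return frag_start + frag_len - e_local, frag_start + frag_len - s_local


def _read_seq(seq: str, gs: int, ge: int, strand: str) -> str:
    sub = seq[gs:ge]
    return sub if strand == "+" else revcomp(sub)


def simulate_standard_reads(
    template: StandardTemplate, cfg: SimulationConfig
) -> List[AlignedRead]:
    """Simulate SCL-exo reads of the standard (coordinates local to the template).

    Each read independently draws a strand (uniform) and a failure category
    (undigested / read-through / stall at the configured probabilities);
    the 5' start follows the category as described in the module docstring.
    Deterministic under a fixed ``cfg.rng_seed``.
    """
    if not template.hm_positions_forward or not template.hm_positions_reverse:
        raise ValueError("template must carry >= 1 hydroxymethylated C per strand")
    L = len(template)
    rng = np.random.default_rng(cfg.rng_seed)
    total = cfg.n_reads * cfg.n_replicates

    strands = rng.integers(0, 2, size=total)  # 0 -> '+', 1 -> '-'
    cats = rng.choice(
        3, size=total, p=[cfg.p_undigested, cfg.p_nostall, cfg.p_stall]
    )
    deltas = _sample_offsets(rng, cfg.stall_offset_mean, cfg.stall_offset_max, total)

    hm_local = {s: template.hm_local(s) for s in "+-"}
    first_local = {s: int(hm_local[s][0]) for s in "+-"}
    later_local = {s: hm_local[s][1:] for s in "+-"}
    # pre-draw uniform indices into the "later" arrays (unused entries ignored)
    later_idx = {
        s: rng.integers(0, max(1, later_local[s].size), size=total) for s in "+-"
    }

    reads: List[AlignedRead] = []
    for i in range(total):
        strand = "+" if strands[i] == 0 else "-"
        first = first_local[strand]
        cat = cats[i]
        if cat == _UNDIGESTED:
            start = 0
        elif cat == _STALL:
            start = max(0, first - int(deltas[i]))
        else:  # read-through: past the first modified C
            later = later_local[strand]
            if later.size == 0:
                start = L // 2
            else:
                start = int(later[later_idx[strand][i]]) - int(deltas[i])
            start = min(max(start, first + 1), L - 1)
        end = min(L, start + cfg.read_length)
        gs, ge = _local_to_interval(template.name, 0, L, strand, start, end)
        reads.append(
            AlignedRead(
                interval=GenomicInterval(template.name, gs, ge, strand),
                read_seq=_read_seq(template.seq, gs, ge, strand),
                replicate_id=f"rep{1 + i // cfg.n_reads}",
            )
        )
    return reads


def simulate_genomic_reads(
    ref: ReferenceSequence,
    hm: Hydroxymethylome,
    cfg: SimulationConfig,
    protocol: str = "scl-exo",
) -> SimulatedReadSet:
    """Simulate captured-fragment reads over a genomic reference.

    Fragments (uniform start, length uniform over ``fragment_length_range``)
    are captured only if >= 1 CpG on some strand is biotinylated (per-strand
    Bernoulli draw at its hydroxymethylation level).  The sequenced strand is
    chosen uniformly among strands carrying >= 1 biotinylated C; the read 5'
    start then follows the standard-template rules relative to the first
    biotinylated C of that strand.  ``protocol="scl-seq"`` is the no-digestion
    control: identical capture, read start uniform over the fragment.
    """
    if protocol not in ("scl-exo", "scl-seq"):
        raise ValueError("protocol must be 'scl-exo' or 'scl-seq'")
    if hm.n_sites() == 0:
        raise ValueError("hydroxymethylome is empty")
    L = len(ref)
    lo, hi = cfg.fragment_length_range
    if L < lo:
        raise ValueError("reference shorter than minimum fragment length")
    hi = min(hi, L)

    cpg_pos = hm.positions(ref.chrom)
    lvl = np.array([hm.level(ref.chrom, int(p)) for p in cpg_pos], dtype=float)
    lvl_fwd, lvl_rev = lvl[:, 0], lvl[:, 1]
    if float(lvl.max(initial=0.0)) == 0.0:
        # no CpG can ever be biotinylated -> nothing is captured
        return SimulatedReadSet(
            reads={f"rep{r+1}": [] for r in range(cfg.n_replicates)},
            captured_hm={f"rep{r+1}": set() for r in range(cfg.n_replicates)},
            anchors={f"rep{r+1}": [] for r in range(cfg.n_replicates)},
        )

    rng = np.random.default_rng(cfg.rng_seed)
    out = SimulatedReadSet(reads={}, captured_hm={}, anchors={})
    max_attempts = 1000 * cfg.n_reads
    offset_pmf = truncated_geometric_pmf(cfg.stall_offset_mean, cfg.stall_offset_max)
    cat_p = [cfg.p_undigested, cfg.p_nostall, cfg.p_stall]

    for rep in range(cfg.n_replicates):
        rep_id = f"rep{rep + 1}"
        reads: List[AlignedRead] = []
        anchors: List[Optional[Tuple[str, int]]] = []
        captured: Set[Tuple[str, int]] = set()
        attempts = 0

        def try_background():
            """One background-fragment draw; always yields a read."""
            flen = int(rng.integers(lo, hi + 1))
            fstart = int(rng.integers(0, L - flen + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            if protocol == "scl-seq" or rng.random() < cfg.p_undigested:
                start = 0
            else:
                # processive exonuclease drop-off with nothing to stall on
                start = int(rng.integers(0, flen))
            return fstart, flen, strand, start, None

        def try_specific():
            """One specific-capture draw; None if the fragment is not
            captured or its only protected C is read through (strand lost)."""
            flen = int(rng.integers(lo, hi + 1))
            fstart = int(rng.integers(0, L - flen + 1))
            fend = fstart + flen
            # CpGs fully inside the fragment (C and G within [fstart, fend))
            i0 = int(np.searchsorted(cpg_pos, fstart, side="left"))
            i1 = int(np.searchsorted(cpg_pos, fend - 1, side="left"))
            if i0 == i1:
                return None
            sites = cpg_pos[i0:i1]
            biot_fwd = rng.random(sites.size) < lvl_fwd[i0:i1]
            biot_rev = rng.random(sites.size) < lvl_rev[i0:i1]
            has = [biot_fwd.any(), biot_rev.any()]
            if not any(has):
                return None
            if all(has):
                strand = "+" if rng.random() < 0.5 else "-"
            else:
                strand = "+" if has[0] else "-"

            if strand == "+":
                biot_local = np.sort(sites[biot_fwd] - fstart)

                def canon_of_local(u: int) -> int:
                    return fstart + int(u)
            else:
                # reverse-strand C sits on the G of the CpG (canonical + 1)
                biot_local = np.sort((fend - 1) - (sites[biot_rev] + 1))

                def canon_of_local(u: int) -> int:
                    return (fend - 1) - int(u) - 1

            for site in sites[biot_fwd]:
                captured.add((ref.chrom, int(site)))
            for site in sites[biot_rev]:
                captured.add((ref.chrom, int(site)))

            anchor: Optional[Tuple[str, int]] = None
            if protocol == "scl-seq":
                start = 0  # no digestion: read from the fragment 5' end
            else:
                first = int(biot_local[0])
                cat = int(rng.choice(3, p=cat_p))
                delta = int(rng.choice(cfg.stall_offset_max + 1, p=offset_pmf))
                if cat == _UNDIGESTED:
                    start = 0
                elif cat == _STALL:
                    start = max(0, first - delta)
                    anchor = (ref.chrom, canon_of_local(first))
                else:
                    later = biot_local[1:]
                    if later.size == 0:
                        # read-through past the only protected C: the strand
                        # is digested away and no read is recovered
                        return None
                    chosen = int(later[rng.integers(0, later.size)])
                    start = min(max(chosen - delta, first + 1), flen - 1)
                    anchor = (ref.chrom, canon_of_local(chosen))
            return fstart, flen, strand, start, anchor

        while len(reads) < cfg.n_reads:
            # the background fraction is a property of the sequenced library,
            # so the branch is drawn per emitted read, not per fragment attempt
            is_background = rng.random() < cfg.p_background
            drawn = None
            while drawn is None:
                attempts += 1
                if attempts > max_attempts:
                    raise RuntimeError(
                        "fragment capture rate too low; "
                        "raise hm levels or the n_reads budget"
                    )
                drawn = try_background() if is_background else try_specific()
            fstart, flen, strand, start, anchor = drawn
            end_local = min(flen, start + cfg.read_length)
            gs, ge = _local_to_interval(ref.chrom, fstart, flen, strand, start, end_local)
            reads.append(
                AlignedRead(
                    interval=GenomicInterval(ref.chrom, gs, ge, strand),
                    read_seq=_read_seq(ref.seq, gs, ge, strand),
                    replicate_id=rep_id,
                )
            )
            anchors.append(anchor)
        out.reads[rep_id] = reads
        out.anchors[rep_id] = anchors
        out.captured_hm[rep_id] = captured
    return out


# ---------------------------------------------------------------------------
# Synthetic references and hydroxymethylomes
# ---------------------------------------------------------------------------

def make_cpg_reference(
    n_cpgs: int = 200,
    gap_range: Tuple[int, int] = (60, 140),
    chrom: str = "chrS",
    seed: int = 0,
    pad: int = 600,
) -> Tuple[ReferenceSequence, np.ndarray]:
    """A synthetic chromosome whose only CpG dinucleotides are planted sparsely.

    Background sequence is random with accidental CG dinucleotides broken, so
    the returned positions enumerate the chromosome's CpG sites exactly.
    ``gap_range`` (min >= 12 recommended) keeps neighbouring CpGs farther
    apart than a 10-base read window.
    """
    if n_cpgs < 1:
        raise ValueError("n_cpgs must be >= 1")
    lo, hi = gap_range
    if not 2 <= lo <= hi:
        raise ValueError("gap_range must satisfy 2 <= lo <= hi")
    rng = np.random.default_rng(seed)
    gaps = rng.integers(lo, hi + 1, size=n_cpgs)
    positions = pad + np.cumsum(gaps)
    length = int(positions[-1]) + 2 + pad
    seq = rng.choice(np.array(list("ACGT")), size=length).tolist()
    for i in range(length - 1):  # break accidental CpGs
        if seq[i] == "C" and seq[i + 1] == "G":
            seq[i + 1] = "T"
    for p in positions:
        seq[p] = "C"
        seq[p + 1] = "G"
    seq_str = "".join(seq)
    ref = ReferenceSequence(chrom=chrom, seq=seq_str)
    assert np.array_equal(ref.cpg_sites(), positions)
    return ref, positions.astype(np.int64)


def random_hydroxymethylome(
    ref: ReferenceSequence,
    levels: Sequence[float] = (0.0, 0.2, 0.5, 1.0),
    seed: int = 0,
    symmetric: bool = True,
) -> Hydroxymethylome:
    """Assign each CpG of ``ref`` a hydroxymethylation level drawn from ``levels``.

    With ``symmetric=True`` (the common biological case for 5hmCpG ground
    truth here) both strands share the level; otherwise strands draw
    independently.
    """
    rng = np.random.default_rng(seed)
    sites = ref.cpg_sites()
    lv = np.asarray(levels, dtype=float)
    data: Dict[int, Tuple[float, float]] = {}
    for p in sites:
        lf = float(rng.choice(lv))
        lr = lf if symmetric else float(rng.choice(lv))
        data[int(p)] = (lf, lr)
    return Hydroxymethylome({ref.chrom: data}, reference=ref)


def write_ground_truth(hm: Hydroxymethylome, path) -> None:
    """Write the hydroxymethylome as a TSV (chrom, position, level_fwd, level_rev)."""
    import pandas as pd

    rows = []
    for chrom in hm.chroms():
        for pos in hm.positions(chrom):
            lf, lr = hm.level(chrom, int(pos))
            rows.append((chrom, int(pos), lf, lr))
    pd.DataFrame(rows, columns=["chrom", "position", "level_fwd", "level_rev"]).to_csv(
        path, sep="\t", index=False
    )
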