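"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's own helpers and data structures:
each is a direct, slow transcription of the operation's definition, so a
disagreement indicts the implementation, not the oracle.
"""

import math


def classify_read_brute(chrom, start, end, strand, read_seq, window_len=10, ref_seq=None):
    """Return (class_name, position) by literal window scanning.

    ``ref_seq`` is the full chromosome string (or None).  Positions are
    canonical for CpG classes (forward-strand C), the minus-strand C for CpH.
    """
    w = min(window_len, len(read_seq))
    cpg, cph = [], []
    for i in range(w):
        if read_seq[i] != "C":
            continue
        if i + 1 < len(read_seq):
            follower = read_seq[i + 1]
        elif ref_seq is not None:
            # next base along the sequenced strand, off the read's 3' end
            if strand == "+":
                follower = ref_seq[end] if end < len(ref_seq) else None
            else:
                nxt = ref_seq[start - 1] if start - 1 >= 0 else None
                follower = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}.get(nxt)
        else:
            follower = None
        if follower == "G":
            cpg.append(i)
        else:
            cph.append(i)

    def genomic(i):
        return start + i if strand == "+" else end - 1 - i

    if len(cpg) == 1:
        g = genomic(cpg[0])
        return "id_cpg", g if strand == "+" else g - 1
    if len(cpg) >= 2:
        g = genomic(cpg[0])
        return "probable_cpg", g if strand == "+" else g - 1
    if cph:
        return "cph", genomic(cph[0])
    return "no_c", None


def consensus_brute(track_dicts, min_coverage, min_replicates, strict=True):
    """Per-position loop over the union of all replicate positions."""
    out = {}
    chroms = set()
    for t in track_dicts:
        chroms |= set(t)
    for chrom in chroms:
        positions = set()
        for t in track_dicts:
            positions |= set(t.get(chrom, {}))
        for p in positions:
            covs = [t.get(chrom, {}).get(p, 0) for t in track_dicts]
            if strict:
                support = sum(c > min_coverage for c in covs)
            else:
                support = sum(c >= min_coverage for c in covs)
            if support >= min_replicates:
                out.setdefault(chrom, {})[p] = sum(covs)
    return out


def blacklist_brute(track_dict, intervals):
    """Per-position membership test against every interval."""
    out = {}
    for chrom, sub in track_dict.items():
        for p, cov in sub.items():
            hit = any(
                iv_chrom == chrom and s <= p < e for iv_chrom, s, e in intervals
            )
            if not hit:
                out.setdefault(chrom, {})[p] = cov
    return out


def peak_inclusion_brute(track_dict, intervals, min_coverage):
    inside = outside = 0
    for chrom, sub in track_dict.items():
        for p, cov in sub.items():
            if cov < min_coverage:
                continue
            hit = any(
                iv_chrom == chrom and s <= p < e for iv_chrom, s, e in intervals
            )
            if hit:
                inside += 1
            else:
                outside += 1
    return inside, outside


def score_bin_brute(positions_scores, edges):
    """Map each (pos, score) to its bin index; last bin closed above."""
    bins = {i: [] for i in range(len(edges) - 1)}
    for pos, s in positions_scores:
        if s == edges[-1]:
            bins[len(edges) - 2].append(pos)
            continue
        for i in range(len(edges) - 1):
            if edges[i] <= s < edges[i + 1]:
                bins[i].append(pos)
                break
    return bins


def pearson_brute(xs, ys):
    """Textbook Pearson correlation from raw sums."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    return sxy / math.sqrt(sxx * syy)
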