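"""analysis: correlations, peak inclusion, density strata, metaprofiles, bins."""

import pytest

import sclexo as sx
from sclexo.analysis import UndefinedCorrelationError

from oracles import pearson_brute, peak_inclusion_brute, score_bin_brute


def random_track(rng, chrom="chr1", n=300, space=5000, max_cov=50):
    pos = rng.choice(space, size=n, replace=False)
    cov = rng.integers(1, max_cov, size=n)
    return sx.CpGSignalTrack({chrom: {int(p): int(c) for p, c in zip(pos, cov)}})


class TestTrackCorrelation:
    def test_self_correlation_is_one(self, rng):
        t = random_track(rng)
        assert sx.track_correlation(t, t) == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        t = random_track(rng)
        doubled = sx.CpGSignalTrack(
            {c: {p: 2 * v for p, v in sub.items()} for c, sub in t.to_dict().items()}
        )
        assert sx.track_correlation(t, doubled) == pytest.approx(1.0)

    def test_symmetry_and_bounds(self, rng):
        a, b = random_track(rng), random_track(rng)
        r_ab = sx.track_correlation(a, b)
        r_ba = sx.track_correlation(b, a)
        assert r_ab == pytest.approx(r_ba)
        assert -1.0 <= r_ab <= 1.0

    def test_matches_textbook_formula(self, rng):
        a, b = random_track(rng), random_track(rng)
        pos = sorted(
            {int(p) for p in a.positions("chr1")} | {int(p) for p in b.positions("chr1")}
        )
        xs = [a.get("chr1", p) for p in pos]
        ys = [b.get("chr1", p) for p in pos]
        assert sx.track_correlation(a, b) == pytest.approx(
            pearson_brute(xs, ys), abs=1e-12
        )

    def test_coverage_window_restriction(self):
        a = sx.CpGSignalTrack({"c": {1: 10, 2: 100, 3: 30, 4: 25}})
        b = sx.CpGSignalTrack({"c": {1: 12, 2: 90, 3: 28, 4: 30}})
        r_all = sx.track_correlation(a, b)
        r_win = sx.track_correlation(a, b, coverage_window=(20, 60))
        assert r_all != r_win  # the 20-60x window drops positions 1 and 2

    def test_undefined_correlation_raises(self):
        flat = sx.CpGSignalTrack({"c": {1: 5, 2: 5}})
        other = sx.CpGSignalTrack({"c": {1: 1, 2: 9}})
        with pytest.raises(UndefinedCorrelationError):
            sx.track_correlation(flat, other)
        with pytest.raises(UndefinedCorrelationError):
            sx.track_correlation(sx.CpGSignalTrack(), sx.CpGSignalTrack())


class TestPeakInclusion:
    def test_all_inside_one_big_peak(self, rng):
        t = random_track(rng, space=1000)
        res = sx.peak_inclusion(t, [sx.GenomicInterval("chr1", 0, 1000)])
        assert res.pct_inside == 100.0

    def test_no_peaks_zero_percent(self, rng):
        t = random_track(rng)
        res = sx.peak_inclusion(t, [])
        assert res.pct_inside == 0.0
        assert res.n_outside == t.n_positions()

    def test_matches_brute_force_with_coverage_filter(self, rng):
        t = random_track(rng, n=500, space=4000)
        peaks = []
        for _ in range(40):
            s = int(rng.integers(0, 3900))
            peaks.append(sx.GenomicInterval("chr1", s, s + int(rng.integers(1, 100))))
        res = sx.peak_inclusion(t, peaks, min_coverage=20)
        inside, outside = peak_inclusion_brute(
            t.to_dict(), [(iv.chrom, iv.start, iv.end) for iv in peaks], 20
        )
        assert (res.n_inside, res.n_outside) == (inside, outside)
        assert res.n_total == inside + outside  # Venn counts partition


class TestCpgDensityStrata:
    def test_isolated_cpg_is_density_one(self):
        ref = sx.ReferenceSequence("c", "A" * 200 + "CG" + "A" * 200)
        track = sx.CpGSignalTrack({"c": {200: 7}})
        strata = sx.cpg_density_strata(track, ref)
        assert list(strata.index) == [1]
        assert strata.loc[1, "mean_signal"] == 7

    def test_tandem_cpgs_density_at_least_two(self):
        ref = sx.ReferenceSequence("c", "A" * 200 + "CGCG" + "A" * 200)
        track = sx.CpGSignalTrack({"c": {200: 1, 202: 1}})
        strata = sx.cpg_density_strata(track, ref)
        assert all(d >= 2 for d in strata.index)

    def test_window_clipped_at_chromosome_ends(self):
        ref = sx.ReferenceSequence("c", "CG" + "A" * 100)
        track = sx.CpGSignalTrack({"c": {0: 3}})
        strata = sx.cpg_density_strata(track, ref, window=300)
        assert strata.loc[1, "n_positions"] == 1

    def test_signal_flat_across_density_when_levels_uniform(self):
        """When hydroxymethylation is independent of CpG density, stratum
        mean signals stay within 15 % of each other."""
        ref, positions = sx.make_cpg_reference(
            n_cpgs=150, gap_range=(110, 260), seed=71
        )
        hm = sx.Hydroxymethylome(
            {ref.chrom: {int(p): (0.5, 0.5) for p in positions}}, reference=ref
        )
        cfg = sx.SimulationConfig(
            n_reads=20_000, n_replicates=1, fragment_length_range=(80, 120),
            rng_seed=72,
        )
        sim = sx.simulate_genomic_reads(ref, hm, cfg)
        bundle = sx.build_tracks(sim.reads["rep1"], reference=ref)
        strata = sx.cpg_density_strata(bundle.id_track, ref)
        strata = strata[strata["n_positions"] >= 10]  # ignore tiny strata
        means = strata["mean_signal"]
        assert len(means) >= 2
        assert means.max() / means.min() < 1.15


class TestMotifMetaprofile:
    def test_rcgy_anchor_example(self):
        # anchor at the C of "ACGT": A=R, T=Y, so an RCGY instance starts at -1
        ref = sx.ReferenceSequence("c", "TTTTTACGTTTTTT")
        prof = sx.motif_metaprofile(ref, [6], motif="RCGY", halfwidth=3)
        idx = {int(o): d for o, d in zip(prof.offsets, prof.density)}
        assert idx[-1] == 1.0

    def test_no_cg_anywhere_gives_zero_profile(self):
        ref = sx.ReferenceSequence("c", "ATATATATATATATAT")
        prof = sx.motif_metaprofile(ref, [8], motif="RCGY", halfwidth=4)
        assert not prof.density.any()

    def test_cg_motif_at_offset_zero_for_cpg_anchors(self, sparse_ref):
        ref, positions = sparse_ref
        prof = sx.motif_metaprofile(ref, positions[:50], motif="CG", halfwidth=5)
        idx = {int(o): d for o, d in zip(prof.offsets, prof.density)}
        assert idx[0] == 1.0

    def test_empty_anchor_set_rejected(self, sparse_ref):
        ref, _ = sparse_ref
        with pytest.raises(ValueError):
            sx.motif_metaprofile(ref, [], motif="RCGY")

    def test_rcgy_enrichment_at_rcgy_biased_anchors(self, rng):
        """Anchors placed at RCGY CpGs show higher central RCGY density than
        random non-CpG anchors."""
        ref, positions = sx.make_cpg_reference(n_cpgs=120, gap_range=(40, 80), seed=73)
        seq = list(ref.seq)
        rcgy_anchors = []
        for p in positions[:60]:
            seq[p - 1] = "A"  # force R just upstream, Y just downstream
            seq[p + 2] = "T"
            rcgy_anchors.append(int(p))
        biased = sx.ReferenceSequence(ref.chrom, "".join(seq))
        cpg_set = set(int(p) for p in biased.cpg_sites())
        random_anchors = []
        while len(random_anchors) < 60:
            q = int(rng.integers(100, len(biased) - 100))
            if q not in cpg_set:
                random_anchors.append(q)
        prof_b = sx.motif_metaprofile(biased, rcgy_anchors, "RCGY", halfwidth=2)
        prof_r = sx.motif_metaprofile(biased, random_anchors, "RCGY", halfwidth=2)
        center_b = prof_b.density[prof_b.offsets == -1][0]
        center_r = prof_r.density[prof_r.offsets == -1][0]
        assert center_b > center_r


class TestScoreBin:
    def make_scored(self, rng, n=200):
        track = random_track(rng, n=n, space=2000)
        scores = sx.ScoreTrack()
        for chrom, pos, _ in track.items():
            scores.set(chrom, pos, float(rng.uniform(0, 1)))
        return track, scores

    def test_all_zero_scores_fall_in_first_bin(self, rng):
        track = random_track(rng, n=50, space=500)
        scores = sx.ScoreTrack()
        for chrom, pos, _ in track.items():
            scores.set(chrom, pos, 0.0)
        res = sx.score_bin(track, scores)
        assert res.table.loc["[0, 0.075)", "n"] == 50

    def test_boundary_score_belongs_upward(self):
        track = sx.CpGSignalTrack({"c": {1: 5, 2: 5, 3: 5}})
        scores = sx.ScoreTrack({"c": {1: 0.075, 2: 0.75, 3: 1.0}})
        res = sx.score_bin(track, scores)
        assert ("c", 1) not in res.positions["[0, 0.075)"]
        assert ("c", 1) in res.positions["[0.075, 0.75)"]
        assert ("c", 2) in res.positions["[0.75, 1]"]
        assert ("c", 3) in res.positions["[0.75, 1]"]  # top edge closed

    def test_unscored_positions_reported_separately(self, rng):
        track = sx.CpGSignalTrack({"c": {1: 5, 2: 5}})
        scores = sx.ScoreTrack({"c": {1: 0.5}})
        res = sx.score_bin(track, scores)
        assert res.positions["unscored"] == {("c", 2)}

    def test_matches_brute_force_partition(self, rng):
        track, scores = self.make_scored(rng)
        edges = [0.0, 0.075, 0.75, 1.0]
        res = sx.score_bin(track, scores, edges)
        pairs = [((c, p), scores.get(c, p)) for c, p, _ in track.items()]
        expected = score_bin_brute(pairs, edges)
        labels = ["[0, 0.075)", "[0.075, 0.75)", "[0.75, 1]"]
        for i, lab in enumerate(labels):
            assert res.positions[lab] == set(expected[i])
        # bins partition the scored positions
        assert sum(res.table.loc[labels, "n"]) == track.n_positions()

    def test_unsorted_edges_rejected(self, rng):
        track, scores = self.make_scored(rng, n=10)
        with pytest.raises(ValueError):
            sx.score_bin(track, scores, [0, 0.5, 0.3, 1])
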