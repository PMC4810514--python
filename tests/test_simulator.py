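"""simulator: template construction, failure-mode frequencies, determinism."""

import numpy as np
import pytest

import sclexo as sx
from sclexo.simulator import truncated_geometric_pmf
from sclexo.trackio import revcomp


class TestStandardTemplate:
    def test_default_length_and_primers(self):
        t = sx.make_standard_template()
        assert len(t) == 224
        assert t.primer_len_5p == t.primer_len_3p == 24

    def test_fixture_pins_first_forward_hm_at_28(self, template):
        assert template.first_hm("+") == 28  # 1-based position 29

    def test_all_interior_cs_are_modified_on_a_strand(self, template):
        interior = range(template.primer_len_5p, len(template) - template.primer_len_3p)
        fwd, rev = set(template.hm_positions_forward), set(template.hm_positions_reverse)
        for i in interior:
            if template.seq[i] == "C":
                assert i in fwd
            elif template.seq[i] == "G":
                assert i in rev
        # and primers carry no modifications at all
        assert all(p in interior for p in fwd | rev)

    def test_too_short_template_rejected(self):
        with pytest.raises(ValueError):
            sx.make_standard_template(seq_len=40)


class TestStallOffsetDistribution:
    def test_degenerate_cases(self):
        assert truncated_geometric_pmf(0.0, 10)[0] == 1.0
        assert truncated_geometric_pmf(3.0, 0).tolist() == [1.0]

    @pytest.mark.parametrize("mean,maxoff", [(1.0, 10), (3.0, 10), (4.9, 10), (2.0, 5)])
    def test_pmf_hits_requested_mean(self, mean, maxoff):
        pmf = truncated_geometric_pmf(mean, maxoff)
        assert pmf.sum() == pytest.approx(1.0)
        assert float(np.dot(np.arange(maxoff + 1), pmf)) == pytest.approx(mean, abs=1e-9)


class TestStandardReads:
    def test_degenerate_config_starts_at_first_hm(self, template):
        cfg = sx.SimulationConfig(
            p_undigested=0, p_nostall=0, stall_offset_mean=0, stall_offset_max=0,
            n_reads=200, n_replicates=1, rng_seed=1,
        )
        for read in sx.simulate_standard_reads(template, cfg):
            L = len(template)
            local = read.start if read.strand == "+" else L - read.end
            assert local == int(template.hm_local(read.strand)[0])

    def test_same_seed_is_byte_identical(self, template):
        cfg = sx.SimulationConfig(n_reads=500, n_replicates=2, rng_seed=42)
        assert sx.simulate_standard_reads(template, cfg) == sx.simulate_standard_reads(
            template, cfg
        )

    def test_read_seq_matches_reference_slice(self, template):
        cfg = sx.SimulationConfig(n_reads=300, n_replicates=1, rng_seed=3)
        for read in sx.simulate_standard_reads(template, cfg):
            ref_slice = template.seq[read.start : read.end]
            expected = ref_slice if read.strand == "+" else revcomp(ref_slice)
            assert read.read_seq == expected
            assert 0 <= read.start < read.end <= len(template)

    def test_category_frequencies_match_paper_rates(self, template):
        """Undigested/read-through fractions converge to 12.38 % / 51.04 %."""
        cfg = sx.SimulationConfig(n_reads=100_000, n_replicates=1, rng_seed=7)
        reads = sx.simulate_standard_reads(template, cfg)
        n = len(reads)
        L = len(template)
        first = {s: int(template.hm_local(s)[0]) for s in "+-"}
        upstream = nostall = 0
        for read in reads:
            local = read.start if read.strand == "+" else L - read.end
            if local < first[read.strand] - cfg.stall_offset_max:
                upstream += 1
            elif local > first[read.strand]:
                nostall += 1
        se_u = (0.1238 * (1 - 0.1238) / n) ** 0.5
        se_n = (0.5104 * (1 - 0.5104) / n) ** 0.5
        assert abs(upstream / n - 0.1238) < 3 * se_u
        assert abs(nostall / n - 0.5104) < 3 * se_n

    def test_mean_stall_offset(self, template):
        cfg = sx.SimulationConfig(
            p_undigested=0, p_nostall=0, n_reads=50_000, n_replicates=1, rng_seed=9
        )
        reads = sx.simulate_standard_reads(template, cfg)
        L = len(template)
        offsets = []
        for read in reads:
            local = read.start if read.strand == "+" else L - read.end
            offsets.append(int(template.hm_local(read.strand)[0]) - local)
        offsets = np.array(offsets)
        assert (0 <= offsets).all() and (offsets <= cfg.stall_offset_max).all()
        se = offsets.std() / len(offsets) ** 0.5
        assert abs(offsets.mean() - cfg.stall_offset_mean) < 3 * se

    def test_empty_template_rejected(self):
        bare = sx.StandardTemplate(
            seq="A" * 100, primer_len_5p=10, primer_len_3p=10,
            hm_positions_forward=(), hm_positions_reverse=(),
        )
        with pytest.raises(ValueError):
            sx.simulate_standard_reads(bare, sx.SimulationConfig(n_reads=1))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p_undigested": -0.1},
            {"p_undigested": 0.7, "p_nostall": 0.7},
            {"stall_offset_mean": 11, "stall_offset_max": 10},
            {"fragment_length_range": (10, 5)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sx.SimulationConfig(**kwargs)


class TestGenomicReads:
    def test_single_site_level_one_degenerate(self):
        ref, positions = sx.make_cpg_reference(n_cpgs=1, gap_range=(50, 50), seed=2)
        site = int(positions[0])
        hm = sx.Hydroxymethylome({ref.chrom: {site: (1.0, 1.0)}}, reference=ref)
        cfg = sx.SimulationConfig(
            p_undigested=0, p_nostall=0, p_background=0,
            stall_offset_mean=0, stall_offset_max=0,
            n_reads=100, n_replicates=1, fragment_length_range=(60, 80), rng_seed=5,
        )
        sim = sx.simulate_genomic_reads(ref, hm, cfg)
        for read in sim.reads["rep1"]:
            if read.strand == "+":
                assert read.start == site  # read starts at the C
            else:
                assert read.end == site + 2  # 5' end on the G of the CpG

    def test_level_zero_captures_nothing(self, sparse_ref):
        ref, positions = sparse_ref
        hm = sx.Hydroxymethylome(
            {ref.chrom: {int(p): (0.0, 0.0) for p in positions}}, reference=ref
        )
        cfg = sx.SimulationConfig(n_reads=10, n_replicates=1, rng_seed=1)
        sim = sx.simulate_genomic_reads(ref, hm, cfg)
        assert sim.reads["rep1"] == []

    def test_reads_lie_within_reference_and_match_sequence(self, sparse_ref):
        ref, _ = sparse_ref
        hm = sx.random_hydroxymethylome(ref, levels=(0.5, 1.0), seed=6)
        cfg = sx.SimulationConfig(
            n_reads=500, n_replicates=1, fragment_length_range=(100, 200), rng_seed=8
        )
        sim = sx.simulate_genomic_reads(ref, hm, cfg)
        for read in sim.reads["rep1"]:
            assert 0 <= read.start < read.end <= len(ref)
            ref_slice = ref.seq[read.start : read.end]
            expected = ref_slice if read.strand == "+" else revcomp(ref_slice)
            assert read.read_seq == expected

    def test_non_cpg_position_rejected_by_hydroxymethylome(self, sparse_ref):
        ref, positions = sparse_ref
        bad = int(positions[0]) + 1
        with pytest.raises(ValueError):
            sx.Hydroxymethylome({ref.chrom: {bad: (1.0, 1.0)}}, reference=ref)

    def test_short_reference_rejected(self):
        ref = sx.ReferenceSequence("c", "ACGT" * 10)
        hm = sx.Hydroxymethylome({"c": {1: (1.0, 1.0)}})
        cfg = sx.SimulationConfig(fragment_length_range=(200, 500), n_reads=1)
        with pytest.raises(ValueError):
            sx.simulate_genomic_reads(ref, hm, cfg)

    def test_sclseq_control_spreads_read_starts(self, sparse_ref):
        """Without digestion, read 5' ends are uniform over fragments, not
        piled at modified CpGs."""
        ref, positions = sparse_ref
        hm = sx.random_hydroxymethylome(ref, levels=(1.0,), seed=6)
        cfg = sx.SimulationConfig(
            p_background=0,
            n_reads=2000, n_replicates=1, fragment_length_range=(200, 400), rng_seed=13
        )
        exo = sx.simulate_genomic_reads(ref, hm, cfg, protocol="scl-exo")
        ctrl = sx.simulate_genomic_reads(ref, hm, cfg, protocol="scl-seq")
        site_set = set(int(p) for p in positions)

        def frac_at_sites(reads):
            hits = 0
            for r in reads:
                five = r.start if r.strand == "+" else r.end - 1
                window = range(five - 10, five + 11)
                if any(p in site_set for p in window):
                    hits += 1
            return hits / len(reads)

        assert frac_at_sites(exo.reads["rep1"]) > 2 * frac_at_sites(ctrl.reads["rep1"])
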