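"""Fixture genome construction, tiling arithmetic, and read simulation."""

import numpy as np
import pytest

from ampedit import _tables
from ampedit.crispr_targeting import locate_protospacer, reverse_complement
from ampedit.synthetic_data import (Genome, PlantingError, ReferenceConfig,
                                    ScenarioSpec, VariantSpec, build_reference,
                                    control_scenarios, design_tiling,
                                    pairs_per_amplicon, simulate_reads,
                                    stock_variants, table1_scenarios,
                                    write_fastq_pairs, write_table1_scenarios)


class TestBuildReference:
    def test_planted_spacers_located_exactly_once(self, genome, targets):
        for t in targets:
            site = locate_protospacer(genome, t)  # raises if 0 or >1 sites
            strand = "-" if t.declared_strand == "antisense" else "+"
            assert site.strand == strand

    def test_guide_spacing_follows_offset_arithmetic(self, genome, targets):
        """gp64+418 sits 287 target-bp from gp64+131 (= 418 - 131)."""
        sites = {t.name: locate_protospacer(genome, t) for t in targets}
        assert sites["gp64+131"].start - sites["gp64+418"].start == 287

    def test_deletion_contexts_match_published_alleles(self, genome):
        assert genome.slice(107_199, 107_204) == "CTCCAC"
        assert genome.slice(106_935, 106_936) == "CA"
        assert genome.slice(106_975, 106_975) == "T"
        assert genome.slice(107_222, 107_222) == "C"
        assert genome.slice(12_427, 12_446) == "CTAGAGATCTCTAGAGATCT"

    def test_hr_arrays_are_at_rich(self, genome, annotation):
        for f in annotation.of_class("hr"):
            seq = genome.slice(f.start, f.end)
            at = (seq.count("A") + seq.count("T")) / len(seq)
            assert at >= 0.6, f.label

    def test_no_hr_config_yields_no_hr_intervals(self):
        _, ann, _ = build_reference(ReferenceConfig(hrs=()))
        assert ann.of_class("hr") == []

    def test_anchor_near_genome_edge_rejected(self):
        with pytest.raises(PlantingError):
            build_reference(ReferenceConfig(length=8_000,
                                            anchor_window_start=500,
                                            sense_plant_start=4_000,
                                            hrs=(), orfs=()))


class TestDesignTiling:
    def test_six_amplicons_alternate_pools_on_5kb(self):
        g = Genome("g", "ACGT" * 1250)
        sch = design_tiling(g, amplicon_len=1000, overlap=100, primer_len=22)
        assert len(sch.amplicons) == 6
        assert [a.pool for a in sch.amplicons] == [1, 2, 1, 2, 1, 2]
        assert sch.amplicons[-1].end == 5000

    def test_amplicon_longer_than_genome_gives_single_amplicon(self):
        g = Genome("g", "ACGT" * 100)
        sch = design_tiling(g, amplicon_len=1000, overlap=100, primer_len=22)
        assert len(sch.amplicons) == 1
        assert (sch.amplicons[0].start, sch.amplicons[0].end) == (1, 400)

    def test_zero_overlap_makes_inserts_abut(self):
        g = Genome("g", "ACGT" * 1250)
        sch = design_tiling(g, amplicon_len=1000, overlap=0, primer_len=22)
        for a, b in zip(sch.amplicons, sch.amplicons[1:]):
            if b is not sch.amplicons[-1]:
                assert b.insert_start == a.insert_end + 1

    def test_consecutive_inserts_overlap_by_at_least_overlap(self, scheme):
        for a, b in zip(scheme.amplicons[:-1], scheme.amplicons[1:-1]):
            assert a.insert_end - b.insert_start + 1 >= 100

    def test_every_feature_position_insert_covered(self, annotation, scheme):
        spans = [(a.insert_start, a.insert_end) for a in scheme.amplicons]
        for f in annotation.features:
            for pos in (f.start, (f.start + f.end) // 2, f.end):
                assert any(s <= pos <= e for s, e in spans), f.label

    def test_bed_round_trip(self, scheme, tmp_path):
        p = tmp_path / "scheme.bed"
        scheme.to_bed(p)
        back = type(scheme).from_bed(p)
        assert [(a.name, a.start, a.end, a.pool) for a in back.amplicons] == \
            [(a.name, a.start, a.end, a.pool) for a in scheme.amplicons]


@pytest.fixture(scope="module")
def small_scenario():
    return ScenarioSpec(
        sample_name="gp64+378", fraction="cell_pellet",
        variants=[VariantSpec(pos=106_975, alt="-T", frequency=0.0451)],
        depth=400, seeds=[5, 6], region=(106_950, 107_000))


class TestSimulateReads:
    def test_deterministic_fastq_bytes(self, genome, scheme, small_scenario,
                                       tmp_path):
        for run in (1, 2):
            reps = simulate_reads(genome, scheme, small_scenario)
            write_fastq_pairs(reps[0], tmp_path / f"r{run}_1.fq",
                              tmp_path / f"r{run}_2.fq")
        assert (tmp_path / "r1_1.fq").read_bytes() == \
            (tmp_path / "r2_1.fq").read_bytes()
        assert (tmp_path / "r1_2.fq").read_bytes() == \
            (tmp_path / "r2_2.fq").read_bytes()

    def test_error_free_reads_are_reference_substrings(self, genome, scheme):
        sc = ScenarioSpec(sample_name="ctl", fraction="cell_pellet",
                          variants=[], depth=30, seeds=[3, 4],
                          region=(50_000, 50_200), error_scale=0.0,
                          indel_error_rate=0.0)
        reps = simulate_reads(genome, scheme, sc)
        for p in reps[0]:
            assert p.seq1 in genome.sequence
            assert reverse_complement(p.seq2) in genome.sequence

    def test_spiked_fraction_within_binomial_error(self, genome, scheme,
                                                   small_scenario):
        """The fraction of fragments carrying the deletion converges on
        the scenario frequency."""
        sc = ScenarioSpec(**{**small_scenario.__dict__,
                             "error_scale": 0.0, "indel_error_rate": 0.0})
        reps = simulate_reads(genome, scheme, sc)
        amp = [a for a in scheme.amplicons
               if a.insert_start <= 106_975 <= a.insert_end][0]
        ref_frag = genome.slice(amp.start, amp.end)
        mut_prefix = (ref_frag[:106_975 - amp.start]
                      + ref_frag[106_976 - amp.start:])[:300]
        n = mut = 0
        for p in reps[0] + reps[1]:
            if p.amplicon_of_origin != amp.name:
                continue
            n += 1
            mut += p.seq1 == mut_prefix
        f = sc.variants[0].frequency
        assert n > 400
        assert abs(mut / n - f) < 3 * np.sqrt(f * (1 - f) / n)

    def test_mean_insert_coverage_tracks_depth(self, genome):
        """1000 bp amplicons with 2x250 reads: mean per-position insert
        coverage within 10% of the requested 400x."""
        sch = design_tiling(genome, amplicon_len=1000, overlap=100,
                            primer_len=22)
        amp = sch.amplicons[50]
        n_pairs = pairs_per_amplicon(400, amp, read_length=250)
        cov = np.zeros(amp.insert_end - amp.insert_start + 1)
        r1 = (amp.start, amp.start + 249)
        r2 = (amp.end - 249, amp.end)
        for s, e in (r1, r2):
            lo = max(s, amp.insert_start) - amp.insert_start
            hi = min(e, amp.insert_end) - amp.insert_start
            cov[lo:hi + 1] += n_pairs
        assert abs(cov.mean() - 400) / 400 < 0.10

    def test_variant_frequency_sum_validation(self):
        with pytest.raises(ValueError, match="summed alt frequency"):
            ScenarioSpec(sample_name="x", fraction="stock",
                         variants=[VariantSpec(1000, "A", 0.6),
                                   VariantSpec(1000, "C", 0.5)])

    def test_variant_outside_inserts_warns(self, genome, scheme):
        sc = ScenarioSpec(sample_name="x", fraction="stock",
                          variants=[VariantSpec(pos=5, alt="A",
                                                frequency=0.05)],
                          depth=10, seeds=[1, 2], region=(50_000, 50_100))
        with pytest.warns(UserWarning, match="undetectable"):
            simulate_reads(genome, scheme, sc)


class TestBundledScenarios:
    def test_supernatant_minus160_has_five_deletions(self):
        sc = table1_scenarios()["gp64-160_supernatant"]
        assert len(sc.variants) == 5
        assert all(v.alt.startswith("-") for v in sc.variants)

    def test_gp64_418_cell_pellet_single_variant(self):
        sc = table1_scenarios()["gp64+418_cell_pellet"]
        assert [(v.pos, v.alt, v.frequency) for v in sc.variants] == \
            [(106_935, "-CA", 0.0424)]

    def test_stock_catalogue_counts(self, genome, annotation):
        vs = stock_variants(genome, annotation)
        assert len(vs) == 141
        assert sum(v.conserved for v in vs) == 97

    def test_controls_carry_no_gp64_variants(self):
        for sc in control_scenarios().values():
            assert sc.variants == []

    def test_yaml_round_trip(self, genome, annotation, tmp_path):
        paths = write_table1_scenarios(tmp_path, genome, annotation)
        assert set(paths) >= {"gp64-160_supernatant", "virus_stock",
                              "scrambled", "infected_only"}
        sc = ScenarioSpec.from_yaml(paths["gp64-160_supernatant"])
        assert sc == table1_scenarios()["gp64-160_supernatant"]
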