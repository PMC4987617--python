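"""Arrangement enumeration, read classification, junction calling, depth."""

import numpy as np
import pytest

from circlescan.genome_model import CircInterval, CircularSequence, GenomeSet
from circlescan.junction_analysis import (
    AlignmentSegment,
    ReadPath,
    call_breakpoint_junctions,
    classify_read,
    count_support,
    depth_profile,
    enumerate_arrangements,
    junction_presence_matrix,
    load_alignments,
)
from circlescan.repeat_finder import RepeatPair
from circlescan.synthetic_data import (
    Molecule,
    SimConfig,
    simulate_genome,
    simulate_long_reads,
    simulate_molecules,
)


def _pair(c1, s1, e1, c2, s2, e2, orientation):
    strand2 = "-" if orientation == "inverted" else "+"
    return RepeatPair(
        CircInterval(c1, s1, e1, "+"),
        CircInterval(c2, s2, e2, strand2),
        orientation,
        e1 - s1 + 1,
    )


class TestEnumerateArrangements:
    def test_direct_excision_conserves_length(self):
        g = GenomeSet([CircularSequence("c", "A" * 50000, True)])
        pair = _pair("c", 5000, 6499, "c", 30000, 31499, "direct")
        sigs = enumerate_arrangements(pair, g)
        ref = [s for s in sigs if s.kind == "reference"]
        rec = [s for s in sigs if s.kind == "recombinant"]
        assert len(ref) == 2 and len(rec) == 2
        assert sum(s.product_length for s in rec) == 50000

    def test_inter_chromosomal_fusion_length(self):
        g = GenomeSet(
            [CircularSequence("a", "A" * 30000, True), CircularSequence("b", "A" * 20000, True)]
        )
        for orient in ("direct", "inverted"):
            pair = _pair("a", 100, 399, "b", 5000, 5299, orient)
            rec = [s for s in enumerate_arrangements(pair, g) if s.kind == "recombinant"]
            assert len(rec) == 2
            assert all(s.product_length == 50000 for s in rec)

    def test_inverted_segment_size_from_printed_coordinates(self):
        # the 4 kb inverted pair on a 300778 b circle flips a 120181 b segment
        g = GenomeSet([CircularSequence("chr1", "A" * 300778, True)])
        pair = _pair("chr1", 45730, 49805, "chr1", 169987, 174062, "inverted")
        rec = [s for s in enumerate_arrangements(pair, g) if s.kind == "recombinant"]
        assert {s.inverted_segment_length for s in rec} == {169986 - 49806 + 1}
        assert {s.inverted_segment_length for s in rec} == {120181}

    def test_overlapping_copies_degenerate(self):
        g = GenomeSet([CircularSequence("c", "A" * 1000, True)])
        pair = _pair("c", 10, 200, "c", 150, 340, "direct")
        with pytest.raises(ValueError):
            enumerate_arrangements(pair, g)

    def test_copy_relabeling_keeps_recombinant_signatures(self):
        g = GenomeSet([CircularSequence("c", "A" * 50000, True)])
        fwd = _pair("c", 5000, 6499, "c", 30000, 31499, "inverted")
        swapped = RepeatPair(fwd.copy2, fwd.copy1, "inverted", fwd.repeat_length)
        sig_a = {s.breakends for s in enumerate_arrangements(fwd, g) if s.kind == "recombinant"}
        sig_b = {s.breakends for s in enumerate_arrangements(swapped, g) if s.kind == "recombinant"}
        assert sig_a == sig_b

    def test_description_notation(self):
        g = GenomeSet(
            [CircularSequence("chromosome_1", "A" * 300000, True),
             CircularSequence("chromosome_2", "A" * 145000, True)]
        )
        pair = _pair("chromosome_1", 195001, 196000, "chromosome_2", 111201, 112200, "direct")
        rec = [s for s in enumerate_arrangements(pair, g) if s.kind == "recombinant"]
        descs = {s.description for s in rec}
        assert any("join chromosome_2" in d and "Kb" in d for d in descs)


class TestLoadAlignments:
    def test_empty_sam(self, tmp_path):
        p = tmp_path / "empty.sam"
        p.write_text("@HD\tVN:1.6\n@SQ\tSN:c\tLN:100\n")
        assert load_alignments(str(p)) == []

    def test_primary_plus_supplementary_grouped(self, tmp_path):
        p = tmp_path / "two.sam"
        p.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:c\tLN:1000\n"
            "r1\t0\tc\t1\t60\t50M50S\t*\t0\t0\t" + "A" * 100 + "\t" + "I" * 100 + "\n"
            "r1\t2048\tc\t501\t60\t50S50M\t*\t0\t0\t" + "A" * 100 + "\t" + "I" * 100 + "\n"
        )
        paths = load_alignments(str(p))
        assert len(paths) == 1
        assert len(paths[0].segments) == 2
        seg1, seg2 = paths[0].segments
        assert (seg1.read_start, seg1.read_end) == (1, 50)
        assert (seg2.read_start, seg2.read_end) == (51, 100)
        assert seg2.is_supplementary

    def test_unknown_reference_rejected(self, tmp_path, sim_small):
        _, genome, _ = sim_small
        p = tmp_path / "bad.sam"
        p.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:nope\tLN:1000\n"
            "r1\t0\tnope\t1\t60\t10M\t*\t0\t0\tAAAAAAAAAA\t" + "I" * 10 + "\n"
        )
        with pytest.raises(ValueError):
            load_alignments(str(p), genome)

    def test_truth_sam_round_trip(self, tmp_path):
        cfg = SimConfig.small(seed=31, depth=4, inversion_fraction=0.3)
        genome, truth = simulate_genome(cfg)
        mols = simulate_molecules(genome, truth, cfg)
        sam = tmp_path / "truth.sam"
        paths = simulate_long_reads(mols, genome, cfg, sam_path=str(sam), truth=truth)
        loaded = {p.read_id: p for p in load_alignments(str(sam), genome)}
        assert set(loaded) == {p.read_id for p in paths}
        for p in paths:
            assert loaded[p.read_id].segments == p.segments

    def test_paf_round_trip(self, tmp_path):
        # PAF written by hand mirroring one split read
        p = tmp_path / "a.paf"
        p.write_text(
            "r1\t100\t0\t50\t+\tc\t1000\t0\t50\t50\t50\t60\ttp:A:P\n"
            "r1\t100\t50\t100\t-\tc\t1000\t500\t550\t50\t50\t60\ttp:A:P\n"
        )
        paths = load_alignments(str(p))
        assert len(paths) == 1
        s1, s2 = paths[0].segments
        assert (s1.ref.start, s1.ref.end, s1.strand) == (1, 50, "+")
        assert (s2.ref.start, s2.ref.end, s2.strand) == (501, 550, "-")


class TestClassifyRead:
    def test_read_in_unique_region_uninformative(self, sim_small):
        _, genome, truth = sim_small
        pair = truth.pairs_by_name["large_direct"]
        # a read far from both copies
        seg = AlignmentSegment("r0", 1, 500, CircInterval("chromosome_2", 1, 500, "+"), "+")
        cls = classify_read(ReadPath("r0", [seg]), pair, genome, min_anchor=100)
        assert cls.category == "uninformative"

    def test_spanning_read_supports_reference_copy(self, sim_small):
        _, genome, truth = sim_small
        pair = truth.pairs_by_name["large_inverted"]
        c1 = pair.copy1
        seg = AlignmentSegment(
            "r0", 1, 1400,
            CircInterval(c1.chrom_id, c1.start - 500, c1.end + 500, "+"), "+",
        )
        cls = classify_read(ReadPath("r0", [seg]), pair, genome, min_anchor=200)
        assert cls.category == "ref_copy1"

    def test_excision_read_classified_recombinant(self, sim_small):
        _, genome, truth = sim_small
        pair = truth.pairs_by_name["large_direct"]
        s1, s2 = pair.copy1.start, pair.copy2.start
        e1 = pair.copy1.end
        # read from the excision circle crossing its closure junction:
        # ...inner flank up to s2-1, then copy1 start onward
        segs = [
            AlignmentSegment("r0", 1, 1000,
                             CircInterval(pair.copy1.chrom_id, s2 - 1000, s2 - 1, "+"), "+"),
            AlignmentSegment("r0", 1001, 1000 + (e1 - s1 + 1) + 800,
                             CircInterval(pair.copy1.chrom_id, s1, e1 + 800, "+"), "+"),
        ]
        cls = classify_read(ReadPath("r0", segs), pair, genome, min_anchor=200)
        assert cls.category == "recombinant"
        assert cls.junction.name == "excision_circle"

    def test_zero_noise_simulated_isoform_reads(self):
        cfg = SimConfig.small(seed=41, depth=20, inversion_fraction=1.0,
                              sub_rate=0.0, ins_rate=0.0, del_rate=0.0)
        genome, truth = simulate_genome(cfg)
        mols = simulate_molecules(genome, truth, cfg)
        paths = simulate_long_reads(mols, genome, cfg, truth=truth)
        pair = truth.pairs_by_name["large_inverted"]
        iso = [p for p in paths if truth.read_molecule[p.read_id].endswith("_inverted")]
        cats = {classify_read(p, pair, genome, min_anchor=100, breakpoint_tol=0).category
                for p in iso}
        assert "recombinant" in cats
        assert not cats & {"ref_copy1", "ref_copy2", "ref_both"}


class TestCountSupport:
    def test_partition_identity(self, sim_clean_reads):
        _, genome, truth, paths = sim_clean_reads
        pairs = [truth.pairs_by_name["large_direct"], truth.pairs_by_name["large_inverted"]]
        for sup in count_support(paths, pairs, genome, min_anchor=100, breakpoint_tol=0):
            total = (
                sup.count_ref_copy1_only
                + sup.count_ref_copy2_only
                + sup.count_ref_both
                + sup.count_recombinant
                + sup.uninformative_count
            )
            assert total == sup.n_evaluated == len(paths)

    def test_no_false_recombinants_without_planted_recombination(self, sim_clean_reads):
        _, genome, truth, paths = sim_clean_reads
        sups = count_support(
            paths, truth.repeat_pairs, genome, min_anchor=100, breakpoint_tol=0
        )
        for sup in sups:
            assert sup.count_recombinant == 0
            assert sup.verdict == "reference-only"

    def test_zero_reads_reference_only_with_warning(self, sim_small):
        _, genome, truth = sim_small
        sup = count_support([], [truth.pairs_by_name["large_direct"]], genome)[0]
        assert sup.verdict == "reference-only"
        assert sup.low_evidence

    @pytest.mark.parametrize("frac", [0.1, 0.3, 0.5])
    def test_recovery_of_planted_inversion_fraction(self, frac):
        cfg = SimConfig.small(seed=int(frac * 100), depth=30, inversion_fraction=frac,
                              sub_rate=0.0, ins_rate=0.0, del_rate=0.0)
        genome, truth = simulate_genome(cfg)
        mols = simulate_molecules(genome, truth, cfg)
        paths = simulate_long_reads(mols, genome, cfg, truth=truth)
        pair = truth.pairs_by_name["large_inverted"]
        sup = count_support(paths, [pair], genome, min_anchor=100, breakpoint_tol=0)[0]
        n = sup.count_recombinant + sup.count_reference
        assert n >= 30, "need enough informative reads for the interval test"
        phat = sup.count_recombinant / n
        half = 1.96 * np.sqrt(frac * (1 - frac) / n)
        assert abs(phat - frac) <= half + 1e-9
        assert sup.verdict == "mixed"

    def test_direct_excision_fraction_recovered(self):
        cfg = SimConfig.small(seed=77, depth=30, direct_fraction=0.5,
                              sub_rate=0.0, ins_rate=0.0, del_rate=0.0)
        genome, truth = simulate_genome(cfg)
        mols = simulate_molecules(genome, truth, cfg)
        names = {m.label for m in mols}
        assert {"excision", "remainder"} <= names
        paths = simulate_long_reads(mols, genome, cfg, truth=truth)
        pair = truth.pairs_by_name["large_direct"]
        sup = count_support(paths, [pair], genome, min_anchor=100, breakpoint_tol=0)[0]
        assert sup.count_recombinant > 0
        assert set(sup.recombinant_counts) == {"excision_circle", "remainder_circle"}
        assert sup.verdict == "mixed"

    def test_noisy_reads_still_classified(self):
        cfg = SimConfig.small(seed=55, depth=25, inversion_fraction=0.4)  # default few-% errors
        genome, truth = simulate_genome(cfg)
        mols = simulate_molecules(genome, truth, cfg)
        paths = simulate_long_reads(mols, genome, cfg, truth=truth)
        pair = truth.pairs_by_name["large_inverted"]
        sup = count_support(paths, [pair], genome, min_anchor=100, breakpoint_tol=50)[0]
        assert sup.count_recombinant > 0 and sup.count_reference > 0


class TestJunctionCalling:
    def test_colinear_reads_give_no_calls(self, sim_clean_reads):
        _, genome, _, paths = sim_clean_reads
        assert call_breakpoint_junctions(paths, genome, min_reads=1) == []

    def test_planted_fusion_junction_called(self):
        # fused-molecule scenario: chromosome 1 19.6 kb (+) joins chromosome 2 11.2 kb (+)
        cfg = SimConfig.small(seed=61, depth=10, sub_rate=0.0, ins_rate=0.0, del_rate=0.0)
        genome, truth = simulate_genome(cfg)
        L1 = genome["chromosome_1"].length
        L2 = genome["chromosome_2"].length
        fused = Molecule(
            "fused_custom",
            [("chromosome_1", 1, 19600, "+"), ("chromosome_2", 11220, L2, "+"),
             ("chromosome_1", 19601, L1 - 19600, "+")],
            1.0,
            "fusion",
        )
        paths = simulate_long_reads([fused], genome, cfg, truth=truth)
        calls = call_breakpoint_junctions(paths, genome, min_reads=2, cluster_window=100)
        def near(be, chrom, pos, orient):
            return be.chrom == chrom and be.orient == orient and abs(be.pos - pos) <= 100

        hits = [
            c for c in calls
            if any(near(be, "chromosome_1", 19600, "+") for be in c.signature.breakends)
            and any(near(be, "chromosome_2", 11220, "-") for be in c.signature.breakends)
        ]
        assert len(hits) == 1
        assert hits[0].support >= 2
        # the fused circle's second junction (leaving chromosome 2) is also called
        assert any(
            any(near(be, "chromosome_2", 11219, "+") for be in c.signature.breakends)
            and any(near(be, "chromosome_1", 19601, "-") for be in c.signature.breakends)
            for c in calls
        )

    def test_repeat_mediated_junction_annotated(self):
        cfg = SimConfig.small(seed=63, depth=20, fusion_fraction=0.5,
                              sub_rate=0.0, ins_rate=0.0, del_rate=0.0)
        genome, truth = simulate_genome(cfg)
        mols = simulate_molecules(genome, truth, cfg)
        paths = simulate_long_reads(mols, genome, cfg, truth=truth)
        calls = call_breakpoint_junctions(
            paths, genome, min_reads=2, repeat_pairs=truth.repeat_pairs
        )
        assert calls
        assert any(c.signature.kind == "recombinant" for c in calls)

    def test_presence_matrix_across_samples(self):
        cfg0 = SimConfig.small(seed=71, depth=8, sub_rate=0.0, ins_rate=0.0, del_rate=0.0)
        genome, truth = simulate_genome(cfg0)
        mols_fused = simulate_molecules(
            genome, truth, SimConfig.small(seed=71, depth=8, fusion_fraction=0.6,
                                           sub_rate=0.0, ins_rate=0.0, del_rate=0.0)
        )
        mols_master = [m for m in mols_fused if m.label == "master"]
        for m in mols_master:
            m.weight = 1.0
        calls_by_sample = {}
        for i in range(8):
            carrier = i < 2
            mols = mols_fused if carrier else mols_master
            rng = np.random.default_rng([100 + i])
            paths = simulate_long_reads(mols, genome, cfg0, rng=rng)
            calls_by_sample[f"s{i + 1}"] = call_breakpoint_junctions(
                paths, genome, min_reads=2
            )
        df = junction_presence_matrix(calls_by_sample, genome)
        assert not df.empty
        fused_rows = df[[f"s{i}" for i in range(1, 9)]].values
        # the fused junction is present in exactly the two carrier samples
        carriers = fused_rows.max(axis=0)
        assert list(carriers) == [1, 1, 0, 0, 0, 0, 0, 0]


class TestDepth:
    def test_single_full_circle_read(self):
        g = GenomeSet([CircularSequence("c", "A" * 500, True)])
        path = ReadPath(
            "r0", [AlignmentSegment("r0", 1, 500, CircInterval("c", 1, 500, "+"), "+")]
        )
        prof = depth_profile([path], g, window=50)
        assert prof.median == 1.0 and prof.mean == 1.0
        assert all((w == 1.0).all() for w in prof.per_window.values())
        assert prof.low_intervals == []

    def test_simulated_depth_near_target(self, sim_clean_reads):
        cfg, genome, _, paths = sim_clean_reads
        prof = depth_profile(paths, genome, window=100)
        assert abs(prof.median - cfg.read_model.depth) <= 2

    def test_planted_low_coverage_segment_flagged(self):
        g = GenomeSet([CircularSequence("c", "A" * 30000, True)])
        paths = []
        i = 0
        for start in range(1, 29901, 10):  # ~10x tiling of 100-mers
            end = start + 99
            if 10000 < start <= 20000 and start % 2000:  # ~0.5% coverage inside the hole
                continue
            paths.append(
                ReadPath(f"r{i}", [AlignmentSegment(f"r{i}", 1, 100, CircInterval("c", 1 if end > 30000 else start, min(end, 30000), "+"), "+")])
            )
            i += 1
        prof = depth_profile(paths, g, window=100, low_frac=0.1, min_span=1000)
        assert prof.low_intervals, "hole should be flagged"
        iv = prof.low_intervals[0]
        assert iv.chrom_id == "c"
        assert 9800 <= iv.start <= 10400
        assert 19700 <= iv.end <= 20300
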