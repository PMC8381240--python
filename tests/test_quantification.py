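"""SAM parsing, multimapper exclusion, overlap counting, and CPM."""

import numpy as np
import pandas as pd
import pytest

from retroloci import catalog as cat
from retroloci import quantification as q

SQ_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:100000\n"


def sam_line(read_id, pos, cigar, seq_len=None, nh=None, flag=0, chrom="chr1"):
    if seq_len is None:
        # derive query length from cigar ops that consume the query
        import re

        seq_len = sum(
            int(n) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar) if op in "MIS=X"
        )
    seq = "A" * seq_len
    tag = f"\tNH:i:{nh}" if nh is not None else ""
    return f"{read_id}\t{flag}\t{chrom}\t{pos}\t255\t{cigar}\t*\t0\t0\t{seq}\t{'I' * seq_len}{tag}"


def make_locus(name, start, end, strand="+", chrom="chr1"):
    return cat.RetroelementLocus(
        name=name,
        element_class="ERV",
        segments=(cat.GeneSegment("pol", cat.GenomicInterval(chrom, start, end, strand)),),
    )


def naive_cigar_blocks(cigar: str, pos: int):
    """Oracle: walk the cigar string text directly."""
    import re

    blocks, cur_start, cur = [], pos, pos
    for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        n = int(n)
        if op in "M=XD":
            cur += n
        elif op == "N":
            if cur > cur_start:
                blocks.append((cur_start, cur - 1))
            cur_start = cur = cur + n
    if cur > cur_start:
        blocks.append((cur_start, cur - 1))
    return blocks


class TestReadAlignments:
    def test_simple_match_block(self):
        records = q.read_alignments(SQ_HEADER + sam_line("r1", 101, "50M"))
        assert records[0].aligned_blocks == ((101, 150),)
        assert records[0].nh == 1 and records[0].mapped

    def test_intron_gap_splits_blocks(self):
        records = q.read_alignments(SQ_HEADER + sam_line("r1", 1, "20M100N30M"))
        assert records[0].aligned_blocks == ((1, 20), (121, 150))

    def test_deletion_stays_in_one_block(self):
        records = q.read_alignments(SQ_HEADER + sam_line("r1", 10, "10M5D10M"))
        assert records[0].aligned_blocks == ((10, 34),)

    def test_soft_clips_and_insertions_consume_no_reference(self):
        records = q.read_alignments(SQ_HEADER + sam_line("r1", 100, "5S10M3I10M5S"))
        assert records[0].aligned_blocks == ((100, 119),)

    def test_unmapped_flag_gives_unmapped_record(self):
        line = "u1\t4\t*\t0\t0\t*\t*\t0\t0\tAAAA\tIIII"
        records = q.read_alignments(SQ_HEADER + line)
        assert not records[0].mapped and records[0].aligned_blocks == ()

    def test_nh_tag_parsed_and_default_one(self):
        text = SQ_HEADER + sam_line("r1", 1, "10M", nh=3) + "\n" + sam_line("r2", 1, "10M")
        records = q.read_alignments(text)
        assert [r.nh for r in records] == [3, 1]

    def test_reverse_flag_sets_strand(self):
        records = q.read_alignments(SQ_HEADER + sam_line("r1", 1, "10M", flag=16))
        assert records[0].strand == "-"

    def test_malformed_record_reports_line_number(self):
        text = SQ_HEADER + "garbage line that is not sam\n"
        with pytest.raises(q.SamParseError, match="line 3"):
            q.read_alignments(text)

    def test_random_cigars_match_naive_walker_oracle(self):
        rng = np.random.default_rng(17)
        ops = ["M", "I", "D", "N", "S", "=", "X"]
        for _ in range(300):
            n_ops = rng.integers(1, 6)
            parts = []
            for j in range(n_ops):
                op = ops[rng.integers(len(ops))]
                if j == 0 or j == n_ops - 1:
                    op = "M"  # keep cigars structurally valid
                parts.append(f"{rng.integers(1, 60)}{op}")
            cigar = "".join(parts)
            pos = int(rng.integers(1, 5000))
            records = q.read_alignments(SQ_HEADER + sam_line("r", pos, cigar))
            assert list(records[0].aligned_blocks) == naive_cigar_blocks(cigar, pos)


class TestFilterMultimappers:
    def test_nh_threshold_removes_whole_reads(self):
        text = SQ_HEADER + "\n".join(
            [
                sam_line("a", 1, "10M", nh=1),
                sam_line("b", 1, "10M", nh=2),
                sam_line("b", 500, "10M", nh=2, flag=256),
                sam_line("c", 1, "10M", nh=3),
                sam_line("c", 600, "10M", nh=3, flag=256),
            ]
        )
        kept = q.filter_multimappers(q.read_alignments(text), max_loci=2)
        assert sorted({r.read_id for r in kept}) == ["a", "b"]
        assert len([r for r in kept if r.read_id == "b"]) == 2

    def test_empty_input(self):
        assert q.filter_multimappers([]) == []

    def test_matches_brute_force_predicate(self):
        rng = np.random.default_rng(3)
        records = []
        for i in range(200):
            nh = int(rng.integers(1, 5))
            records.append(
                q.AlignmentRecord(
                    read_id=f"r{i % 60}",
                    chrom="chr1",
                    pos=1,
                    aligned_blocks=((1, 10),),
                    nh=nh,
                    mapped=bool(rng.random() < 0.9),
                )
            )
        for max_loci in (1, 2, 3):
            kept = q.filter_multimappers(records, max_loci=max_loci)
            read_max = {}
            for r in records:
                if r.mapped:
                    read_max[r.read_id] = max(read_max.get(r.read_id, 1), r.nh)
            expected = [r for r in records if r.mapped and read_max[r.read_id] <= max_loci]
            assert kept == expected

    def test_raising_max_loci_never_decreases_counts(self, planted_reads, planted_genome):
        records = q.read_alignments(planted_reads.sam_text)
        prev = None
        for max_loci in (1, 2, 3):
            counts, _ = q.count_by_locus(
                q.filter_multimappers(records, max_loci=max_loci), planted_genome.loci
            )
            if prev is not None:
                assert (counts >= prev).all()
            prev = counts


class TestCountByLocus:
    def test_read_inside_single_locus(self):
        loci = [make_locus("A", 100, 200), make_locus("B", 500, 600)]
        records = q.read_alignments(SQ_HEADER + sam_line("r1", 120, "50M"))
        counts, libsize = q.count_by_locus(records, loci)
        assert counts.to_dict() == {"A": 1, "B": 0} and libsize == 1

    def test_best_overlap_prefers_larger_overlap(self):
        # read 101-140: 30 bp in A (overlap 111-140), 10 bp in B (101-110)
        loci = [make_locus("A", 111, 300), make_locus("B", 50, 110)]
        records = q.read_alignments(SQ_HEADER + sam_line("r1", 101, "40M"))
        counts, _ = q.count_by_locus(records, loci, assignment="best-overlap")
        assert counts.to_dict() == {"A": 1, "B": 0}

    def test_any_overlap_credits_both(self):
        loci = [make_locus("A", 111, 300), make_locus("B", 50, 110)]
        records = q.read_alignments(SQ_HEADER + sam_line("r1", 101, "40M"))
        counts, _ = q.count_by_locus(records, loci, assignment="any-overlap")
        assert counts.to_dict() == {"A": 1, "B": 1}

    def test_tie_breaks_to_lexicographically_smaller_name(self):
        loci = [make_locus("Z", 100, 119), make_locus("A", 120, 139)]
        records = q.read_alignments(SQ_HEADER + sam_line("r1", 110, "20M"))  # 10 bp in each
        counts, _ = q.count_by_locus(records, loci)
        assert counts.to_dict() == {"Z": 0, "A": 1}

    def test_mates_sharing_read_id_count_once(self):
        loci = [make_locus("A", 100, 400)]
        text = SQ_HEADER + sam_line("frag", 120, "50M") + "\n" + sam_line("frag", 300, "50M", flag=0)
        counts, libsize = q.count_by_locus(q.read_alignments(text), loci)
        assert counts["A"] == 1 and libsize == 1

    def test_stranded_mode_requires_same_strand(self):
        loci = [make_locus("A", 100, 200, strand="+")]
        rev = q.read_alignments(SQ_HEADER + sam_line("r1", 120, "20M", flag=16))
        counts_unstranded, _ = q.count_by_locus(rev, loci)
        counts_stranded, _ = q.count_by_locus(rev, loci, stranded=True)
        assert counts_unstranded["A"] == 1 and counts_stranded["A"] == 0

    def test_counts_invariant_to_record_order(self, planted_reads, planted_genome):
        records = q.filter_multimappers(q.read_alignments(planted_reads.sam_text))
        counts_fwd, _ = q.count_by_locus(records, planted_genome.loci)
        counts_rev, _ = q.count_by_locus(list(reversed(records)), planted_genome.loci)
        assert counts_fwd.equals(counts_rev)

    def test_best_overlap_total_bounded_by_retained_reads(self, planted_reads, planted_genome):
        records = q.filter_multimappers(q.read_alignments(planted_reads.sam_text))
        counts, libsize = q.count_by_locus(records, planted_genome.loci)
        assert counts.sum() <= libsize

    def test_simulated_counts_match_brute_force_interval_oracle(
        self, planted_reads, planted_genome
    ):
        records = q.filter_multimappers(q.read_alignments(planted_reads.sam_text))
        footprints = {
            l.name: cat.locus_footprint(l) for l in planted_genome.loci
        }
        # oracle: direct quadratic scan over reads x loci
        by_read = {}
        for r in records:
            by_read.setdefault(r.read_id, []).append(r)
        expected = {name: 0 for name in footprints}
        for recs in by_read.values():
            ov = {}
            for r in recs:
                for s, e in r.aligned_blocks:
                    for name, fp in footprints.items():
                        if fp.chrom == r.chrom and s <= fp.end and fp.start <= e:
                            ov[name] = ov.get(name, 0) + (
                                min(e, fp.end) - max(s, fp.start) + 1
                            )
            if ov:
                best = max(ov.values())
                expected[min(n for n, v in ov.items() if v == best)] += 1
        counts, _ = q.count_by_locus(records, planted_genome.loci)
        assert counts.to_dict() == expected


class TestCpm:
    def test_value_formula(self):
        matrix = q.CountMatrix(
            counts=pd.DataFrame({"s1": [5, 0]}, index=["A", "B"]),
            library_size=pd.Series({"s1": 10**6}),
        )
        cpm = q.cpm_normalize(matrix)
        assert cpm.loc["A", "s1"] == 5.0 and cpm.loc["B", "s1"] == 0.0

    def test_column_sums_equal_assigned_fraction_of_million(self, planted_reads, planted_genome):
        records = q.filter_multimappers(q.read_alignments(planted_reads.sam_text))
        counts, libsize = q.count_by_locus(records, planted_genome.loci)
        matrix = q.CountMatrix(
            counts=counts.to_frame("s1"), library_size=pd.Series({"s1": libsize})
        )
        cpm = q.cpm_normalize(matrix)
        assigned_fraction = counts.sum() / libsize
        assert cpm["s1"].sum() == pytest.approx(1e6 * assigned_fraction)

    def test_zero_library_size_rejected(self):
        matrix = q.CountMatrix(
            counts=pd.DataFrame({"s1": [0]}, index=["A"]),
            library_size=pd.Series({"s1": 0}),
        )
        with pytest.raises(ValueError):
            q.cpm_normalize(matrix)
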