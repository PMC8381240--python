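"""Sequence extraction, translation, ORF assessment, motif scanning, and
competence calls, each checked against an independent brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retroloci import catalog as cat
from retroloci import competence as comp
from retroloci import synthetic_data as sd

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp_slice(chrom_seq: str, start: int, end: int, strand: str) -> str:
    """Independent oracle: explicit 1-based slice and letter-by-letter RC."""
    piece = chrom_seq[start - 1 : end]
    if strand == "-":
        piece = "".join(_COMPLEMENT[b] for b in reversed(piece))
    return piece


def segment(chrom, start, end, strand, role="pol"):
    return cat.GeneSegment(role, cat.GenomicInterval(chrom, start, end, strand))


class TestExtractSegmentSequence:
    def test_plus_strand_slice(self):
        genome = {"chrT": "ACGTACGT"}
        assert comp.extract_segment_sequence(genome, segment("chrT", 1, 4, "+")) == "ACGT"

    def test_minus_strand_is_reverse_complement(self):
        genome = {"chrT": "ACG"}
        assert comp.extract_segment_sequence(genome, segment("chrT", 1, 3, "-")) == "CGT"

    def test_out_of_bounds_raises(self):
        with pytest.raises(ValueError, match="pol"):
            comp.extract_segment_sequence({"chrT": "ACGT"}, segment("chrT", 2, 10, "+"))

    def test_random_segments_match_naive_oracle(self):
        rng = np.random.default_rng(11)
        chrom = "".join(rng.choice(list("ACGT"), size=500))
        genome = {"c": chrom}
        for _ in range(200):
            start = int(rng.integers(1, 480))
            end = int(rng.integers(start, 500))
            strand = "+" if rng.random() < 0.5 else "-"
            assert comp.extract_segment_sequence(
                genome, segment("c", start, end, strand)
            ) == naive_revcomp_slice(chrom, start, end, strand)


class TestTranslate:
    @pytest.mark.parametrize(
        "nt,expected",
        [
            ("ATGTAA", "M*"),
            ("ATGNNN", "MX"),
            ("ATGAA", "M"),  # trailing partial codon dropped
            ("", ""),
            ("atgtaa", "M*"),  # case-insensitive
        ],
    )
    def test_examples(self, nt, expected):
        assert comp.translate(nt) == expected

    def test_any_codon_containing_n_becomes_x(self):
        # stricter than IUPAC resolution: GCN is X here, not A
        assert comp.translate("GCN") == "X"

    def test_random_codons_match_biopython_table(self):
        from Bio.Seq import Seq

        rng = np.random.default_rng(5)
        codons = ["".join(rng.choice(list("ACGT"), size=3)) for _ in range(300)]
        nt = "".join(codons)
        assert comp.translate(nt) == str(Seq(nt).translate())


class TestAssessOrf:
    def test_clean_full_length_pol_not_truncated(self):
        build = sd.build_locus_sequence(
            sd.PlantedLocusSpec("x", "ERV", "intact"), seed=0
        )
        pol = next(s for s in build.segments if s[0] == "pol")
        seq = build.sequence[pol[1] - 1 : pol[2]]
        report = comp.assess_orf(seq, "pol")
        assert not report.truncated
        assert report.premature_stop_index is None
        assert report.length_fraction >= 0.9

    def test_premature_stop_at_known_codon(self):
        build = sd.build_locus_sequence(sd.PlantedLocusSpec("x", "ERV", "intact"), seed=0)
        pol = next(s for s in build.segments if s[0] == "pol")
        seq = build.sequence[pol[1] - 1 : pol[2]]
        mutated = seq[:300] + "TAA" + seq[303:]
        report = comp.assess_orf(mutated, "pol")
        assert report.truncated and report.premature_stop_index == 100

    def test_short_fragment_truncated_via_length_fraction(self):
        seq = "GCT" * 100  # 300 nt of alanine, no stops
        report = comp.assess_orf(seq, "pol")  # canonical pol is 3402 nt
        assert report.truncated
        assert report.premature_stop_index is None
        assert report.length_fraction < 0.9

    def test_terminal_stop_window_is_not_premature(self):
        seq = "GCT" * 99 + "TAA"  # stop at the final codon
        report = comp.assess_orf(seq, "pol", comp.CompetenceConfig(min_length_fraction=0.0))
        assert report.premature_stop_index is None and not report.truncated

    def test_no_stop_and_sufficient_length_never_truncated(self):
        for n in (1140, 1200, 1300):
            assert not comp.assess_orf("GCT" * n, "pol").truncated


class TestFrameRelation:
    def _locus(self, gag_start, pol_start, strand="+", gag_len=300, pol_len=300):
        return cat.RetroelementLocus(
            name="fr",
            element_class="ERV",
            segments=(
                segment("c", gag_start, gag_start + gag_len - 1, strand, role="gag"),
                segment("c", pol_start, pol_start + pol_len - 1, strand, role="pol"),
            ),
        )

    def test_offset_zero_in_frame(self):
        rel = comp.gag_pol_frame_relation(self._locus(1, 301))
        assert rel.gag_pol_offset == 0 and rel.in_frame

    def test_offset_one_out_of_frame_by_default(self):
        rel = comp.gag_pol_frame_relation(self._locus(1, 302))
        assert rel.gag_pol_offset == 1 and not rel.in_frame

    def test_configured_offsets_admit_frameshift(self):
        config = comp.CompetenceConfig().with_offsets([0, 2])
        rel = comp.gag_pol_frame_relation(self._locus(1, 303), config)
        assert rel.gag_pol_offset == 2 and rel.in_frame

    def test_minus_strand_uses_descending_coordinates(self):
        # coding order on '-' runs from high to low coordinates: compare ends
        locus = cat.RetroelementLocus(
            name="m",
            element_class="ERV",
            segments=(
                segment("c", 701, 1000, "-", role="gag"),
                segment("c", 101, 700, "-", role="pol"),
            ),
        )
        rel = comp.gag_pol_frame_relation(locus)
        assert rel.gag_pol_offset == (1000 - 700) % 3 == 0 and rel.in_frame

    def test_missing_segment_raises_coded_error(self):
        locus = cat.RetroelementLocus(
            name="nopol",
            element_class="ERV",
            segments=(segment("c", 1, 300, "+", role="gag"),),
        )
        with pytest.raises(comp.MissingSegmentError):
            comp.gag_pol_frame_relation(locus)


def brute_force_motif_scan(aa: str):
    """Oracle: explicit per-position window checks, no regex."""
    std = set(comp.STANDARD_AA)
    hits = []
    for i in range(len(aa)):
        w = aa[i:]
        if len(w) >= 4 and w[0] == "Y" and w[1] in std and w[2] == "D" and w[3] == "D":
            hits.append(("YxDD", i))
        if w.startswith("DLKDAF"):
            hits.append(("DLKDAF", i))
        if (
            len(w) >= 8
            and w[0] in "WY"
            and all(c in std for c in w[1:4])
            and w[4:8] == "LPQG"
        ):
            hits.append(("WY-LPQG", i))
        if w.startswith("QDLREVNK"):
            hits.append(("QDLREVNK", i))
    return hits


class TestScanRtMotifs:
    def test_yxdd_example(self):
        hits = comp.scan_rt_motifs("AAYMDDAA")
        assert [(h.motif_id, h.position) for h in hits] == [("YxDD", 2)]

    def test_template_binding_motifs(self):
        hits = comp.scan_rt_motifs("WAAALPQGQDLREVNK")
        assert {(h.motif_id, h.position) for h in hits} == {("WY-LPQG", 0), ("QDLREVNK", 8)}

    def test_x_never_matches_ambiguous_or_stop(self):
        assert comp.scan_rt_motifs("YXDD") == []  # literal 'X' is not a residue
        assert comp.scan_rt_motifs("Y*DD") == []
        assert comp.scan_rt_motifs("W*AALPQG") == []

    def test_random_sequences_match_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        alphabet = list(comp.STANDARD_AA + "X*")
        for _ in range(300):
            aa = "".join(rng.choice(alphabet, size=200))
            got = {(h.motif_id, h.position) for h in comp.scan_rt_motifs(aa)}
            assert got == set(brute_force_motif_scan(aa))

    @given(prefix=st.text(alphabet=comp.STANDARD_AA, min_size=0, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_position_shift_equivariance(self, prefix):
        core = "WAAALPQGQDLREVNKDLKDAFYMDD"
        base = {(h.motif_id, h.position) for h in comp.scan_rt_motifs(core)}
        shifted = {(h.motif_id, h.position) for h in comp.scan_rt_motifs(prefix + core)}
        expected = {(m, p + len(prefix)) for m, p in base}
        # the prefix may create additional hits at the junction; the shifted
        # copies of the core hits must all be present
        assert expected <= shifted


class TestCallCompetence:
    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize(
        "element_class,integrity",
        [("ERV", c) for c in sd.ERV_INTEGRITY_CLASSES]
        + [("LINE1", c) for c in sd.LINE1_INTEGRITY_CLASSES],
    )
    def test_recovers_planted_verdict_and_reasons(self, element_class, integrity, strand):
        spec = sd.PlantedLocusSpec(
            name="probe",
            element_class=element_class,
            integrity_class=integrity,
            chrom="chrS",
            offset=200,
            strand=strand,
        )
        sim = sd.SimulationSpec(seed=31, chrom_lengths={"chrS": 10000}, loci=(spec,))
        build = sd.build_genome(sim)
        call = comp.call_competence(build.loci[0], build.genome)
        truth = build.truth["probe"]
        assert call.verdict == truth.verdict
        assert set(call.reasons) == set(truth.reasons)

    def test_strand_relocation_leaves_call_unchanged(self):
        # same construction seed, opposite strands -> identical verdict/reasons
        calls = []
        for strand in "+-":
            spec = sd.PlantedLocusSpec(
                "s", "ERV", "pol_premature_stop", chrom="c", offset=100, strand=strand
            )
            sim = sd.SimulationSpec(seed=13, chrom_lengths={"c": 9000}, loci=(spec,))
            build = sd.build_genome(sim)
            calls.append(comp.call_competence(build.loci[0], build.genome))
        assert calls[0].verdict == calls[1].verdict
        assert set(calls[0].reasons) == set(calls[1].reasons)

    def test_intact_erv_reports_all_four_motifs(self):
        sim = sd.SimulationSpec(
            seed=3,
            chrom_lengths={"c": 9000},
            loci=(sd.PlantedLocusSpec("i", "ERV", "intact", chrom="c", offset=100),),
        )
        build = sd.build_genome(sim)
        call = comp.call_competence(build.loci[0], build.genome)
        assert call.verdict == "competent"
        assert {h.motif_id for h in call.motif_hits} == set(comp.MOTIF_IDS)

    def test_verdict_reasons_consistency_enforced(self):
        with pytest.raises(ValueError):
            comp.CompetenceCall("x", "ERV", "competent", reasons=("TRUNCATED_POL",))
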