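"""Reverse-transcription / retrotransposition competence calls from sequence.

A locus is *competent* when its annotated genes retain the sequence features
required for activity:

* ERV: the gag and pro-pol ORFs are present and not truncated, gag is in
  frame with pro-pol, and the pol translation carries the four conserved
  reverse-transcriptase active-site motifs of the RVT_1 domain —
  YxDD and DLKDAF (Mg2+ coordination / polymerization site) and
  [WY]xxxLPQG and QDLREVNK (template binding).
* LINE-1: ORF1 (RNA chaperone) and ORF2 (RT/endonuclease) are present and
  not truncated, and the ORF2 translation carries YxDD.

Every failed condition is recorded as a coded reason; a locus is competent
iff no reason accrues.  "Truncated" means an in-frame premature stop codon
(earlier than the last ``terminal_stop_window`` codons) or a nucleotide
length below ``min_length_fraction`` of the configured canonical gene length.
Translation is always frame 0 of the annotated, strand-oriented segment —
the catalog coordinates are taken to delimit the ORF.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from Bio.Data import CodonTable
from Bio.Seq import reverse_complement

from .catalog import GeneSegment, RetroelementLocus

__all__ = [
    "CompetenceConfig",
    "OrfReport",
    "FrameRelation",
    "RtMotifHit",
    "CompetenceCall",
    "MOTIF_IDS",
    "MOTIF_LENGTHS",
    "ERV_REQUIRED_MOTIFS",
    "LINE1_REQUIRED_MOTIFS",
    "extract_segment_sequence",
    "translate",
    "assess_orf",
    "gag_pol_frame_relation",
    "scan_rt_motifs",
    "call_competence",
    "MissingSegmentError",
]

# ---------------------------------------------------------------------------
# Genetic code (standard table; stops rendered '*', any codon with a non-ACGT
# base rendered 'X' — deliberately stricter than IUPAC ambiguity resolution).

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    _CODON_TO_AA[_stop] = "*"

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# RT active-site motifs.  'x' positions match any one of the 20 standard
# residues (never 'X' or '*'); bracketed positions are alternatives; all other
# positions are literal.  Lookahead groups allow overlapping occurrences.
MOTIF_PATTERNS: dict[str, re.Pattern] = {
    "YxDD": re.compile(f"(?=(Y[{STANDARD_AA}]DD))"),
    "DLKDAF": re.compile("(?=(DLKDAF))"),
    "WY-LPQG": re.compile(f"(?=([WY][{STANDARD_AA}]{{3}}LPQG))"),
    "QDLREVNK": re.compile("(?=(QDLREVNK))"),
}
MOTIF_IDS = tuple(MOTIF_PATTERNS)
MOTIF_LENGTHS = {"YxDD": 4, "DLKDAF": 6, "WY-LPQG": 8, "QDLREVNK": 8}

ERV_REQUIRED_MOTIFS = ("YxDD", "DLKDAF", "WY-LPQG", "QDLREVNK")
LINE1_REQUIRED_MOTIFS = ("YxDD",)

#: Expected 5'->3' order of the template-binding and catalytic motifs within
#: an RT domain, enforced only under ``strict_motif_order``.
_MOTIF_ORDER = ("WY-LPQG", "QDLREVNK", "YxDD")


class MissingSegmentError(ValueError):
    """A required gene segment is absent from the locus annotation."""

    code = "MISSING_SEGMENT"


@dataclass(frozen=True)
class CompetenceConfig:
    """Tunables of the competence model.

    canonical_lengths
        Reference nucleotide lengths per gene role used for the
        length-fraction arm of the truncation rule.  Defaults approximate
        full-length murine gammaretroviral gag/pol/env and LINE-1 ORF1/ORF2.
    min_length_fraction
        A segment shorter than this fraction of canonical is truncated.
    terminal_stop_window
        Stops within this many codons of the segment end count as the
        natural terminal stop, not premature.
    allowed_frame_offsets
        gag->pol codon-phase offsets accepted as "in frame".  {0} models
        readthrough-style gammaretroviral expression; add 2 to admit a -1
        programmed frameshift.
    strict_motif_order
        Additionally require [WY]xxxLPQG < QDLREVNK < YxDD by position.
    """

    canonical_lengths: Mapping[str, int] = field(
        default_factory=lambda: {
            "gag": 1602,
            "pol": 3402,
            "env": 1902,
            "ORF1": 1101,
            "ORF2": 3801,
        }
    )
    min_length_fraction: float = 0.9
    terminal_stop_window: int = 5
    allowed_frame_offsets: frozenset[int] = frozenset({0})
    strict_motif_order: bool = False

    def with_offsets(self, offsets: Sequence[int]) -> "CompetenceConfig":
        return replace(self, allowed_frame_offsets=frozenset(offsets))


DEFAULT_CONFIG = CompetenceConfig()


@dataclass(frozen=True)
class OrfReport:
    role: str
    nt_length: int
    aa_sequence: str
    premature_stop_index: int | None
    truncated: bool
    length_fraction: float


@dataclass(frozen=True)
class FrameRelation:
    gag_pol_offset: int
    in_frame: bool


@dataclass(frozen=True)
class RtMotifHit:
    motif_id: str
    position: int  # 0-based start index in the protein


@dataclass(frozen=True)
class CompetenceCall:
    locus_name: str
    element_class: str
    verdict: str  # "competent" | "defective"
    reasons: tuple[str, ...]
    motif_hits: tuple[RtMotifHit, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "reasons", tuple(self.reasons))
        object.__setattr__(self, "motif_hits", tuple(self.motif_hits))
        expected = "competent" if not self.reasons else "defective"
        if self.verdict != expected:
            raise ValueError(
                f"verdict {self.verdict!r} inconsistent with reasons {self.reasons!r}"
            )


# ---------------------------------------------------------------------------
# Sequence access and translation


def extract_segment_sequence(genome: Mapping[str, str], segment: GeneSegment) -> str:
    """Slice a segment out of the genome, oriented 5'->3' on the coding strand.

    ``genome`` maps chromosome name to sequence (e.g. from
    :func:`retroloci.io.load_fasta`).  Minus-strand segments are returned
    reverse-complemented, so index 0 is the segment's 5' end.
    """
    iv = segment.interval
    try:
        chrom_seq = genome[iv.chrom]
    except KeyError as exc:
        raise KeyError(f"segment {segment.role} ({iv.chrom}): chromosome absent from genome") from exc
    if iv.end > len(chrom_seq):
        raise ValueError(
            f"segment {segment.role} ({iv.chrom}:{iv.start}-{iv.end}) exceeds "
            f"chromosome length {len(chrom_seq)}"
        )
    seq = str(chrom_seq[iv.start - 1 : iv.end]).upper()
    if iv.strand == "-":
        seq = reverse_complement(seq)
    return seq


def translate(nt: str) -> str:
    """Translate frame 0 with the standard genetic code.

    Stops are ``'*'``; any codon containing a base other than A/C/G/T becomes
    ``'X'``; a trailing partial codon is ignored.
    """
    nt = nt.upper()
    aa = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        aa.append(_CODON_TO_AA.get(nt[i : i + 3], "X"))
    return "".join(aa)


def assess_orf(
    segment_seq: str, role: str, config: CompetenceConfig = DEFAULT_CONFIG
) -> OrfReport:
    """Judge ORF integrity of a strand-oriented segment sequence.

    A stop is premature when its codon index lies before the final
    ``terminal_stop_window`` codons; the segment is truncated when a premature
    stop exists or its length fraction falls below the configured minimum.
    """
    if not segment_seq:
        raise ValueError("segment sequence is empty")
    aa = translate(segment_seq)
    n_codons = len(aa)
    stop_at = aa.find("*")
    premature: int | None = None
    if 0 <= stop_at < n_codons - config.terminal_stop_window:
        premature = stop_at
    canonical = config.canonical_lengths.get(role)
    fraction = len(segment_seq) / canonical if canonical else 1.0
    truncated = premature is not None or fraction < config.min_length_fraction
    return OrfReport(
        role=role,
        nt_length=len(segment_seq),
        aa_sequence=aa,
        premature_stop_index=premature,
        truncated=truncated,
        length_fraction=fraction,
    )


def gag_pol_frame_relation(
    locus: RetroelementLocus, config: CompetenceConfig = DEFAULT_CONFIG
) -> FrameRelation:
    """Codon-phase offset between the gag and pol reading frames.

    Strand-oriented CDS starts are compared mod 3: on '+' the genomic starts,
    on '-' the genomic ends (coordinates descend along the coding strand).
    """
    gag = locus.segment("gag")
    pol = locus.segment("pol")
    if gag is None or pol is None:
        missing = "gag" if gag is None else "pol"
        raise MissingSegmentError(f"locus {locus.name!r} lacks a {missing} segment")
    if locus.strand == "+":
        offset = (pol.interval.start - gag.interval.start) % 3
    else:
        offset = (gag.interval.end - pol.interval.end) % 3
    return FrameRelation(gag_pol_offset=offset, in_frame=offset in config.allowed_frame_offsets)


def scan_rt_motifs(aa: str) -> list[RtMotifHit]:
    """Find every occurrence of the four RT active-site motifs in a protein.

    Occurrences may overlap; hits are reported in motif order, then position.
    """
    hits: list[RtMotifHit] = []
    for motif_id, pattern in MOTIF_PATTERNS.items():
        for m in pattern.finditer(aa):
            hits.append(RtMotifHit(motif_id=motif_id, position=m.start()))
    return hits


# ---------------------------------------------------------------------------
# The competence rules


def _check_orf(
    locus: RetroelementLocus,
    genome: Mapping[str, str],
    role: str,
    config: CompetenceConfig,
    reasons: list[str],
) -> OrfReport | None:
    seg = locus.segment(role)
    if seg is None:
        reasons.append(f"MISSING_{role.upper()}")
        return None
    report = assess_orf(extract_segment_sequence(genome, seg), role, config)
    if report.truncated:
        reasons.append(f"TRUNCATED_{role.upper()}")
    return report


def call_competence(
    locus: RetroelementLocus,
    genome: Mapping[str, str],
    config: CompetenceConfig = DEFAULT_CONFIG,
) -> CompetenceCall:
    """Apply the ERV or LINE-1 competence rule to one locus.

    ERV: competent iff gag and pol are present, neither truncated, gag in
    frame with pol, and all four RT motifs occur in the pol translation.
    LINE-1: competent iff ORF1 and ORF2 are present, neither truncated, and
    YxDD occurs in the ORF2 translation.  Each failed condition contributes
    one coded reason; failures never raise.
    """
    reasons: list[str] = []
    motif_hits: tuple[RtMotifHit, ...] = ()

    if locus.element_class == "ERV":
        gag_report = _check_orf(locus, genome, "gag", config, reasons)
        pol_report = _check_orf(locus, genome, "pol", config, reasons)
        if gag_report is not None and pol_report is not None:
            relation = gag_pol_frame_relation(locus, config)
            if not relation.in_frame:
                reasons.append("GAG_POL_FRAMESHIFT")
        if pol_report is not None:
            hits = scan_rt_motifs(pol_report.aa_sequence)
            motif_hits = tuple(hits)
            present = {h.motif_id for h in hits}
            for motif_id in ERV_REQUIRED_MOTIFS:
                if motif_id not in present:
                    reasons.append(f"MOTIF_ABSENT:{motif_id}")
            if config.strict_motif_order and all(m in present for m in _MOTIF_ORDER):
                firsts = {
                    m: min(h.position for h in hits if h.motif_id == m) for m in _MOTIF_ORDER
                }
                if not (firsts["WY-LPQG"] < firsts["QDLREVNK"] < firsts["YxDD"]):
                    reasons.append("MOTIF_ORDER_VIOLATION")
    elif locus.element_class == "LINE1":
        _check_orf(locus, genome, "ORF1", config, reasons)
        orf2_report = _check_orf(locus, genome, "ORF2", config, reasons)
        if orf2_report is not None:
            hits = scan_rt_motifs(orf2_report.aa_sequence)
            motif_hits = tuple(hits)
            present = {h.motif_id for h in hits}
            for motif_id in LINE1_REQUIRED_MOTIFS:
                if motif_id not in present:
                    reasons.append(f"MOTIF_ABSENT:{motif_id}")
    else:  # pragma: no cover - catalog construction forbids other classes
        raise ValueError(f"unknown element class {locus.element_class!r}")

    verdict = "competent" if not reasons else "defective"
    return CompetenceCall(
        locus_name=locus.name,
        element_class=locus.element_class,
        verdict=verdict,
        reasons=tuple(reasons),
        motif_hits=motif_hits,
    )
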