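"""Seedable generators for every input the pipeline consumes, with ground truth.

The generators plant retroelement loci of *known* integrity class into random
genomes, emit alignment records with controlled multimapping, draw
negative-binomial count matrices with planted fold changes, and build qPCR CT
and flow-cytometry tables with known expression ratios — so each pipeline
stage can be checked against construction-time truth without any external
data.

Integrity classes and the competence verdict they force:

==================  =======  ==========================================
class               element  forced verdict / reason
==================  =======  ==========================================
intact              both     competent
gag_frameshift      ERV      GAG_POL_FRAMESHIFT (1-nt insertion in the
                             gag-pol spacer)
pol_premature_stop  ERV      TRUNCATED_POL (mid-pol codon -> TAA)
pol_fragment        ERV      TRUNCATED_POL (pol cut below the canonical
                             length fraction; motifs retained)
motif_ablated       both     MOTIF_ABSENT:YxDD (YxDD site not spliced in)
missing_orf1        LINE1    MISSING_ORF1 (no ORF1 annotation)
truncated_orf2      LINE1    TRUNCATED_ORF2 (mid-ORF2 codon -> TAA)
==================  =======  ==========================================

Construction guarantees exact truth: ORF bodies are sampled from codons whose
amino acids exclude D and Q, so no RT motif (each of which needs a D or Q)
can arise by chance — motif occurrences are exactly the spliced ones.  All
generators are pure functions of (spec, seed); identical inputs give
byte-identical outputs (numpy PCG64 streams).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .catalog import GeneSegment, GenomicInterval, RetroelementLocus, locus_footprint
from .competence import _CODON_TO_AA, CompetenceCall

__all__ = [
    "PlantedLocusSpec",
    "SimulationSpec",
    "CountSimulation",
    "CtSimulation",
    "FlowSimulation",
    "LocusBuild",
    "GenomeBuild",
    "AlignmentSim",
    "build_locus_sequence",
    "build_genome",
    "simulate_alignments",
    "simulate_counts",
    "simulate_ct_table",
    "simulate_flow_table",
    "ERV_INTEGRITY_CLASSES",
    "LINE1_INTEGRITY_CLASSES",
]

ERV_INTEGRITY_CLASSES = (
    "intact",
    "gag_frameshift",
    "pol_premature_stop",
    "pol_fragment",
    "motif_ablated",
)
LINE1_INTEGRITY_CLASSES = ("intact", "missing_orf1", "truncated_orf2", "motif_ablated")

# ORF-body alphabet: the 20 standard residues minus D and Q.  Every RT motif
# contains at least one D or Q, so bodies cannot create accidental motifs.
_BODY_AA = "ACEFGHIKLMNPRSTVWY"

# Synonymous-codon table for body sampling (stop codons excluded by design).
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in _CODON_TO_AA.items():
    if _aa != "*":
        _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
for _codons in _AA_TO_CODONS.values():
    _codons.sort()

# Gene geometry (codon counts include the terminal stop); aligned with the
# default canonical lengths of the competence model.
_GAG_CODONS = 534  # 1602 nt
_POL_CODONS = 1134  # 3402 nt
_ENV_CODONS = 634  # 1902 nt
_ORF1_CODONS = 367  # 1101 nt
_ORF2_CODONS = 1267  # 3801 nt
_FLANK = 30
_SPACER = 99  # multiple of 3: keeps gag and pol in frame

# Motif splice sites (0-based codon index within the body of pol / ORF2).
_POL_SPLICES = {200: "WIEALPQG", 300: "QDLREVNK", 400: "DLKDAF", 500: "YMDD"}
_ORF2_SPLICES = {500: "YMDD"}
_POL_STOP_CODON = 700  # premature-stop lesion site (after all motifs)
_ORF2_STOP_CODON = 600
_POL_FRAGMENT_NT = 1800  # 600 codons: keeps all motifs, fraction 0.53 < 0.9

_DNA = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class PlantedLocusSpec:
    """One locus to plant: where, which element class, which lesion."""

    name: str
    element_class: str
    integrity_class: str
    chrom: str = "chr1"
    offset: int = 0  # 0-based insertion offset on the chromosome
    strand: str = "+"

    def __post_init__(self) -> None:
        allowed = {
            "ERV": ERV_INTEGRITY_CLASSES,
            "LINE1": LINE1_INTEGRITY_CLASSES,
        }.get(self.element_class)
        if allowed is None:
            raise ValueError(f"element_class must be ERV or LINE1, got {self.element_class!r}")
        if self.integrity_class not in allowed:
            raise ValueError(
                f"integrity class {self.integrity_class!r} incompatible with "
                f"{self.element_class} (allowed: {allowed})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")


@dataclass(frozen=True)
class SimulationSpec:
    """Genome + read simulation: planted loci, expression, multimapping."""

    seed: int
    chrom_lengths: Mapping[str, int]
    loci: tuple[PlantedLocusSpec, ...]
    expression: Mapping[str, float] = field(default_factory=dict)
    read_length: int = 75
    n_reads: int = 2000
    multimap_fraction: float = 0.0
    multimap3_fraction: float = 0.0
    paralog_pairs: tuple[tuple[str, str], ...] = ()
    background_fraction: float = 0.1

    def __post_init__(self) -> None:
        object.__setattr__(self, "loci", tuple(self.loci))
        object.__setattr__(self, "paralog_pairs", tuple(map(tuple, self.paralog_pairs)))
        for frac in (self.multimap_fraction, self.multimap3_fraction, self.background_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


@dataclass(frozen=True)
class LocusBuild:
    """A constructed locus: forward-orientation sequence, relative segments, truth."""

    sequence: str
    segments: tuple[tuple[str, int, int], ...]  # (role, rel start, rel end), 1-based
    truth: CompetenceCall


@dataclass(frozen=True)
class GenomeBuild:
    fasta_text: str
    catalog_text: str
    genome: Mapping[str, str]
    loci: tuple[RetroelementLocus, ...]
    truth: Mapping[str, CompetenceCall]


@dataclass(frozen=True)
class AlignmentSim:
    sam_text: str
    truth_counts: Mapping[str, int]
    library_size: int  # distinct reads surviving the NH <= 2 filter


# ---------------------------------------------------------------------------
# Locus construction


def _random_body(n_codons: int, rng: np.random.Generator, splices: Mapping[int, str]) -> str:
    aa = list(rng.choice(list(_BODY_AA), size=n_codons))
    for pos, peptide in splices.items():
        if pos + len(peptide) > n_codons:
            raise ValueError("splice exceeds body length")
        aa[pos : pos + len(peptide)] = list(peptide)
    codons = [_AA_TO_CODONS[a][rng.integers(len(_AA_TO_CODONS[a]))] for a in aa]
    return "".join(codons)


def _random_nt(n: int, rng: np.random.Generator) -> str:
    return rng.choice(_DNA, size=n).tobytes().decode()


def _mutate_codon_to_stop(orf_nt: str, codon_index: int) -> str:
    i = codon_index * 3
    return orf_nt[:i] + "TAA" + orf_nt[i + 3 :]


def build_locus_sequence(
    spec: PlantedLocusSpec, seed: int | np.random.Generator
) -> LocusBuild:
    """Construct the locus sequence, relative gene segments, and forced verdict.

    The sequence is returned in forward (coding-strand) orientation; minus-
    strand placement is handled by :func:`build_genome`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ic = spec.integrity_class
    reasons: tuple[str, ...] = ()

    if spec.element_class == "ERV":
        gag = _random_body(_GAG_CODONS - 1, rng, {}) + "TAA"
        spacer1_len = _SPACER + (1 if ic == "gag_frameshift" else 0)
        pol_splices = dict(_POL_SPLICES)
        if ic == "motif_ablated":
            del pol_splices[500]  # drop the YxDD site
        pol = _random_body(_POL_CODONS - 1, rng, pol_splices) + "TAA"
        if ic == "pol_premature_stop":
            pol = _mutate_codon_to_stop(pol, _POL_STOP_CODON)
        elif ic == "pol_fragment":
            pol = pol[:_POL_FRAGMENT_NT]
        env = _random_body(_ENV_CODONS - 1, rng, {}) + "TAA"

        parts = [
            ("flank", _random_nt(_FLANK, rng)),
            ("gag", gag),
            ("spacer", _random_nt(spacer1_len, rng)),
            ("pol", pol),
            ("spacer", _random_nt(_SPACER, rng)),
            ("env", env),
            ("flank", _random_nt(_FLANK, rng)),
        ]
        reasons = {
            "intact": (),
            "gag_frameshift": ("GAG_POL_FRAMESHIFT",),
            "pol_premature_stop": ("TRUNCATED_POL",),
            "pol_fragment": ("TRUNCATED_POL",),
            "motif_ablated": ("MOTIF_ABSENT:YxDD",),
        }[ic]
    else:  # LINE1
        orf2_splices = dict(_ORF2_SPLICES)
        if ic == "motif_ablated":
            orf2_splices.pop(500)
        orf2 = _random_body(_ORF2_CODONS - 1, rng, orf2_splices) + "TAA"
        if ic == "truncated_orf2":
            orf2 = _mutate_codon_to_stop(orf2, _ORF2_STOP_CODON)
        parts = [("flank", _random_nt(_FLANK, rng))]
        if ic != "missing_orf1":
            orf1 = _random_body(_ORF1_CODONS - 1, rng, {}) + "TAA"
            parts += [("ORF1", orf1), ("spacer", _random_nt(_SPACER, rng))]
        parts += [("ORF2", orf2), ("flank", _random_nt(_FLANK, rng))]
        reasons = {
            "intact": (),
            "missing_orf1": ("MISSING_ORF1",),
            "truncated_orf2": ("TRUNCATED_ORF2",),
            "motif_ablated": ("MOTIF_ABSENT:YxDD",),
        }[ic]

    sequence = ""
    segments: list[tuple[str, int, int]] = []
    pos = 0
    for label, chunk in parts:
        if label in ("gag", "pol", "env", "ORF1", "ORF2"):
            segments.append((label, pos + 1, pos + len(chunk)))
        sequence += chunk
        pos += len(chunk)

    truth = CompetenceCall(
        locus_name=spec.name,
        element_class=spec.element_class,
        verdict="competent" if not reasons else "defective",
        reasons=reasons,
    )
    return LocusBuild(sequence=sequence, segments=tuple(segments), truth=truth)


# ---------------------------------------------------------------------------
# Genome assembly


def _map_segment(
    rel_start: int, rel_end: int, offset: int, length: int, strand: str
) -> tuple[int, int]:
    """Map a 1-based segment on the forward locus sequence to the chromosome."""
    if strand == "+":
        return offset + rel_start, offset + rel_end
    return offset + length - rel_end + 1, offset + length - rel_start + 1


def build_genome(sim: SimulationSpec) -> GenomeBuild:
    """Random background chromosomes with planted loci; returns FASTA + catalog.

    Minus-strand loci are inserted as the reverse complement of the built
    sequence, with segment coordinates mapped accordingly.  Planted loci must
    fit their chromosomes and must not overlap one another.
    """
    ss = np.random.SeedSequence(sim.seed)
    children = ss.spawn(1 + len(sim.loci))
    bg_rng = np.random.default_rng(children[0])

    chroms: dict[str, np.ndarray] = {
        name: bg_rng.choice(_DNA, size=length)
        for name, length in sim.chrom_lengths.items()
    }

    placed: dict[str, list[tuple[int, int]]] = {}
    loci: list[RetroelementLocus] = []
    truth: dict[str, CompetenceCall] = {}

    for spec, child in zip(sim.loci, children[1:]):
        build = build_locus_sequence(spec, np.random.default_rng(child))
        length = len(build.sequence)
        if spec.chrom not in chroms:
            raise ValueError(f"locus {spec.name!r}: unknown chromosome {spec.chrom!r}")
        if spec.offset + length > len(chroms[spec.chrom]):
            raise ValueError(f"locus {spec.name!r} does not fit chromosome {spec.chrom!r}")
        span = (spec.offset, spec.offset + length)
        for other in placed.get(spec.chrom, []):
            if span[0] < other[1] and other[0] < span[1]:
                raise ValueError(f"locus {spec.name!r} overlaps a previously planted locus")
        placed.setdefault(spec.chrom, []).append(span)

        inserted = build.sequence if spec.strand == "+" else reverse_complement(build.sequence)
        chroms[spec.chrom][span[0] : span[1]] = np.frombuffer(inserted.encode(), dtype="S1")

        segments = []
        for role, rel_s, rel_e in build.segments:
            g_start, g_end = _map_segment(rel_s, rel_e, spec.offset, length, spec.strand)
            segments.append(
                GeneSegment(
                    role=role,
                    interval=GenomicInterval(
                        chrom=spec.chrom, start=g_start, end=g_end, strand=spec.strand
                    ),
                )
            )
        loci.append(
            RetroelementLocus(
                name=spec.name,
                element_class=spec.element_class,
                segments=tuple(segments),
            )
        )
        truth[spec.name] = build.truth

    genome = {name: arr.tobytes().decode() for name, arr in chroms.items()}
    return GenomeBuild(
        fasta_text=_fasta(genome),
        catalog_text=_catalog_tsv(loci),
        genome=genome,
        loci=tuple(loci),
        truth=truth,
    )


def _fasta(genome: Mapping[str, str], width: int = 70) -> str:
    lines = []
    for name, seq in genome.items():
        lines.append(f">{name}")
        lines.extend(seq[i : i + width] for i in range(0, len(seq), width))
    return "\n".join(lines) + "\n"


def _catalog_tsv(loci: Sequence[RetroelementLocus]) -> str:
    header = ["name", "class", "gag", "pol", "env", "ORF1", "ORF2", "aliases"]
    rows = ["\t".join(header)]
    for locus in loci:
        cells = {role: "" for role in header[2:7]}
        for seg in locus.segments:
            iv = seg.interval
            cells[seg.role] = f"{iv.chrom}:{iv.start}-{iv.end} ({iv.strand})"
        rows.append(
            "\t".join(
                [locus.name, locus.element_class]
                + [cells[r] for r in header[2:7]]
                + [",".join(locus.aliases)]
            )
        )
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# Read simulation


def simulate_alignments(
    sim: SimulationSpec,
    genome: Mapping[str, str],
    loci: Sequence[RetroelementLocus],
) -> AlignmentSim:
    """Emit SAM records with ground-truth per-locus counts.

    Per-locus read counts are multinomial in the expression weights.  Reads
    are perfect-match, plus-strand, fixed-length (``<len>M``) placements
    uniform within locus footprints.  A ``multimap_fraction`` of the reads of
    paralog-paired loci is emitted as duplicate records at both paralog sites
    with NH=2 (the duplicate placement is positional; its bases are taken
    from the originating site).  A ``multimap3_fraction`` is emitted with
    NH=3 and must vanish from counts under the strict filter.  Background
    reads fall outside all footprints.  Truth bookkeeping mirrors the
    counting contract: an NH=2 read ties between equal-length paralog
    footprints and is credited to the lexicographically smaller name.
    """
    rng = np.random.default_rng(np.random.SeedSequence((sim.seed, 0x5EAD)))
    footprints = {locus.name: locus_footprint(locus) for locus in loci}
    partner = {}
    for a, b in sim.paralog_pairs:
        for x, y in ((a, b), (b, a)):
            if x not in footprints or y not in footprints:
                raise ValueError(f"paralog pair references unknown locus {x!r}/{y!r}")
        if footprints[a].length != footprints[b].length:
            raise ValueError(f"paralog pair ({a!r}, {b!r}) must have equal footprint lengths")
        partner[a] = b
        partner[b] = a

    names = [locus.name for locus in loci]
    weights = np.array([float(sim.expression.get(n, 0.0)) for n in names])
    truth_counts = {n: 0 for n in names}
    sam_lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        *(
            f"@SQ\tSN:{chrom}\tLN:{len(seq)}"
            for chrom, seq in genome.items()
        ),
    ]
    read_no = 0
    n_retained = 0
    L = sim.read_length

    def emit(read_id: str, flag: int, chrom: str, pos: int, seq: str, nh: int) -> None:
        qual = "I" * len(seq)
        sam_lines.append(
            f"{read_id}\t{flag}\t{chrom}\t{pos}\t255\t{len(seq)}M\t*\t0\t0\t{seq}\t{qual}\tNH:i:{nh}"
        )

    if weights.sum() > 0 and sim.n_reads > 0:
        per_locus = rng.multinomial(sim.n_reads, weights / weights.sum())
    else:
        per_locus = np.zeros(len(names), dtype=int)

    for name, n_reads in zip(names, per_locus):
        fp = footprints[name]
        if n_reads and fp.length < L:
            raise ValueError(f"footprint of {name!r} shorter than the read length")
        for _ in range(int(n_reads)):
            read_no += 1
            read_id = f"read{read_no:07d}"
            rel = int(rng.integers(0, fp.length - L + 1))
            pos = fp.start + rel
            seq = genome[fp.chrom][pos - 1 : pos - 1 + L]
            u = rng.random()
            if u < sim.multimap3_fraction and name in partner:
                other_fp = footprints[partner[name]]
                emit(read_id, 0, fp.chrom, pos, seq, nh=3)
                emit(read_id, 256, other_fp.chrom, other_fp.start + rel, seq, nh=3)
                # filtered out entirely: no truth count, not retained
            elif u < sim.multimap3_fraction + sim.multimap_fraction and name in partner:
                other_fp = footprints[partner[name]]
                emit(read_id, 0, fp.chrom, pos, seq, nh=2)
                emit(read_id, 256, other_fp.chrom, other_fp.start + rel, seq, nh=2)
                truth_counts[min(name, partner[name])] += 1
                n_retained += 1
            else:
                emit(read_id, 0, fp.chrom, pos, seq, nh=1)
                truth_counts[name] += 1
                n_retained += 1

    # Background reads outside every footprint
    n_bg = int(round(sim.background_fraction * sim.n_reads))
    chrom_names = list(genome)
    chrom_lens = np.array([len(genome[c]) for c in chrom_names], dtype=float)
    fp_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for fp in footprints.values():
        fp_by_chrom.setdefault(fp.chrom, []).append((fp.start, fp.end))
    emitted_bg = 0
    attempts = 0
    while emitted_bg < n_bg and attempts < 100 * max(n_bg, 1):
        attempts += 1
        chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_lens / chrom_lens.sum())]
        if len(genome[chrom]) < L:
            continue
        pos = int(rng.integers(1, len(genome[chrom]) - L + 2))
        read_iv = (pos, pos + L - 1)
        if any(read_iv[0] <= e and s <= read_iv[1] for s, e in fp_by_chrom.get(chrom, [])):
            continue
        read_no += 1
        emit(f"read{read_no:07d}", 0, chrom, pos, genome[chrom][pos - 1 : pos - 1 + L], nh=1)
        emitted_bg += 1
        n_retained += 1
    if emitted_bg < n_bg:
        raise RuntimeError("could not place background reads outside footprints")

    return AlignmentSim(
        sam_text="\n".join(sam_lines) + "\n",
        truth_counts=truth_counts,
        library_size=n_retained,
    )


# ---------------------------------------------------------------------------
# Count-matrix, CT-table, and flow-table simulation


@dataclass(frozen=True)
class CountSimulation:
    """NB count-matrix simulation with planted fold changes."""

    seed: int
    n_features: int = 1000
    n_per_group: tuple[int, int] = (5, 5)
    baseline_mean: float = 100.0
    mean_log_sd: float = 0.5  # lognormal spread of per-feature baselines
    dispersion: float = 0.1
    fold_change: float = 1.0
    planted_fraction: float = 0.0
    group_labels: tuple[str, str] = ("group1", "group2")

    def __post_init__(self) -> None:
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must lie in [0, 1]")
        if min(self.n_per_group) < 2:
            raise ValueError("at least 2 samples per group")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, alpha: float, size: tuple[int, ...]
) -> np.ndarray:
    if alpha <= 0:
        return rng.poisson(mu, size=size)
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p, size=size)


def simulate_counts(
    spec: CountSimulation,
) -> tuple[pd.DataFrame, pd.Series, frozenset[str]]:
    """Draw an NB count matrix; returns (counts, sample groups, planted set).

    Per-feature baselines are lognormal around ``baseline_mean``; a
    ``planted_fraction`` of features has its group-2 mean multiplied by
    ``fold_change``.  With ``fold_change == 1`` or ``planted_fraction == 0``
    the planted truth set is empty.  ``dispersion == 0`` yields Poisson draws.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xC0047)))
    n = spec.n_features
    features = [f"feature{i:05d}" for i in range(n)]
    base = rng.lognormal(mean=np.log(spec.baseline_mean), sigma=spec.mean_log_sd, size=n)

    n_planted = int(round(spec.planted_fraction * n)) if spec.fold_change != 1.0 else 0
    planted_idx = rng.choice(n, size=n_planted, replace=False) if n_planted else np.array([], int)
    fc = np.ones(n)
    fc[planted_idx] = spec.fold_change

    n1, n2 = spec.n_per_group
    g1, g2 = spec.group_labels
    counts1 = _nb_draw(rng, base[:, None], spec.dispersion, (n, n1))
    counts2 = _nb_draw(rng, (base * fc)[:, None], spec.dispersion, (n, n2))
    samples = [f"{g1}_{i + 1}" for i in range(n1)] + [f"{g2}_{i + 1}" for i in range(n2)]
    counts = pd.DataFrame(
        np.hstack([counts1, counts2]), index=features, columns=samples
    )
    groups = pd.Series([g1] * n1 + [g2] * n2, index=samples)
    planted = frozenset(features[i] for i in planted_idx)
    return counts, groups, planted


@dataclass(frozen=True)
class CtSimulation:
    """qPCR CT tables whose ΔCT values recover planted expression ratios."""

    seed: int
    target_ratios: Mapping[str, float] = field(default_factory=lambda: {"ERV1": 4.0})
    n_per_group: int = 10
    ct_noise_sd: float = 0.2
    housekeeping_ct: float = 20.0
    control_delta: float = -6.0  # CT_housekeeping - CT_target in controls
    group_labels: tuple[str, str] = ("unassociated", "associated")


def simulate_ct_table(spec: CtSimulation) -> tuple[pd.DataFrame, dict[str, float]]:
    """CT pairs constructed so relative expression recovers the planted ratios.

    Controls sit at ``control_delta`` cycles below the housekeeping gene; the
    case group shifts the target CT by ``log2(ratio)`` cycles.  Gaussian noise
    of ``ct_noise_sd`` cycles is added to each CT independently.  With zero
    noise, :func:`retroloci.assays.fold_increase` returns the ratio exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xDC7)))
    control, case = spec.group_labels
    rows = []
    for target, ratio in spec.target_ratios.items():
        if ratio <= 0:
            raise ValueError("planted ratios must be positive")
        for group, delta in (
            (control, spec.control_delta),
            (case, spec.control_delta + np.log2(ratio)),
        ):
            for i in range(spec.n_per_group):
                ct_hk = spec.housekeeping_ct + rng.normal(0, spec.ct_noise_sd)
                ct_t = spec.housekeeping_ct - delta + rng.normal(0, spec.ct_noise_sd)
                rows.append(
                    {
                        "sample": f"{group}_{i + 1}",
                        "group": group,
                        "target": target,
                        "ct_target": ct_t,
                        "ct_housekeeping": ct_hk,
                    }
                )
    return pd.DataFrame(rows), dict(spec.target_ratios)


@dataclass(frozen=True)
class FlowSimulation:
    """Flow frequency/MFI rows with known iMFI truth (the product)."""

    seed: int
    populations: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"MLV SU+": (35.0, 1200.0)}
    )


def simulate_flow_table(spec: FlowSimulation) -> tuple[pd.DataFrame, dict[str, float]]:
    """Flow table rows; truth maps population -> frequency * MFI."""
    rows = []
    truth = {}
    for label, (freq, mfi) in spec.populations.items():
        if not 0 <= freq <= 100:
            raise ValueError(f"population {label!r}: frequency must be in [0, 100]")
        if mfi < 0:
            raise ValueError(f"population {label!r}: MFI must be >= 0")
        rows.append({"population": label, "frequency_percent": freq, "mfi": mfi})
        truth[label] = freq * mfi
    return pd.DataFrame(rows), truth
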