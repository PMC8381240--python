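# Methods

`retroloci` implements a locus-level analysis of endogenous retroelement
(ERV and LINE-1) expression and coding potential.  This note describes the
models and procedures, their assumptions, the tunable parameters, and the
choices made where the design was genuinely open.

## Locus catalogs and coordinates

A retroelement locus is a named set of gene segments (gag/pro-pol/env for
ERVs; ORF1/ORF2 for LINE-1) on one chromosome and strand.  Catalog tables
display coordinates 1-based inclusive with an explicit strand, the
convention of gEVE-style locus annotation; internal arithmetic is 0-based
half-open, and BED export shifts accordingly (`start_out = start - 1`).
Strand is never inferred: a coordinate cell without a strand is a parse
error.  Locus names are opaque labels; aliases (e.g. Xmv45, Emv2) are
secondary keys, and lookup by either must resolve uniquely.

The packaged catalog (`data/table1_loci.tsv`) lists 26 mouse (GRCm38) loci:
23 ERVs and 3 LINE-1s.  Several rows are partial — pol-only ERVs, ORF2-only
LINE-1s.  Catalog validation reports these as warnings, not errors, because
partial annotation is a genuine feature of such catalogs; role duplication
and class/role mismatches are errors.  The wide fixture dialect carries one
column per gene role (including an ORF1 column, empty in the packaged
catalog, so synthetic LINE-1 catalogs round-trip through the same format);
a long "gEVE" dialect with one row per segment is also read.

The unit of read counting is the locus *footprint*: the span from the
minimum segment start to the maximum segment end.  This matches reporting
expression per locus rather than per gene.

## Competence model

A locus is called reverse-transcription / retrotransposition **competent**
when its sequence retains the features required for activity, and
**defective** otherwise, with one coded reason per failed condition
(`verdict == competent` iff the reason list is empty).

**ERV rule** — competent iff: gag present and not truncated; pro-pol present
and not truncated; gag in frame with pro-pol; and the pol translation
contains all four conserved RT active-site motifs of the RVT_1 domain:

| motif        | pattern                  | role                       |
|--------------|--------------------------|----------------------------|
| `YxDD`       | Y, any, D, D             | Mg²⁺ coordination/catalysis |
| `DLKDAF`     | literal                  | Mg²⁺ coordination/catalysis |
| `[WY]xxxLPQG`| W or Y, any ×3, L,P,Q,G  | template binding           |
| `QDLREVNK`   | literal                  | template binding           |

`x` matches any of the 20 standard residues, never `X` (ambiguous) or `*`
(stop).  The four motifs are required jointly but order-free by default;
`strict_motif_order=True` additionally requires
`[WY]xxxLPQG < QDLREVNK < YxDD` by position, the arrangement of an intact RT
domain.  The default is the weaker joint reading because requiring a
specific order is a stronger assumption than motif conservation itself.
The env gene does not enter the verdict: competence here means ability to
reverse-transcribe, not to form infectious particles.

**LINE-1 rule** — competent iff ORF1 and ORF2 are present and not
truncated and the ORF2 translation contains `YxDD` (the one catalytic motif
conserved in LINE-1 RT).  "Lacks ORF1" means no annotated ORF1 segment in
the catalog — absence of annotation is taken at face value.

**Truncation.**  A segment is truncated when (a) its frame-0 translation
contains a stop earlier than the last `terminal_stop_window` codons
(default 5 — stops inside that window are read as the natural terminal
stop), or (b) its nucleotide length is below `min_length_fraction`
(default 0.9) of a configurable canonical length per role.  Default
canonical lengths (nt): gag 1602, pol 3402, env 1902, ORF1 1101, ORF2 3801 —
round full-length figures for murine gammaretroviral genes and LINE-1 ORFs,
deliberately configurable because any single reference length is a
simplification across families.  This two-arm rule captures both internal
nonsense mutations and the 5′/3′ erosion visible in partial loci.

**Frame relation.**  The gag→pol codon-phase offset is computed from
strand-oriented CDS starts (genomic starts on `+`, genomic ends on `-`,
since coding order descends on the minus strand), mod 3.  Default allowed
offsets: `{0}`, i.e. readthrough-style expression as in gammaretroviruses;
configuring `{0, 2}` admits a −1 programmed frameshift.  Start-codon
presence is *not* required — the criteria concern truncation and frame, not
initiation.

**Translation** is always frame 0 of the annotated segment (annotation is
taken to delimit the ORF; no 6-frame search), standard genetic code, with
any codon containing a non-ACGT base rendered `X`.  This is stricter than
IUPAC ambiguity resolution on purpose: a partially ambiguous codon should
not silently count as a specific residue when motif-matching.

Not implemented by design: profile-HMM search against the full RVT_1 model,
structural validation, and homolog search — the motif model is a
deliberately transparent, rule-based classifier.

## Quantification

Alignment records are parsed from SAM (pysam-backed; mandatory 11 fields,
CIGAR ops M/=/X/I/D/N/S/H, optional `NH:i`).  Aligned reference blocks merge
M/=/X/D runs and split at N; soft/hard clips and insertions consume no
reference.

**Multimapper exclusion.**  A read whose reported number of alignment loci
(`NH`) exceeds `max_loci` (default 2) is treated as unmapped: *all* of its
records are removed.  This is exclusion, not redistribution — no EM-style
reassignment.  Records without an NH tag count as uniquely mapped (SAM
semantics, conservative).

**Counting.**  A read contributes to a locus when any aligned block overlaps
the locus footprint by ≥ 1 bp.  Under `best-overlap` (default) a read counts
toward the single locus with the greatest total overlap, ties broken by
lexicographically smallest locus name — a deterministic, order-independent
rule; under `any-overlap` it counts toward every overlapped locus.  Records
sharing a read id (mates, multiple placements) are counted as one fragment,
with overlap totalled across records.  Counting is unstranded by default
(library strandedness is often unknown); `stranded=True` restricts to
same-strand overlap.  Library size is the number of distinct retained reads.
Counts are raw; CPM (`count × 10⁶ / library size`) is provided for reporting
only — the DE test consumes raw counts.

## Differential expression

The test is a two-group negative-binomial Wald test — a documented,
calibrated substitute for a full shrinkage-based DE framework, adequate
because the scientific content here is the locus framework and the filter
profiles, not DE machinery:

1. **Scaling**: median-of-ratios size factors; when a sample has < 50%
   nonzero features or no feature is positive everywhere (tiny matrices),
   total-count scaling is used instead.
2. **Dispersion**: per-feature method of moments on scaled counts,
   `α = (s² − m)/m²` pooled across groups, floored at 10⁻⁸.  For the Wald
   variance, per-feature estimates are moderated toward the across-feature
   trend — a 10%-trimmed mean — with limma-style weighting
   `(prior_df·trend + df·α)/(prior_df + df)`, `prior_df = 50` by default.
   The trimmed mean (not the median) is used because the method-of-moments
   estimator's median is noticeably downward-biased at small n, which would
   anti-conservatively shrink variances.  Moderation strength was set so the
   normal-reference Wald test holds its nominal size on null NB data at
   n = 5 per group (measured type-I error ≈ 0.057 at nominal 0.05; pure
   per-feature variance gives ≈ 0.085).
3. **Statistic**: `log2fc = log2((m₂+c)/(m₁+c))` with pseudocount `c = 0.5`;
   delta-method SE from NB variance `(μ + αμ²)/n` per group (with the
   pseudocount folded into μ so one-group-zero features remain finite);
   two-sided p from the normal reference.  Group 1 is the explicitly given
   `reference` group, else the lexicographically smaller label — a
   deterministic convention that makes label-swap exactly antisymmetric.
4. **Multiplicity**: Benjamini–Hochberg step-up across tested features
   (statsmodels-backed).  Features with all-zero counts in both groups are
   excluded and reported with p = FDR = 1.

**Filter profiles**: `genes` keeps FDR < 0.05 AND |fold change| > 2
(two-sided, i.e. |log2fc| > 1, since induction and repression both count);
`retroelements` keeps FDR < 0.05 only.  Inequalities are strict.

Out of scope: multi-factor designs, shrinkage priors on fold changes,
outlier handling.

## Assay formulas

* qPCR relative expression: `2^(CT_housekeeping − CT_target) × 10⁴`; equal
  CTs give exactly 10⁴.  Fold increase is the ratio of unpaired group
  arithmetic means (no pairing structure is assumed).
* Flow iMFI: `frequency × MFI`, with frequency on the **percent of parent
  gate scale (0–100)**.  The percent convention is stated prominently
  because frequency could equally be a 0–1 fraction; all package I/O uses
  percent.

## Synthetic data: what it emulates, and what it does not

The generators produce every pipeline input with construction-time truth:

* **Locus construction**: ORFs are built from random codons whose amino
  acids exclude D and Q; since every RT motif contains a D or Q, no motif
  can arise by chance, and the spliced-in motifs (at fixed pol codons 200,
  300, 400, 500) are provably the only occurrences.  Stop-free frames are
  guaranteed by sampling from non-stop codons; each ORF ends with a natural
  TAA.  Lesions are applied per integrity class: a 1-nt insertion in the
  gag–pol spacer (frameshift), a mid-pol/mid-ORF2 codon mutated to TAA
  (premature stop, placed after all motifs so the reason list stays exact),
  pol cut to 1800 nt (length-fraction truncation, motifs retained), the
  YxDD splice omitted (motif ablation), or the ORF1 annotation omitted.
* **Genomes**: uniform-ACGT background with loci pasted at fixed offsets;
  minus-strand loci are inserted as reverse complements with coordinates
  mapped accordingly.
* **Reads**: perfect-match, plus-strand, fixed-length placements uniform
  within footprints; multinomial allocation across loci by expression
  weight; a configurable fraction duplicated across equal-length paralog
  sites with NH=2 (tie-broken lexicographically in the truth bookkeeping,
  mirroring the counting contract) or NH=3 (must vanish under the strict
  filter); background reads placed outside all footprints.
* **Count matrices**: NB draws (Poisson at dispersion 0) around lognormal
  per-feature baselines (spread 0.5 log units around a default mean of 100),
  with a planted fraction of features multiplied by a fold change in group 2.
  Default study shape: 1000 features, 5 vs 5 samples, dispersion 0.1.
* **Assay tables**: CT pairs placed so the ΔCT formula recovers planted
  ratios exactly at zero noise (controls at −6 ΔCT cycles relative to the
  housekeeping gene, cases shifted by log2(ratio); Gaussian CT noise,
  default sd 0.2 cycles); flow rows carry specified frequency/MFI so the
  iMFI truth is their product.

All generators are pure functions of (spec, seed), using numpy PCG64
streams; identical inputs give byte-identical outputs on a platform, and
PCG64 makes this stable across platforms in practice.

**What passing these tests does not show.**  The synthetic data contain no
sequencing errors, indels, quality variation, fragment-length distributions,
soft-clipped or spliced reads, GC or mappability bias, overlapping loci, or
realistic retroviral sequence divergence; paralog multimapping is positional
rather than sequence-driven.  Recovery of planted truth therefore validates
the *contracts* (coordinate arithmetic, filtering, counting, the competence
rules, test calibration) — it does not demonstrate accuracy on real
libraries, where alignment ambiguity and annotation error dominate.

## Numerical and degenerate-input choices

* BH on an empty vector returns an empty vector; a single p is unchanged.
* Dispersion estimates from zero-variance features hit the 10⁻⁸ floor.
* Size-factor computation refuses samples with zero total counts.
* `count_by_locus` on records whose chromosome is absent from the catalog
  simply assigns nothing (background reads are expected).
* SAM parse errors report the approximate line number (header lines +
  record index).
* Validation issues are returned, never raised; parse-level malformations
  (bad coordinate cell, duplicate locus name) raise with row/column context.

## Problem sizes

Default verification sizes: 54 planted loci (every integrity class × both
strands × 3 replicates) for competence recovery; 1000 randomized instances
each for the motif-scan and CIGAR-block oracle comparisons; ~2000 simulated
reads for quantification exactness; 100 simulation replicates of
1000 features at 5 vs 5 for DE calibration.  These sizes give stable
aggregate statistics while keeping the full suite fast enough to run on
every change.
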