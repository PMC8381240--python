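"""End-to-end orchestration: catalog -> competence -> counting -> DE -> report.

The merged report has one row per catalog locus: per-sample counts, group
means, log2 fold change, FDR, filter-profile pass flag, competence verdict
with coded reasons, and a ``highlight`` flag marking loci that are both
differentially expressed and RT-competent (the loci a study would underline).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import catalog as cat
from . import competence as comp
from . import diffexp, quantification
from .io import load_fasta

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "MissingInputError",
    "CatalogValidationError",
    "run_pipeline",
]

log = logging.getLogger("retroloci")


class PipelineError(RuntimeError):
    exit_code = 1


class MissingInputError(PipelineError):
    exit_code = 2


class CatalogValidationError(PipelineError):
    exit_code = 3


@dataclass
class PipelineConfig:
    catalog_path: Path
    genome_path: Path
    sam_paths: Mapping[str, Path]  # sample -> SAM
    groups: Mapping[str, str]  # sample -> group label
    out_dir: Path
    max_loci: int = 2
    assignment: str = "best-overlap"
    stranded: bool = False
    competence: comp.CompetenceConfig = field(default_factory=comp.CompetenceConfig)
    de_profile: str = "retroelements"
    de_reference: str | None = None  # baseline group for log2fc; default lexicographic

    def __post_init__(self) -> None:
        if self.max_loci < 1:
            raise ValueError("max_loci must be >= 1")
        if not self.sam_paths:
            raise MissingInputError("no SAM inputs given")


def _check_inputs(config: PipelineConfig) -> None:
    paths = [config.catalog_path, config.genome_path, *config.sam_paths.values()]
    missing = [str(p) for p in paths if not Path(p).exists()]
    if missing:
        raise MissingInputError(f"missing input files: {missing}")


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Run all stages and write the report bundle into ``config.out_dir``.

    Writes ``counts.tsv``, ``competence.tsv``, ``loci.bed``, ``report.tsv``
    and ``report.json``; returns the merged report.  Raises
    :class:`MissingInputError` (exit 2 in the CLI) for absent files and
    :class:`CatalogValidationError` (exit 3) for catalog errors.
    """
    _check_inputs(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log.info("parsing catalog %s", config.catalog_path)
    try:
        loci = cat.parse_locus_table(Path(config.catalog_path).read_text())
    except cat.CatalogError as exc:
        raise CatalogValidationError(str(exc)) from exc
    issues = cat.validate_catalog(loci)
    for issue in issues:
        log.log(
            logging.ERROR if issue.severity == "error" else logging.WARNING,
            "catalog %s: %s", issue.locus_name, issue.message,
        )
    if any(i.severity == "error" for i in issues):
        raise CatalogValidationError(
            f"catalog has {sum(i.severity == 'error' for i in issues)} error(s)"
        )

    log.info("loading genome %s", config.genome_path)
    genome = load_fasta(Path(config.genome_path))
    calls = {l.name: comp.call_competence(l, genome, config.competence) for l in loci}

    log.info("counting %d samples", len(config.sam_paths))
    matrix = quantification.build_count_matrix(
        config.sam_paths,
        loci,
        max_loci=config.max_loci,
        assignment=config.assignment,
        stranded=config.stranded,
    )

    log.info("differential expression (%s profile)", config.de_profile)
    de = diffexp.nb_wald_test(
        matrix, pd.Series(dict(config.groups)), reference=config.de_reference
    )
    profile = diffexp.get_profile(config.de_profile)

    report = matrix.counts.copy()
    report.insert(0, "locus", report.index)
    report["log2fc"] = de["log2fc"]
    report["p_value"] = de["p_value"]
    report["fdr"] = de["fdr"]
    report["de_significant"] = de[f"pass_{profile.name}"]
    report["verdict"] = [calls[n].verdict for n in report.index]
    report["reasons"] = [";".join(calls[n].reasons) for n in report.index]
    report["rt_competent"] = report["verdict"] == "competent"
    report["highlight"] = report["de_significant"] & report["rt_competent"]

    matrix.counts.to_csv(out_dir / "counts.tsv", sep="\t")
    _write_competence(calls, out_dir / "competence.tsv")
    (out_dir / "loci.bed").write_text(cat.export_bed(loci))
    report.to_csv(out_dir / "report.tsv", sep="\t", index=False)
    (out_dir / "report.json").write_text(
        json.dumps(
            {
                "n_loci": len(loci),
                "library_size": {k: int(v) for k, v in matrix.library_size.items()},
                "profile": profile.name,
                "loci": report.drop(columns="locus").to_dict(orient="index"),
            },
            indent=2,
            default=_jsonable,
        )
        + "\n"
    )
    log.info("report written to %s", out_dir)
    return report


def _jsonable(obj):
    try:
        return obj.item()  # numpy scalars
    except AttributeError:  # pragma: no cover
        return str(obj)


def _write_competence(calls: Mapping[str, comp.CompetenceCall], path: Path) -> None:
    rows = []
    for call in calls.values():
        rows.append(
            {
                "locus": call.locus_name,
                "class": call.element_class,
                "verdict": call.verdict,
                "reasons": ";".join(call.reasons),
                "motif_hits": ";".join(
                    f"{h.motif_id}@{h.position}" for h in call.motif_hits
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
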