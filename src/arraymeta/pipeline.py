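"""End-to-end pipeline orchestration: extract -> refine -> merge -> statistics.

Stages run in workflow order with per-stage progress logging and the
per-study found/missing gene report.  All file outputs obey the
preserve-by-default overwrite policy: a second run leaves existing
"Extracted Data", "Refined Data" and "Merged.txt" files untouched and —
deliberately — performs statistics on the *existing* merged file, so a
user can hand-edit it (delete genes, studies or columns; sort rows)
between runs and re-combine over exactly what remains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .extraction import ExtractedStudy, extract_study, persist_extracted
from .io_formats import (
    GENE_LIST_FILENAME,
    MERGED_FILENAME,
    STATS_SUMMARY_FILENAME,
    GeneList,
    OverwritePolicy,
    PipelineError,
    StudyFolder,
    read_gene_list,
    scan_study_folders,
)
from .merge import FilterConfig, MergedTable, apply_filters, load_merged, merge_studies, write_merged
from .meta_stats import MetaResult, StatConfig, annotate_merged, compute_study_tests, write_stats_summary
from .refinement import RefineConfig, RefinedStudy, refine_study

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    root: Path
    genes_path: Path | None = None          # default: <root>/Genes of interest.txt
    refine: RefineConfig = field(default_factory=RefineConfig)
    stats: StatConfig = field(default_factory=StatConfig)
    filters: FilterConfig | None = None     # case-study filters, off by default
    run_stats: bool = True
    force_overwrite: bool = False

    @property
    def policy(self) -> OverwritePolicy:
        return OverwritePolicy.FORCE if self.force_overwrite else OverwritePolicy.PRESERVE


@dataclass
class PipelineResult:
    folders: list[StudyFolder]
    extracted: list[ExtractedStudy]
    refined: list[RefinedStudy]
    merged: MergedTable
    metas: list[MetaResult] = field(default_factory=list)
    merged_path: Path | None = None


def _stage(name: str, i: int, n: int) -> None:
    logger.info("[%s] %d/%d (%.0f%%)", name, i, n, 100.0 * i / n if n else 100.0)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full workflow on a study tree; raises PipelineError on failure."""
    root = Path(config.root)
    genes_path = config.genes_path or root / GENE_LIST_FILENAME
    genes = read_gene_list(genes_path)
    folders = scan_study_folders(root)
    if not folders:
        raise PipelineError(f"no numbered study folders found under {root}")

    extracted: list[ExtractedStudy] = []
    for i, folder in enumerate(folders, 1):
        ex = extract_study(folder, genes)
        persist_extracted(ex, root, config.policy)
        extracted.append(ex)
        _stage("extraction", i, len(folders))

    refined: list[RefinedStudy] = []
    for i, ex in enumerate(extracted, 1):
        rf = refine_study(ex, config.refine)
        from .refinement import persist_refined

        persist_refined(rf, root, config.policy)
        refined.append(rf)
        _stage("refinement", i, len(folders))

    merged = merge_studies(refined, gene_order=list(genes))
    if config.filters is not None:
        merged = apply_filters(merged, config.filters)
    merged_path = root / MERGED_FILENAME
    preexisting = merged_path.exists() and not config.force_overwrite
    write_merged(merged, merged_path, config.policy)
    _stage("merging", 1, 1)
    if preexisting:
        # a preserved (possibly hand-edited) merged file is the statistics
        # substrate, not the freshly merged table
        merged = load_merged(merged_path)

    result = PipelineResult(
        folders=folders, extracted=extracted, refined=refined,
        merged=merged, merged_path=merged_path,
    )
    if config.run_stats:
        tests = compute_study_tests(refined, config.stats)
        annotated, metas = annotate_merged(merged, tests, config.stats)
        write_merged(annotated, merged_path, OverwritePolicy.FORCE)
        write_stats_summary(metas, root / STATS_SUMMARY_FILENAME, OverwritePolicy.FORCE)
        result.merged = annotated
        result.metas = metas
        _stage("statistics", 1, 1)
    return result


def stats_only(config: RunConfig) -> PipelineResult:
    """Re-run statistics on an existing (possibly hand-edited) Merged.txt.

    Extraction and refinement are recomputed in memory to recover per-sample
    values, but no extraction/refinement/merge files are touched; the
    combination is restricted to the genes and columns surviving in the
    merged file.
    """
    root = Path(config.root)
    merged_path = root / MERGED_FILENAME
    if not merged_path.exists():
        raise PipelineError(f"{merged_path} not found — run the pipeline first")
    merged = load_merged(merged_path)

    genes_path = config.genes_path or root / GENE_LIST_FILENAME
    genes = read_gene_list(genes_path)
    folders = scan_study_folders(root)
    extracted = [extract_study(f, genes) for f in folders]
    refined = [refine_study(ex, config.refine) for ex in extracted]

    tests = compute_study_tests(refined, config.stats)
    annotated, metas = annotate_merged(merged, tests, config.stats)
    write_merged(annotated, merged_path, OverwritePolicy.FORCE)
    write_stats_summary(metas, root / STATS_SUMMARY_FILENAME, OverwritePolicy.FORCE)
    _stage("statistics", 1, 1)
    return PipelineResult(
        folders=folders, extracted=extracted, refined=refined,
        merged=annotated, metas=metas, merged_path=merged_path,
    )
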