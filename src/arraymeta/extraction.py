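"""Pull gene-of-interest rows out of each study's expression matrix.

For every study the gene list is mapped to probe IDs through that study's
annotation and the matching matrix rows are copied out verbatim (no numeric
transformation happens at this stage).  Each gene lands in exactly one of
three dispositions, mirroring what the user needs to see per study:

* ``found`` — at least one annotated probe has a row in the data,
* ``missing_in_annotation`` — the gene does not appear in Annotation.txt,
* ``annotated_but_absent`` — annotated, but none of its probes are in Data.txt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_formats import (
    EXTRACTED_DIRNAME,
    AnnotationTable,
    GeneList,
    OverwritePolicy,
    StudyFolder,
    ValidationError,
    write_table,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExtractionReport:
    """Disjoint partition of the gene list for one study."""

    found: tuple[str, ...]
    missing_in_annotation: tuple[str, ...]
    annotated_but_absent: tuple[str, ...]

    def __post_init__(self) -> None:
        sets = [set(self.found), set(self.missing_in_annotation), set(self.annotated_but_absent)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValidationError("extraction report categories overlap")


@dataclass(frozen=True)
class ExtractedRow:
    gene_id: str
    probe_id: str
    values: np.ndarray  # aligned to ExtractedStudy.sample_ids (design order)


@dataclass
class ExtractedStudy:
    """All extracted rows of one study, columns re-ordered to design order."""

    folder: StudyFolder
    sample_ids: list[str]
    rows: list[ExtractedRow]
    report: ExtractionReport

    @property
    def design(self):
        return self.folder.design

    @property
    def study_number(self) -> int:
        return self.folder.study_number


def map_genes_to_probes(genes: GeneList, annotation: AnnotationTable) -> dict[str, list[str]]:
    """Exact, case-sensitive gene -> probe-ID mapping; unannotated genes map to []."""
    by_gene: dict[str, list[str]] = {g: [] for g in genes}
    for gene, probe, _specificity in annotation.records:
        if gene in by_gene and probe not in by_gene[gene]:
            by_gene[gene].append(probe)
    return by_gene


def extract_study(folder: StudyFolder, genes: GeneList) -> ExtractedStudy:
    """Extract every (gene, probe) row present in the study's matrix.

    Raises :class:`ValidationError` listing any design sample IDs missing
    from the matrix header.  Values are copied exactly as parsed.
    """
    expr = folder.expression
    design = folder.design
    missing_samples = [s for s in design.sample_to_group if s not in expr.sample_ids]
    if missing_samples:
        raise ValidationError(
            f"study {folder.study_number}: design samples not in matrix header: {missing_samples}"
        )
    order = design.design_order_samples
    col_idx = [expr.sample_ids.index(s) for s in order]
    probe_pos = {p: i for i, p in enumerate(expr.probe_ids)}
    mapping = map_genes_to_probes(genes, folder.annotation)

    rows: list[ExtractedRow] = []
    found, missing_annot, absent = [], [], []
    for gene in genes:
        probes = mapping[gene]
        if not probes:
            missing_annot.append(gene)
            continue
        present = [p for p in probes if p in probe_pos]
        if not present:
            absent.append(gene)
            continue
        found.append(gene)
        for p in present:
            rows.append(ExtractedRow(gene, p, expr.values[probe_pos[p]][col_idx].copy()))
    report = ExtractionReport(tuple(found), tuple(missing_annot), tuple(absent))
    logger.info(
        "study %d (%s): %d genes found, %d not in annotation, %d annotated but absent",
        folder.study_number, folder.study_name,
        len(found), len(missing_annot), len(absent),
    )
    return ExtractedStudy(folder=folder, sample_ids=order, rows=rows, report=report)


def persist_extracted(
    extracted: ExtractedStudy,
    root: Path | str,
    policy: OverwritePolicy = OverwritePolicy.PRESERVE,
) -> Path:
    """Write one 'Extracted Data/output_<n>.txt' per study (preserve by default)."""
    out = Path(root) / EXTRACTED_DIRNAME / f"output_{extracted.study_number}.txt"
    header = ["Gene", "Probe", *extracted.sample_ids]
    body = [[r.gene_id, r.probe_id, *[float(v) for v in r.values]] for r in extracted.rows]
    return write_table([header, *body], out, policy)
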