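"""Merge per-study ratio tables into one spreadsheet and apply study filters.

The merged spreadsheet has one row per gene and one column per
(study, non-control group) comparison, carrying the log2 fold change vs
that study's control.  Column metadata (study number, group name, group and
control sample sizes) travels in header rows, and the column labels are
repeated in a final "Labels" footer row so the file survives hand editing:
users may delete genes, delete columns or sort rows in a spreadsheet tool
before running statistics, as long as the first (gene) column and the
footer labels remain intact.

Filters mirror a typical meta-analysis hygiene pass: drop comparisons with
too few samples, genes measured in too few studies, and genes whose
direction of regulation is inconsistent across studies.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    MERGED_FILENAME,
    OverwritePolicy,
    ValidationError,
    parse_number,
    write_table,
)
from .refinement import RefinedStudy

logger = logging.getLogger(__name__)

_LABEL_RE = re.compile(r"^S(\d+):(.+)$")
_RESERVED_FIRST_CELLS = {"Gene", "Study", "Group", "N_group", "N_control", "Labels"}
_STAT_PREFIXES = ("p:", "combined:")


@dataclass(frozen=True)
class ColumnMeta:
    """Identity and sample sizes of one (study, non-control group) column."""

    study_number: int
    group: str
    n_group: int | None = None
    n_control: int | None = None

    @property
    def label(self) -> str:
        return f"S{self.study_number}:{self.group}"


@dataclass
class MergedTable:
    """Gene x (study, group) log2-ratio matrix with column metadata.

    ``values`` is a DataFrame indexed by gene with one column per
    :class:`ColumnMeta` label; ``stats`` holds appended statistics columns
    (``p:<label>`` and ``combined:*``) when present.
    """

    columns: list[ColumnMeta]
    values: pd.DataFrame
    stats: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        labels = [c.label for c in self.columns]
        if len(set(labels)) != len(labels):
            dup = next(l for l in labels if labels.count(l) > 1)
            raise ValidationError(f"duplicate merged column {dup!r}")
        if list(self.values.columns) != labels:
            raise ValidationError("values columns do not match column metadata")
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate gene rows in merged table")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def column(self, label: str) -> ColumnMeta:
        return next(c for c in self.columns if c.label == label)


@dataclass(frozen=True)
class FilterConfig:
    """Case-study defaults: N >= 5 per group, >= 5 studies, >= 75% agreement."""

    min_group_n: int = 5
    min_studies_per_gene: int = 5
    min_direction_agreement: float = 0.75

    def __post_init__(self) -> None:
        if self.min_group_n < 1 or self.min_studies_per_gene < 1:
            raise ValidationError("filter thresholds must be positive")
        if not 0 < self.min_direction_agreement <= 1:
            raise ValidationError("min_direction_agreement must be in (0, 1]")


def merge_studies(
    refined: list[RefinedStudy],
    gene_order: list[str] | None = None,
) -> MergedTable:
    """Merge refined studies into one table.

    Columns are ordered by study number then by each design's group order;
    genes follow *gene_order* (the original gene list) restricted to genes
    found in at least one study, or first-appearance order if not given.
    """
    if not refined:
        raise ValidationError("no refined studies to merge")
    refined = sorted(refined, key=lambda r: r.study_number)

    columns: list[ColumnMeta] = []
    for study in refined:
        design = study.design
        for g in design.noncontrol_groups:
            # column-level N: the declared sample count of the group
            columns.append(
                ColumnMeta(
                    study_number=study.study_number,
                    group=g,
                    n_group=len(design.samples_in(g)),
                    n_control=len(design.samples_in(design.control_group)),
                )
            )

    seen: dict[str, None] = {}
    for study in refined:
        for gene in study.genes:
            seen.setdefault(gene, None)
    if gene_order is not None:
        genes = [g for g in gene_order if g in seen]
    else:
        genes = list(seen)
    for g in genes:
        if g in _RESERVED_FIRST_CELLS:
            raise ValidationError(f"gene id {g!r} collides with a reserved table keyword")

    labels = [c.label for c in columns]
    if len(set(labels)) != len(labels):
        dup = next(l for l in labels if labels.count(l) > 1)
        raise ValidationError(f"duplicate (study, group) column {dup!r}")

    values = pd.DataFrame(np.nan, index=pd.Index(genes, name="Gene"), columns=labels)
    for study in refined:
        for gene, rg in study.genes.items():
            for g, ratio in rg.ratios.items():
                values.at[gene, f"S{study.study_number}:{g}"] = ratio
    return MergedTable(columns=columns, values=values)


def _study_direction(signs: list[int]) -> int:
    """Majority ratio sign of one study's cells for one gene; tie or all-zero -> 0."""
    up = sum(1 for s in signs if s > 0)
    down = sum(1 for s in signs if s < 0)
    if up > down:
        return 1
    if down > up:
        return -1
    return 0


def apply_filters(table: MergedTable, config: FilterConfig) -> MergedTable:
    """Apply the three case-study filters, in order.

    1. drop columns whose group N is below ``min_group_n``;
    2. drop genes with non-missing ratios in fewer than
       ``min_studies_per_gene`` distinct studies;
    3. drop genes whose dominant direction (per-study majority sign; an exact
       within-study tie counts for neither side) is shared by fewer than
       ``min_direction_agreement`` of the contributing studies.
    """
    if any(c.n_group is None for c in table.columns):
        raise ValidationError("cannot filter: column sample sizes (N_group) are missing")
    keep_cols = [c for c in table.columns if c.n_group >= config.min_group_n]
    values = table.values[[c.label for c in keep_cols]]

    keep_genes: list[str] = []
    for gene in values.index:
        by_study: dict[int, list[int]] = {}
        for c in keep_cols:
            v = values.at[gene, c.label]
            if np.isfinite(v):
                by_study.setdefault(c.study_number, []).append(int(np.sign(v)))
        if len(by_study) < config.min_studies_per_gene:
            continue
        dirs = [_study_direction(s) for s in by_study.values()]
        up = sum(1 for d in dirs if d > 0)
        down = sum(1 for d in dirs if d < 0)
        if max(up, down) / len(dirs) < config.min_direction_agreement:
            continue
        keep_genes.append(gene)

    return MergedTable(columns=keep_cols, values=values.loc[keep_genes].copy())


# ---------------------------------------------------------------------------
# persistence


def merged_rows(table: MergedTable) -> list[list[object]]:
    """Serialize a merged table (with any stats columns) to rows of cells."""
    stat_labels = list(table.stats.columns) if table.stats is not None else []
    labels = [c.label for c in table.columns] + stat_labels
    rows: list[list[object]] = [["Gene", *labels]]
    rows.append(["Study", *[c.study_number for c in table.columns], *[""] * len(stat_labels)])
    rows.append(["Group", *[c.group for c in table.columns], *[""] * len(stat_labels)])
    rows.append(["N_group", *[c.n_group for c in table.columns], *[""] * len(stat_labels)])
    rows.append(["N_control", *[c.n_control for c in table.columns], *[""] * len(stat_labels)])
    for gene in table.values.index:
        row: list[object] = [gene, *[float(v) for v in table.values.loc[gene]]]
        if table.stats is not None:
            row += [v for v in table.stats.loc[gene]]
        rows.append(row)
    rows.append(["Labels", *labels])
    return rows


def write_merged(
    table: MergedTable,
    path: Path | str,
    policy: OverwritePolicy = OverwritePolicy.PRESERVE,
) -> Path:
    return write_table(merged_rows(table), path, policy)


def load_merged(path: Path | str) -> MergedTable:
    """Load a merged spreadsheet, tolerating the hand edits the format allows.

    Users may delete gene rows, delete columns, or sort the body; the first
    column must still hold the gene IDs (header cell "Gene") and the final
    "Labels" footer row must list the remaining column labels.  Statistics
    columns (``p:...``, ``combined:...``) from a previous run are split off
    into ``stats``.
    """
    path = Path(path)
    raw = [ln.split("\t") for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if not raw or raw[0][0].strip() != "Gene":
        raise ValidationError(
            f"{path}: first column altered — header row must start with 'Gene'"
        )
    header = [c.strip() for c in raw[0][1:]]
    if raw[-1][0].strip() != "Labels":
        raise ValidationError(f"{path}: footer 'Labels' row is missing")
    footer = [c.strip() for c in raw[-1][1:]]
    if footer != header:
        raise ValidationError(f"{path}: footer labels do not match the column headers")

    meta_rows: dict[str, list[str]] = {}
    body: list[tuple[str, list[str]]] = []
    for cells in raw[1:-1]:
        first = cells[0].strip()
        rest = [c.strip() for c in cells[1:]]
        rest += [""] * (len(header) - len(rest))
        if first in {"Study", "Group", "N_group", "N_control"}:
            meta_rows[first] = rest
        elif first in _RESERVED_FIRST_CELLS:
            raise ValidationError(f"{path}: unexpected reserved row {first!r}")
        else:
            body.append((first, rest))

    ratio_pos = [i for i, l in enumerate(header)
                 if not l.startswith(_STAT_PREFIXES)]
    stat_pos = [i for i in range(len(header)) if i not in ratio_pos]

    columns: list[ColumnMeta] = []
    for i in ratio_pos:
        m = _LABEL_RE.match(header[i])
        if m is None:
            raise ValidationError(f"{path}: unparseable column label {header[i]!r}")
        n_group = n_control = None
        if "N_group" in meta_rows and meta_rows["N_group"][i]:
            n_group = int(float(meta_rows["N_group"][i]))
        if "N_control" in meta_rows and meta_rows["N_control"][i]:
            n_control = int(float(meta_rows["N_control"][i]))
        columns.append(
            ColumnMeta(int(m.group(1)), m.group(2), n_group=n_group, n_control=n_control)
        )

    genes = [g for g, _ in body]
    if len(set(genes)) != len(genes):
        dup = next(g for g in genes if genes.count(g) > 1)
        raise ValidationError(f"{path}: duplicate gene row {dup!r}")
    values = pd.DataFrame(
        [
            [parse_number(rest[i], context=f"{path}: gene {g}, column {header[i]}")
             for i in ratio_pos]
            for g, rest in body
        ],
        index=pd.Index(genes, name="Gene"),
        columns=[c.label for c in columns],
    )
    stats = None
    if stat_pos:
        stats = pd.DataFrame(
            [[rest[i] for i in stat_pos] for _g, rest in body],
            index=values.index,
            columns=[header[i] for i in stat_pos],
        )
    return MergedTable(columns=columns, values=values, stats=stats)


def write_merged_to_root(
    table: MergedTable, root: Path | str, policy: OverwritePolicy = OverwritePolicy.PRESERVE
) -> Path:
    return write_merged(table, Path(root) / MERGED_FILENAME, policy)
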