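"""Readers and writers for the plain-text study-folder layout.

A meta-analysis run is driven by a directory tree of numbered study
folders, each holding a normalized expression matrix (``Data.txt``), a
gene-to-probe annotation (``Annotation.txt``) and a group design
(``Data Description.txt``), plus a single gene-of-interest list shared
by all studies (``Genes of interest.txt`` at the tree root)::

    root/
      Genes of interest.txt
      1 StudyA/
        Data.txt               probes x samples, tab-separated, header row
        Annotation.txt         gene <TAB> probe [<TAB> specificity [<TAB> suffix]]
        Data Description.txt   one group per line: label <TAB> sample ids...
      2 StudyB NOLOG/          "NOLOG" marks a study stored on linear scale
        ...

Every file is tab-separated UTF-8 text and numbers must use ``.`` as the
decimal separator; a ``,`` anywhere in a numeric cell raises
:class:`DecimalSeparatorError` rather than being silently mis-parsed by
a locale-aware reader.  Output tables honour a preserve-by-default
overwrite policy so that partial re-runs never clobber files a user may
have hand-edited.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

GENE_LIST_FILENAME = "Genes of interest.txt"
DATA_FILENAME = "Data.txt"
ANNOTATION_FILENAME = "Annotation.txt"
DESIGN_FILENAME = "Data Description.txt"
EXTRACTED_DIRNAME = "Extracted Data"
REFINED_DIRNAME = "Refined Data"
MERGED_FILENAME = "Merged.txt"
STATS_SUMMARY_FILENAME = "stats_summary.txt"

CONTROL_MARKER = "CONTROL:"
NOLOG_TOKEN = "NOLOG"

_FOLDER_RE = re.compile(r"^(\d+) +(.*\S)\s*$")


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PipelineError):
    """A file does not follow the expected tab-separated dialect."""


class ValidationError(PipelineError):
    """Parsed content violates an invariant (duplicates, bad references...)."""


class DecimalSeparatorError(FormatError):
    """A numeric cell contains a ',' — only '.' decimal separators are allowed."""


class Scale(enum.Enum):
    LOG2 = "log2"
    LINEAR = "linear"
    AUTO = "auto"


class OverwritePolicy(enum.Enum):
    PRESERVE = "preserve"
    FORCE = "force"


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GeneList:
    """Ordered, duplicate-free list of gene identifiers (symbols or any unique ID)."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("gene list is empty")
        seen: set[str] = set()
        for g in self.genes:
            if not g or not g.strip():
                raise ValidationError("gene list contains an empty identifier")
            if g in seen:
                raise ValidationError(f"duplicate gene identifier: {g!r}")
            seen.add(g)

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class AnnotationTable:
    """Gene -> probe mapping for one array platform.

    ``records`` holds ``(gene_id, probe_id, specificity)`` rows in file order;
    ``priority_suffixes`` is the ordered probe-ID suffix whitelist (best first)
    used to prioritise or exclude probes by their Affymetrix-style name ending
    (e.g. ``_at`` before ``_s_at``); empty means "no prioritisation".
    """

    records: tuple[tuple[str, str, str | None], ...]
    priority_suffixes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        pairs: set[tuple[str, str]] = set()
        for gene, probe, _specificity in self.records:
            if not probe:
                raise ValidationError(f"empty probe id for gene {gene!r}")
            if (gene, probe) in pairs:
                raise ValidationError(f"duplicate annotation pair ({gene!r}, {probe!r})")
            pairs.add((gene, probe))
        if len(set(self.priority_suffixes)) != len(self.priority_suffixes):
            raise ValidationError("priority suffix list contains duplicates")

    def probes_for(self, gene: str) -> list[str]:
        return [p for g, p, _s in self.records if g == gene]


@dataclass
class StudyDesign:
    """Sample-to-group assignment for one study with a designated control group."""

    groups: tuple[str, ...]
    sample_to_group: dict[str, str]
    control_group: str
    study_number: int = 0
    study_name: str = ""

    def __post_init__(self) -> None:
        if self.control_group not in self.groups:
            raise ValidationError(
                f"control group {self.control_group!r} not among groups {self.groups}"
            )
        counts = {g: 0 for g in self.groups}
        for s, g in self.sample_to_group.items():
            if g not in counts:
                raise ValidationError(f"sample {s!r} assigned to unknown group {g!r}")
            counts[g] += 1
        empty = [g for g, c in counts.items() if c == 0]
        if empty:
            raise ValidationError(f"groups with no samples: {empty}")

    def samples_in(self, group: str) -> list[str]:
        """Sample IDs of one group, in file order."""
        return [s for s, g in self.sample_to_group.items() if g == group]

    @property
    def design_order_samples(self) -> list[str]:
        """All sample IDs clustered by group, groups in declared order."""
        return [s for g in self.groups for s in self.samples_in(g)]

    @property
    def noncontrol_groups(self) -> list[str]:
        return [g for g in self.groups if g != self.control_group]


@dataclass
class ExpressionStudy:
    """Probe x sample numeric matrix; missing cells are NaN."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # float, shape (n_probes, n_samples)
    scale: Scale = Scale.AUTO
    nolog_flag: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("duplicate probe ids in expression matrix")

    def row(self, probe_id: str) -> np.ndarray:
        return self.values[self.probe_ids.index(probe_id)]


@dataclass
class StudyFolder:
    """One numbered study directory with its three parsed input files."""

    path: Path
    study_number: int
    study_name: str
    design: StudyDesign
    annotation: AnnotationTable
    expression: ExpressionStudy


# ---------------------------------------------------------------------------
# low-level tab-separated helpers


def _read_rows(path: Path) -> list[list[str]]:
    try:
        text = Path(path).read_text(encoding="utf-8")
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    rows = []
    for line in text.splitlines():
        if line.strip() == "":
            continue
        rows.append([c.strip() for c in line.split("\t")])
    return rows


def parse_number(cell: str, *, context: str) -> float:
    """Parse one numeric cell; '' is missing (NaN), ',' is a hard error."""
    if cell == "":
        return float("nan")
    if "," in cell:
        raise DecimalSeparatorError(
            f"{context}: value {cell!r} contains ','; use '.' as the decimal separator"
        )
    try:
        return float(cell)
    except ValueError as exc:
        raise FormatError(f"{context}: non-numeric value {cell!r}") from exc


def _fmt(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        if np.isnan(value):
            return ""
        return format(value, ".10g")
    return str(value)


# ---------------------------------------------------------------------------
# readers


def read_gene_list(path: Path | str) -> GeneList:
    """Read the gene-of-interest list: one identifier per line, blanks skipped.

    Raises :class:`ValidationError` naming the first duplicate identifier —
    duplicate gene names silently corrupt the merged output, so they are
    rejected up front.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    genes = [ln.strip() for ln in lines if ln.strip()]
    if not genes:
        raise ValidationError(f"gene list {path} is empty")
    seen: set[str] = set()
    for g in genes:
        if g in seen:
            raise ValidationError(f"duplicate gene identifier {g!r} in {path}")
        seen.add(g)
    return GeneList(tuple(genes))


def read_annotation(path: Path | str) -> AnnotationTable:
    """Read a gene->probe annotation table.

    Columns: 1 gene ID, 2 probe ID, optional 3 specificity class, optional 4
    one priority suffix per row (collected in file order, best first).  Exact
    duplicate (gene, probe) rows are dropped with a log note.
    """
    rows = _read_rows(Path(path))
    records: list[tuple[str, str, str | None]] = []
    suffixes: list[str] = []
    seen_pairs: set[tuple[str, str]] = set()
    for i, row in enumerate(rows, start=1):
        if len(row) < 2 or not row[0] or not row[1]:
            raise FormatError(
                f"{path}: line {i}: expected at least gene and probe columns, got {row!r}"
            )
        gene, probe = row[0], row[1]
        specificity = row[2] if len(row) > 2 and row[2] else None
        if len(row) > 3 and row[3]:
            if row[3] in suffixes:
                raise ValidationError(f"{path}: line {i}: duplicate priority suffix {row[3]!r}")
            suffixes.append(row[3])
        if (gene, probe) in seen_pairs:
            logger.info("%s: line %d: duplicate annotation row (%s, %s) dropped", path, i, gene, probe)
            continue
        seen_pairs.add((gene, probe))
        records.append((gene, probe, specificity))
    return AnnotationTable(tuple(records), tuple(suffixes))


def read_design(path: Path | str, *, study_number: int = 0, study_name: str = "") -> StudyDesign:
    """Read the group design: one group per line, label then its sample IDs.

    A label prefixed ``CONTROL:`` designates the control group; without a
    marker the first-listed group is control.
    """
    rows = _read_rows(Path(path))
    if not rows:
        raise FormatError(f"{path}: empty design file")
    groups: list[str] = []
    sample_to_group: dict[str, str] = {}
    control: str | None = None
    for i, row in enumerate(rows, start=1):
        label, samples = row[0], [c for c in row[1:] if c]
        if label.startswith(CONTROL_MARKER):
            label = label[len(CONTROL_MARKER):].strip()
            if control is not None:
                raise ValidationError(f"{path}: line {i}: more than one CONTROL: marker")
            control = label
        if not label:
            raise FormatError(f"{path}: line {i}: empty group label")
        if label in groups:
            raise ValidationError(f"{path}: line {i}: duplicate group label {label!r}")
        if not samples:
            raise ValidationError(f"{path}: line {i}: group {label!r} has no samples")
        groups.append(label)
        for s in samples:
            if s in sample_to_group:
                raise ValidationError(
                    f"{path}: sample {s!r} assigned to both "
                    f"{sample_to_group[s]!r} and {label!r}"
                )
            sample_to_group[s] = label
    if control is None:
        control = groups[0]
    return StudyDesign(
        groups=tuple(groups),
        sample_to_group=sample_to_group,
        control_group=control,
        study_number=study_number,
        study_name=study_name,
    )


def read_matrix(path: Path | str) -> ExpressionStudy:
    """Read a probes x samples expression matrix.

    First row: header with sample IDs (first cell ignored); first column:
    probe IDs.  Empty cells become NaN; a ',' in any numeric cell raises
    :class:`DecimalSeparatorError` with its coordinates.
    """
    rows = _read_rows(Path(path))
    if len(rows) < 2:
        raise FormatError(f"{path}: expected a header row and at least one probe row")
    sample_ids = rows[0][1:]
    if not sample_ids:
        raise FormatError(f"{path}: header row has no sample columns")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError(f"{path}: duplicate sample ids in header")
    probe_ids: list[str] = []
    values = np.full((len(rows) - 1, len(sample_ids)), np.nan)
    for r, row in enumerate(rows[1:], start=2):
        if not row[0]:
            raise FormatError(f"{path}: row {r}: empty probe id")
        if len(row) - 1 > len(sample_ids):
            raise FormatError(f"{path}: row {r}: more cells than header columns")
        probe_ids.append(row[0])
        for c, cell in enumerate(row[1:]):
            values[r - 2, c] = parse_number(cell, context=f"{path}: row {r}, column {c + 2}")
    if len(set(probe_ids)) != len(probe_ids):
        dup = next(p for p in probe_ids if probe_ids.count(p) > 1)
        raise ValidationError(f"{path}: duplicate probe id {dup!r}")
    return ExpressionStudy(probe_ids=probe_ids, sample_ids=sample_ids, values=values)


def parse_folder_name(name: str) -> tuple[int, str, bool] | None:
    """Parse '<number> <study name>[ NOLOG]' -> (number, name, nolog) or None."""
    m = _FOLDER_RE.match(name)
    if m is None:
        return None
    number = int(m.group(1))
    rest = m.group(2)
    tokens = rest.split()
    nolog = NOLOG_TOKEN in tokens
    study_name = " ".join(t for t in tokens if t != NOLOG_TOKEN)
    return number, study_name, nolog


def scan_study_folders(root: Path | str) -> list[StudyFolder]:
    """Discover, parse and validate every numbered study folder under *root*.

    Folders whose name is not '<integer> <name>' (e.g. output folders or a
    "SubVIs" directory) are skipped with a logged warning.  Result is sorted
    by study number regardless of directory creation order.
    """
    root = Path(root)
    folders: list[StudyFolder] = []
    numbers_seen: dict[int, str] = {}
    for entry in sorted(root.iterdir(), key=lambda p: p.name):
        if not entry.is_dir():
            continue
        parsed = parse_folder_name(entry.name)
        if parsed is None:
            logger.warning("skipping folder without leading '<number> ' prefix: %s", entry.name)
            continue
        number, study_name, nolog = parsed
        if number in numbers_seen:
            raise ValidationError(
                f"duplicate study number {number}: {numbers_seen[number]!r} and {entry.name!r}"
            )
        numbers_seen[number] = entry.name
        design = read_design(entry / DESIGN_FILENAME, study_number=number, study_name=study_name)
        annotation = read_annotation(entry / ANNOTATION_FILENAME)
        expression = read_matrix(entry / DATA_FILENAME)
        expression.nolog_flag = nolog
        if nolog:
            expression.scale = Scale.LINEAR
        folders.append(
            StudyFolder(
                path=entry,
                study_number=number,
                study_name=study_name,
                design=design,
                annotation=annotation,
                expression=expression,
            )
        )
    folders.sort(key=lambda f: f.study_number)
    return folders


# ---------------------------------------------------------------------------
# writer


def write_table(
    rows: Iterable[Sequence[object]],
    path: Path | str,
    policy: OverwritePolicy = OverwritePolicy.PRESERVE,
) -> Path:
    """Write rows of cells as tab-separated text.

    Under the default PRESERVE policy an existing file is left untouched (a
    skip is logged) so that re-runs never destroy hand-edited outputs; FORCE
    replaces it.
    """
    path = Path(path)
    if path.exists() and policy is OverwritePolicy.PRESERVE:
        logger.info("preserving existing file, not overwritten: %s", path)
        return path
    path.parent.mkdir(parents=True, exist_ok=True)
    text = "\n".join("\t".join(_fmt(c) for c in row) for row in rows)
    path.write_text(text + "\n", encoding="utf-8")
    return path
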