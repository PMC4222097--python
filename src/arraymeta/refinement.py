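"""Scale resolution, probe collapsing and group-to-control ratios.

Studies arrive either log2-transformed or linear.  In AUTO mode the scale
is inferred from the largest finite intensity (log2 microarray intensities
rarely exceed ~16, linear ones run into the thousands); in MANUAL mode the
"NOLOG" folder token alone decides.  The detected scale is logged per study
so the user can verify it.

Genes measured by several probes are collapsed to one: probes are ranked by
an ordered suffix whitelist (Affymetrix-style specificity endings such as
"_at", "_s_at"); among top-ranked probes the one with the highest
mean/median control-group intensity wins.  Ratios are log2 fold changes:
center(group) - center(control) on the log2 scale, computed after samples
are clustered into their declared groups regardless of column order in the
data file.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .extraction import ExtractedStudy
from .io_formats import (
    REFINED_DIRNAME,
    ExpressionStudy,
    OverwritePolicy,
    Scale,
    StudyDesign,
    ValidationError,
    write_table,
)

logger = logging.getLogger(__name__)

#: Sentinel rank for a probe rejected by a non-empty priority list.
EXCLUDED = None


class Center(enum.Enum):
    MEAN = "mean"
    MEDIAN = "median"


class LogMode(enum.Enum):
    AUTO = "auto"
    MANUAL = "manual"


@dataclass(frozen=True)
class RefineConfig:
    center: Center = Center.MEAN
    log_mode: LogMode = LogMode.AUTO
    auto_log_threshold: float = 50.0

    def __post_init__(self) -> None:
        if not self.auto_log_threshold > 1:
            raise ValidationError("auto_log_threshold must be > 1")


@dataclass
class RefinedGene:
    probe_id: str
    group_values: dict[str, np.ndarray]  # log2-scale samples per group (NaN = missing)
    group_n: dict[str, int]              # non-missing count per group
    group_center: dict[str, float]       # mean or median per group (NaN if empty)
    ratios: dict[str, float]             # non-control group -> log2 fold change


@dataclass
class RefinedStudy:
    study_number: int
    study_name: str
    design: StudyDesign
    center: Center
    genes: dict[str, RefinedGene] = field(default_factory=dict)


def _center(values: np.ndarray, center: Center) -> float:
    vals = values[np.isfinite(values)]
    if vals.size == 0:
        return float("nan")
    return float(np.mean(vals) if center is Center.MEAN else np.median(vals))


def detect_log2(expression: ExpressionStudy, threshold: float = 50.0) -> bool:
    """Heuristic scale detection: already log2 iff max finite value <= threshold."""
    finite = expression.values[np.isfinite(expression.values)]
    if finite.size == 0:
        raise ValidationError("cannot detect scale: matrix has no finite values")
    return bool(finite.max() <= threshold)


def to_log2(expression: ExpressionStudy, is_log2: bool) -> ExpressionStudy:
    """Return the matrix on log2 scale; linear input must be strictly positive.

    A non-positive value in linear data raises :class:`ValidationError`
    naming the offending cell — normalized matrices should be positive, and
    a silent offset would distort every downstream ratio.
    """
    if is_log2:
        return expression
    values = expression.values
    bad = np.argwhere(np.isfinite(values) & (values <= 0))
    if bad.size:
        r, c = bad[0]
        raise ValidationError(
            f"non-positive value {values[r, c]!r} in linear-scale data at probe "
            f"{expression.probe_ids[r]!r}, sample {expression.sample_ids[c]!r}"
        )
    return ExpressionStudy(
        probe_ids=list(expression.probe_ids),
        sample_ids=list(expression.sample_ids),
        values=np.log2(values),
        scale=Scale.LOG2,
        nolog_flag=expression.nolog_flag,
    )


def log2_values(values: np.ndarray, *, context: str = "") -> np.ndarray:
    """log2-transform a value vector, rejecting non-positive entries."""
    finite = np.isfinite(values)
    if np.any(finite & (values <= 0)):
        i = int(np.argmax(finite & (values <= 0)))
        raise ValidationError(
            f"{context}: non-positive value {values[i]!r} in linear-scale data"
        )
    out = np.full_like(values, np.nan, dtype=float)
    out[finite] = np.log2(values[finite])
    return out


def probe_priority(probe_id: str, priority_suffixes: tuple[str, ...] | list[str]):
    """Rank a probe by the suffix whitelist (0 = best); EXCLUDED when no match.

    Suffixes are tested longest-first so that e.g. "_at" in the list does not
    swallow a probe ending in "_s_at"; the returned rank is the matched
    suffix's position in the list.  With an empty list every probe ranks 0.
    """
    if not priority_suffixes:
        return 0
    matches = [(len(s), -i) for i, s in enumerate(priority_suffixes) if probe_id.endswith(s)]
    if not matches:
        return EXCLUDED
    _, neg_i = max(matches)
    return -neg_i


def select_probe(
    candidates: list[tuple[str, np.ndarray]],
    priority_suffixes: tuple[str, ...] | list[str],
    center: Center,
) -> str | None:
    """Pick one probe per gene: best priority rank, then brightest control center.

    *candidates* is [(probe_id, control-group values)] in annotation order.
    Among minimum-rank candidates the one with the highest mean/median of its
    control values wins; an exact tie keeps the first in annotation order.
    Returns None when a non-empty priority list excludes every candidate.
    """
    ranked = []
    for order, (probe, control_values) in enumerate(candidates):
        rank = probe_priority(probe, priority_suffixes)
        if rank is EXCLUDED:
            continue
        c = _center(np.asarray(control_values, dtype=float), center)
        key = -c if math.isfinite(c) else math.inf  # all-missing sorts last
        ranked.append((rank, key, order, probe))
    if not ranked:
        return None
    ranked.sort()
    return ranked[0][3]


def compute_ratios(
    extracted: ExtractedStudy,
    selected: dict[str, tuple[str, np.ndarray]],
    config: RefineConfig,
) -> RefinedStudy:
    """Group samples by design and compute per-gene log2 ratios vs control.

    *selected* maps gene -> (chosen probe, log2-scale values aligned to
    ``extracted.sample_ids``).  Ratio = center(group) - center(control) on
    log2 scale; a group with zero non-missing values yields a missing ratio.
    """
    design = extracted.design
    sample_pos = {s: i for i, s in enumerate(extracted.sample_ids)}
    group_idx = {
        g: np.array([sample_pos[s] for s in design.samples_in(g)], dtype=int)
        for g in design.groups
    }
    refined = RefinedStudy(
        study_number=design.study_number,
        study_name=design.study_name,
        design=design,
        center=config.center,
    )
    for gene, (probe, log2_row) in selected.items():
        gvals = {g: log2_row[idx] for g, idx in group_idx.items()}
        gn = {g: int(np.isfinite(v).sum()) for g, v in gvals.items()}
        gc = {g: _center(v, config.center) for g, v in gvals.items()}
        ctrl = gc[design.control_group]
        ratios = {g: gc[g] - ctrl for g in design.noncontrol_groups}
        refined.genes[gene] = RefinedGene(probe, gvals, gn, gc, ratios)
    return refined


def refine_study(extracted: ExtractedStudy, config: RefineConfig) -> RefinedStudy:
    """Full refinement of one extracted study: scale, probe choice, ratios."""
    folder = extracted.folder
    if config.log_mode is LogMode.MANUAL:
        is_log2 = not folder.expression.nolog_flag
        logger.info("study %d: manual scale: %s", folder.study_number,
                    "log2" if is_log2 else "linear (NOLOG)")
    else:
        is_log2 = detect_log2(folder.expression, config.auto_log_threshold)
        logger.info("study %d: auto-detected scale: %s — please check if correct!",
                    folder.study_number, "log2" if is_log2 else "linear")

    by_gene: dict[str, list[tuple[str, np.ndarray]]] = {}
    for row in extracted.rows:
        vals = row.values if is_log2 else log2_values(
            row.values, context=f"study {folder.study_number}, probe {row.probe_id}"
        )
        by_gene.setdefault(row.gene_id, []).append((row.probe_id, vals))

    design = extracted.design
    sample_pos = {s: i for i, s in enumerate(extracted.sample_ids)}
    ctrl_idx = np.array(
        [sample_pos[s] for s in design.samples_in(design.control_group)], dtype=int
    )
    priorities = folder.annotation.priority_suffixes

    selected: dict[str, tuple[str, np.ndarray]] = {}
    for gene, cands in by_gene.items():
        choice = select_probe(
            [(p, v[ctrl_idx]) for p, v in cands], priorities, config.center
        )
        if choice is None:
            logger.warning("study %d: gene %s dropped — all probes excluded by priority list",
                           folder.study_number, gene)
            continue
        selected[gene] = next((p, v) for p, v in cands if p == choice)
    return compute_ratios(extracted, selected, config)


def persist_refined(
    refined: RefinedStudy,
    root: Path | str,
    policy: OverwritePolicy = OverwritePolicy.PRESERVE,
) -> Path:
    """Write 'Refined Data/refined_<n>.txt': per gene the chosen probe and,
    per group, its N, center and (non-control) ratio vs control."""
    design = refined.design
    header: list[str] = ["Gene", "Probe"]
    for g in design.groups:
        header += [f"{g}:N", f"{g}:{refined.center.value}"]
        if g != design.control_group:
            header.append(f"{g}:ratio")
    body = []
    for gene, rg in refined.genes.items():
        row: list[object] = [gene, rg.probe_id]
        for g in design.groups:
            row += [rg.group_n[g], rg.group_center[g]]
            if g != design.control_group:
                row.append(rg.ratios[g])
        body.append(row)
    out = Path(root) / REFINED_DIRNAME / f"refined_{refined.study_number}.txt"
    return write_table([header, *body], out, policy)
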