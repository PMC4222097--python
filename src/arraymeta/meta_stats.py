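"""Per-study one-tailed t-tests and cross-study p-value combination.

For every gene and every (study, non-control group) comparison a pooled-
variance two-sample Student's t-test is run on the log2 intensities; the
one-tailed p-value is taken in the observed direction (p_one = p_two / 2)
and carries the sign of the group-minus-control mean difference.

Two classical combination methods merge the per-study p-values:

* **Stouffer's Z-transform.**  Each p becomes a signed normal quantile
  Z_i = Phi^-1(1 - p_one,i) * direction_i, so that strong evidence in the
  "up" direction gives a large positive Z and evidence in opposite
  directions cancels.  The combined score is Z_s = sum(Z_i) / sqrt(N)
  (unweighted; an unnormalised sum / N variant is available for
  compatibility) and the combined two-sided p is p_s = 2 * (1 - Phi(|Z_s|)).
  Because Phi^-1(1 - p_two/2) * sign(t) is exactly standard normal whenever
  the per-study p is uniform, Stouffer's statistic is calibrated under the
  null.

* **Fisher's method.**  chi2 = -2 * sum(ln p_one,i) referred to a
  chi-square distribution with 2k degrees of freedom.  Fisher's statistic
  is sign-blind; a consensus direction is attached afterwards by majority
  vote of the per-study directions.  Note that feeding it one-tailed
  p-values taken in the observed direction (which live in (0, 0.5] under
  the null) makes it anticonservative; see the methods documentation.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import OverwritePolicy, ValidationError, write_table
from .merge import MergedTable
from .refinement import RefinedStudy

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300  # clamp for p = 0 before Phi^-1 / log


class StatMethod(enum.Enum):
    STOUFFER = "stouffer"
    FISHER = "fisher"


class StoufferDenominator(enum.Enum):
    SQRT_N = "sqrt-n"  # canonical Z-transform denominator
    N = "n"            # plain-average variant


@dataclass(frozen=True)
class StatConfig:
    method: StatMethod = StatMethod.STOUFFER
    stouffer_denominator: StoufferDenominator = StoufferDenominator.SQRT_N
    welch: bool = False            # unequal-variance t instead of pooled Student
    benjamini_hochberg: bool = False  # append an FDR-adjusted column


@dataclass(frozen=True)
class StudyTestResult:
    """One gene's one-tailed t-test in one (study, group) comparison."""

    gene_id: str
    study_number: int
    group: str
    p_one: float
    direction: int          # sign(mean_group - mean_control); 0 iff exactly equal
    t_stat: float
    df: float
    n_group: int
    n_control: int
    testable: bool = True


@dataclass(frozen=True)
class MetaResult:
    """Combined cross-study evidence for one gene."""

    gene_id: str
    method: StatMethod
    k: int                         # number of p-values combined
    p_combined: float
    direction_consensus: int
    z_scores: tuple[float, ...] = ()
    z_combined: float | None = None
    n_scores: int | None = None
    chi2: float | None = None
    dof: int | None = None
    studies_used: int = 0

    @property
    def statistic(self) -> float:
        return self.z_combined if self.method is StatMethod.STOUFFER else self.chi2


def one_tailed_t(
    group_values: np.ndarray,
    control_values: np.ndarray,
    *,
    welch: bool = False,
) -> tuple[float, int, float, float, bool]:
    """Two-sample t-test reporting the one-sided tail in the observed direction.

    Returns ``(p_one, direction, t, df, testable)``.  Pooled-variance Student
    by default (df = n1 + n2 - 2); Welch on request.  Fewer than two
    non-missing values on either side makes the comparison untestable.
    Identical group means give t = 0, p_one = 0.5 and direction 0.
    """
    g = np.asarray(group_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    g = g[np.isfinite(g)]
    c = c[np.isfinite(c)]
    if g.size < 2 or c.size < 2:
        return float("nan"), 0, float("nan"), float("nan"), False
    diff = float(np.mean(g) - np.mean(c))
    direction = 0 if diff == 0 else (1 if diff > 0 else -1)
    res = sps.ttest_ind(g, c, equal_var=not welch)
    t, p_two = float(res.statistic), float(res.pvalue)
    df = float(res.df)
    if not math.isfinite(t):  # zero pooled variance
        if direction == 0:
            t, p_two = 0.0, 1.0
        else:
            t = math.copysign(math.inf, diff)
            p_two = 0.0
        df = float(g.size + c.size - 2) if not welch else df
    p_one = p_two / 2 if direction != 0 else 0.5
    p_one = min(max(p_one, 0.0), 1.0)
    return p_one, direction, t, df, True


def _clamp_p(p: float) -> float:
    if p < _P_FLOOR:
        logger.warning("p-value %.3g clamped to %.0e before combination", p, _P_FLOOR)
        return _P_FLOOR
    return min(p, 1.0)


def stouffer_combine(results: list[StudyTestResult], config: StatConfig = StatConfig()) -> MetaResult:
    """Combine signed per-study evidence with Stouffer's Z-transform."""
    usable = [r for r in results if r.testable]
    if not usable:
        raise ValidationError("no testable results to combine")
    z_scores = tuple(
        float(sps.norm.isf(_clamp_p(r.p_one))) * r.direction for r in usable
    )
    n = len(z_scores)
    denom = math.sqrt(n) if config.stouffer_denominator is StoufferDenominator.SQRT_N else n
    z_s = float(np.sum(z_scores)) / denom
    p_s = float(2.0 * sps.norm.sf(abs(z_s)))
    p_s = max(min(p_s, 1.0), 5e-324)
    return MetaResult(
        gene_id=usable[0].gene_id,
        method=StatMethod.STOUFFER,
        k=n,
        p_combined=p_s,
        direction_consensus=0 if z_s == 0 else (1 if z_s > 0 else -1),
        z_scores=z_scores,
        z_combined=z_s,
        n_scores=n,
        studies_used=len({r.study_number for r in usable}),
    )


def fisher_combine(results: list[StudyTestResult], config: StatConfig = StatConfig()) -> MetaResult:
    """Combine per-study p-values with Fisher's chi-square method (sign-blind)."""
    usable = [r for r in results if r.testable]
    if not usable:
        raise ValidationError("no testable results to combine")
    k = len(usable)
    chi2 = float(-2.0 * sum(math.log(_clamp_p(r.p_one)) for r in usable))
    p = float(sps.chi2.sf(chi2, 2 * k))
    p = max(min(p, 1.0), 5e-324)
    sign_sum = sum(r.direction for r in usable)
    consensus = 0 if sign_sum == 0 else (1 if sign_sum > 0 else -1)
    return MetaResult(
        gene_id=usable[0].gene_id,
        method=StatMethod.FISHER,
        k=k,
        p_combined=p,
        direction_consensus=consensus,
        chi2=chi2,
        dof=2 * k,
        studies_used=len({r.study_number for r in usable}),
    )


def combine(results: list[StudyTestResult], config: StatConfig = StatConfig()) -> MetaResult:
    if config.method is StatMethod.STOUFFER:
        return stouffer_combine(results, config)
    return fisher_combine(results, config)


def compute_study_tests(
    refined: list[RefinedStudy], config: StatConfig = StatConfig()
) -> list[StudyTestResult]:
    """t-test every gene in every (study, non-control group) comparison."""
    out: list[StudyTestResult] = []
    for study in refined:
        design = study.design
        ctrl = design.control_group
        for gene, rg in study.genes.items():
            for g in design.noncontrol_groups:
                p_one, direction, t, df, testable = one_tailed_t(
                    rg.group_values[g], rg.group_values[ctrl], welch=config.welch
                )
                if not testable:
                    logger.info(
                        "study %d group %s gene %s: untestable (fewer than 2 values "
                        "per side), excluded from combination",
                        study.study_number, g, gene,
                    )
                out.append(
                    StudyTestResult(
                        gene_id=gene,
                        study_number=study.study_number,
                        group=g,
                        p_one=p_one,
                        direction=direction,
                        t_stat=t,
                        df=df,
                        n_group=rg.group_n[g],
                        n_control=rg.group_n[ctrl],
                        testable=testable,
                    )
                )
    return out


def annotate_merged(
    table: MergedTable,
    results: list[StudyTestResult],
    config: StatConfig = StatConfig(),
) -> tuple[MergedTable, list[MetaResult]]:
    """Append per-study p-values and the combined statistic to a merged table.

    Only results matching the table's genes and its surviving
    (study, group) columns are used, so a hand-edited table (rows or columns
    deleted, rows sorted) is combined over exactly what remains.  A gene
    with zero testable comparisons gets missing statistics cells.
    """
    col_keys = {(c.study_number, c.group): c.label for c in table.columns}
    by_gene: dict[str, list[StudyTestResult]] = {g: [] for g in table.values.index}
    for r in results:
        if r.gene_id in by_gene and (r.study_number, r.group) in col_keys:
            by_gene[r.gene_id].append(r)

    sign_char = {1: "+", -1: "-", 0: "0"}
    p_cols = {f"p:{label}": {} for label in col_keys.values()}
    combined_rows: dict[str, list[object]] = {}
    metas: list[MetaResult] = []
    for gene, rs in by_gene.items():
        for r in rs:
            if r.testable:
                p_cols[f"p:{col_keys[(r.study_number, r.group)]}"][gene] = r.p_one
        testable = [r for r in rs if r.testable]
        if not testable:
            combined_rows[gene] = ["", "", "", ""]
            continue
        meta = combine(testable, config)
        metas.append(meta)
        combined_rows[gene] = [
            format(meta.statistic, ".6g"),
            format(meta.p_combined, ".6g"),
            sign_char[meta.direction_consensus],
            meta.k,
        ]

    genes = list(table.values.index)
    stats = pd.DataFrame(index=table.values.index)
    for label in col_keys.values():
        col = p_cols[f"p:{label}"]
        stats[f"p:{label}"] = [
            format(col[g], ".6g") if g in col else "" for g in genes
        ]
    stat_name = "combined:Z" if config.method is StatMethod.STOUFFER else "combined:chi2"
    for i, name in enumerate([stat_name, "combined:p", "combined:sign", "combined:k"]):
        stats[name] = [combined_rows[g][i] for g in genes]
    if config.benjamini_hochberg:
        pmap = {m.gene_id: m.p_combined for m in metas}
        order = [g for g in genes if g in pmap]
        if order:
            adj = sps.false_discovery_control([pmap[g] for g in order], method="bh")
            adj_map = dict(zip(order, adj))
            stats["combined:p_bh"] = [
                format(adj_map[g], ".6g") if g in adj_map else "" for g in genes
            ]

    annotated = MergedTable(
        columns=list(table.columns), values=table.values.copy(), stats=stats
    )
    return annotated, metas


def write_stats_summary(
    metas: list[MetaResult],
    path: Path | str,
    policy: OverwritePolicy = OverwritePolicy.FORCE,
) -> Path:
    """Write 'stats_summary.txt': one row per gene with the combined result."""
    header = ["Gene", "method", "statistic", "dof_or_N", "p_combined", "sign", "studies_used"]
    sign_char = {1: "+", -1: "-", 0: "0"}
    body = [
        [
            m.gene_id,
            m.method.value,
            format(m.statistic, ".6g"),
            m.dof if m.method is StatMethod.FISHER else m.n_scores,
            format(m.p_combined, ".6g"),
            sign_char[m.direction_consensus],
            m.studies_used,
        ]
        for m in metas
    ]
    return write_table([header, *body], path, policy)
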