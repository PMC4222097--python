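"""Synthetic multi-study folder trees with known ground truth.

The generator emits the exact on-disk layout the pipeline consumes —
numbered study folders with ``Data.txt``, ``Annotation.txt`` and
``Data Description.txt`` plus a shared gene list — so that every stage,
from parsing to combined statistics, is testable end to end without any
external download.

The default configuration mirrors a multi-cohort disease-vs-control
meta-analysis: 12 studies, two groups per study, 8 samples per group,
288 genes measured by 1–3 probes each, i.i.d. Gaussian noise with
sigma = 1 on the log2 scale, and an Affymetrix-style probe-suffix scheme.
Per gene and study a baseline log2 intensity is drawn, the designated
"true" probe sits at that baseline while decoy probes are 3 log2 units
dimmer (so control-group brightness identifies the true probe
deterministically), and injected genes receive a constant log2 effect in
every non-control group.  Studies listed in ``linear_scale_studies`` are
written as 2^x with a "NOLOG" folder token.

Everything derives from a single integer seed; two runs with the same
config produce byte-identical trees.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .io_formats import (
    ANNOTATION_FILENAME,
    DATA_FILENAME,
    DESIGN_FILENAME,
    GENE_LIST_FILENAME,
    CONTROL_MARKER,
    ValidationError,
)

GROUND_TRUTH_FILENAME = "ground_truth.txt"

MUTATIONS = ("comma_decimal", "duplicate_gene", "missing_annotation_row", "unnumbered_folder")


@dataclass(frozen=True)
class SynthConfig:
    n_studies: int = 12
    groups_per_study: int = 2          # including control
    samples_per_group: int = 8
    n_genes: int = 288
    probes_per_gene: tuple[int, int] = (1, 3)   # inclusive range
    effect_genes: Mapping[str, float] = field(default_factory=dict)  # gene -> log2 effect
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    probe_brightness_gap: float = 3.0  # log2 deficit of each decoy probe
    n_decoy_probes: int = 20           # unannotated probes per study
    linear_scale_studies: frozenset[int] = frozenset()  # 1-based study numbers
    suffix_scheme: tuple[str, ...] = ("_at", "_s_at", "_x_at")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1 or self.n_genes < 1 or self.samples_per_group < 1:
            raise ValidationError("all synthetic counts must be positive")
        if self.groups_per_study < 2:
            raise ValidationError("need at least control + one group")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")

    def gene_names(self) -> list[str]:
        return [f"GENE{i:04d}" for i in range(1, self.n_genes + 1)]


@dataclass
class GroundTruth:
    """What the generator injected, keyed by gene."""

    effects: dict[str, float]      # 0.0 for null genes
    directions: dict[str, int]
    best_probe: dict[str, str]
    seed: int


def _groups(config: SynthConfig) -> list[str]:
    return ["control"] + [f"disease{i}" for i in range(1, config.groups_per_study)]


def generate_tree(config: SynthConfig, root: Path | str, force: bool = False) -> GroundTruth:
    """Write a complete synthetic study tree under *root* and return its truth.

    Raises :class:`ValidationError` if *root* exists non-empty without
    *force*.  Deterministic for a given config (seed included).
    """
    root = Path(root)
    if root.exists() and any(root.iterdir()):
        if not force:
            raise ValidationError(f"refusing to write into non-empty directory {root}")
        shutil.rmtree(root)
    root.mkdir(parents=True, exist_ok=True)

    unknown = set(config.effect_genes) - set(config.gene_names())
    if unknown:
        raise ValidationError(f"effect genes not in gene set: {sorted(unknown)}")

    rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    gene_index = {g: i for i, g in enumerate(genes)}
    groups = _groups(config)
    lo, hi = config.probes_per_gene
    n_probes = {g: int(rng.integers(lo, hi + 1)) for g in genes}

    def probe_name(gene: str, j: int) -> str:
        # even-index genes: all probes share the top suffix so the control-
        # brightness tie-break decides; odd-index genes: suffixes cycle so
        # priority ranking decides (brightness agrees in both cases)
        if not config.suffix_scheme:
            suffix = ""
        elif gene_index[gene] % 2 == 0:
            suffix = config.suffix_scheme[0]
        else:
            suffix = config.suffix_scheme[j % len(config.suffix_scheme)]
        return f"{gene}_p{j}{suffix}"

    truth = GroundTruth(
        effects={g: float(config.effect_genes.get(g, 0.0)) for g in genes},
        directions={g: int(np.sign(config.effect_genes.get(g, 0.0))) for g in genes},
        best_probe={g: probe_name(g, 0) for g in genes},
        seed=config.seed,
    )

    (root / GENE_LIST_FILENAME).write_text("\n".join(genes) + "\n", encoding="utf-8")

    for study in range(1, config.n_studies + 1):
        linear = study in config.linear_scale_studies
        name = f"{study} Synthetic{study:02d}" + (" NOLOG" if linear else "")
        folder = root / name
        folder.mkdir()

        samples = {
            g: [f"S{study}{g[:1].upper()}{gi}R{r}" for r in range(1, config.samples_per_group + 1)]
            for gi, g in enumerate(groups)
        }
        design_lines = []
        for g in groups:
            label = CONTROL_MARKER + g if g == "control" else g
            design_lines.append("\t".join([label, *samples[g]]))
        (folder / DESIGN_FILENAME).write_text("\n".join(design_lines) + "\n", encoding="utf-8")

        ann_lines = []
        suffix_col = list(config.suffix_scheme)
        row_i = 0
        for gene in genes:
            for j in range(n_probes[gene]):
                cells = [gene, probe_name(gene, j), ""]
                if row_i < len(suffix_col):
                    cells.append(suffix_col[row_i])
                ann_lines.append("\t".join(cells).rstrip("\t"))
                row_i += 1
        (folder / ANNOTATION_FILENAME).write_text("\n".join(ann_lines) + "\n", encoding="utf-8")

        sample_order = [s for g in groups for s in samples[g]]
        # shuffle columns so group clustering actually has work to do
        perm = rng.permutation(len(sample_order))
        shuffled = [sample_order[i] for i in perm]
        group_of = {s: g for g in groups for s in samples[g]}

        lines = ["\t".join(["ID", *shuffled])]
        for gene in genes:
            base = rng.normal(config.baseline_mean, config.baseline_sd)
            effect = truth.effects[gene]
            for j in range(n_probes[gene]):
                offset = 0.0 if j == 0 else -config.probe_brightness_gap * j
                row_vals = []
                for s in shuffled:
                    g = group_of[s]
                    mu = base + offset + (effect if g != "control" else 0.0)
                    row_vals.append(mu + rng.normal(0.0, config.noise_sd))
                cells = [
                    format(2.0 ** v, ".12g") if linear else format(v, ".10f")
                    for v in row_vals
                ]
                lines.append("\t".join([probe_name(gene, j), *cells]))
        for d in range(config.n_decoy_probes):
            row_vals = rng.normal(config.baseline_mean, config.baseline_sd, len(shuffled))
            cells = [
                format(2.0 ** v, ".12g") if linear else format(v, ".10f") for v in row_vals
            ]
            lines.append("\t".join([f"DECOY{d:03d}_at", *cells]))
        (folder / DATA_FILENAME).write_text("\n".join(lines) + "\n", encoding="utf-8")

    gt_lines = [f"# seed={config.seed}", "Gene\teffect\tdirection\tbest_probe"]
    for g in genes:
        gt_lines.append(f"{g}\t{truth.effects[g]:.6g}\t{truth.directions[g]}\t{truth.best_probe[g]}")
    (root / GROUND_TRUTH_FILENAME).write_text("\n".join(gt_lines) + "\n", encoding="utf-8")
    return truth


def read_ground_truth(root: Path | str) -> GroundTruth:
    lines = (Path(root) / GROUND_TRUTH_FILENAME).read_text(encoding="utf-8").splitlines()
    seed = int(lines[0].split("=", 1)[1])
    truth = GroundTruth(effects={}, directions={}, best_probe={}, seed=seed)
    for ln in lines[2:]:
        gene, eff, direction, probe = ln.split("\t")
        truth.effects[gene] = float(eff)
        truth.directions[gene] = int(direction)
        truth.best_probe[gene] = probe
    return truth


def degrade_tree(root: Path | str, mutation: str) -> None:
    """Inject one named defect into a valid tree, for negative-path tests.

    Mutations: ``comma_decimal`` (first data cell of study 1 gets a ','
    decimal), ``duplicate_gene`` (first gene appended again to the gene
    list), ``missing_annotation_row`` (first gene's annotation rows removed
    from study 1), ``unnumbered_folder`` (adds a "SubVIs" directory).
    """
    root = Path(root)
    folders = sorted(
        (p for p in root.iterdir() if p.is_dir() and p.name[:1].isdigit()),
        key=lambda p: p.name,
    )
    if mutation == "comma_decimal":
        data = folders[0] / DATA_FILENAME
        lines = data.read_text(encoding="utf-8").splitlines()
        cells = lines[1].split("\t")
        cells[1] = cells[1].replace(".", ",", 1)
        lines[1] = "\t".join(cells)
        data.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif mutation == "duplicate_gene":
        path = root / GENE_LIST_FILENAME
        genes = path.read_text(encoding="utf-8").splitlines()
        path.write_text("\n".join(genes + [genes[0]]) + "\n", encoding="utf-8")
    elif mutation == "missing_annotation_row":
        ann = folders[0] / ANNOTATION_FILENAME
        lines = ann.read_text(encoding="utf-8").splitlines()
        gene = lines[0].split("\t")[0]
        kept = [ln for ln in lines if not ln.startswith(gene + "\t")]
        ann.write_text("\n".join(kept) + "\n", encoding="utf-8")
    elif mutation == "unnumbered_folder":
        sub = root / "SubVIs"
        sub.mkdir(exist_ok=True)
        (sub / "readme.txt").write_text("helper files\n", encoding="utf-8")
    else:
        raise ValidationError(f"unknown mutation {mutation!r}; choose one of {MUTATIONS}")
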