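"""Merging refined studies, the case-study filters and merged-file round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from arraymeta.io_formats import OverwritePolicy, StudyDesign, ValidationError
from arraymeta.merge import (
    ColumnMeta,
    FilterConfig,
    MergedTable,
    apply_filters,
    load_merged,
    merge_studies,
    write_merged,
)
from arraymeta.refinement import Center, RefinedGene, RefinedStudy


def refined_study(number, groups, genes_ratios, n_per_group=6):
    """Build a RefinedStudy from {gene: {group: ratio}}."""
    all_groups = ("control", *groups)
    design = StudyDesign(
        groups=all_groups,
        sample_to_group={
            f"s{number}_{g}_{i}": g for g in all_groups for i in range(n_per_group)
        },
        control_group="control",
        study_number=number,
        study_name=f"St{number}",
    )
    rs = RefinedStudy(number, f"St{number}", design, Center.MEAN)
    for gene, ratios in genes_ratios.items():
        rs.genes[gene] = RefinedGene(
            probe_id=f"{gene}_at",
            group_values={g: np.zeros(n_per_group) for g in all_groups},
            group_n={g: n_per_group for g in all_groups},
            group_center={g: 8.0 for g in all_groups},
            ratios=dict(ratios),
        )
    return rs


def table_from_cells(cells, n_groups, n_controls=None):
    """MergedTable from {gene: {(study, group): ratio}} plus column Ns."""
    cols = [ColumnMeta(s, g, n, (n_controls or {}).get((s, g), n))
            for (s, g), n in n_groups.items()]
    genes = list(cells)
    values = pd.DataFrame(
        [[cells[gene].get((c.study_number, c.group), np.nan) for c in cols]
         for gene in genes],
        index=pd.Index(genes, name="Gene"),
        columns=[c.label for c in cols],
    )
    return MergedTable(columns=cols, values=values)


class TestMerge:
    def test_column_count_and_order(self):
        r1 = refined_study(2, ("d1", "d2"), {"A": {"d1": 1.0, "d2": 2.0}})
        r2 = refined_study(1, ("dx", "dy"), {"A": {"dx": 3.0, "dy": 4.0}})
        t = merge_studies([r1, r2])
        assert [c.label for c in t.columns] == ["S1:dx", "S1:dy", "S2:d1", "S2:d2"]

    def test_absent_gene_gets_missing_cells(self):
        r1 = refined_study(1, ("d",), {"A": {"d": 1.0}})
        r2 = refined_study(2, ("d",), {"B": {"d": -1.0}})
        t = merge_studies([r1, r2], gene_order=["A", "B"])
        assert np.isnan(t.values.at["A", "S2:d"])
        assert t.values.at["B", "S2:d"] == -1.0

    def test_gene_order_follows_gene_list(self):
        r1 = refined_study(1, ("d",), {"B": {"d": 1.0}})
        r2 = refined_study(2, ("d",), {"A": {"d": 1.0}})
        t = merge_studies([r1, r2], gene_order=["A", "B", "C"])
        assert t.genes == ["A", "B"]  # C found nowhere

    def test_single_study_merge_matches_refined_cells(self):
        ratios = {"A": {"d1": 0.5, "d2": -0.25}, "B": {"d1": 1.5, "d2": np.nan}}
        t = merge_studies([refined_study(3, ("d1", "d2"), ratios)])
        for gene, rr in ratios.items():
            for g, v in rr.items():
                cell = t.values.at[gene, f"S3:{g}"]
                assert (np.isnan(v) and np.isnan(cell)) or cell == v

    def test_merge_then_split_recovers_cells(self):
        studies = [
            refined_study(1, ("d",), {"A": {"d": 0.1}, "B": {"d": 0.2}}),
            refined_study(2, ("e",), {"A": {"e": -0.3}}),
        ]
        t = merge_studies(studies, gene_order=["A", "B"])
        for s in studies:
            for gene, rg in s.genes.items():
                for g, v in rg.ratios.items():
                    assert t.values.at[gene, f"S{s.study_number}:{g}"] == v

    def test_duplicate_study_group_column_rejected(self):
        r1 = refined_study(1, ("d",), {"A": {"d": 1.0}})
        r2 = refined_study(1, ("d",), {"B": {"d": 1.0}})
        with pytest.raises(ValidationError):
            merge_studies([r1, r2])


def brute_filter(cells, n_groups, cfg):
    """Loop-based re-implementation of the three filters (the oracle)."""
    cols = [(s, g) for (s, g), n in n_groups.items() if n >= cfg.min_group_n]
    survivors = []
    for gene, row in cells.items():
        per_study = {}
        for (s, g) in cols:
            v = row.get((s, g))
            if v is not None and not np.isnan(v):
                per_study.setdefault(s, []).append(v)
        if len(per_study) < cfg.min_studies_per_gene:
            continue
        dirs = []
        for vals in per_study.values():
            up = sum(1 for v in vals if v > 0)
            down = sum(1 for v in vals if v < 0)
            dirs.append(1 if up > down else (-1 if down > up else 0))
        n_up = sum(1 for d in dirs if d == 1)
        n_down = sum(1 for d in dirs if d == -1)
        if max(n_up, n_down) / len(dirs) >= cfg.min_direction_agreement:
            survivors.append(gene)
    return survivors, cols


class TestFilters:
    def test_small_group_column_removed(self):
        t = table_from_cells(
            {"A": {(1, "d"): 1.0, (2, "d"): 1.0}},
            {(1, "d"): 4, (2, "d"): 5},
        )
        out = apply_filters(t, FilterConfig(min_group_n=5, min_studies_per_gene=1,
                                            min_direction_agreement=0.5))
        assert [c.label for c in out.columns] == ["S2:d"]

    def test_gene_in_too_few_studies_removed(self):
        cells = {"A": {(s, "d"): 1.0 for s in range(1, 5)},   # 4 studies
                 "B": {(s, "d"): 1.0 for s in range(1, 6)}}   # 5 studies
        t = table_from_cells(cells, {(s, "d"): 8 for s in range(1, 6)})
        out = apply_filters(t, FilterConfig())
        assert out.genes == ["B"]

    @pytest.mark.parametrize("n_up, kept", [(6, True), (5, False)])
    def test_direction_agreement_boundary(self, n_up, kept):
        """6/8 studies agreeing (75%) is retained; 5/8 (62.5%) is removed."""
        signs = [1.0] * n_up + [-1.0] * (8 - n_up)
        cells = {"A": {(s + 1, "d"): signs[s] for s in range(8)}}
        t = table_from_cells(cells, {(s + 1, "d"): 8 for s in range(8)})
        out = apply_filters(t, FilterConfig(min_group_n=5, min_studies_per_gene=5,
                                            min_direction_agreement=0.75))
        assert (out.genes == ["A"]) is kept

    def test_within_study_tie_counts_for_neither_side(self):
        # study 1 has one up and one down column -> direction 0
        cells = {"A": {(1, "d1"): 1.0, (1, "d2"): -1.0,
                       (2, "d"): 1.0, (3, "d"): 1.0}}
        t = table_from_cells(cells, {(1, "d1"): 8, (1, "d2"): 8, (2, "d"): 8, (3, "d"): 8})
        out = apply_filters(t, FilterConfig(min_group_n=5, min_studies_per_gene=3,
                                            min_direction_agreement=0.75))
        # 2 of 3 contributing studies agree up = 66.7% < 75%
        assert out.genes == []

    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        n_studies = data.draw(st.integers(2, 6))
        genes = [f"G{i}" for i in range(data.draw(st.integers(1, 6)))]
        cells = {
            g: {
                (s, "d"): data.draw(
                    st.one_of(st.none(), st.sampled_from([-1.0, 0.0, 1.0, np.nan]))
                )
                for s in range(1, n_studies + 1)
            }
            for g in genes
        }
        cells = {g: {k: v for k, v in row.items() if v is not None}
                 for g, row in cells.items()}
        n_groups = {(s, "d"): data.draw(st.integers(3, 8)) for s in range(1, n_studies + 1)}
        cfg = FilterConfig(
            min_group_n=data.draw(st.integers(3, 6)),
            min_studies_per_gene=data.draw(st.integers(1, 4)),
            min_direction_agreement=data.draw(st.sampled_from([0.5, 0.75, 1.0])),
        )
        t = table_from_cells(cells, n_groups)
        out = apply_filters(t, cfg)
        expected_genes, expected_cols = brute_filter(cells, n_groups, cfg)
        assert out.genes == [g for g in cells if g in expected_genes]
        assert [(c.study_number, c.group) for c in out.columns] == expected_cols

    def test_idempotent(self):
        cells = {"A": {(s, "d"): 1.0 for s in range(1, 7)},
                 "B": {(s, "d"): (-1.0) ** s for s in range(1, 7)}}
        t = table_from_cells(cells, {(s, "d"): 4 + s for s in range(1, 7)})
        cfg = FilterConfig()
        once = apply_filters(t, cfg)
        twice = apply_filters(once, cfg)
        assert twice.genes == once.genes
        assert [c.label for c in twice.columns] == [c.label for c in once.columns]

    @pytest.mark.parametrize("field, looser, tighter", [
        ("min_group_n", 4, 6),
        ("min_studies_per_gene", 2, 4),
        ("min_direction_agreement", 0.5, 0.9),
    ])
    def test_monotone_in_each_threshold(self, field, looser, tighter, rng):
        cells = {
            f"G{i}": {
                (s, "d"): float(rng.choice([-1.0, 1.0, np.nan]))
                for s in range(1, 7)
            }
            for i in range(12)
        }
        t = table_from_cells(cells, {(s, "d"): int(rng.integers(3, 9)) for s in range(1, 7)})
        base = dict(min_group_n=3, min_studies_per_gene=2, min_direction_agreement=0.5)
        loose = apply_filters(t, FilterConfig(**{**base, field: looser}))
        tight = apply_filters(t, FilterConfig(**{**base, field: tighter}))
        assert len(tight.genes) <= len(loose.genes)
        assert len(tight.columns) <= len(loose.columns)

    def test_missing_n_metadata_is_error(self):
        t = table_from_cells({"A": {(1, "d"): 1.0}}, {(1, "d"): 8})
        t.columns[0] = ColumnMeta(1, "d", n_group=None)
        with pytest.raises(ValidationError):
            apply_filters(t, FilterConfig())


class TestMergedFile:
    def _table(self):
        cells = {"A": {(1, "d"): 0.5, (2, "d"): -0.5},
                 "B": {(1, "d"): 1.25, (2, "d"): np.nan},
                 "C": {(1, "d"): -2.0, (2, "d"): 0.75}}
        return table_from_cells(cells, {(1, "d"): 6, (2, "d"): 8})

    def test_round_trip(self, tmp_path):
        t = self._table()
        p = write_merged(t, tmp_path / "Merged.txt")
        back = load_merged(p)
        assert back.genes == t.genes
        assert [c.label for c in back.columns] == [c.label for c in t.columns]
        assert back.column("S1:d").n_group == 6
        pd.testing.assert_frame_equal(back.values, t.values)

    def test_hand_edited_rows_deleted_and_sorted(self, tmp_path):
        p = write_merged(self._table(), tmp_path / "Merged.txt")
        lines = p.read_text().splitlines()
        header, meta, body, footer = lines[0], lines[1:5], lines[5:-1], lines[-1]
        body = [ln for ln in body if not ln.startswith("B\t")]
        body.sort()  # user sorts the remaining genes
        p.write_text("\n".join([header, *meta, *body, footer]) + "\n")
        back = load_merged(p)
        assert back.genes == ["A", "C"]

    def test_column_deleted_by_hand(self, tmp_path):
        p = write_merged(self._table(), tmp_path / "Merged.txt")
        rows = [ln.split("\t") for ln in p.read_text().splitlines()]
        rows = [r[:1] + r[2:] for r in rows]  # drop the S1:d column everywhere
        p.write_text("\n".join("\t".join(r) for r in rows) + "\n")
        back = load_merged(p)
        assert [c.label for c in back.columns] == ["S2:d"]

    def test_missing_footer_is_error(self, tmp_path):
        p = write_merged(self._table(), tmp_path / "Merged.txt")
        lines = p.read_text().splitlines()
        p.write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(ValidationError, match="Labels"):
            load_merged(p)

    def test_altered_first_column_is_error(self, tmp_path):
        p = write_merged(self._table(), tmp_path / "Merged.txt")
        p.write_text(p.read_text().replace("Gene\t", "Id\t", 1))
        with pytest.raises(ValidationError, match="Gene"):
            load_merged(p)
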