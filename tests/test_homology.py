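"""Ohnolog/singleton filter chains and synteny scoring."""

import logging

import numpy as np
import pandas as pd
import pytest

from ohnorhythm.errors import GeneLookupError, SchemaError
from ohnorhythm.homology import (
    GenomeOrder,
    OHNOLOG_FILTERS,
    SyntenyWindow,
    assign_best_ortholog,
    identify_ohnolog_pairs,
    identify_singletons,
    ohnolog_filter_report,
    ortholog_map_from_table,
    singleton_filter_report,
    synteny_score,
)
from ohnorhythm.simulate import DECOY_CLASSES, HOMOLOGY_COLUMNS

OHNOLOG_DECOYS = set(OHNOLOG_FILTERS)
SINGLETON_DECOYS = {
    "neopterygii_ancestor",
    "one_of_many_name",
    "non_one2one_ortholog",
}


def _row(gene, paralog=None, subtype=None, gar=None, gar_type=None,
         chrom="chr1", start=1, name="genex"):
    return {
        "ensembl_gene_id": gene,
        "paralog_gene_id": paralog,
        "paralog_subtype": subtype,
        "paralog_orthology_type": "within_species_paralog" if paralog else None,
        "gar_ortholog_id": gar,
        "gar_orthology_type": gar_type,
        "chromosome_name": chrom,
        "start_position": start,
        "end_position": start + 1000,
        "external_gene_name": name,
    }


def _pair_rows(a, b, gar, subtype="Osteoglossocephalai", chrom_a="chr1",
               start_a=1, chrom_b="chr2", start_b=1):
    return [
        _row(a, paralog=b, subtype=subtype, gar=gar, gar_type="ortholog_one2many",
             chrom=chrom_a, start=start_a),
        _row(b, paralog=a, subtype=subtype, gar=gar, gar_type="ortholog_one2many",
             chrom=chrom_b, start=start_b),
    ]


def _table(rows):
    return pd.DataFrame(rows, columns=list(HOMOLOGY_COLUMNS))


class TestOhnologChain:
    def test_clupeocephala_pair_excluded(self):
        rows = _pair_rows("A", "B", "gar1", subtype="Clupeocephala")
        assert identify_ohnolog_pairs(_table(rows)) == []

    def test_distance_rule_boundary(self):
        close = _table(_pair_rows("A", "B", "gar1", chrom_a="chr1", start_a=1,
                                  chrom_b="chr1", start_b=3_000_001))
        far = _table(_pair_rows("A", "B", "gar1", chrom_a="chr1", start_a=1,
                                chrom_b="chr1", start_b=6_000_001))
        assert identify_ohnolog_pairs(close) == []
        pairs = identify_ohnolog_pairs(far)
        assert len(pairs) == 1 and {pairs[0].gene_a, pairs[0].gene_b} == {"A", "B"}

    def test_gene_in_two_pairs_removed(self):
        rows = []
        rows += _pair_rows("X", "Y", "gar1", chrom_b="chr2")
        rows += _pair_rows("X", "Z", "gar1", chrom_b="chr3")
        assert identify_ohnolog_pairs(_table(rows)) == []

    def test_missing_column_named_in_error(self):
        table = _table(_pair_rows("A", "B", "gar1")).drop(columns=["paralog_subtype"])
        with pytest.raises(SchemaError, match="paralog_subtype"):
            identify_ohnolog_pairs(table)

    def test_planted_pairs_recovered_exactly(self, homology_sim):
        _, table, truth = homology_sim
        pairs = identify_ohnolog_pairs(table)
        got = {g for p in pairs for g in (p.gene_a, p.gene_b)}
        expected = set(truth.loc[truth["label"] == "ohnolog", "gene_id"])
        assert got == expected
        # perfect matching: every gene appears in exactly one pair
        assert len(got) == 2 * len(pairs)

    def test_filter_order_does_not_change_result(self, homology_sim):
        _, table, _ = homology_sim
        forward = identify_ohnolog_pairs(table)
        reversed_ = identify_ohnolog_pairs(
            table, filter_order=tuple(reversed(OHNOLOG_FILTERS))
        )
        assert forward == reversed_


class TestSingletonChain:
    def test_post_tgd_lineage_ancestor_excluded(self):
        rows = [
            _row("A", paralog="B", subtype="Xiphophorus", gar="gar1",
                 gar_type="ortholog_one2one"),
        ]
        assert identify_singletons(_table(rows)) == []

    def test_one_of_many_name_excluded_case_insensitive(self):
        rows = [_row("A", gar="gar1", gar_type="ortholog_one2one",
                     name="sox4 (1 OF Many)")]
        assert identify_singletons(_table(rows)) == []

    def test_clean_one2one_gene_included(self):
        rows = [_row("A", paralog="B", subtype="Vertebrata", gar="gar1",
                     gar_type="ortholog_one2one", name="per2")]
        assert identify_singletons(_table(rows)) == ["A"]

    def test_planted_singletons_recovered_exactly(self, homology_sim):
        _, table, truth = homology_sim
        singles = identify_singletons(table)
        expected = set(truth.loc[truth["label"] == "singleton", "gene_id"])
        assert set(singles) == expected

    def test_ohnolog_and_singleton_sets_disjoint(self, homology_sim):
        _, table, _ = homology_sim
        pair_genes = {
            g
            for p in identify_ohnolog_pairs(table)
            for g in (p.gene_a, p.gene_b)
        }
        assert pair_genes.isdisjoint(identify_singletons(table))


class TestDecoys:
    def test_every_decoy_fails_exactly_its_named_filter(self, homology_sim):
        _, table, truth = homology_sim
        labels = truth.set_index("gene_id")["label"]
        pair_report = ohnolog_filter_report(table)
        seen = set()
        for rec in pair_report.itertuples(index=False):
            label = labels[rec.gene_a]
            if label in OHNOLOG_DECOYS:
                assert rec.failed_filters == (label,), (rec.gene_a, rec.failed_filters)
                seen.add(label)
            elif label == "ohnolog":
                assert rec.passes
        single_report = singleton_filter_report(table).set_index("gene_id")
        for gene, label in labels.items():
            if label in SINGLETON_DECOYS:
                assert single_report.loc[gene, "failed_filters"] == (label,)
                seen.add(label)
            elif label == "singleton":
                assert single_report.loc[gene, "passes"]
        assert seen == set(DECOY_CLASSES)

    def test_no_decoy_gene_survives_either_chain(self, homology_sim):
        _, table, truth = homology_sim
        decoy_genes = set(
            truth.loc[truth["label"].isin(DECOY_CLASSES), "gene_id"]
        )
        pair_genes = {
            g for p in identify_ohnolog_pairs(table) for g in (p.gene_a, p.gene_b)
        }
        singles = set(identify_singletons(table))
        assert decoy_genes.isdisjoint(pair_genes | singles)


class TestSynteny:
    @staticmethod
    def _orders(n_focal=11, n_gar=11):
        focal = pd.DataFrame(
            {
                "gene_id": [f"F{i}" for i in range(n_focal)],
                "chromosome": "chr1",
                "start": np.arange(n_focal) * 100 + 1,
            }
        )
        gar = pd.DataFrame(
            {
                "gene_id": [f"R{i}" for i in range(n_gar)],
                "chromosome": "LG1",
                "start": np.arange(n_gar) * 100 + 1,
            }
        )
        return GenomeOrder(focal), GenomeOrder(gar)

    def test_full_and_empty_and_half_windows(self):
        focal_order, gar_order = self._orders()
        window = focal_order.window("F5", "R5", gar_order, n=5)
        assert len(window.neighbors) == 10 and len(window.gar_neighbors) == 10
        all_match = {f"F{i}": {f"R{i}"} for i in range(11)}
        assert synteny_score(window, all_match) == (1.0, False)
        assert synteny_score(window, {}) == (0.0, False)
        half = {f"F{i}": {f"R{i}"} for i in range(10) if i % 2 == 0}
        # neighbors F0..F4, F6..F10: hits at F0, F2, F4, F6, F8 -> 5 of 10
        score, _ = synteny_score(window, half)
        brute = sum(
            1
            for g in window.neighbors
            if half.get(g, set()) & set(window.gar_neighbors)
        ) / len(window.neighbors)
        assert score == pytest.approx(brute) == 0.5

    def test_truncated_window_uses_actual_neighbor_count(self):
        focal_order, gar_order = self._orders()
        window = focal_order.window("F0", "R0", gar_order, n=5)
        assert len(window.neighbors) == 5  # chromosome start truncates
        all_match = {f"F{i}": {f"R{i}"} for i in range(11)}
        assert synteny_score(window, all_match) == (1.0, False)

    def test_empty_window_flagged(self):
        window = SyntenyWindow("F0", (), "R0", (), 3)
        assert synteny_score(window, {}) == (0.0, True)

    def test_best_ortholog_argmax_and_tie_break(self, caplog):
        focal_order, gar_order = self._orders()
        orthology = {f"F{i}": {f"R{i}"} for i in range(11)}
        best, score = assign_best_ortholog(
            "F5", ["R5", "R9"], focal_order, gar_order, orthology, n=2
        )
        assert best == "R5" and score == 1.0
        # symmetric layout: R4 and R6 windows both contain the same hits
        with caplog.at_level(logging.WARNING):
            tied, _ = assign_best_ortholog(
                "F5", ["R6", "R4"], focal_order, gar_order, orthology, n=2
            )
        assert tied == "R4"
        assert any("tie" in rec.message for rec in caplog.records)

    def test_no_candidates_raises(self):
        focal_order, gar_order = self._orders()
        with pytest.raises(GeneLookupError):
            assign_best_ortholog("F5", [], focal_order, gar_order, {})


def test_ortholog_map_round_trip(homology_sim):
    _, table, truth = homology_sim
    mapping = ortholog_map_from_table(table)
    ohnolog_genes = truth.loc[truth["label"] == "ohnolog", "gene_id"]
    assert all(len(mapping[g]) == 1 for g in ohnolog_genes)
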