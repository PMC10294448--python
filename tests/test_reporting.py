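import numpy as np
import pandas as pd
import pytest

from mtxannot.errors import InvariantError
from mtxannot.gene_annotation import GeneToReadMap
from mtxannot.readflow import ReadLedger, ReadRecord, write_fastq
from mtxannot.reporting import (
    build_expression_table,
    cytoscape_table,
    n50_l50,
    quality_histogram,
    read_summary,
    rollup_taxa,
    rpkm,
    superpathway_matrix,
)


class TestRpkm:
    def test_direct_arithmetic(self):
        assert rpkm(10, 500, 1_000_000) == 20.0

    def test_zero_reads(self):
        assert rpkm(0, 500, 1_000_000) == 0.0

    def test_doubling_total_halves_rpkm(self):
        assert rpkm(10, 500, 2_000_000) == rpkm(10, 500, 1_000_000) / 2

    @pytest.mark.parametrize("kwargs", [
        dict(read_count=1, gene_length_bp=0, total_mapped_reads=1),
        dict(read_count=1, gene_length_bp=1, total_mapped_reads=0),
        dict(read_count=-1, gene_length_bp=1, total_mapped_reads=1),
    ])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            rpkm(**kwargs)


class TestRollup:
    def test_dominant_species_emitted_at_species(self, small_tree):
        groups, assignment = rollup_taxa({14: 60, 15: 40}, small_tree, 0.01)
        assert {g.label for g in groups} == {"G2 sp1", "G2 sp2"}
        assert all(g.rank == "species" for g in groups)
        assert assignment == {14: "G2 sp1", 15: "G2 sp2"}

    def test_subcutoff_congeners_merge_to_genus(self, small_tree):
        # two species of genus 9 at 0.6% and 0.4% merge to a 1.0% genus group
        counts = {14: 6, 15: 4, 18: 990}
        groups, assignment = rollup_taxa(counts, small_tree, 0.01)
        by_label = {g.label: g for g in groups}
        assert by_label["G2"].rank == "genus"
        assert by_label["G2"].read_count == 10
        assert by_label["G2"].read_fraction == pytest.approx(0.01)
        assert assignment[14] == assignment[15] == "G2"

    def test_isolated_subcutoff_species_goes_to_other(self, small_tree):
        counts = {14: 2, 18: 998}
        groups, _ = rollup_taxa(counts, small_tree, 0.01)
        labels = {g.label: g for g in groups}
        assert "Other" in labels
        assert labels["Other"].read_count == 2

    def test_conserves_reads(self, small_tree, rng):
        species = [12, 13, 14, 15, 16, 17, 18, 19, 9, 20, 0]
        for _ in range(50):
            counts = {
                t: int(rng.integers(0, 500))
                for t in species
                if rng.integers(2)
            }
            counts = {t: c for t, c in counts.items() if c}
            if not counts:
                continue
            groups, assignment = rollup_taxa(counts, small_tree, 0.05)
            assert sum(g.read_count for g in groups) == sum(counts.values())
            assert set(assignment) == set(counts)
            for g in groups:
                if g.label != "Other":
                    assert g.read_fraction >= 0.05

    def test_unclassified_goes_to_other(self, small_tree):
        groups, assignment = rollup_taxa({0: 5, 18: 95}, small_tree, 0.01)
        assert assignment[0] == "Other"


def _expression(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "length_bp", "read_count", "rpkm", "taxid",
                       "ec_list"]
    )


class TestCytoscapeTable:
    def test_single_group_column_equals_total(self):
        expr = _expression([("g1", 500, 10, 100.0, 14, "1.1.1.1")])
        table = cytoscape_table(expr, {14: "G2 sp1"}, ["G2 sp1"])
        assert table.loc[0, "G2 sp1"] == table.loc[0, "total_rpkm"] == 100.0

    def test_two_groups_split_30_70(self):
        expr = _expression([
            ("g1", 500, 3, 30.0, 14, "1.1.1.1"),
            ("g2", 500, 7, 70.0, 18, "1.1.1.1"),
        ])
        table = cytoscape_table(expr, {14: "A", 18: "B"}, ["A", "B"])
        row = table.iloc[0]
        assert (row["A"], row["B"], row["total_rpkm"]) == (30.0, 70.0, 100.0)

    def test_group_columns_sum_to_total(self, rng):
        rows = []
        for i in range(60):
            rows.append(
                (f"g{i}", 500, 5, float(rng.uniform(0, 50)),
                 int(rng.choice([14, 15, 18])), "1.1.1.1,2.2.2.2")
            )
        expr = _expression(rows)
        table = cytoscape_table(expr, {14: "A", 15: "A", 18: "B"}, ["A", "B"])
        for _, row in table.iterrows():
            assert row["A"] + row["B"] + row.get("Other", 0.0) == pytest.approx(
                row["total_rpkm"], abs=1e-6
            )

    def test_zero_rpkm_ec_omitted(self):
        expr = _expression([("g1", 500, 0, 0.0, 14, "1.1.1.1")])
        table = cytoscape_table(expr, {14: "A"}, ["A"])
        assert len(table) == 0


class TestSuperpathwayMatrix:
    def test_single_cell(self):
        df = pd.DataFrame({"ec": ["1.1.1.1"], "taxon": ["A"], "rpkm": [42.0]})
        m = superpathway_matrix(df, {"1.1.1.1": ["SP1"]}, {"A": 10}, top_n=20)
        assert m.shape == (1, 1)
        assert m.loc["SP1", "A"] == 42.0

    def test_25_taxa_collapse_to_21_columns(self):
        taxa = [f"T{i}" for i in range(25)]
        df = pd.DataFrame(
            {"ec": ["1.1.1.1"] * 25, "taxon": taxa, "rpkm": [1.0] * 25}
        )
        counts = {t: 100 - i for i, t in enumerate(taxa)}
        m = superpathway_matrix(df, {"1.1.1.1": ["SP1"]}, counts, top_n=20)
        assert len(m.columns) == 21
        assert "Other" in m.columns
        assert m.loc["SP1", "Other"] == 5.0

    def test_ec_in_two_superpathways_counted_in_both(self):
        df = pd.DataFrame({"ec": ["1.1.1.1"], "taxon": ["A"], "rpkm": [10.0]})
        m = superpathway_matrix(df, {"1.1.1.1": ["SP1", "SP2"]}, {"A": 5})
        assert m.loc["SP1", "A"] == m.loc["SP2", "A"] == 10.0

    def test_unmapped_ec_row(self):
        df = pd.DataFrame({"ec": ["9.9.9.9"], "taxon": ["A"], "rpkm": [3.0]})
        m = superpathway_matrix(df, {}, {"A": 5})
        assert m.loc["Unmapped", "A"] == 3.0


class TestReadSummary:
    def _ledger(self, planted):
        ledger = ReadLedger()
        i = 0
        for category, n in planted.items():
            for _ in range(n):
                ledger.add_raw(f"r{i}", "single")
                ledger.record(f"r{i}", "single", category)
                i += 1
        return ledger

    def test_planted_counts_recovered(self):
        planted = {
            "low_quality": 5, "host": 10, "vector": 3, "rRNA_tRNA": 30,
            "annotated": 40, "unidentified": 12,
        }
        gm = GeneToReadMap()
        for j in range(7):
            gm.assign(f"g{j % 3}", f"x{j}", "tier1_nt")
        s = read_summary(self._ledger(planted), gm, unique_ecs_low=9,
                         unique_ecs_high=4)
        assert s.total_reads == 100
        assert s.high_quality_reads == 95
        assert s.host_reads == 10 and s.pct_host == pytest.approx(10.0)
        assert s.rrna_reads == 30 and s.pct_rrna == pytest.approx(30.0)
        assert s.putative_mrna_reads == 52
        assert s.annotated_reads == 40
        # annotated percentage is relative to putative mRNA, not total
        assert s.pct_annotated == pytest.approx(100 * 40 / 52)
        assert s.unique_genes == 3
        assert (s.unique_ecs_low, s.unique_ecs_high) == (9, 4)
        s.validate()

    def test_empty_input_all_zero(self):
        s = read_summary(ReadLedger(), GeneToReadMap(), 0, 0)
        assert s.total_reads == 0 and s.pct_annotated == 0.0

    def test_incomplete_ledger_rejected(self):
        ledger = ReadLedger()
        ledger.add_raw("r1", "fwd")
        with pytest.raises(InvariantError):
            read_summary(ledger, GeneToReadMap(), 0, 0)


class TestN50L50:
    def test_definition_replay(self):
        assert n50_l50([100, 200, 300]) == (300, 1)

    def test_single_contig(self):
        assert n50_l50([777]) == (777, 1)

    def test_all_equal(self):
        assert n50_l50([50] * 8) == (50, 4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            n50_l50([])

    def test_random_lists_match_cumulative_oracle(self, rng):
        for _ in range(100):
            lengths = [int(x) for x in rng.integers(1, 1000, size=rng.integers(1, 30))]
            n50, l50 = n50_l50(lengths)
            ordered = sorted(lengths, reverse=True)
            cum = np.cumsum(ordered)
            idx = int(np.argmax(cum >= cum[-1] / 2))
            assert (n50, l50) == (ordered[idx], idx + 1)


class TestQualityHistogram:
    def test_uniform_quality_single_bin(self, tmp_path):
        reads = [ReadRecord(f"r{i}", "single", "ACGT", "IIII") for i in range(5)]
        write_fastq(reads, tmp_path / "u.fastq")
        before, after = quality_histogram(tmp_path / "u.fastq", tmp_path / "u.fastq")
        assert before.sum() == 5
        assert before[ord("I") - 33] == 5
        assert (before == after).all()

    def test_empty_file_all_zero(self, tmp_path):
        (tmp_path / "e.fastq").write_text("")
        before, _ = quality_histogram(tmp_path / "e.fastq", tmp_path / "e.fastq")
        assert before.sum() == 0

    def test_bin_totals_equal_read_count(self, tmp_path, rng):
        reads = []
        for i in range(80):
            quals = rng.integers(2, 41, size=10)
            reads.append(
                ReadRecord(
                    f"r{i}", "single", "A" * 10,
                    "".join(chr(int(q) + 33) for q in quals),
                )
            )
        write_fastq(reads, tmp_path / "r.fastq")
        before, _ = quality_histogram(tmp_path / "r.fastq", tmp_path / "r.fastq")
        assert before.sum() == 80


class TestExpressionTable:
    def test_rpkm_column_consistent(self):
        gm = GeneToReadMap()
        for i in range(10):
            gm.assign("g1", f"a{i}", "tier1_nt")
        for i in range(30):
            gm.assign("g2", f"b{i}", "tier2_nt")
        table = build_expression_table(
            gm, {"g1": 1000, "g2": 500}, {"g1": 14, "g2": 18},
            {"g1": ["1.1.1.1"]}, total_mapped_reads=40,
        )
        row = table.set_index("gene_id")
        assert row.loc["g1", "rpkm"] == pytest.approx(10 * 1e9 / (1000 * 40))
        assert row.loc["g2", "rpkm"] == pytest.approx(30 * 1e9 / (500 * 40))
        assert row.loc["g1", "ec_list"] == "1.1.1.1"
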