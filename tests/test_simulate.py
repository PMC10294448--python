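import filecmp

import numpy as np
import pytest

from mtxannot.consensus import ClassifierVote, weighted_consensus
from mtxannot.enzyme_annotation import (
    ECCooccurrenceDB,
    StringencyPolicy,
    load_diamond_ec,
    load_prediction_tsv,
    merge_predictions,
)
from mtxannot.gene_annotation import cascade_annotate
from mtxannot.simulate import (
    assign_gene_ecs,
    build_community,
    make_alignment_reports,
    make_classifier_votes,
    make_ec_fixture,
    make_reads,
    make_taxonomy,
    simulate_sample,
)
from mtxannot.taxonomy import write_taxonomy


@pytest.fixture(scope="module")
def community():
    tree = make_taxonomy(2, 2, seed=3)
    spec = build_community(tree, n_species=4, genes_per_species=6, seed=3)
    spec.n_pairs = 600
    return tree, spec


class TestMakeTaxonomy:
    def test_single_lineage_depth_seven(self):
        tree = make_taxonomy(1, 1)
        deepest = max(tree.nodes, key=tree.depth)
        assert tree.depth(deepest) == 7
        assert tree.rank(deepest) == "species"

    def test_binary_tree_species_count(self):
        tree = make_taxonomy(2, 2)
        assert sum(1 for t in tree.nodes if tree.rank(t) == "species") == 2 ** 6

    def test_deterministic_files(self, tmp_path):
        for i in (1, 2):
            write_taxonomy(
                make_taxonomy(2, 2, seed=9),
                tmp_path / f"n{i}.dmp", tmp_path / f"na{i}.dmp",
            )
        assert filecmp.cmp(tmp_path / "n1.dmp", tmp_path / "n2.dmp", shallow=False)
        assert filecmp.cmp(tmp_path / "na1.dmp", tmp_path / "na2.dmp", shallow=False)


class TestMakeReads:
    def test_zero_host_fraction_means_no_host_reads(self, tmp_path):
        tree = make_taxonomy(2, 2, seed=1)
        spec = build_community(
            tree, n_species=3, genes_per_species=4, seed=1,
            host_fraction=0.0, vector_fraction=0.0,
        )
        spec.n_pairs = 300
        reads = make_reads(spec, tmp_path)
        assert (reads.truth["category"] == "host").sum() == 0
        assert (reads.truth["category"] == "vector").sum() == 0

    def test_category_fractions_within_binomial_bounds(self, tmp_path):
        tree = make_taxonomy(2, 2, seed=2)
        spec = build_community(
            tree, n_species=3, genes_per_species=4, seed=2, rrna_fraction=0.5,
        )
        spec.n_pairs = 10_000
        reads = make_reads(spec, tmp_path)
        n_rrna = (reads.truth["category"] == "rRNA_tRNA").sum()
        sigma = np.sqrt(10_000 * 0.5 * 0.5)
        assert abs(n_rrna - 5000) <= 4 * sigma  # i.e. within [4800, 5200]

    def test_same_seed_identical_fastq_bytes(self, tmp_path, community):
        _, spec = community
        out1 = make_reads(spec, tmp_path / "a")
        out2 = make_reads(spec, tmp_path / "b")
        assert filecmp.cmp(out1.fastq_fwd, out2.fastq_fwd, shallow=False)
        assert filecmp.cmp(out1.fastq_rev, out2.fastq_rev, shallow=False)

    def test_low_quality_reads_fail_mean_phred(self, tmp_path, community):
        from mtxannot.readflow import read_fastq

        _, spec = community
        reads = make_reads(spec, tmp_path)
        lq_ids = set(reads.truth.loc[reads.truth.category == "low_quality",
                                     "read_id"])
        for rec in read_fastq(reads.fastq_fwd):
            if rec.read_id in lq_ids:
                assert rec.mean_phred() < 20
            else:
                assert rec.mean_phred() >= 20


class TestAlignmentReports:
    def test_zero_rates_recover_all_true_genes(self, tmp_path, community):
        _, spec = community
        reads = make_reads(spec, tmp_path)
        sam, m8a, m8b = make_alignment_reports(reads.truth, spec, tmp_path, seed=5)
        mrna = reads.truth[reads.truth.category == "mRNA"]
        lengths = {rid: spec.read_length for rid in mrna.read_id}
        gene_map, unannotated = cascade_annotate(lengths, sam, m8a, m8b)
        assert not unannotated
        for row in mrna.itertuples(index=False):
            assert gene_map.gene_of(row.read_id) == row.gene_id

    def test_miss_rate_one_annotates_nothing(self, tmp_path, community):
        _, spec = community
        reads = make_reads(spec, tmp_path)
        sam, m8a, m8b = make_alignment_reports(
            reads.truth, spec, tmp_path, miss_rate=0.999999, seed=5
        )
        mrna = reads.truth[reads.truth.category == "mRNA"]
        lengths = {rid: spec.read_length for rid in mrna.read_id}
        gene_map, unannotated = cascade_annotate(lengths, sam, m8a, m8b)
        # every injected hit is below threshold, so nothing may be assigned
        assert len(gene_map) == 0
        assert unannotated == set(lengths)

    def test_spurious_hits_never_displace_truth(self, tmp_path, community):
        _, spec = community
        reads = make_reads(spec, tmp_path)
        sam, m8a, m8b = make_alignment_reports(
            reads.truth, spec, tmp_path, spurious_rate=0.5, seed=5
        )
        mrna = reads.truth[reads.truth.category == "mRNA"]
        lengths = {rid: spec.read_length for rid in mrna.read_id}
        gene_map, _ = cascade_annotate(lengths, sam, m8a, m8b)
        for row in mrna.itertuples(index=False):
            assert gene_map.gene_of(row.read_id) == row.gene_id


class TestClassifierVotes:
    def test_perfect_accuracy_recovers_truth(self, tmp_path, community):
        tree, spec = community
        reads = make_reads(spec, tmp_path)
        paths = make_classifier_votes(
            reads.truth, tree,
            {"gene_lookup": 1.0, "kaiju": 1.0, "centrifuge": 1.0},
            tmp_path, seed=6,
        )
        truth_taxid = reads.truth.set_index("read_id")["taxid"]
        for source, path in paths.items():
            for line in path.read_text().splitlines():
                flag, rid, taxid = line.split("\t")
                assert int(taxid) == truth_taxid[rid]

    def test_zero_accuracy_yields_congeneric_siblings(self, tmp_path, community):
        tree, spec = community
        reads = make_reads(spec, tmp_path)
        paths = make_classifier_votes(
            reads.truth, tree, {"kaiju": 0.0}, tmp_path, seed=6,
        )
        truth_taxid = reads.truth.set_index("read_id")["taxid"]
        for line in paths["kaiju"].read_text().splitlines():
            _, rid, taxid = line.split("\t")
            true = truth_taxid[rid]
            assert int(taxid) != true
            assert tree.ancestor_at_rank(int(taxid), "genus") == (
                tree.ancestor_at_rank(true, "genus")
            )

    def test_gene_lookup_majority_survives_sibling_noise(
        self, tmp_path, community
    ):
        # gene_lookup correct, both classifiers always wrong congeners:
        # the 0.6 weight still wins at species level
        tree, spec = community
        reads = make_reads(spec, tmp_path)
        paths = make_classifier_votes(
            reads.truth, tree,
            {"gene_lookup": 1.0, "kaiju": 0.0, "centrifuge": 0.0},
            tmp_path, seed=6,
        )
        votes = {}
        for source, path in paths.items():
            for line in path.read_text().splitlines():
                _, rid, taxid = line.split("\t")
                votes.setdefault(rid, []).append(
                    ClassifierVote(rid, source, int(taxid))
                )
        truth_taxid = reads.truth.set_index("read_id")["taxid"]
        for rid, vs in votes.items():
            assert weighted_consensus(vs, tree) == truth_taxid[rid]


class TestECFixture:
    def test_full_sensitivity_high_confidence_recovers_all(self, tmp_path,
                                                           community):
        _, spec = community
        gene_ecs, db = assign_gene_ecs(spec, seed=8)
        paths = make_ec_fixture(
            gene_ecs, db, tmp_path, seed=8,
            priam_prob_range=(0.9, 0.9),
            diamond_evalue_range=(1e-20, 1e-20),
        )
        detect = load_prediction_tsv(paths["detect"], "DETECT")
        priam = load_prediction_tsv(paths["priam"], "PRIAM")
        diamond = load_diamond_ec(paths["diamond_m8"], paths["protein_ec_map"])
        high = merge_predictions(detect, priam, diamond, StringencyPolicy.high())
        for gid, ecs in gene_ecs.items():
            assert set(ecs) <= set(high[gid])

    def test_no_diamond_leaves_only_detect(self, tmp_path, community):
        _, spec = community
        gene_ecs, db = assign_gene_ecs(spec, seed=8)
        paths = make_ec_fixture(
            gene_ecs, db, tmp_path, diamond_sens=0.0, detect_sens=0.5, seed=8
        )
        detect = load_prediction_tsv(paths["detect"], "DETECT")
        priam = load_prediction_tsv(paths["priam"], "PRIAM")
        diamond = load_diamond_ec(paths["diamond_m8"], paths["protein_ec_map"])
        merged = merge_predictions(detect, priam, diamond, StringencyPolicy.low())
        detect_calls = {(p.target_id, p.ec) for p in detect}
        merged_calls = {(t, ec) for t, ecs in merged.items() for ec in ecs}
        assert merged_calls == detect_calls

    def test_same_seed_identical_outputs(self, tmp_path, community):
        _, spec = community
        gene_ecs, db = assign_gene_ecs(spec, seed=8)
        p1 = make_ec_fixture(gene_ecs, db, tmp_path / "a", seed=8)
        p2 = make_ec_fixture(gene_ecs, db, tmp_path / "b", seed=8)
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False)


class TestSimulateSample:
    def test_truth_covers_all_reads_and_paths_exist(self, tmp_path):
        sample = simulate_sample(tmp_path, n_species=3, n_pairs=200, seed=11,
                                 genes_per_species=4)
        assert len(sample.truth) == 200
        for path in sample.paths.values():
            assert path.exists(), path
        # community abundances sum to 1 and species have distinct genera
        tree = sample.tree
        genera = {
            tree.ancestor_at_rank(sp.taxid, "genus") for sp in sample.spec.species
        }
        assert len(genera) == 3
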