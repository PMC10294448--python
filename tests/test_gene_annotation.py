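import re

import pytest

from mtxannot.errors import CigarError, InvariantError
from mtxannot.gene_annotation import (
    ContigGeneIndex,
    GeneToReadMap,
    HitThresholds,
    SamAlignment,
    TabularHit,
    accept_sam_hit,
    accept_tabular_hit,
    best_assignment,
    cascade_annotate,
    cigar_coverage,
    map_reads_to_contig_genes,
    resolve_pair,
)

THRESH = HitThresholds()


def _sam(read_id, gene, cigar, score, mate="fwd", mapped=True):
    return SamAlignment(read_id, mate, gene if mapped else "", cigar, score, mapped)


def _write_sam(path, genes, records):
    """genes: {gene_id: length}; records: (rid, flag, gene, pos, cigar, AS)."""
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for gene, length in genes.items():
        lines.append(f"@SQ\tSN:{gene}\tLN:{length}")
    for rid, flag, gene, pos, cigar, score in records:
        seq = "A" * sum(
            int(n) for n, op in re.findall(r"(\d+)([MIS=X])", cigar) if op in "MIS=X"
        )
        lines.append(
            f"{rid}\t{flag}\t{gene}\t{pos}\t60\t{cigar}\t*\t0\t0\t{seq}\t"
            f"{'I' * len(seq)}\tAS:i:{score}"
        )
    path.write_text("".join(line + "\n" for line in lines))


def _m8_line(rid, gene, ident, aln_len, evalue, bits):
    return f"{rid}\t{gene}\t{ident}\t{aln_len}\t0\t0\t1\t{aln_len}\t1\t{aln_len}\t{evalue}\t{bits}\n"


class TestCigarCoverage:
    def test_full_alignment(self):
        assert cigar_coverage("100M", 100) == 1.0

    def test_half_soft_clipped(self):
        assert cigar_coverage("50M50S", 100) == 0.5

    def test_random_cigars_match_token_oracle(self, rng):
        ops = "MIDNSHP=X"
        for _ in range(300):
            n_ops = int(rng.integers(1, 6))
            tokens = [
                (int(rng.integers(1, 60)), ops[int(rng.integers(len(ops)))])
                for _ in range(n_ops)
            ]
            cigar = "".join(f"{n}{op}" for n, op in tokens)
            read_len = int(rng.integers(50, 200))
            # independent tokenizer: regex-free character walk
            aligned, digits = 0, ""
            for ch in cigar:
                if ch.isdigit():
                    digits += ch
                else:
                    if ch in ("M", "=", "X"):
                        aligned += int(digits)
                    digits = ""
            assert cigar_coverage(cigar, read_len) == min(aligned / read_len, 1.0)

    @pytest.mark.parametrize("bad", ["", "*", "M100", "100", "10M5", "1.5M"])
    def test_malformed_cigar_rejected(self, bad):
        with pytest.raises(CigarError):
            cigar_coverage(bad, 100)

    def test_zero_read_length_rejected(self):
        with pytest.raises(ValueError):
            cigar_coverage("10M", 0)


class TestAcceptSamHit:
    def test_at_threshold_accepted(self):
        assert accept_sam_hit(_sam("r", "g", "90M10S", 100), 100, THRESH)

    def test_below_threshold_rejected(self):
        assert not accept_sam_hit(_sam("r", "g", "89M11S", 100), 100, THRESH)

    def test_unmapped_violates_precondition(self):
        with pytest.raises(ValueError):
            accept_sam_hit(_sam("r", "g", "100M", 0, mapped=False), 100, THRESH)


class TestAcceptTabularHit:
    def _hit(self, ident=98.0, aln=100, bits=200.0, evalue=1e-20):
        return TabularHit("r", "g", ident, aln, bits, evalue)

    def test_exactly_at_all_thresholds_accepted(self):
        hit = self._hit(ident=85.0, aln=65, bits=60.0)
        assert accept_tabular_hit(hit, 100, translated=False, thresholds=THRESH)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(ident=84.9), dict(aln=64), dict(bits=59.9)],
    )
    def test_single_failing_clause_rejects(self, kwargs):
        assert not accept_tabular_hit(
            self._hit(**kwargs), 100, translated=False, thresholds=THRESH
        )

    def test_translated_query_length_in_residues(self):
        # 100 nt -> 33 residues; 22/33 = 66.7% passes, 21/33 = 63.6% fails
        assert accept_tabular_hit(self._hit(aln=22), 100, True, THRESH)
        assert not accept_tabular_hit(self._hit(aln=21), 100, True, THRESH)

    def test_random_hits_match_three_clause_oracle(self, rng):
        for _ in range(500):
            ident = float(rng.uniform(60, 100))
            aln = int(rng.integers(10, 150))
            bits = float(rng.uniform(20, 120))
            qlen = int(rng.integers(60, 300))
            translated = bool(rng.integers(2))
            hit = self._hit(ident=ident, aln=aln, bits=bits)
            eff = qlen // 3 if translated else qlen
            oracle = (
                ident >= 85.0
                and 100.0 * aln / eff >= 65.0
                and bits >= 60.0
            )
            assert accept_tabular_hit(hit, qlen, translated, THRESH) == oracle

    def test_monotone_in_thresholds(self, rng):
        # raising any threshold never turns a rejection into an acceptance
        hits = [
            self._hit(
                ident=float(rng.uniform(60, 100)),
                aln=int(rng.integers(10, 150)),
                bits=float(rng.uniform(20, 120)),
            )
            for _ in range(200)
        ]
        loose = HitThresholds(identity_min=80, aln_len_fraction_min=50,
                              bitscore_min=40)
        tight = HitThresholds(identity_min=90, aln_len_fraction_min=70,
                              bitscore_min=80)
        n_loose = sum(accept_tabular_hit(h, 100, False, loose) for h in hits)
        n_tight = sum(accept_tabular_hit(h, 100, False, tight) for h in hits)
        assert n_tight <= n_loose


class TestBestAssignment:
    def test_tie_keeps_first_maximum(self):
        hits = [("g1", 10.0), ("g2", 20.0), ("g3", 20.0)]
        assert best_assignment(hits) == ("g2", 20.0)

    def test_single_hit(self):
        assert best_assignment([("g1", 5.0)]) == ("g1", 5.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            best_assignment([])

    def test_random_scores_match_argmax_earliest_oracle(self, rng):
        for _ in range(500):
            n = int(rng.integers(1, 10))
            scores = [float(s) for s in rng.integers(0, 6, size=n)]
            hits = [(f"g{i}", s) for i, s in enumerate(scores)]
            best = max(scores)
            oracle_idx = scores.index(best)
            assert best_assignment(hits) == (f"g{oracle_idx}", best)


class TestResolvePair:
    def test_agreeing_mates(self):
        assert resolve_pair(("G", 70.0), ("G", 50.0)) == ("G", 70.0)

    def test_higher_scoring_mate_decides(self):
        assert resolve_pair(("G1", 70.0), ("G2", 90.0)) == ("G2", 90.0)

    def test_tie_keeps_forward_gene(self):
        assert resolve_pair(("G1", 70.0), ("G2", 70.0)) == ("G1", 70.0)

    def test_single_annotated_mate(self):
        assert resolve_pair(("G1", 70.0), None) == ("G1", 70.0)
        assert resolve_pair(None, ("G2", 30.0)) == ("G2", 30.0)

    def test_neither_mate_rejected(self):
        with pytest.raises(ValueError):
            resolve_pair(None, None)


class TestGeneToReadMap:
    def test_double_assignment_rejected(self):
        gm = GeneToReadMap()
        gm.assign("g1", "r1", "tier1_nt")
        with pytest.raises(InvariantError):
            gm.assign("g2", "r1", "tier2_nt")

    def test_tsv_roundtrip(self, tmp_path):
        gm = GeneToReadMap()
        gm.assign("g1", "r1", "tier1_nt")
        gm.assign("g1", "r2", "tier1_nt")
        gm.assign("g2", "r3", "tier3_prot")
        gm.to_tsv(tmp_path / "map.tsv")
        back = GeneToReadMap.from_tsv(tmp_path / "map.tsv")
        assert back.read_counts() == {"g1": 2, "g2": 1}
        assert back.tier_of("r3") == "tier3_prot"


class TestCascade:
    def _files(self, tmp_path):
        genes = {"gA": 900, "gB": 900}
        _write_sam(
            tmp_path / "t1.sam",
            genes,
            [
                ("r1", 65, "gA", 1, "100M", 200),       # accepted tier 1
                ("r2", 65, "gA", 1, "40M60S", 200),     # coverage 0.4 -> reject
            ],
        )
        (tmp_path / "t2.m8").write_text(
            _m8_line("r1", "gB", 98.0, 100, 1e-30, 200.0)  # must be ignored
            + _m8_line("r2", "gB", 98.0, 100, 1e-30, 200.0)  # accepted tier 2
            + _m8_line("r3", "gB", 70.0, 100, 1e-30, 200.0)  # identity fail
        )
        (tmp_path / "t3.m8").write_text(
            _m8_line("r3", "gA", 95.0, 33, 1e-25, 120.0)  # accepted tier 3
            + _m8_line("r4", "gA", 95.0, 33, 1e-3, 30.0)  # bitscore fail
        )
        return tmp_path / "t1.sam", tmp_path / "t2.m8", tmp_path / "t3.m8"

    def test_earlier_tier_wins_and_cascade_conserves(self, tmp_path):
        t1, t2, t3 = self._files(tmp_path)
        lengths = {f"r{i}": 100 for i in range(1, 6)}
        gene_map, unannotated = cascade_annotate(lengths, t1, t2, t3)
        assert gene_map.gene_of("r1") == "gA"
        assert gene_map.tier_of("r1") == "tier1_nt"
        assert gene_map.gene_of("r2") == "gB"
        assert gene_map.tier_of("r2") == "tier2_nt"
        assert gene_map.gene_of("r3") == "gA"
        assert gene_map.tier_of("r3") == "tier3_prot"
        assert unannotated == {"r4", "r5"}
        assert len(gene_map) + len(unannotated) == len(lengths)

    def test_injectivity_across_tiers(self, tmp_path):
        t1, t2, t3 = self._files(tmp_path)
        gene_map, _ = cascade_annotate({f"r{i}": 100 for i in range(1, 6)},
                                       t1, t2, t3)
        all_reads = [r for g in gene_map.genes() for r in gene_map.reads_for(g)]
        assert len(all_reads) == len(set(all_reads))

    def test_pair_resolution_uses_higher_scoring_mate(self, tmp_path):
        genes = {"gA": 900, "gB": 900}
        _write_sam(
            tmp_path / "pair.sam",
            genes,
            [
                ("p1", 65, "gA", 1, "100M", 70),    # fwd -> gA score 70
                ("p1", 129, "gB", 1, "100M", 90),   # rev -> gB score 90
            ],
        )
        gene_map, _ = cascade_annotate({"p1": 100}, tmp_path / "pair.sam",
                                       None, None)
        assert gene_map.gene_of("p1") == "gB"


class TestContigGenes:
    def _index(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "contig1\tpred\tCDS\t1\t300\t.\t+\t0\tID=cg1\n"
            "contig1\tpred\tCDS\t401\t900\t.\t-\t0\tID=cg2\n"
        )
        return ContigGeneIndex.from_gff3(gff)

    def test_interval_lengths(self, tmp_path):
        index = self._index(tmp_path)
        assert index.gene_length("cg1") == 300
        assert index.gene_length("cg2") == 500
        assert [g.gene_id for g in index.genes_on("contig1")] == ["cg1", "cg2"]

    def test_read_assigned_to_higher_scoring_gene(self, tmp_path):
        index = self._index(tmp_path)
        _write_sam(
            tmp_path / "c.sam",
            {"cg1": 300, "cg2": 500},
            [
                ("r1", 0, "cg1", 1, "100M", 60),
                ("r1", 256, "cg2", 1, "100M", 80),  # secondary, higher AS
            ],
        )
        gm = map_reads_to_contig_genes(
            {"contig1": ["r1"]}, index, tmp_path / "c.sam"
        )
        assert gm.gene_of("r1") == "cg2"

    def test_gene_absent_from_index_rejected(self, tmp_path):
        index = self._index(tmp_path)
        _write_sam(
            tmp_path / "c.sam", {"ghost": 300}, [("r1", 0, "ghost", 1, "100M", 60)]
        )
        with pytest.raises(KeyError, match="ghost"):
            map_reads_to_contig_genes({"contig1": ["r1"]}, index, tmp_path / "c.sam")
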