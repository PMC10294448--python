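"""Single-sample stage sequencing with stage-level checkpoint resume.

Stages run in a fixed order — read ledger, gene annotation, enzyme
annotation, taxonomic consensus, reports — each writing its outputs plus
a JSON checkpoint to the output directory. On rerun, a stage whose
checkpoint parses and whose outputs exist is skipped; a failed or
corrupt stage reruns from its beginning. One sample per invocation.
"""

from __future__ import annotations

import gzip
import json
import logging
import shutil
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import consensus as cns
from . import enzyme_annotation as enz
from . import gene_annotation as ga
from . import reporting as rep
from .config import PipelineConfig
from .errors import MtxAnnotError
from .readflow import (
    CATEGORY_ANNOTATED,
    CATEGORY_MRNA,
    CATEGORY_SINGLETON,
    CATEGORY_UNIDENTIFIED,
    CATEGORY_LOW_QUALITY,
    FILTER_CATEGORIES,
    ReadLedger,
    ReadRecord,
    apply_pair_filter,
    chunk,
    dedup,
    promote_orphans,
    read_fastq,
    write_fastq,
)
from .taxonomy import AccessionTaxidMap, load_taxonomy

logger = logging.getLogger("mtxannot")

STAGES = ("ledger", "gene_annotation", "enzyme_annotation", "consensus", "reports")

_HIT_STEMS = {"host": "host_hits", "vector": "vector_hits", "rRNA_tRNA": "rrna_hits"}


def _checkpoint_path(outdir: Path, stage: str) -> Path:
    return outdir / f"checkpoint_{stage}.json"


def _write_checkpoint(outdir: Path, stage: str, outputs: List[Path]) -> None:
    _checkpoint_path(outdir, stage).write_text(
        json.dumps({"stage": stage, "outputs": [str(p) for p in outputs]}, indent=1)
    )


def checkpoint_complete(outdir: Path, stage: str) -> bool:
    """A stage is complete when its checkpoint parses and its outputs exist."""
    path = _checkpoint_path(outdir, stage)
    if not path.exists():
        return False
    try:
        data = json.loads(path.read_text())
    except (json.JSONDecodeError, OSError):
        return False
    if data.get("stage") != stage:
        return False
    return all(Path(p).exists() for p in data.get("outputs", []))


def _load_hit_set(path: Optional[str]) -> set:
    hits = set()
    if path is None:
        return hits
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            hits.add((parts[0], parts[1] if len(parts) > 1 else "single"))
    return hits


# ---------------------------------------------------------------------------
# stage 1: read ledger (quality, dedup, host/vector/rRNA, repopulate)


def stage_ledger(config: PipelineConfig, outdir: Path) -> List[Path]:
    paired = bool(config.fastq_fwd and config.fastq_rev)
    fwd = read_fastq(config.fastq_fwd) if config.fastq_fwd else []
    rev = read_fastq(config.fastq_rev) if config.fastq_rev else []
    singles = read_fastq(config.fastq_single) if config.fastq_single else []
    if paired:
        rev_by_id = {r.read_id: r for r in rev}
        if set(rev_by_id) != {f.read_id for f in fwd}:
            raise MtxAnnotError("forward/reverse FASTQ read ids do not match")
        pairs: List[Tuple[ReadRecord, ReadRecord]] = [
            (f, rev_by_id[f.read_id]) for f in fwd
        ]
    else:
        pairs = []
        singles = singles + fwd + rev

    ledger = ReadLedger()
    for rec in [m for p in pairs for m in p] + singles:
        ledger.add_raw(rec.read_id, rec.mate)

    # quality filter (mean phred) with orphan promotion
    q_min = config.low_quality_mean_phred
    pass_flags = {
        f.read_id: (f.mean_phred() >= q_min, r.mean_phred() >= q_min)
        for f, r in pairs
    }
    promo = promote_orphans(pairs, pass_flags)
    for rec in promo.removed:
        ledger.record(rec.read_id, rec.mate, CATEGORY_LOW_QUALITY)
    for rec in promo.singletons:
        ledger.record(rec.read_id, rec.mate, CATEGORY_SINGLETON)
    live_singles: List[ReadRecord] = list(promo.singletons)
    for rec in singles:
        if rec.mean_phred() >= q_min:
            live_singles.append(rec)
        else:
            ledger.record(rec.read_id, rec.mate, CATEGORY_LOW_QUALITY)
    live_pairs = promo.pairs

    hq_path = outdir / "hq_reads.fastq"
    write_fastq(
        [m for p in live_pairs for m in p] + live_singles, hq_path
    )

    # duplicate collapse (exact sequence identity); pairs keyed on both mates
    pair_reps: List[Tuple[ReadRecord, ReadRecord]] = []
    pair_clusters: Dict[str, List[str]] = {}
    by_pair_seq: Dict[Tuple[str, str], str] = {}
    for f, r in live_pairs:
        key = (f.sequence, r.sequence)
        rep = by_pair_seq.get(key)
        if rep is None:
            by_pair_seq[key] = f.read_id
            pair_reps.append((f, r))
            pair_clusters[f.read_id] = [f.read_id]
        else:
            pair_clusters[rep].append(f.read_id)
    single_reps, single_clusters = dedup(live_singles)
    single_mate = {rec.read_id: rec.mate for rec in live_singles}

    # host / vector / rRNA filtering on representatives
    hit_sets = {
        "host": _load_hit_set(config.host_hits),
        "vector": _load_hit_set(config.vector_hits),
        "rRNA_tRNA": _load_hit_set(config.rrna_hits),
    }
    stringency = config.stringency()
    fate: Dict[Tuple[str, str], str] = {}
    current_pairs = pair_reps
    current_singles = list(single_reps)
    for category in FILTER_CATEGORIES:
        hits = hit_sets[category]
        next_pairs: List[Tuple[ReadRecord, ReadRecord]] = []
        for f, r in current_pairs:
            flags = ((f.read_id, "fwd") in hits, (r.read_id, "rev") in hits)
            out_f, out_r = apply_pair_filter(flags, category, stringency)
            if out_f == "pass" and out_r == "pass":
                next_pairs.append((f, r))
                continue
            for rec, outcome in ((f, out_f), (r, out_r)):
                if outcome == "singleton":
                    current_singles.append(rec)
                    ledger.record(rec.read_id, rec.mate, CATEGORY_SINGLETON)
                else:
                    fate[(rec.read_id, rec.mate)] = outcome
        current_pairs = next_pairs
        next_singles: List[ReadRecord] = []
        for rec in current_singles:
            if (rec.read_id, rec.mate) in hits:
                fate[(rec.read_id, rec.mate)] = category
            else:
                next_singles.append(rec)
        current_singles = next_singles

    for f, r in current_pairs:
        fate[(f.read_id, "fwd")] = CATEGORY_MRNA
        fate[(r.read_id, "rev")] = CATEGORY_MRNA
    for rec in current_singles:
        fate[(rec.read_id, rec.mate)] = CATEGORY_MRNA

    # repopulate duplicates with their representative's fate
    mrna_mates: Dict[str, List[str]] = {}
    mrna_lengths: Dict[str, int] = {}
    length_of = {(rec.read_id, rec.mate): len(rec.sequence)
                 for p in live_pairs for rec in p}
    length_of.update(
        {(rec.read_id, rec.mate): len(rec.sequence) for rec in live_singles}
    )

    def settle(member: str, rep: str, mate: str) -> None:
        outcome = fate[(rep, mate)]
        if member != rep:
            ledger.record(member, mate, f"duplicate_of:{rep}")
        ledger.record(member, mate, outcome)
        if outcome == CATEGORY_MRNA:
            mrna_mates.setdefault(member, []).append(mate)
            mrna_lengths.setdefault(member, length_of[(rep, mate)])

    for rep, members in pair_clusters.items():
        for member in members:
            settle(member, rep, "fwd")
            settle(member, rep, "rev")
    for rep, members in single_clusters.items():
        mate = single_mate[rep]
        for member in members:
            settle(member, rep, mate)

    ledger_path = outdir / "ledger_filtered.tsv"
    ledger.to_tsv(ledger_path)
    mrna_path = outdir / "mrna_reads.tsv"
    with open(mrna_path, "w") as fh:
        fh.write("read_id\tlength\tmates\n")
        for rid in sorted(mrna_mates):
            fh.write(f"{rid}\t{mrna_lengths[rid]}\t{','.join(sorted(mrna_mates[rid]))}\n")
    return [ledger_path, mrna_path, hq_path]


# ---------------------------------------------------------------------------
# stage 2: tiered gene annotation


def _load_mrna_table(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(outdir / "mrna_reads.tsv", sep="\t", dtype=str)


def stage_gene_annotation(config: PipelineConfig, outdir: Path) -> List[Path]:
    mrna = _load_mrna_table(outdir)
    read_lengths = {
        row.read_id: int(row.length) for row in mrna.itertuples(index=False)
    }
    read_mates = {
        row.read_id: row.mates.split(",") for row in mrna.itertuples(index=False)
    }
    gene_map = ga.GeneToReadMap()
    unannotated: set = set()
    for ids in chunk(list(mrna["read_id"]), config.chunk_size):
        sub = {rid: read_lengths[rid] for rid in ids}
        part_map, part_un = ga.cascade_annotate(
            sub, config.tier1_sam, config.tier2_m8, config.tier3_m8,
            config.thresholds(),
        )
        gene_map.merge(part_map)
        unannotated |= part_un

    ledger = ReadLedger.from_tsv(outdir / "ledger_filtered.tsv")
    for rid, mates in read_mates.items():
        terminal = (
            CATEGORY_ANNOTATED if rid in gene_map else CATEGORY_UNIDENTIFIED
        )
        for mate in mates:
            ledger.record(rid, mate, terminal)
    ledger.assert_complete()

    map_path = outdir / "gene_read_map.tsv"
    gene_map.to_tsv(map_path)
    ledger_path = outdir / "ledger.tsv"
    ledger.to_tsv(ledger_path)
    un_path = outdir / "unannotated_reads.txt"
    un_path.write_text("".join(rid + "\n" for rid in sorted(unannotated)))
    return [map_path, ledger_path, un_path]


# ---------------------------------------------------------------------------
# stage 3: ensemble enzyme annotation


def stage_enzyme_annotation(config: PipelineConfig, outdir: Path) -> List[Path]:
    gene_map = ga.GeneToReadMap.from_tsv(outdir / "gene_read_map.tsv")
    observed = set(gene_map.genes())
    detect = [
        p for p in enz.load_prediction_tsv(config.detect, "DETECT")
        if p.target_id in observed
    ] if config.detect else []
    priam = [
        p for p in enz.load_prediction_tsv(config.priam, "PRIAM")
        if p.target_id in observed
    ] if config.priam else []
    diamond = [
        p
        for p in enz.load_diamond_ec(config.diamond_ec_m8, config.protein_ec_map)
        if p.target_id in observed
    ] if config.diamond_ec_m8 and config.protein_ec_map else []
    db = enz.ECCooccurrenceDB.load(config.ec_pairs) if config.ec_pairs else (
        enz.ECCooccurrenceDB()
    )
    low, high = enz.annotate_enzymes(detect, priam, diamond, db)
    low_path = outdir / "ec_low.tsv"
    high_path = outdir / "ec_high.tsv"
    enz.write_ec_reports(low, high, low_path, high_path)
    return [low_path, high_path]


# ---------------------------------------------------------------------------
# stage 4: weighted taxonomic consensus


def stage_consensus(config: PipelineConfig, outdir: Path) -> List[Path]:
    tree = load_taxonomy(config.nodes_dmp, config.names_dmp)
    acc_map = AccessionTaxidMap.load(config.accession2taxid)
    gene_map = ga.GeneToReadMap.from_tsv(outdir / "gene_read_map.tsv")
    mrna = _load_mrna_table(outdir)

    votes_by_read: Dict[str, List[cns.ClassifierVote]] = {
        rid: [] for rid in mrna["read_id"]
    }
    for rid in gene_map.read_ids():
        if rid in votes_by_read:
            votes_by_read[rid].append(
                cns.gene_vote(rid, gene_map.gene_of(rid), acc_map)
            )
    for source, path in (
        ("kaiju", config.kaiju_votes),
        ("centrifuge", config.centrifuge_votes),
    ):
        if path is None:
            continue
        for vote in cns.load_classifier_votes(path, source):
            if vote.read_id in votes_by_read:
                votes_by_read[vote.read_id].append(vote)

    weights = config.consensus_weights()
    read_taxids = {
        rid: (
            cns.weighted_consensus(vs, tree, weights) if vs else 0
        )
        for rid, vs in votes_by_read.items()
    }
    consensus_path = outdir / "consensus.tsv"
    cns.write_consensus_tsv(read_taxids, tree, consensus_path)
    taxa_path = outdir / "taxa_table.tsv"
    rep.write_taxa_table(cns.taxa_table(read_taxids, tree), taxa_path)
    ranks_path = outdir / "rank_breakdown.tsv"
    breakdown = cns.rank_breakdown(read_taxids, tree)
    with open(ranks_path, "w") as fh:
        fh.write("rank\tfraction\n")
        for rank in ("species", "genus", "family_or_higher", "unclassified"):
            fh.write(f"{rank}\t{breakdown[rank]:.6f}\n")
    return [consensus_path, taxa_path, ranks_path]


# ---------------------------------------------------------------------------
# stage 5: reports


def _load_ec_report(path: Path) -> Dict[str, Dict[str, float]]:
    result: Dict[str, Dict[str, float]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            target, ec, score = line.rstrip("\n").split("\t")
            result.setdefault(target, {})[ec] = float(score)
    return result


def _load_consensus(path: Path) -> Dict[str, int]:
    taxids: Dict[str, int] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            rid, taxid = line.rstrip("\n").split("\t")[:2]
            taxids[rid] = int(taxid)
    return taxids


def stage_reports(config: PipelineConfig, outdir: Path) -> List[Path]:
    tree = load_taxonomy(config.nodes_dmp, config.names_dmp)
    acc_map = AccessionTaxidMap.load(config.accession2taxid)
    ledger = ReadLedger.from_tsv(outdir / "ledger.tsv")
    gene_map = ga.GeneToReadMap.from_tsv(outdir / "gene_read_map.tsv")
    ec_low = _load_ec_report(outdir / "ec_low.tsv")
    ec_high = _load_ec_report(outdir / "ec_high.tsv")
    read_taxids = _load_consensus(outdir / "consensus.tsv")

    outputs: List[Path] = []

    unique_low = len({ec for ecs in ec_low.values() for ec in ecs})
    unique_high = len({ec for ecs in ec_high.values() for ec in ecs})
    summary = rep.read_summary(ledger, gene_map, unique_low, unique_high)
    summary_path = outdir / "read_summary.tsv"
    summary.to_tsv(summary_path)
    outputs.append(summary_path)

    gene_lengths = {}
    if config.gene_lengths:
        with open(config.gene_lengths) as fh:
            fh.readline()
            for line in fh:
                gid, length = line.rstrip("\n").split("\t")[:2]
                gene_lengths[gid] = int(length)
    gene_taxids = {
        gene: acc_map.get(cns.extract_accession(gene)) for gene in gene_map.genes()
    }
    expression = rep.build_expression_table(
        gene_map, gene_lengths, gene_taxids, {g: list(ec_low.get(g, {})) for g in
                                              gene_map.genes()},
    )
    expr_path = outdir / "expression_table.tsv"
    expression.to_csv(expr_path, sep="\t", index=False, float_format="%.6f")
    outputs.append(expr_path)

    taxid_counts: Dict[int, int] = {}
    for taxid in read_taxids.values():
        taxid_counts[taxid] = taxid_counts.get(taxid, 0) + 1
    groups, assignment = rep.rollup_taxa(taxid_counts, tree, config.taxa_cutoff)
    labels = [g.label for g in groups]
    cyto = rep.cytoscape_table(expression, assignment, labels)
    cyto_path = outdir / "cytoscape_table.tsv"
    cyto.to_csv(cyto_path, sep="\t", index=False, float_format="%.6f")
    outputs.append(cyto_path)

    if config.ec_superpathways:
        from .simulate import load_superpathway_map

        pw_map = load_superpathway_map(config.ec_superpathways)
        group_cols = [c for c in cyto.columns if c not in ("ec", "total_rpkm")]
        melted = cyto.melt(
            id_vars=["ec"], value_vars=group_cols, var_name="taxon",
            value_name="rpkm",
        )
        melted = melted[melted["rpkm"] > 0]
        counts = {g.label: g.read_count for g in groups}
        matrix = rep.superpathway_matrix(
            melted, pw_map, counts, top_n=config.heatmap_top_n
        )
        matrix_path = outdir / "EC_coverage.csv"
        matrix.to_csv(matrix_path, float_format="%.6f")
        outputs.append(matrix_path)
        try:
            rep.render_superpathway_heatmap(matrix, outdir / "EC_coverage.png")
        except Exception:  # rendering is cosmetic; never fail the stage
            logger.warning("superpathway heatmap rendering failed", exc_info=True)

    before_paths = [
        p for p in (config.fastq_fwd, config.fastq_rev, config.fastq_single) if p
    ]
    hq_path = outdir / "hq_reads.fastq"
    if before_paths and hq_path.exists():
        before = np.zeros(rep.PHRED_BINS, dtype=int)
        for p in before_paths:
            b, _ = rep.quality_histogram(p, p)
            before += b
        _, after = rep.quality_histogram(before_paths[0], hq_path)
        hist_path = outdir / "quality_histogram.tsv"
        rep.write_quality_histogram(before, after, hist_path)
        outputs.append(hist_path)

    if config.contig_lengths:
        lengths = [
            int(x)
            for x in Path(config.contig_lengths).read_text().split()
            if x.strip()
        ]
        n50, l50 = rep.n50_l50(lengths)
        contig_path = outdir / "contig_stats.tsv"
        contig_path.write_text(f"statistic\tvalue\nN50\t{n50}\nL50\t{l50}\n")
        outputs.append(contig_path)

    return outputs


_STAGE_FUNCS = {
    "ledger": stage_ledger,
    "gene_annotation": stage_gene_annotation,
    "enzyme_annotation": stage_enzyme_annotation,
    "consensus": stage_consensus,
    "reports": stage_reports,
}

_INTERIM_FILES = ("hq_reads.fastq", "unannotated_reads.txt")


def _apply_interim_policy(config: PipelineConfig, outdir: Path) -> None:
    if config.keep_interim == "keep":
        return
    for name in _INTERIM_FILES:
        path = outdir / name
        if not path.exists():
            continue
        if config.keep_interim == "delete":
            path.unlink()
        else:  # compress
            with open(path, "rb") as src, gzip.open(f"{path}.gz", "wb") as dst:
                shutil.copyfileobj(src, dst)
            path.unlink()


def run(
    config: PipelineConfig, output_dir, resume: bool = True
) -> Dict[str, List[Path]]:
    """Run all stages for one sample, honoring stage-level resume.

    Returns a map of stage name to output paths. A stage failure
    propagates after logging the stage name; completed checkpoints are
    preserved so a rerun restarts at the failed stage.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: Dict[str, List[Path]] = {}
    for stage in STAGES:
        if resume and checkpoint_complete(outdir, stage):
            logger.info("stage %s: checkpoint complete, skipping", stage)
            data = json.loads(_checkpoint_path(outdir, stage).read_text())
            results[stage] = [Path(p) for p in data["outputs"]]
            continue
        logger.info("stage %s: running", stage)
        try:
            outputs = _STAGE_FUNCS[stage](config, outdir)
        except Exception:
            logger.error("stage %s failed", stage)
            raise
        _write_checkpoint(outdir, stage, outputs)
        results[stage] = outputs
    _apply_interim_policy(config, outdir)
    return results
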