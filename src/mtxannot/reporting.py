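"""Output tables: read summary, RPKM expression, taxon rollup, EC breakdowns,
superpathway matrix, contig statistics and quality histograms.

RPKM (reads per kilobase of transcript per million mapped reads) uses the
canonical definition ``count * 1e9 / (length_bp * total_mapped)``. The
taxon rollup starts at species and iteratively merges sub-cutoff taxa
with their sub-cutoff siblings into shared higher-rank groups (genus,
family, order, class, phylum); whatever is still below the cutoff at
phylum falls into the residual ``Other`` group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .errors import InvariantError
from .gene_annotation import GeneToReadMap
from .readflow import (
    CATEGORY_ANNOTATED,
    CATEGORY_HOST,
    CATEGORY_LOW_QUALITY,
    CATEGORY_RRNA,
    CATEGORY_UNIDENTIFIED,
    CATEGORY_VECTOR,
    ReadLedger,
    read_fastq,
)
from .taxonomy import TaxonomyTree, UNCLASSIFIED_TAXID

#: Rollup ranks in merge order (species upward to phylum).
ROLLUP_RANKS = ("species", "genus", "family", "order", "class", "phylum")

OTHER_LABEL = "Other"
UNMAPPED_LABEL = "Unmapped"


def rpkm(read_count: float, gene_length_bp: int, total_mapped_reads: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if gene_length_bp < 1:
        raise ValueError(f"gene_length_bp must be >= 1, got {gene_length_bp}")
    if total_mapped_reads < 1:
        raise ValueError(
            f"total_mapped_reads must be >= 1, got {total_mapped_reads}"
        )
    if read_count < 0:
        raise ValueError(f"read_count must be >= 0, got {read_count}")
    return read_count * 1e9 / (gene_length_bp * total_mapped_reads)


@dataclass
class TaxonGroup:
    """A reporting group of taxa emitted by the abundance rollup."""

    label: str
    rank: str
    member_taxids: Set[int]
    read_count: int
    read_fraction: float


def rollup_taxa(
    taxon_counts: Mapping[int, int],
    tree: TaxonomyTree,
    cutoff_fraction: float = 0.01,
) -> Tuple[List[TaxonGroup], Dict[int, str]]:
    """Merge sub-cutoff taxa upward until each emitted group meets the cutoff.

    Starting at species rank, taxa holding at least ``cutoff_fraction`` of
    total reads are emitted at their own rank; sub-cutoff taxa are pooled
    with sub-cutoff siblings into their shared ancestor at the next rank
    and re-tested, up through phylum. Residual sub-cutoff mass (and any
    unclassified taxid-0 reads) goes to ``Other``.

    Returns the group list (by descending read count) plus a taxid ->
    group-label assignment covering every input taxid.
    """
    total = sum(taxon_counts.values())
    groups: List[TaxonGroup] = []
    assignment: Dict[int, str] = {}
    if total == 0:
        return groups, assignment

    other_count = 0
    other_members: Set[int] = set()

    # pending[rank_index]: node_taxid -> (count, member input taxids)
    pending: List[Dict[int, Tuple[int, Set[int]]]] = [
        {} for _ in range(len(ROLLUP_RANKS))
    ]

    def place(taxid: int, count: int) -> None:
        nonlocal other_count
        if taxid == UNCLASSIFIED_TAXID or taxid not in tree:
            other_count += count
            other_members.add(taxid)
            return
        rank = tree.nearest_named_rank(taxid)
        if rank not in ROLLUP_RANKS:  # superkingdom/root-level assignment
            other_count += count
            other_members.add(taxid)
            return
        idx = ROLLUP_RANKS.index(rank)
        node = tree.ancestor_at_rank(taxid, rank)
        cur, members = pending[idx].get(node, (0, set()))
        pending[idx][node] = (cur + count, members | {taxid})

    for taxid, count in taxon_counts.items():
        place(taxid, count)

    for idx, rank in enumerate(ROLLUP_RANKS):
        for node in sorted(pending[idx]):
            count, members = pending[idx][node]
            if count / total >= cutoff_fraction:
                groups.append(
                    TaxonGroup(
                        label=tree.name(node),
                        rank=rank,
                        member_taxids=members,
                        read_count=count,
                        read_fraction=count / total,
                    )
                )
                continue
            # merge upward with sub-cutoff siblings sharing the next-rank parent
            parent = None
            for up in ROLLUP_RANKS[idx + 1 :]:
                parent = tree.ancestor_at_rank(node, up)
                if parent is not None:
                    up_idx = ROLLUP_RANKS.index(up)
                    cur, mem = pending[up_idx].get(parent, (0, set()))
                    pending[up_idx][parent] = (cur + count, mem | members)
                    break
            if parent is None:
                other_count += count
                other_members |= members

    if other_count:
        groups.append(
            TaxonGroup(
                label=OTHER_LABEL,
                rank="other",
                member_taxids=other_members,
                read_count=other_count,
                read_fraction=other_count / total,
            )
        )
    groups.sort(key=lambda g: (-g.read_count, g.label))
    for group in groups:
        for taxid in group.member_taxids:
            assignment[taxid] = group.label
    if sum(g.read_count for g in groups) != total:
        raise InvariantError("taxon rollup does not conserve read counts")
    return groups, assignment


@dataclass(frozen=True)
class ExpressionRow:
    gene_id: str
    length_bp: int
    read_count: float
    rpkm: float
    taxid: int
    ec_list: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError("length_bp must be >= 1")
        if self.rpkm < 0:
            raise ValueError("rpkm must be >= 0")


def build_expression_table(
    gene_map: GeneToReadMap,
    gene_lengths: Mapping[str, int],
    gene_taxids: Mapping[str, int],
    gene_ecs: Mapping[str, Iterable[str]],
    total_mapped_reads: Optional[int] = None,
) -> pd.DataFrame:
    """Gene-level expression table (length, read count, RPKM, taxid, ECs).

    Gene lengths must be on the nucleotide scale (protein-tier targets are
    expected at 3x the residue count). ``total_mapped_reads`` defaults to
    the number of assigned reads in the map.
    """
    counts = gene_map.read_counts()
    total = total_mapped_reads if total_mapped_reads is not None else sum(
        counts.values()
    )
    rows = []
    for gene in gene_map.genes():
        length = int(gene_lengths[gene])
        count = counts[gene]
        rows.append(
            {
                "gene_id": gene,
                "length_bp": length,
                "read_count": count,
                "rpkm": rpkm(count, length, max(total, 1)),
                "taxid": int(gene_taxids.get(gene, UNCLASSIFIED_TAXID)),
                "ec_list": ",".join(sorted(gene_ecs.get(gene, ()))),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "length_bp", "read_count", "rpkm", "taxid", "ec_list"],
    )


def cytoscape_table(
    expression: pd.DataFrame,
    group_assignment: Mapping[int, str],
    group_labels: Sequence[str],
) -> pd.DataFrame:
    """Per-EC total RPKM with a breakdown column per taxon group.

    Each gene's RPKM contributes to every EC annotated on it, under the
    group its taxid rolls up to. Per-group columns sum to the EC total;
    ECs with zero total RPKM are omitted.
    """
    labels = list(group_labels)
    rows: Dict[str, Dict[str, float]] = {}
    for rec in expression.itertuples(index=False):
        ecs = [e for e in str(rec.ec_list).split(",") if e]
        if not ecs or rec.rpkm <= 0:
            continue
        group = group_assignment.get(int(rec.taxid), OTHER_LABEL)
        if group not in labels:
            group = OTHER_LABEL
        for ec in ecs:
            row = rows.setdefault(ec, {lab: 0.0 for lab in labels})
            row.setdefault(group, 0.0)
            row[group] += float(rec.rpkm)
    out_labels = labels if OTHER_LABEL in labels else labels + [OTHER_LABEL]
    table = pd.DataFrame(
        [
            {"ec": ec, **{lab: vals.get(lab, 0.0) for lab in out_labels}}
            for ec, vals in sorted(rows.items())
        ],
        columns=["ec", *out_labels],
    )
    if len(table):
        table.insert(1, "total_rpkm", table[out_labels].sum(axis=1))
        table = table[table["total_rpkm"] > 0].reset_index(drop=True)
    else:
        table.insert(1, "total_rpkm", pd.Series(dtype=float))
    return table


def superpathway_matrix(
    ec_rpkm_by_taxon: pd.DataFrame,
    ec_to_superpathway: Mapping[str, Sequence[str]],
    taxon_read_counts: Mapping[str, int],
    top_n: int = 20,
) -> pd.DataFrame:
    """Superpathway x taxon RPKM matrix over the ``top_n`` most-read taxa.

    ``ec_rpkm_by_taxon`` has columns (ec, taxon, rpkm). An EC mapped to
    several superpathways contributes to each of their rows; unmapped ECs
    fall into an ``Unmapped`` row. Taxa are ranked by total read count;
    taxa beyond ``top_n`` are summed into an ``Other`` column.
    """
    ranked = sorted(
        taxon_read_counts, key=lambda t: (-taxon_read_counts[t], t)
    )
    top = ranked[:top_n]
    columns = top + ([OTHER_LABEL] if len(ranked) > top_n else [])
    cells: Dict[Tuple[str, str], float] = {}
    for rec in ec_rpkm_by_taxon.itertuples(index=False):
        taxon = rec.taxon if rec.taxon in top else OTHER_LABEL
        if taxon == OTHER_LABEL and OTHER_LABEL not in columns:
            columns.append(OTHER_LABEL)
        pathways = list(ec_to_superpathway.get(str(rec.ec), ())) or [UNMAPPED_LABEL]
        for pw in pathways:
            cells[(pw, taxon)] = cells.get((pw, taxon), 0.0) + float(rec.rpkm)
    pathways = sorted({pw for pw, _ in cells})
    matrix = pd.DataFrame(0.0, index=pathways, columns=columns)
    for (pw, taxon), value in cells.items():
        matrix.loc[pw, taxon] = value
    matrix.index.name = "superpathway"
    return matrix


@dataclass(frozen=True)
class ReadSummary:
    """The 16 read-processing summary fields."""

    total_reads: int
    high_quality_reads: int
    pct_high_quality: float
    host_reads: int
    pct_host: float
    vector_reads: int
    pct_vector: float
    rrna_reads: int
    pct_rrna: float
    putative_mrna_reads: int
    pct_putative_mrna: float
    annotated_reads: int
    pct_annotated: float
    unique_genes: int
    unique_ecs_high: int
    unique_ecs_low: int

    def validate(self) -> None:
        pairs = [
            (self.pct_high_quality, self.high_quality_reads, self.total_reads),
            (self.pct_host, self.host_reads, self.total_reads),
            (self.pct_vector, self.vector_reads, self.total_reads),
            (self.pct_rrna, self.rrna_reads, self.total_reads),
            (self.pct_putative_mrna, self.putative_mrna_reads, self.total_reads),
            (self.pct_annotated, self.annotated_reads, self.putative_mrna_reads),
        ]
        for pct, num, denom in pairs:
            expected = 100.0 * num / denom if denom else 0.0
            if abs(pct - expected) > 1e-6:
                raise InvariantError(
                    f"summary percentage {pct} inconsistent with {num}/{denom}"
                )
        if self.putative_mrna_reads > self.total_reads:
            raise InvariantError("putative mRNA exceeds total reads")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("field\tvalue\n")
            for name, value in self.__dict__.items():
                if isinstance(value, float):
                    fh.write(f"{name}\t{value:.6f}\n")
                else:
                    fh.write(f"{name}\t{value}\n")


def _pct(num: float, denom: float) -> float:
    return 100.0 * num / denom if denom else 0.0


def read_summary(
    ledger: ReadLedger,
    gene_map: GeneToReadMap,
    unique_ecs_low: int,
    unique_ecs_high: int,
) -> ReadSummary:
    """Compile the 16-field read summary from a completed ledger."""
    ledger.assert_complete()
    counts = ledger.terminal_counts()
    total = len(ledger)
    low_quality = counts.get(CATEGORY_LOW_QUALITY, 0)
    host = counts.get(CATEGORY_HOST, 0)
    vector = counts.get(CATEGORY_VECTOR, 0)
    rrna = counts.get(CATEGORY_RRNA, 0)
    annotated = counts.get(CATEGORY_ANNOTATED, 0)
    unidentified = counts.get(CATEGORY_UNIDENTIFIED, 0)
    high_quality = total - low_quality
    putative = annotated + unidentified
    summary = ReadSummary(
        total_reads=total,
        high_quality_reads=high_quality,
        pct_high_quality=_pct(high_quality, total),
        host_reads=host,
        pct_host=_pct(host, total),
        vector_reads=vector,
        pct_vector=_pct(vector, total),
        rrna_reads=rrna,
        pct_rrna=_pct(rrna, total),
        putative_mrna_reads=putative,
        pct_putative_mrna=_pct(putative, total),
        annotated_reads=annotated,
        pct_annotated=_pct(annotated, putative),
        unique_genes=len(gene_map.genes()),
        unique_ecs_high=unique_ecs_high,
        unique_ecs_low=unique_ecs_low,
    )
    summary.validate()
    return summary


def n50_l50(contig_lengths: Sequence[int]) -> Tuple[int, int]:
    """Assembly statistics: the length at which the cumulative sum of
    descending-sorted contig lengths reaches half the total (N50) and the
    number of contigs used to get there (L50)."""
    if not contig_lengths:
        raise ValueError("n50_l50 requires at least one contig length")
    if any(length <= 0 for length in contig_lengths):
        raise ValueError("contig lengths must be positive")
    ordered = sorted(contig_lengths, reverse=True)
    half = sum(ordered) / 2.0
    cumulative = 0
    for i, length in enumerate(ordered, start=1):
        cumulative += length
        if cumulative >= half:
            return length, i
    raise AssertionError("unreachable")


PHRED_BINS = 42  # integer mean-quality bins 0..41


def quality_histogram(fastq_before, fastq_after) -> Tuple[np.ndarray, np.ndarray]:
    """Binned per-read mean phred counts before and after quality filtering."""

    def hist(path) -> np.ndarray:
        counts = np.zeros(PHRED_BINS, dtype=int)
        for read in read_fastq(path):
            bin_idx = min(int(read.mean_phred()), PHRED_BINS - 1)
            counts[bin_idx] += 1
        return counts

    return hist(fastq_before), hist(fastq_after)


def write_quality_histogram(before: np.ndarray, after: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("mean_phred_bin\treads_before\treads_after\n")
        for i in range(PHRED_BINS):
            fh.write(f"{i}\t{before[i]}\t{after[i]}\n")


def write_taxa_table(
    taxon_counts: Mapping[str, int], path
) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\tread_pair_count\n")
        for taxon in sorted(taxon_counts, key=lambda t: (-taxon_counts[t], t)):
            fh.write(f"{taxon}\t{taxon_counts[taxon]}\n")


def render_superpathway_heatmap(matrix: pd.DataFrame, png_path) -> None:
    """Optional PNG rendering of the superpathway matrix (cosmetic)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * len(matrix.columns)), max(3, 0.4 * len(matrix)))
    )
    data = np.log10(matrix.to_numpy(dtype=float) + 1.0)
    im = ax.imshow(data, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="log10(RPKM + 1)")
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
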