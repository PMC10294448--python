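"""Tiered homology-hit post-processing into a gene-to-read map.

Three tiers of sequence-similarity reports are consumed in order:

1. a nucleotide SAM report (fast aligner), accepted when the CIGAR-derived
   aligned fraction of the read is >= 90%;
2. a nucleotide BLAST-tabular (m8) report, accepted at identity >= 85%,
   alignment-length >= 65% of the query and bitscore >= 60;
3. a translated-protein m8 report with the same cutoffs but the query
   length converted to residues (floor(nt/3)).

A read accepted at an earlier tier never reaches later tiers, multiple
hits for one read are adjudicated by score with the earliest maximal hit
winning ties, and the two mates of a pair are always assigned to the
same gene (the higher-scoring mate decides). The resulting map assigns
each read id to at most one gene.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .errors import CigarError, InvariantError

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

M8_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
]


@dataclass(frozen=True)
class HitThresholds:
    """Acceptance cutoffs for the three annotation tiers (printed defaults)."""

    cigar_coverage_min: float = 0.90
    identity_min: float = 85.0
    aln_len_fraction_min: float = 65.0
    bitscore_min: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cigar_coverage_min <= 1.0:
            raise ValueError("cigar_coverage_min must be in [0, 1]")
        if not 0.0 <= self.identity_min <= 100.0:
            raise ValueError("identity_min must be in [0, 100]")
        if not 0.0 <= self.aln_len_fraction_min <= 100.0:
            raise ValueError("aln_len_fraction_min must be in [0, 100]")


@dataclass(frozen=True)
class SamAlignment:
    """Slim view of one SAM record: read, mate, target gene, CIGAR and score."""

    read_id: str
    mate: str
    gene_id: str
    cigar: str
    alignment_score: int
    mapped: bool
    read_length: int = 0


@dataclass(frozen=True)
class TabularHit:
    """One m8 (BLAST outfmt-6) row."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity must be in [0, 100]")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")


#: BWA invocation constants used upstream when aligning reads to contig
#: gene models (mismatch, gap-open, gap-extend, clipping penalties).
#: Recorded for users who run the aligner; this library only parses SAM.
BWA_CONTIG_PARAMS = {"B": 40, "O": 60, "E": 10, "L": 50}


def parse_cigar(cigar: str) -> List[Tuple[int, str]]:
    """Tokenize a CIGAR string into (length, op) pairs, validating syntax."""
    if not cigar or cigar == "*":
        raise CigarError(f"malformed CIGAR {cigar!r}")
    pos = 0
    ops: List[Tuple[int, str]] = []
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise CigarError(f"malformed CIGAR {cigar!r}")
        length = int(m.group(1))
        if length < 1:
            raise CigarError(f"non-positive operation length in CIGAR {cigar!r}")
        ops.append((length, m.group(2)))
        pos = m.end()
    if pos != len(cigar):
        raise CigarError(f"malformed CIGAR {cigar!r}")
    return ops


def cigar_coverage(cigar: str, read_length: int) -> float:
    """Fraction of the read aligned to the reference (M/=/X ops), capped at 1.

    Read length includes soft-clipped bases: clipped and inserted bases are
    not reference-aligned and therefore count against coverage.
    """
    if read_length < 1:
        raise ValueError(f"read_length must be >= 1, got {read_length}")
    aligned = sum(n for n, op in parse_cigar(cigar) if op in "M=X")
    return min(aligned / read_length, 1.0)


def accept_sam_hit(
    aln: SamAlignment, read_length: int, thresholds: HitThresholds = HitThresholds()
) -> bool:
    """Accept a SAM hit when the CIGAR coverage meets the 90% cutoff."""
    if not aln.mapped:
        raise ValueError(f"accept_sam_hit requires a mapped record ({aln.read_id})")
    return cigar_coverage(aln.cigar, read_length) >= thresholds.cigar_coverage_min


def accept_tabular_hit(
    hit: TabularHit,
    query_length_nt: int,
    translated: bool,
    thresholds: HitThresholds = HitThresholds(),
) -> bool:
    """Three-clause acceptance for m8 hits (identity / length fraction / bitscore).

    For translated searches the effective query length is floor(nt/3)
    residues, matching the residue units of the m8 alignment length.
    """
    if query_length_nt < 1:
        raise ValueError(f"query_length_nt must be >= 1, got {query_length_nt}")
    effective = query_length_nt // 3 if translated else query_length_nt
    effective = max(effective, 1)
    if hit.percent_identity < thresholds.identity_min:
        return False
    if 100.0 * hit.alignment_length / effective < thresholds.aln_len_fraction_min:
        return False
    if hit.bitscore < thresholds.bitscore_min:
        return False
    return True


def best_assignment(
    hits: Sequence[Tuple[str, float]],
) -> Tuple[str, float]:
    """Earliest maximal-score hit from an ordered (gene_id, score) list.

    A later hit replaces the running best only when its score strictly
    exceeds it, so ties go to the first hit in report order.
    """
    if not hits:
        raise ValueError("best_assignment requires at least one hit")
    best_gene, best_score = hits[0]
    for gene, score in hits[1:]:
        if score > best_score:
            best_gene, best_score = gene, score
    return best_gene, best_score


def resolve_pair(
    fwd_best: Optional[Tuple[str, float]], rev_best: Optional[Tuple[str, float]]
) -> Tuple[str, float]:
    """Assign both mates of a pair to one gene: the higher-scoring mate
    decides; ties keep the forward mate's gene."""
    if fwd_best is None and rev_best is None:
        raise ValueError("resolve_pair requires at least one annotated mate")
    if fwd_best is None:
        return rev_best  # type: ignore[return-value]
    if rev_best is None:
        return fwd_best
    return rev_best if rev_best[1] > fwd_best[1] else fwd_best


class GeneToReadMap:
    """Gene/protein -> read-id assignments, each read assigned at most once."""

    TIERS = ("tier1_nt", "tier2_nt", "tier3_prot")

    def __init__(self) -> None:
        self._genes: Dict[str, List[str]] = {}
        self._read_gene: Dict[str, str] = {}
        self._read_tier: Dict[str, str] = {}

    def assign(self, gene_id: str, read_id: str, tier: str) -> None:
        if tier not in self.TIERS:
            raise ValueError(f"unknown tier {tier!r}")
        if read_id in self._read_gene:
            raise InvariantError(
                f"read {read_id!r} already assigned to {self._read_gene[read_id]!r}"
            )
        self._genes.setdefault(gene_id, []).append(read_id)
        self._read_gene[read_id] = gene_id
        self._read_tier[read_id] = tier

    def __len__(self) -> int:
        return len(self._read_gene)

    def __contains__(self, read_id: str) -> bool:
        return read_id in self._read_gene

    def genes(self) -> List[str]:
        return sorted(self._genes)

    def reads_for(self, gene_id: str) -> List[str]:
        return list(self._genes.get(gene_id, []))

    def gene_of(self, read_id: str) -> str:
        return self._read_gene[read_id]

    def tier_of(self, read_id: str) -> str:
        return self._read_tier[read_id]

    def read_ids(self) -> Set[str]:
        return set(self._read_gene)

    def read_counts(self) -> Dict[str, int]:
        return {g: len(rs) for g, rs in self._genes.items()}

    def merge(self, other: "GeneToReadMap") -> None:
        for rid, gene in other._read_gene.items():
            self.assign(gene, rid, other._read_tier[rid])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\ttier\tn_reads\tread_ids\n")
            for gene in sorted(self._genes):
                reads = sorted(self._genes[gene])
                tier = self._read_tier[reads[0]]
                fh.write(f"{gene}\t{tier}\t{len(reads)}\t{','.join(reads)}\n")

    @classmethod
    def from_tsv(cls, path) -> "GeneToReadMap":
        gene_map = cls()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("gene_id"):
                raise InvariantError(f"not a gene-to-read map file: {path}")
            for line in fh:
                gene, tier, _, read_ids = line.rstrip("\n").split("\t")
                for rid in read_ids.split(","):
                    if rid:
                        gene_map.assign(gene, rid, tier)
        return gene_map


def read_sam(path) -> Tuple[List[SamAlignment], Dict[str, int]]:
    """Parse a SAM file (pysam) into ordered alignments plus reference lengths.

    Secondary and supplementary records are kept as additional candidate
    matches in file order. The score is the AS tag, falling back to
    mapping quality when AS is absent.
    """
    import pysam

    alignments: List[SamAlignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        ref_lengths = dict(zip(sam.references, sam.lengths))
        for rec in sam:
            mapped = not rec.is_unmapped
            mate = "single"
            if rec.is_paired:
                mate = "rev" if rec.is_read2 else "fwd"
            score = 0
            if mapped:
                score = (
                    rec.get_tag("AS") if rec.has_tag("AS") else rec.mapping_quality
                )
            length = rec.infer_read_length() or (
                len(rec.query_sequence) if rec.query_sequence else 0
            )
            alignments.append(
                SamAlignment(
                    read_id=rec.query_name,
                    mate=mate,
                    gene_id=rec.reference_name if mapped else "",
                    cigar=rec.cigarstring if mapped else "",
                    alignment_score=int(score),
                    mapped=mapped,
                    read_length=int(length or 0),
                )
            )
    return alignments, ref_lengths


def read_m8(path) -> pd.DataFrame:
    """Load a 12-column BLAST-tabular report preserving file order."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=M8_COLUMNS, comment="#")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=M8_COLUMNS)
    return df


def _sam_tier_assign(
    alignments: Sequence[SamAlignment],
    remaining: Set[str],
    read_lengths: Mapping[str, int],
    thresholds: HitThresholds,
    gene_map: GeneToReadMap,
    tier: str,
) -> None:
    # accepted hits per read id, split per mate, preserving file order
    per_read: Dict[str, Dict[str, List[Tuple[str, float]]]] = {}
    for aln in alignments:
        if not aln.mapped or aln.read_id not in remaining:
            continue
        length = read_lengths.get(aln.read_id, aln.read_length)
        if length < 1:
            length = aln.read_length
        if not accept_sam_hit(aln, length, thresholds):
            continue
        per_read.setdefault(aln.read_id, {}).setdefault(aln.mate, []).append(
            (aln.gene_id, float(aln.alignment_score))
        )
    for rid, by_mate in per_read.items():
        fwd_hits = by_mate.get("fwd", []) + by_mate.get("single", []) + by_mate.get(
            "merged", []
        )
        rev_hits = by_mate.get("rev", [])
        fwd_best = best_assignment(fwd_hits) if fwd_hits else None
        rev_best = best_assignment(rev_hits) if rev_hits else None
        gene, _ = resolve_pair(fwd_best, rev_best)
        gene_map.assign(gene, rid, tier)
        remaining.discard(rid)


def _m8_tier_assign(
    df: pd.DataFrame,
    remaining: Set[str],
    read_lengths: Mapping[str, int],
    translated: bool,
    thresholds: HitThresholds,
    gene_map: GeneToReadMap,
    tier: str,
) -> None:
    per_read: Dict[str, List[Tuple[str, float]]] = {}
    for row in df.itertuples(index=False):
        rid = str(row.query_id)
        if rid not in remaining:
            continue
        length = read_lengths.get(rid, 0)
        if length < 1:
            continue
        hit = TabularHit(
            query_id=rid,
            subject_id=str(row.subject_id),
            percent_identity=float(row.percent_identity),
            alignment_length=int(row.alignment_length),
            bitscore=float(row.bitscore),
            evalue=float(row.evalue),
        )
        if accept_tabular_hit(hit, length, translated, thresholds):
            per_read.setdefault(rid, []).append((hit.subject_id, hit.bitscore))
    for rid, hits in per_read.items():
        gene, _ = best_assignment(hits)
        gene_map.assign(gene, rid, tier)
        remaining.discard(rid)


def cascade_annotate(
    read_lengths: Mapping[str, int],
    tier1_sam,
    tier2_m8,
    tier3_m8,
    thresholds: HitThresholds = HitThresholds(),
) -> Tuple[GeneToReadMap, Set[str]]:
    """Run the three-tier annotation cascade over a set of reads.

    ``read_lengths`` maps each candidate read id to its length in
    nucleotides (mates of a pair share an id and a length). Reads
    accepted at a tier are excluded from later tiers; the returned
    unannotated set is the input minus all assignments.
    """
    remaining: Set[str] = set(read_lengths)
    gene_map = GeneToReadMap()
    if tier1_sam is not None:
        alignments, _ = read_sam(tier1_sam)
        _sam_tier_assign(
            alignments, remaining, read_lengths, thresholds, gene_map, "tier1_nt"
        )
    if tier2_m8 is not None:
        _m8_tier_assign(
            read_m8(tier2_m8), remaining, read_lengths, False, thresholds,
            gene_map, "tier2_nt",
        )
    if tier3_m8 is not None:
        _m8_tier_assign(
            read_m8(tier3_m8), remaining, read_lengths, True, thresholds,
            gene_map, "tier3_prot",
        )
    if len(gene_map) + len(remaining) != len(read_lengths):
        raise InvariantError("cascade lost or duplicated reads")
    return gene_map, remaining


@dataclass(frozen=True)
class GeneInterval:
    gene_id: str
    start: int  # 1-based inclusive
    end: int  # inclusive
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class ContigGeneIndex:
    """Ordered gene intervals per contig, loaded from GFF3 (1-based inclusive)."""

    def __init__(self, intervals: Mapping[str, Sequence[GeneInterval]]):
        self._by_contig: Dict[str, List[GeneInterval]] = {
            c: sorted(iv, key=lambda g: g.start) for c, iv in intervals.items()
        }
        self._by_gene: Dict[str, Tuple[str, GeneInterval]] = {}
        for contig, ivs in self._by_contig.items():
            for iv in ivs:
                if iv.gene_id in self._by_gene:
                    raise InvariantError(f"duplicate gene id {iv.gene_id!r} in index")
                self._by_gene[iv.gene_id] = (contig, iv)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_gene

    def contigs(self) -> List[str]:
        return sorted(self._by_contig)

    def genes_on(self, contig: str) -> List[GeneInterval]:
        return list(self._by_contig.get(contig, []))

    def gene_length(self, gene_id: str) -> int:
        return self._by_gene[gene_id][1].length

    @classmethod
    def from_gff3(cls, path) -> "ContigGeneIndex":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=[
                "seqid", "source", "type", "start", "end",
                "score", "strand", "phase", "attributes",
            ],
        )
        intervals: Dict[str, List[GeneInterval]] = {}
        for row in df.itertuples(index=False):
            attrs = dict(
                kv.split("=", 1) for kv in str(row.attributes).split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", f"{row.seqid}:{row.start}-{row.end}")
            intervals.setdefault(str(row.seqid), []).append(
                GeneInterval(gene_id, int(row.start), int(row.end), str(row.strand))
            )
        return cls(intervals)


def map_reads_to_contig_genes(
    contig_read_map: Mapping[str, Sequence[str]],
    gene_index: ContigGeneIndex,
    gene_sam,
    thresholds: HitThresholds = HitThresholds(),
) -> GeneToReadMap:
    """Assign contig-derived reads to discrete gene models via SAM alignments.

    Every reference gene in the SAM must exist in the gene index. Each
    read gets at most one gene (coverage-accepted, earliest-highest-score).
    """
    alignments, _ = read_sam(gene_sam)
    for aln in alignments:
        if aln.mapped and aln.gene_id not in gene_index:
            raise KeyError(f"gene {aln.gene_id!r} absent from contig gene index")
    contig_reads: Set[str] = {
        rid for reads in contig_read_map.values() for rid in reads
    }
    gene_map = GeneToReadMap()
    remaining = set(contig_reads)
    read_lengths = {
        aln.read_id: aln.read_length for aln in alignments if aln.read_length
    }
    _sam_tier_assign(
        alignments, remaining, read_lengths, thresholds, gene_map, "tier1_nt"
    )
    return gene_map
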