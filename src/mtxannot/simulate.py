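"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates a small microbial community metatranscriptome:
planted species with known relative abundances expressing planted genes,
plus host, vector, rRNA/tRNA and low-quality contaminant reads. For each
generated dataset it also fabricates the downstream tool outputs the
pipeline consumes — tiered alignment reports (SAM + two m8 files),
short-read classifier votes, EC predictor tables, taxonomy dump files,
accession and superpathway maps — all consistent with a truth table, so
acceptance rules can be checked against known labels. Scores and hit
geometry are constructed so that, at zero noise, the acceptance
thresholds recover the truth exactly. Everything is byte-deterministic
under a fixed seed.

It does not model realistic error profiles (no quality-by-cycle model,
no indels): alignment itself is mocked, so sequences only need identity
bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .enzyme_annotation import ECCooccurrenceDB
from .readflow import ReadRecord, write_fastq
from .taxonomy import (
    AccessionTaxidMap,
    NAMED_RANKS,
    TaxonNode,
    TaxonomyTree,
    write_taxonomy,
)

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

CATEGORY_PROBS_ORDER = ("low_quality", "host", "vector", "rRNA_tRNA", "mRNA")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# taxonomy


def make_taxonomy(
    n_phyla: int, n_per_level: int, seed: int = 0
) -> TaxonomyTree:
    """Balanced taxonomy with all seven named ranks.

    The root has one superkingdom child with ``n_phyla`` phyla, and every
    node below branches into ``n_per_level`` children down to species, so
    the tree holds ``n_phyla * n_per_level**5`` species. Deterministic
    for fixed arguments (the seed is accepted for interface symmetry).
    """
    if n_phyla < 1 or n_per_level < 1:
        raise ValueError("n_phyla and n_per_level must be >= 1")
    nodes: Dict[int, TaxonNode] = {1: TaxonNode(1, 1, "no_rank", "root")}
    next_taxid = 2
    nodes[2] = TaxonNode(2, 1, "superkingdom", "Bacteria")
    next_taxid = 3
    frontier = [2]
    for rank in NAMED_RANKS[1:]:  # phylum .. species
        branching = n_phyla if rank == "phylum" else n_per_level
        new_frontier: List[int] = []
        counter = 1
        for parent in frontier:
            for _ in range(branching):
                taxid = next_taxid
                next_taxid += 1
                nodes[taxid] = TaxonNode(
                    taxid, parent, rank, f"{rank.capitalize()}_{counter}"
                )
                new_frontier.append(taxid)
                counter += 1
        frontier = new_frontier
    return TaxonomyTree(nodes)


# ---------------------------------------------------------------------------
# community specification


@dataclass
class SpeciesSpec:
    """One planted species: taxid, relative abundance and its gene set."""

    taxid: int
    abundance: float
    genes: Dict[str, str]  # gene_id -> nucleotide sequence


@dataclass
class CommunitySpec:
    """Study conditions for one synthetic metatranscriptome sample."""

    species: List[SpeciesSpec]
    n_pairs: int = 10_000
    paired: bool = True
    read_length: int = 100
    host_fraction: float = 0.05
    vector_fraction: float = 0.02
    rrna_fraction: float = 0.30
    low_quality_fraction: float = 0.03
    subst_rate: float = 0.0
    duplicate_fraction: float = 0.0
    orphan_hit_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total_ab = sum(s.abundance for s in self.species)
        if self.species and abs(total_ab - 1.0) > 1e-9:
            raise ValueError(f"species abundances must sum to 1, got {total_ab}")
        contaminants = (
            self.host_fraction
            + self.vector_fraction
            + self.rrna_fraction
            + self.low_quality_fraction
        )
        if contaminants >= 1.0:
            raise ValueError("contaminant fractions must sum to < 1")
        for frac in (
            self.host_fraction,
            self.vector_fraction,
            self.rrna_fraction,
            self.low_quality_fraction,
            self.subst_rate,
            self.duplicate_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")

    def gene_lengths(self) -> Dict[str, int]:
        return {
            gid: len(seq) for sp in self.species for gid, seq in sp.genes.items()
        }

    def gene_taxids(self) -> Dict[str, int]:
        return {gid: sp.taxid for sp in self.species for gid in sp.genes}


def build_community(
    tree: TaxonomyTree,
    n_species: int = 5,
    genes_per_species: int = 20,
    gene_length_range: Tuple[int, int] = (600, 1500),
    abundances: Optional[Sequence[float]] = None,
    seed: int = 0,
    **spec_kwargs,
) -> CommunitySpec:
    """Plant a community on species nodes of ``tree``.

    Species are taken from distinct genera (every other species node in
    taxid order) so each planted species has an unplanted congeneric
    sibling available for the classifier confusion model.
    """
    rng = np.random.default_rng(seed)
    species_nodes = sorted(
        t for t in tree.nodes if tree.rank(t) == "species"
    )
    chosen = species_nodes[:: max(1, len(species_nodes) // max(n_species, 1))][
        :n_species
    ]
    if len(chosen) < n_species:
        raise ValueError(
            f"taxonomy has only {len(chosen)} selectable species, need {n_species}"
        )
    if abundances is None:
        # moderately uneven community, renormalized
        raw = rng.dirichlet(np.full(n_species, 5.0))
        abundances = (raw / raw.sum()).tolist()
    species: List[SpeciesSpec] = []
    acc_counter = 1
    for idx, taxid in enumerate(chosen):
        genes: Dict[str, str] = {}
        for j in range(genes_per_species):
            length = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
            gene_id = f"g{idx}_{j}|ACC{acc_counter:05d}"
            acc_counter += 1
            genes[gene_id] = _random_seq(rng, length)
        species.append(SpeciesSpec(taxid=taxid, abundance=float(abundances[idx]), genes=genes))
    return CommunitySpec(species=species, seed=seed, **spec_kwargs)


def accession_map_for(spec: CommunitySpec) -> AccessionTaxidMap:
    mapping = {
        gid.rsplit("|", 1)[-1]: sp.taxid
        for sp in spec.species
        for gid in sp.genes
    }
    return AccessionTaxidMap(mapping)


# ---------------------------------------------------------------------------
# reads + truth


@dataclass
class SimulatedReads:
    """FASTQ paths, the truth table and the per-category hit lists."""

    fastq_fwd: Optional[Path]
    fastq_rev: Optional[Path]
    fastq_single: Optional[Path]
    truth: pd.DataFrame  # read_id, category, gene_id, taxid, fwd_pos


def make_reads(spec: CommunitySpec, outdir) -> SimulatedReads:
    """Generate FASTQ reads and the matching truth table.

    Per read pair a category is drawn from the spec fractions
    (low-quality, host, vector, rRNA/tRNA, the remainder mRNA); mRNA
    pairs draw a species by abundance and a gene uniformly. Byte-
    deterministic under the spec seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # decorrelate from the gene-sequence stream (same seed, distinct key)
    rng = np.random.default_rng((spec.seed, 1))

    mrna_fraction = 1.0 - (
        spec.low_quality_fraction
        + spec.host_fraction
        + spec.vector_fraction
        + spec.rrna_fraction
    )
    probs = np.array(
        [
            spec.low_quality_fraction,
            spec.host_fraction,
            spec.vector_fraction,
            spec.rrna_fraction,
            mrna_fraction,
        ]
    )
    ab = np.array([s.abundance for s in spec.species])
    gene_ids = [sorted(sp.genes) for sp in spec.species]

    # contaminant reference pools
    contaminant_pool = {
        cat: [_random_seq(rng, 2000) for _ in range(4)]
        for cat in ("host", "vector", "rRNA_tRNA")
    }

    rl = spec.read_length
    fwd_reads: List[ReadRecord] = []
    rev_reads: List[ReadRecord] = []
    truth_rows: List[dict] = []

    def good_quality() -> str:
        return "".join(chr(int(q) + 33) for q in rng.integers(32, 41, size=rl))

    def bad_quality() -> str:
        return "".join(chr(int(q) + 33) for q in rng.integers(2, 13, size=rl))

    def mutate(seq: str) -> str:
        if spec.subst_rate <= 0:
            return seq
        chars = list(seq)
        for i in range(len(chars)):
            if rng.random() < spec.subst_rate:
                chars[i] = str(rng.choice(_BASES))
        return "".join(chars)

    def window(source: str) -> Tuple[str, str, int]:
        """fwd read, rev read (revcomp of downstream window), fwd start."""
        insert = rl + int(rng.integers(0, 101))
        max_start = max(len(source) - insert, 0)
        start = int(rng.integers(0, max_start + 1)) if max_start else 0
        fwd = source[start : start + rl].ljust(rl, "A")
        rev_window = source[start + insert - rl : start + insert].ljust(rl, "A")
        return mutate(fwd), mutate(_revcomp(rev_window)), start

    for i in range(spec.n_pairs):
        rid = f"r{i:06d}"
        cat_idx = int(rng.choice(len(CATEGORY_PROBS_ORDER), p=probs))
        category = CATEGORY_PROBS_ORDER[cat_idx]
        gene_id, taxid, pos = "", 0, -1
        if category == "mRNA":
            sp_idx = int(rng.choice(len(spec.species), p=ab))
            sp = spec.species[sp_idx]
            gene_id = gene_ids[sp_idx][int(rng.integers(len(gene_ids[sp_idx])))]
            taxid = sp.taxid
            fwd_seq, rev_seq, pos = window(sp.genes[gene_id])
            fwd_q = rev_q = None
        elif category == "low_quality":
            fwd_seq, rev_seq = _random_seq(rng, rl), _random_seq(rng, rl)
            fwd_q = rev_q = "bad"
        else:
            pool = contaminant_pool[category]
            source = pool[int(rng.integers(len(pool)))]
            fwd_seq, rev_seq, pos = window(source)
            fwd_q = rev_q = None
        fwd_reads.append(
            ReadRecord(
                rid,
                "fwd" if spec.paired else "single",
                fwd_seq,
                bad_quality() if fwd_q else good_quality(),
            )
        )
        if spec.paired:
            rev_reads.append(
                ReadRecord(
                    rid,
                    "rev",
                    rev_seq,
                    bad_quality() if rev_q else good_quality(),
                )
            )
        truth_rows.append(
            {
                "read_id": rid,
                "category": category,
                "gene_id": gene_id,
                "taxid": taxid,
                "fwd_pos": pos,
            }
        )

    # exact duplicates of earlier reads (new ids, same sequences and truth)
    n_dups = int(round(spec.duplicate_fraction * spec.n_pairs))
    for j in range(n_dups):
        src = int(rng.integers(spec.n_pairs))
        rid = f"d{j:06d}"
        fwd_reads.append(
            ReadRecord(rid, fwd_reads[src].mate, fwd_reads[src].sequence,
                       fwd_reads[src].quality)
        )
        if spec.paired:
            rev_reads.append(
                ReadRecord(rid, "rev", rev_reads[src].sequence,
                           rev_reads[src].quality)
            )
        row = dict(truth_rows[src])
        row["read_id"] = rid
        truth_rows.append(row)

    truth = pd.DataFrame(truth_rows)
    if spec.paired:
        fwd_path, rev_path = outdir / "reads_1.fastq", outdir / "reads_2.fastq"
        write_fastq(fwd_reads, fwd_path)
        write_fastq(rev_reads, rev_path)
        result = SimulatedReads(fwd_path, rev_path, None, truth)
    else:
        single = outdir / "reads.fastq"
        write_fastq(fwd_reads, single)
        result = SimulatedReads(None, None, single, truth)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return result


def write_filter_hits(
    truth: pd.DataFrame, spec: CommunitySpec, outdir, seed: Optional[int] = None
) -> Dict[str, Path]:
    """Per-category hit lists (read_id, mate) emulating the filter aligners.

    By default both mates of a contaminant pair hit; with
    ``orphan_hit_fraction`` > 0 a random subset of pairs hits on the
    forward mate only, exercising the low-stringency orphan path.
    """
    outdir = Path(outdir)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    paths: Dict[str, Path] = {}
    mapping = {"host": "host", "vector": "vector", "rRNA_tRNA": "rrna"}
    for category, stem in mapping.items():
        path = outdir / f"{stem}_hits.tsv"
        with open(path, "w") as fh:
            for row in truth.itertuples(index=False):
                if row.category != category:
                    continue
                fwd_only = (
                    spec.paired
                    and spec.orphan_hit_fraction > 0
                    and rng.random() < spec.orphan_hit_fraction
                )
                if spec.paired:
                    fh.write(f"{row.read_id}\tfwd\n")
                    if not fwd_only:
                        fh.write(f"{row.read_id}\trev\n")
                else:
                    fh.write(f"{row.read_id}\tsingle\n")
        paths[category] = path
    return paths


# ---------------------------------------------------------------------------
# alignment reports


def make_alignment_reports(
    truth: pd.DataFrame,
    spec: CommunitySpec,
    outdir,
    miss_rate: float = 0.0,
    spurious_rate: float = 0.0,
    seed: int = 0,
) -> Tuple[Path, Path, Path]:
    """Tiered alignment reports (SAM, nucleotide m8, translated m8).

    Each true mRNA read id gets, with probability ``1 - miss_rate``, one
    correct above-threshold hit at a uniformly drawn tier; missed reads
    receive a below-threshold hit in their tier. ``spurious_rate``
    injects extra wrong-gene hits that are either below threshold or
    above threshold with a lower score than the correct hit, so the
    acceptance rules recover the truth exactly at zero rates.
    """
    import pysam

    if not 0.0 <= miss_rate < 1.0 or not 0.0 <= spurious_rate < 1.0:
        raise ValueError("rates must lie in [0, 1)")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rl = spec.read_length
    lengths = spec.gene_lengths()
    all_genes = sorted(lengths)

    sam_path = outdir / "tier1.sam"
    m8_nt_path = outdir / "tier2.m8"
    m8_prot_path = outdir / "tier3.m8"

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": g, "LN": lengths[g]} for g in all_genes],
    }
    ref_index = {g: i for i, g in enumerate(all_genes)}

    m8_nt_rows: List[str] = []
    m8_prot_rows: List[str] = []

    def m8_row(rid, gene, ident, aln_len, evalue, bits) -> str:
        return (
            f"{rid}\t{gene}\t{ident:.1f}\t{aln_len}\t0\t0\t1\t{aln_len}\t1\t"
            f"{aln_len}\t{evalue:.2e}\t{bits:.1f}"
        )

    with pysam.AlignmentFile(str(sam_path), "w", header=header) as sam:

        def sam_record(rid, mate, gene, pos, score, cigar_ops):
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = rid
            rec.flag = (0x1 | 0x40) if mate == "fwd" else (0x1 | 0x80)
            if not spec.paired:
                rec.flag = 0
            rec.reference_id = ref_index[gene]
            rec.reference_start = pos
            rec.mapping_quality = 60
            rec.cigartuples = cigar_ops
            rec.query_sequence = "A" * rl
            rec.set_tag("AS", int(score))
            sam.write(rec)

        for row in truth.itertuples(index=False):
            if row.category != "mRNA":
                continue
            rid = row.read_id
            gene = row.gene_id
            pos = max(int(row.fwd_pos), 0)
            tier = int(rng.integers(1, 4))
            missed = rng.random() < miss_rate
            spurious = rng.random() < spurious_rate
            wrong_gene = all_genes[int(rng.integers(len(all_genes)))]
            if tier == 1:
                if missed:
                    # 50% soft-clipped: coverage 0.5 < 0.90 -> rejected
                    sam_record(
                        rid, "fwd", gene, pos, 2 * rl,
                        [(0, rl // 2), (4, rl - rl // 2)],
                    )
                else:
                    sam_record(rid, "fwd", gene, pos, 2 * rl, [(0, rl)])
                    if spec.paired:
                        sam_record(rid, "rev", gene, pos, 2 * rl, [(0, rl)])
                    if spurious:
                        # accepted but lower-scored wrong-gene candidate
                        sam_record(rid, "fwd", wrong_gene, 0, rl, [(0, rl)])
            elif tier == 2:
                if missed:
                    m8_nt_rows.append(m8_row(rid, gene, 70.0, rl, 1e-20, 150.0))
                else:
                    m8_nt_rows.append(m8_row(rid, gene, 98.0, rl, 1e-30, 200.0))
                    if spurious:
                        m8_nt_rows.append(
                            m8_row(rid, wrong_gene, 98.0, rl, 1e-20, 100.0)
                        )
            else:
                res = max(rl // 3, 1)
                if missed:
                    m8_prot_rows.append(m8_row(rid, gene, 95.0, res, 1e-20, 40.0))
                else:
                    m8_prot_rows.append(m8_row(rid, gene, 95.0, res, 1e-25, 120.0))
                    if spurious:
                        m8_prot_rows.append(
                            m8_row(rid, wrong_gene, 60.0, res, 1e-3, 30.0)
                        )

    m8_nt_path.write_text("".join(r + "\n" for r in m8_nt_rows))
    m8_prot_path.write_text("".join(r + "\n" for r in m8_prot_rows))
    return sam_path, m8_nt_path, m8_prot_path


# ---------------------------------------------------------------------------
# classifier votes


def _sibling_species(tree: TaxonomyTree, taxid: int, rng: np.random.Generator) -> int:
    """A congeneric species other than ``taxid`` (confusable sibling)."""
    genus = tree.ancestor_at_rank(taxid, "genus")
    siblings = [
        t for t in tree.children(genus) if t != taxid and tree.rank(t) == "species"
    ] if genus is not None else []
    if not siblings:
        species = sorted(
            t for t in tree.nodes if tree.rank(t) == "species" and t != taxid
        )
        return species[int(rng.integers(len(species)))]
    return sorted(siblings)[int(rng.integers(len(siblings)))]


def make_classifier_votes(
    truth: pd.DataFrame,
    tree: TaxonomyTree,
    accuracy: Mapping[str, float],
    outdir,
    seed: int = 0,
) -> Dict[str, Path]:
    """Per-source vote files (classified_flag, read_id, taxid) for mRNA reads.

    Each source calls the true species with its stated accuracy and a
    congeneric sibling otherwise (the confusable-sibling error model).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: Dict[str, Path] = {}
    for source in ("gene_lookup", "kaiju", "centrifuge"):
        acc = float(accuracy.get(source, 1.0))
        path = outdir / f"{source}_votes.tsv"
        with open(path, "w") as fh:
            for row in truth.itertuples(index=False):
                if row.category != "mRNA":
                    continue
                taxid = (
                    int(row.taxid)
                    if rng.random() < acc
                    else _sibling_species(tree, int(row.taxid), rng)
                )
                fh.write(f"C\t{row.read_id}\t{taxid}\n")
        paths[source] = path
    return paths


# ---------------------------------------------------------------------------
# enzyme predictor fixtures


def assign_gene_ecs(
    spec: CommunitySpec, seed: int = 0, two_ec_fraction: float = 0.2
) -> Tuple[Dict[str, List[str]], ECCooccurrenceDB]:
    """Plant 1-2 true ECs per gene and a curated pair DB covering the
    co-assigned pairs (plus decoy pairs)."""
    rng = np.random.default_rng(seed)
    universe = [
        f"{a}.{b}.{c}.{d}"
        for a in range(1, 4)
        for b in range(1, 4)
        for c in range(1, 3)
        for d in range(1, 6)
    ]
    gene_ecs: Dict[str, List[str]] = {}
    db = ECCooccurrenceDB()
    for sp in spec.species:
        for gid in sorted(sp.genes):
            if rng.random() < two_ec_fraction:
                picks = rng.choice(len(universe), size=2, replace=False)
                ecs = sorted(universe[int(p)] for p in picks)
                db.add(ecs[0], ecs[1])
            else:
                ecs = [universe[int(rng.integers(len(universe)))]]
            gene_ecs[gid] = ecs
    # decoy pairs not used by any gene
    for _ in range(5):
        picks = rng.choice(len(universe), size=2, replace=False)
        a, b = universe[int(picks[0])], universe[int(picks[1])]
        if a != b:
            db.add(a, b)
    return gene_ecs, db


def make_ec_fixture(
    gene_ecs: Mapping[str, Sequence[str]],
    db: ECCooccurrenceDB,
    outdir,
    detect_sens: float = 1.0,
    priam_sens: float = 1.0,
    diamond_sens: float = 1.0,
    seed: int = 0,
    priam_prob_range: Tuple[float, float] = (0.3, 0.95),
    diamond_evalue_range: Tuple[float, float] = (1e-20, 1e-6),
) -> Dict[str, Path]:
    """Predictor outputs for the three EC sources plus the pair database.

    Each true EC is emitted per source with that source's sensitivity.
    PRIAM probabilities and DIAMOND e-values are drawn across the
    stringency cutoffs (log-uniform for e-values) so both report modes
    are exercised; pass degenerate ranges to pin them.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    detect_path = outdir / "detect.tsv"
    priam_path = outdir / "priam.tsv"
    diamond_path = outdir / "diamond_ec.m8"
    protmap_path = outdir / "protein_ec_map.tsv"
    pairs_path = outdir / "ec_pairs.tsv"

    lo, hi = np.log10(diamond_evalue_range[0]), np.log10(diamond_evalue_range[1])
    ec_protein = {}
    with open(detect_path, "w") as d_fh, open(priam_path, "w") as p_fh, open(
        diamond_path, "w"
    ) as x_fh:
        d_fh.write("target_id\tec\tprobability\n")
        p_fh.write("target_id\tec\tprobability\n")
        for gid in sorted(gene_ecs):
            for ec in gene_ecs[gid]:
                prot = ec_protein.setdefault(ec, f"sp|{ec.replace('.', '_')}")
                if rng.random() < detect_sens:
                    d_fh.write(f"{gid}\t{ec}\t{rng.uniform(0.8, 0.99):.4f}\n")
                if rng.random() < priam_sens:
                    p_fh.write(
                        f"{gid}\t{ec}\t"
                        f"{rng.uniform(priam_prob_range[0], priam_prob_range[1]):.4f}\n"
                    )
                if rng.random() < diamond_sens:
                    evalue = 10 ** rng.uniform(lo, hi)
                    x_fh.write(
                        f"{gid}\t{prot}\t97.0\t50\t0\t0\t1\t50\t1\t50\t"
                        f"{evalue:.2e}\t80.0\n"
                    )
    with open(protmap_path, "w") as fh:
        fh.write("protein\tec\n")
        for ec in sorted(ec_protein):
            fh.write(f"{ec_protein[ec]}\t{ec}\n")
    db.write(pairs_path)
    return {
        "detect": detect_path,
        "priam": priam_path,
        "diamond_m8": diamond_path,
        "protein_ec_map": protmap_path,
        "ec_pairs": pairs_path,
    }


def make_superpathway_map(
    gene_ecs: Mapping[str, Sequence[str]], outdir, n_pathways: int = 6, seed: int = 0
) -> Path:
    """EC -> superpathway table (an EC may belong to 1-2 pathways)."""
    outdir = Path(outdir)
    rng = np.random.default_rng(seed)
    ecs = sorted({ec for ecs in gene_ecs.values() for ec in ecs})
    path = outdir / "ec_superpathways.tsv"
    with open(path, "w") as fh:
        fh.write("ec\tsuperpathway\n")
        for ec in ecs:
            n = 2 if rng.random() < 0.2 else 1
            picks = rng.choice(n_pathways, size=n, replace=False)
            for p in sorted(int(x) for x in picks):
                fh.write(f"{ec}\tSuperpathway_{p + 1}\n")
    return path


def load_superpathway_map(path) -> Dict[str, List[str]]:
    mapping: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "ec\t")):
                continue
            ec, pw = line.split("\t")[:2]
            mapping.setdefault(ec, []).append(pw)
    return mapping


# ---------------------------------------------------------------------------
# one-call sample simulation


@dataclass
class SimulatedSample:
    """All file paths and in-memory truth for one simulated sample."""

    outdir: Path
    spec: CommunitySpec
    tree: TaxonomyTree
    truth: pd.DataFrame
    gene_ecs: Dict[str, List[str]]
    paths: Dict[str, Path] = field(default_factory=dict)


def simulate_sample(
    outdir,
    n_species: int = 5,
    n_pairs: int = 10_000,
    seed: int = 0,
    miss_rate: float = 0.0,
    spurious_rate: float = 0.0,
    classifier_accuracy: Optional[Mapping[str, float]] = None,
    detect_sens: float = 1.0,
    priam_sens: float = 1.0,
    diamond_sens: float = 1.0,
    **spec_kwargs,
) -> SimulatedSample:
    """Generate a complete input set for one pipeline run.

    Writes FASTQ reads, filter hit lists, tiered alignment reports,
    classifier votes, EC predictor files, taxonomy dumps, the accession
    and superpathway maps, a gene-length table and the truth table, all
    under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = make_taxonomy(2, 2, seed=seed)
    spec = build_community(tree, n_species=n_species, seed=seed, **spec_kwargs)
    spec.n_pairs = n_pairs

    reads = make_reads(spec, outdir)
    hits = write_filter_hits(reads.truth, spec, outdir)
    sam, m8_nt, m8_prot = make_alignment_reports(
        reads.truth, spec, outdir, miss_rate=miss_rate,
        spurious_rate=spurious_rate, seed=seed + 1,
    )
    votes = make_classifier_votes(
        reads.truth,
        tree,
        classifier_accuracy or {"gene_lookup": 1.0, "kaiju": 1.0, "centrifuge": 1.0},
        outdir,
        seed=seed + 2,
    )
    gene_ecs, db = assign_gene_ecs(spec, seed=seed + 3)
    ec_paths = make_ec_fixture(
        gene_ecs, db, outdir, detect_sens=detect_sens, priam_sens=priam_sens,
        diamond_sens=diamond_sens, seed=seed + 4,
    )
    superpathways = make_superpathway_map(gene_ecs, outdir, seed=seed + 5)

    nodes_path, names_path = outdir / "nodes.dmp", outdir / "names.dmp"
    write_taxonomy(tree, nodes_path, names_path)
    acc_map = accession_map_for(spec)
    acc_path = outdir / "accession2taxid.tsv"
    acc_map.write(acc_path)

    lengths_path = outdir / "gene_lengths.tsv"
    with open(lengths_path, "w") as fh:
        fh.write("gene_id\tlength_bp\n")
        for gid, length in sorted(spec.gene_lengths().items()):
            fh.write(f"{gid}\t{length}\n")

    paths = {
        "fastq_fwd": reads.fastq_fwd,
        "fastq_rev": reads.fastq_rev,
        "fastq_single": reads.fastq_single,
        "host_hits": hits["host"],
        "vector_hits": hits["vector"],
        "rrna_hits": hits["rRNA_tRNA"],
        "tier1_sam": sam,
        "tier2_m8": m8_nt,
        "tier3_m8": m8_prot,
        "kaiju_votes": votes["kaiju"],
        "centrifuge_votes": votes["centrifuge"],
        "gene_lookup_votes": votes["gene_lookup"],
        "detect": ec_paths["detect"],
        "priam": ec_paths["priam"],
        "diamond_ec_m8": ec_paths["diamond_m8"],
        "protein_ec_map": ec_paths["protein_ec_map"],
        "ec_pairs": ec_paths["ec_pairs"],
        "ec_superpathways": superpathways,
        "nodes_dmp": nodes_path,
        "names_dmp": names_path,
        "accession2taxid": acc_path,
        "gene_lengths": lengths_path,
        "truth": outdir / "truth.tsv",
    }
    return SimulatedSample(
        outdir=outdir, spec=spec, tree=tree, truth=reads.truth,
        gene_ecs=gene_ecs, paths={k: v for k, v in paths.items() if v is not None},
    )
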