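"""Weighted taxonomic consensus over three per-read classification sources.

Each read can receive up to three votes: the taxid inferred from its gene
annotation (via an accession-to-taxid lookup) and the calls of two
short-read classifiers. Votes are merged with a weighted-lineage majority
rule: every nonzero vote deposits its weight on each node of its lineage,
and the consensus is the deepest node holding more than half of the total
deposited weight (ties at equal depth resolve to the LCA of the tied
nodes). Default weights are 0.6 for the gene lookup and 0.2 for each
classifier; unclassified sources (taxid 0) abstain rather than dilute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional

from .taxonomy import AccessionTaxidMap, TaxonomyTree, UNCLASSIFIED_TAXID

VOTE_SOURCES = ("gene_lookup", "kaiju", "centrifuge")


@dataclass(frozen=True)
class ClassifierVote:
    """One source's taxid call for one read (0 = unclassified)."""

    read_id: str
    source: str
    taxid: int

    def __post_init__(self) -> None:
        if self.source not in VOTE_SOURCES:
            raise ValueError(
                f"source must be one of {VOTE_SOURCES}, got {self.source!r}"
            )
        if self.taxid < 0:
            raise ValueError(f"taxid must be >= 0, got {self.taxid}")


@dataclass(frozen=True)
class ConsensusWeights:
    """Per-source vote weights; must be positive and sum to 1."""

    gene_lookup: float = 0.6
    kaiju: float = 0.2
    centrifuge: float = 0.2

    def __post_init__(self) -> None:
        weights = (self.gene_lookup, self.kaiju, self.centrifuge)
        if any(w <= 0 for w in weights):
            raise ValueError("all consensus weights must be positive")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError(f"consensus weights must sum to 1, got {sum(weights)}")

    def of(self, source: str) -> float:
        return getattr(self, source)


def extract_accession(gene_id: str) -> str:
    """Accession token of a gene/protein id (last '|'-separated field)."""
    return gene_id.rsplit("|", 1)[-1]


def gene_vote(
    read_id: str, gene_id: str, accession_map: AccessionTaxidMap
) -> ClassifierVote:
    """Vote derived from a read's annotated gene via the accession lookup.

    An unmapped accession yields taxid 0 (unclassified).
    """
    taxid = accession_map.get(extract_accession(gene_id))
    return ClassifierVote(read_id, "gene_lookup", taxid)


def weighted_consensus(
    votes: Iterable[ClassifierVote],
    tree: TaxonomyTree,
    weights: ConsensusWeights = ConsensusWeights(),
) -> int:
    """Weighted-lineage majority consensus taxid for one read.

    Every nonzero vote deposits its source weight on each node of its
    lineage; with W the total weight of nonzero votes, the deepest node
    with accumulated weight > W/2 wins. Equal-depth ties resolve to the
    LCA of the tied nodes. All votes unclassified -> 0.
    """
    votes = list(votes)
    active = [v for v in votes if v.taxid != UNCLASSIFIED_TAXID]
    if not active:
        return UNCLASSIFIED_TAXID
    accumulated: Dict[int, float] = {}
    total = 0.0
    for vote in active:
        w = weights.of(vote.source)
        total += w
        for node in tree.lineage(vote.taxid):
            accumulated[node] = accumulated.get(node, 0.0) + w
    half = total / 2.0
    candidates = [node for node, w in accumulated.items() if w > half]
    if not candidates:  # root always accumulates the full weight
        return tree.root
    max_depth = max(tree.depth(n) for n in candidates)
    deepest = [n for n in candidates if tree.depth(n) == max_depth]
    if len(deepest) == 1:
        return deepest[0]
    return tree.lca(deepest)


def consensus_all(
    votes_by_read: Mapping[str, Iterable[ClassifierVote]],
    tree: TaxonomyTree,
    weights: ConsensusWeights = ConsensusWeights(),
) -> Dict[str, int]:
    return {
        rid: weighted_consensus(vs, tree, weights)
        for rid, vs in votes_by_read.items()
    }


def taxa_table(
    read_taxids: Mapping[str, int], tree: Optional[TaxonomyTree] = None
) -> Dict[str, int]:
    """Read-pair counts per taxon label.

    Mates of a pair share one read id, so each id contributes one count
    (a fwd+rev pair, a merged read, or a true singleton each count once).
    Taxid 0 is reported as ``Unclassified``.
    """
    counts: Dict[str, int] = {}
    for taxid in read_taxids.values():
        if taxid == UNCLASSIFIED_TAXID:
            label = "Unclassified"
        elif tree is not None:
            label = tree.name(taxid)
        else:
            label = str(taxid)
        counts[label] = counts.get(label, 0) + 1
    return counts


def rank_breakdown(
    read_taxids: Mapping[str, int], tree: TaxonomyTree
) -> Dict[str, float]:
    """Fractions of reads resolved at species, genus, family-or-higher, or
    unclassified.

    A read counts once at the named rank of its consensus node; nodes with
    ``no_rank`` roll to the nearest named ancestor. Fractions sum to 1.
    """
    tallies = {"species": 0, "genus": 0, "family_or_higher": 0, "unclassified": 0}
    n = len(read_taxids)
    if n == 0:
        return {k: 0.0 for k in tallies}
    for taxid in read_taxids.values():
        if taxid == UNCLASSIFIED_TAXID:
            tallies["unclassified"] += 1
            continue
        rank = tree.nearest_named_rank(taxid)
        if rank == "species":
            tallies["species"] += 1
        elif rank == "genus":
            tallies["genus"] += 1
        else:
            tallies["family_or_higher"] += 1
    return {k: v / n for k, v in tallies.items()}


def load_classifier_votes(path, source: str) -> List[ClassifierVote]:
    """Load classifier output TSV rows (classified_flag, read_id, taxid)."""
    votes: List[ClassifierVote] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            flag, read_id, taxid = line.split("\t")[:3]
            votes.append(
                ClassifierVote(
                    read_id,
                    source,
                    int(taxid) if flag.upper() == "C" else UNCLASSIFIED_TAXID,
                )
            )
    return votes


def write_consensus_tsv(
    read_taxids: Mapping[str, int], tree: TaxonomyTree, path
) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttaxid\trank\tlineage\n")
        for rid in sorted(read_taxids):
            taxid = read_taxids[rid]
            if taxid == UNCLASSIFIED_TAXID:
                fh.write(f"{rid}\t0\tunclassified\t\n")
            else:
                lineage = ";".join(tree.name(t) for t in tree.lineage(taxid))
                fh.write(f"{rid}\t{taxid}\t{tree.rank(taxid)}\t{lineage}\n")
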