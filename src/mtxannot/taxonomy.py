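"""NCBI-style taxonomy tree with lineage, rank and ancestor queries.

The tree is a simplified variant of the NCBI taxonomy: a rooted tree of
taxids where each node carries one of the seven named ranks (species,
genus, family, order, class, phylum, superkingdom) or ``no_rank``.
Taxid 0 is reserved for "unclassified" and is never a member of the tree;
short-read classifiers emit 0 when they make no call.

Dump files follow the NCBI ``nodes.dmp``/``names.dmp`` dialect: fields
separated by ``\\t|\\t`` and records terminated by ``\\t|``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping

from .errors import TaxonomyError, TaxonomyParseError

#: Named ranks in root-to-leaf order used for rank-based reporting.
NAMED_RANKS = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

UNCLASSIFIED_TAXID = 0


@dataclass(frozen=True)
class TaxonNode:
    """One node of the taxonomy: taxid, parent, rank and scientific name."""

    taxid: int
    parent_taxid: int
    rank: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.taxid <= 0:
            raise TaxonomyError(f"taxid must be positive, got {self.taxid}")
        if self.parent_taxid <= 0:
            raise TaxonomyError(
                f"parent_taxid must be positive, got {self.parent_taxid} "
                f"for taxid {self.taxid}"
            )


class TaxonomyTree:
    """Rooted taxid tree supporting lineage, LCA and rank lookups.

    Parameters
    ----------
    nodes : mapping of taxid to :class:`TaxonNode`
        Must contain exactly one root (a node whose parent is itself);
        every other node's parent must be present and every lineage must
        terminate at the root.
    """

    def __init__(self, nodes: Mapping[int, TaxonNode]):
        if not nodes:
            raise TaxonomyError("taxonomy must contain at least one node")
        self.nodes: Dict[int, TaxonNode] = dict(nodes)
        roots = [t for t, n in self.nodes.items() if n.parent_taxid == t]
        if len(roots) != 1:
            raise TaxonomyError(
                f"taxonomy must have exactly one root, found {len(roots)}"
            )
        self.root: int = roots[0]
        for taxid, node in self.nodes.items():
            if node.parent_taxid not in self.nodes:
                raise TaxonomyParseError(
                    f"taxid {taxid} has missing parent {node.parent_taxid}"
                )
        # cycle check: every lineage must reach the root within |nodes| steps
        for taxid in self.nodes:
            self.lineage(taxid)
        self._depth_cache: Dict[int, int] = {}

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def parent(self, taxid: int) -> int:
        return self._node(taxid).parent_taxid

    def rank(self, taxid: int) -> str:
        return self._node(taxid).rank

    def name(self, taxid: int) -> str:
        node = self._node(taxid)
        return node.name or str(taxid)

    def _node(self, taxid: int) -> TaxonNode:
        try:
            return self.nodes[taxid]
        except KeyError:
            raise TaxonomyError(f"unknown taxid {taxid}") from None

    def lineage(self, taxid: int) -> List[int]:
        """Root-to-``taxid`` chain of taxids (root first, ``taxid`` last)."""
        chain = [taxid]
        node = self._node(taxid)
        steps = 0
        while node.parent_taxid != node.taxid:
            node = self._node(node.parent_taxid)
            chain.append(node.taxid)
            steps += 1
            if steps > len(self.nodes):
                raise TaxonomyError(f"cycle detected in lineage of taxid {taxid}")
        chain.reverse()
        return chain

    def depth(self, taxid: int) -> int:
        """Number of edges from the root (root has depth 0)."""
        if taxid not in self._depth_cache:
            self._depth_cache[taxid] = len(self.lineage(taxid)) - 1
        return self._depth_cache[taxid]

    def lca(self, taxids: Iterable[int]) -> int:
        """Lowest common ancestor: deepest node on every input lineage."""
        taxids = list(taxids)
        if not taxids:
            raise ValueError("lca of an empty taxid set is undefined")
        lineages = [self.lineage(t) for t in taxids]
        ancestor = self.root
        for level in range(min(len(ln) for ln in lineages)):
            step = {ln[level] for ln in lineages}
            if len(step) != 1:
                break
            ancestor = step.pop()
        return ancestor

    def children(self, taxid: int) -> List[int]:
        self._node(taxid)
        return [
            t
            for t, n in self.nodes.items()
            if n.parent_taxid == taxid and t != taxid
        ]

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """The lineage node holding ``rank``, or None if the lineage skips it."""
        for t in self.lineage(taxid):
            if self.rank(t) == rank:
                return t
        return None

    def nearest_named_rank(self, taxid: int) -> str:
        """Rank of ``taxid``, rolling ``no_rank`` nodes to the closest named ancestor.

        Returns ``no_rank`` only when no ancestor carries a named rank
        (e.g. the root itself).
        """
        for t in reversed(self.lineage(taxid)):
            r = self.rank(t)
            if r in NAMED_RANKS:
                return r
        return "no_rank"


def _parse_dmp_line(line: str) -> List[str]:
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return line.split("\t|\t")


def load_taxonomy(nodes_path, names_path) -> TaxonomyTree:
    """Load a :class:`TaxonomyTree` from NCBI-dialect nodes/names dump files.

    ``nodes.dmp`` columns: taxid | parent taxid | rank | ... ;
    ``names.dmp`` columns: taxid | name | unique name | name class.
    Only ``scientific name`` rows are used for names. Ranks outside the
    seven named levels are mapped to ``no_rank``.
    """
    names: Dict[int, str] = {}
    with open(names_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _parse_dmp_line(line)
            if len(fields) < 4:
                raise TaxonomyParseError(
                    f"names.dmp row has {len(fields)} fields, expected >= 4"
                )
            if fields[3].strip() == "scientific name" or int(fields[0]) not in names:
                names[int(fields[0])] = fields[1].strip()

    nodes: Dict[int, TaxonNode] = {}
    with open(nodes_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _parse_dmp_line(line)
            if len(fields) < 3:
                raise TaxonomyParseError(
                    f"nodes.dmp row has {len(fields)} fields, expected >= 3"
                )
            taxid = int(fields[0])
            parent = int(fields[1])
            rank = fields[2].strip()
            if rank not in NAMED_RANKS:
                rank = "no_rank"
            nodes[taxid] = TaxonNode(taxid, parent, rank, names.get(taxid, ""))
    return TaxonomyTree(nodes)


def write_taxonomy(tree: TaxonomyTree, nodes_path, names_path) -> None:
    """Write ``tree`` back out in the NCBI dump dialect (deterministic order)."""
    with open(nodes_path, "w") as fh:
        for taxid in sorted(tree.nodes):
            n = tree.nodes[taxid]
            fh.write(f"{n.taxid}\t|\t{n.parent_taxid}\t|\t{n.rank}\t|\n")
    with open(names_path, "w") as fh:
        for taxid in sorted(tree.nodes):
            n = tree.nodes[taxid]
            fh.write(f"{n.taxid}\t|\t{n.name or n.taxid}\t|\t\t|\tscientific name\t|\n")


class AccessionTaxidMap:
    """Accession -> taxid lookup, NCBI accession2taxid 4-column TSV dialect."""

    def __init__(self, mapping: Mapping[str, int] | None = None):
        self._map: Dict[str, int] = dict(mapping or {})

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, accession: str) -> bool:
        return accession in self._map

    def get(self, accession: str) -> int:
        """Taxid for ``accession``; 0 (unclassified) when unmapped."""
        return self._map.get(accession, UNCLASSIFIED_TAXID)

    @classmethod
    def load(cls, path) -> "AccessionTaxidMap":
        """Read a 4-column TSV (accession, accession.version, taxid, gi).

        A header row naming the first column ``accession`` is skipped.
        Both the bare accession and the versioned accession are indexed.
        """
        mapping: Dict[str, int] = {}
        with open(path) as fh:
            for i, line in enumerate(fh):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if i == 0 and parts[0] == "accession":
                    continue
                taxid = int(parts[2])
                mapping[parts[0]] = taxid
                if len(parts) > 1 and parts[1]:
                    mapping[parts[1]] = taxid
        return cls(mapping)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("accession\taccession.version\ttaxid\tgi\n")
            for acc in sorted(self._map):
                fh.write(f"{acc}\t{acc}\t{self._map[acc]}\t0\n")
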