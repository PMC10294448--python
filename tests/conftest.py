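import numpy as np
import pytest

from mtxannot.consensus import ConsensusWeights
from mtxannot.simulate import make_taxonomy
from mtxannot.taxonomy import TaxonNode, TaxonomyTree


def brute_force_consensus(votes, tree, weights=ConsensusWeights()):
    """Independent accumulator oracle: explicit per-node weight sums over
    the lineage of every non-abstaining vote."""
    active = [v for v in votes if v.taxid != 0]
    if not active:
        return 0
    acc = {}
    total = 0.0
    for v in active:
        w = weights.of(v.source)
        total += w
        for node in tree.lineage(v.taxid):
            acc[node] = acc.get(node, 0.0) + w
    winners = [n for n, w in acc.items() if w > total / 2]
    best_depth = max(tree.depth(n) for n in winners)
    deepest = sorted(n for n in winners if tree.depth(n) == best_depth)
    return deepest[0] if len(deepest) == 1 else tree.lca(deepest)


@pytest.fixture(scope="session")
def fixture_tree() -> TaxonomyTree:
    """Balanced 7-rank taxonomy with 64 species (2 phyla, binary below)."""
    return make_taxonomy(2, 2, seed=0)


@pytest.fixture(scope="session")
def small_tree() -> TaxonomyTree:
    """Hand-built ~20-node tree with a no_rank internal node and uneven depth.

    root(1) -> Bacteria(2, superkingdom) -> phylum 3 -> class 4 -> order 5
    -> families 6,7 -> genera 8..11 -> species 12..19, plus a no_rank
    clade node 20 between genus 8 and its species 12/13.
    """
    nodes = {
        1: TaxonNode(1, 1, "no_rank", "root"),
        2: TaxonNode(2, 1, "superkingdom", "Bacteria"),
        3: TaxonNode(3, 2, "phylum", "P1"),
        4: TaxonNode(4, 3, "class", "C1"),
        5: TaxonNode(5, 4, "order", "O1"),
        6: TaxonNode(6, 5, "family", "F1"),
        7: TaxonNode(7, 5, "family", "F2"),
        8: TaxonNode(8, 6, "genus", "G1"),
        9: TaxonNode(9, 6, "genus", "G2"),
        10: TaxonNode(10, 7, "genus", "G3"),
        11: TaxonNode(11, 7, "genus", "G4"),
        20: TaxonNode(20, 8, "no_rank", "G1 clade A"),
        12: TaxonNode(12, 20, "species", "G1 sp1"),
        13: TaxonNode(13, 20, "species", "G1 sp2"),
        14: TaxonNode(14, 9, "species", "G2 sp1"),
        15: TaxonNode(15, 9, "species", "G2 sp2"),
        16: TaxonNode(16, 10, "species", "G3 sp1"),
        17: TaxonNode(17, 10, "species", "G3 sp2"),
        18: TaxonNode(18, 11, "species", "G4 sp1"),
        19: TaxonNode(19, 11, "species", "G4 sp2"),
    }
    return TaxonomyTree(nodes)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_101)
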