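"""Read bookkeeping through the filtering stages.

Every read (identified by read id plus mate) is tracked through an
ordered trajectory of categories and must end in exactly one terminal
category, so that terminal-category counts always sum to the raw input
count. The module also implements orphan promotion (a surviving mate of
a filtered pair becomes a singleton), the paired-read filter stringency
rule (high: a hit on either mate filters both; low: only the hitting
mate is filtered and the other is promoted to singleton), exact-duplicate
collapsing with later repopulation, fixed-size chunking, and the
set-algebra used to disambiguate read ids claimed by several categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

from .errors import InvariantError

MATES = ("fwd", "rev", "merged", "single")

#: Categories a read may pass through.
CATEGORY_RAW = "raw"
CATEGORY_LOW_QUALITY = "low_quality"
CATEGORY_HOST = "host"
CATEGORY_VECTOR = "vector"
CATEGORY_RRNA = "rRNA_tRNA"
CATEGORY_MRNA = "putative_mRNA"
CATEGORY_SINGLETON = "singleton"
CATEGORY_ANNOTATED = "annotated"
CATEGORY_UNIDENTIFIED = "unidentified"

#: Categories a read may end in; every read ends in exactly one of these.
TERMINAL_CATEGORIES = frozenset(
    {
        CATEGORY_LOW_QUALITY,
        CATEGORY_HOST,
        CATEGORY_VECTOR,
        CATEGORY_RRNA,
        CATEGORY_ANNOTATED,
        CATEGORY_UNIDENTIFIED,
    }
)

FILTER_CATEGORIES = (CATEGORY_HOST, CATEGORY_VECTOR, CATEGORY_RRNA)


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read with its mate role and phred+33 quality."""

    read_id: str
    mate: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be nonempty")
        if self.mate not in MATES:
            raise ValueError(f"mate must be one of {MATES}, got {self.mate!r}")
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"sequence/quality length mismatch for read {self.read_id}"
            )

    def mean_phred(self) -> float:
        if not self.quality:
            return 0.0
        return sum(ord(c) - 33 for c in self.quality) / len(self.quality)


@dataclass(frozen=True)
class FilterStringency:
    """Paired-read filter behaviour: ``high`` filters both mates on a
    single-mate hit, ``low`` filters only the hitting mate."""

    mode: str = "high"

    def __post_init__(self) -> None:
        if self.mode not in ("high", "low"):
            raise ValueError(f"stringency mode must be high or low, got {self.mode!r}")


class ReadLedger:
    """Per-read category trajectories with conservation guarantees.

    Keys are ``(read_id, mate)`` tuples. Once a read reaches a terminal
    category no further transitions are allowed.
    """

    def __init__(self) -> None:
        self._traj: Dict[Tuple[str, str], List[str]] = {}

    def __len__(self) -> int:
        return len(self._traj)

    def __contains__(self, key: Tuple[str, str]) -> bool:
        return key in self._traj

    def keys(self):
        return self._traj.keys()

    def add_raw(self, read_id: str, mate: str) -> None:
        key = (read_id, mate)
        if key in self._traj:
            raise InvariantError(f"read {key} registered twice")
        self._traj[key] = [CATEGORY_RAW]

    def record(self, read_id: str, mate: str, category: str) -> None:
        key = (read_id, mate)
        traj = self._traj.get(key)
        if traj is None:
            raise InvariantError(f"read {key} was never registered")
        if traj[-1] in TERMINAL_CATEGORIES:
            raise InvariantError(
                f"read {key} already terminal ({traj[-1]}), cannot move to {category}"
            )
        traj.append(category)

    def trajectory(self, read_id: str, mate: str) -> List[str]:
        return list(self._traj[(read_id, mate)])

    def terminal_category(self, read_id: str, mate: str) -> str | None:
        last = self._traj[(read_id, mate)][-1]
        return last if last in TERMINAL_CATEGORIES else None

    def is_terminal(self, read_id: str, mate: str) -> bool:
        return self.terminal_category(read_id, mate) is not None

    def passed_through(self, category: str) -> Set[Tuple[str, str]]:
        return {k for k, t in self._traj.items() if category in t}

    def terminal_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for traj in self._traj.values():
            last = traj[-1]
            counts[last] = counts.get(last, 0) + 1
        return counts

    def assert_complete(self) -> None:
        """Every read must be in a terminal category and counts must conserve."""
        counts = self.terminal_counts()
        bad = set(counts) - TERMINAL_CATEGORIES
        if bad:
            raise InvariantError(f"non-terminal final categories: {sorted(bad)}")
        if sum(counts.values()) != len(self._traj):
            raise InvariantError("terminal counts do not sum to the input count")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tmate\tterminal_category\ttrajectory\n")
            for (rid, mate) in sorted(self._traj):
                traj = self._traj[(rid, mate)]
                fh.write(f"{rid}\t{mate}\t{traj[-1]}\t{';'.join(traj)}\n")

    @classmethod
    def from_tsv(cls, path) -> "ReadLedger":
        ledger = cls()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("read_id"):
                raise InvariantError(f"not a ledger file: {path}")
            for line in fh:
                rid, mate, _, traj = line.rstrip("\n").split("\t")
                ledger._traj[(rid, mate)] = traj.split(";")
        return ledger


@dataclass
class OrphanPromotion:
    """Result of applying per-mate pass flags to read pairs."""

    pairs: List[Tuple[ReadRecord, ReadRecord]] = field(default_factory=list)
    singletons: List[ReadRecord] = field(default_factory=list)
    removed: List[ReadRecord] = field(default_factory=list)


def promote_orphans(
    pairs: Iterable[Tuple[ReadRecord, ReadRecord]],
    pass_flags: Mapping[str, Tuple[bool, bool]],
) -> OrphanPromotion:
    """Split pairs by per-mate pass/fail flags.

    Both mates passing keeps the pair; exactly one passing promotes the
    survivor to the singleton group; neither passing removes both reads.
    """
    out = OrphanPromotion()
    for fwd, rev in pairs:
        fwd_ok, rev_ok = pass_flags[fwd.read_id]
        if fwd_ok and rev_ok:
            out.pairs.append((fwd, rev))
        elif fwd_ok:
            out.singletons.append(fwd)
            out.removed.append(rev)
        elif rev_ok:
            out.singletons.append(rev)
            out.removed.append(fwd)
        else:
            out.removed.extend((fwd, rev))
    return out


def apply_pair_filter(
    hit_flags: Tuple[bool, bool],
    category: str,
    stringency: FilterStringency = FilterStringency("high"),
) -> Tuple[str, str]:
    """Per-mate outcome of a host/vector/rRNA filter on one read pair.

    Returns an outcome per mate: the filter category, ``"pass"`` (the mate
    continues paired), or ``"singleton"`` (the mate continues unpaired
    because its partner was filtered under low stringency).
    """
    if category not in FILTER_CATEGORIES:
        raise ValueError(f"category must be one of {FILTER_CATEGORIES}")
    fwd_hit, rev_hit = hit_flags
    if not (fwd_hit or rev_hit):
        return ("pass", "pass")
    if stringency.mode == "high":
        return (category, category)
    # low stringency: only hitting mates are filtered; the survivor orphans
    return (
        category if fwd_hit else "singleton",
        category if rev_hit else "singleton",
    )


def dedup(reads: Sequence[ReadRecord]) -> Tuple[List[ReadRecord], Dict[str, List[str]]]:
    """Collapse exact full-length sequence duplicates.

    The first occurrence of each distinct sequence becomes the
    representative; the cluster map sends each representative id to all
    member ids (itself included) so the collapse can be undone later.
    """
    reps: List[ReadRecord] = []
    by_seq: Dict[str, str] = {}
    clusters: Dict[str, List[str]] = {}
    for read in reads:
        rep_id = by_seq.get(read.sequence)
        if rep_id is None:
            by_seq[read.sequence] = read.read_id
            reps.append(read)
            clusters[read.read_id] = [read.read_id]
        else:
            clusters[rep_id].append(read.read_id)
    return reps, clusters


def repopulate(
    cluster_map: Mapping[str, List[str]], surviving_rep_ids: Iterable[str]
) -> List[str]:
    """Expand surviving representatives back to all their duplicate members."""
    expanded: List[str] = []
    for rep_id in surviving_rep_ids:
        if rep_id not in cluster_map:
            raise KeyError(f"unknown representative id {rep_id!r}")
        expanded.extend(cluster_map[rep_id])
    return expanded


def chunk(reads: Sequence, chunk_size: int = 50_000) -> List[List]:
    """Split ``reads`` into ordered chunks of ``chunk_size`` (last may be short)."""
    if chunk_size < 1:
        raise ValueError(f"chunk_size must be >= 1, got {chunk_size}")
    return [list(reads[i : i + chunk_size]) for i in range(0, len(reads), chunk_size)]


def disambiguate_categories(
    category_id_sets: Mapping[str, Set[str]],
) -> Tuple[Dict[str, Set[str]], Set[str]]:
    """Resolve read ids claimed by several categories.

    Each output set keeps only the ids unique to that category; ids found
    in two or more input categories go to the ambiguous set. Output sets
    are pairwise disjoint.
    """
    membership: Dict[str, int] = {}
    for ids in category_id_sets.values():
        for rid in ids:
            membership[rid] = membership.get(rid, 0) + 1
    ambiguous = {rid for rid, n in membership.items() if n >= 2}
    resolved = {
        cat: {rid for rid in ids if rid not in ambiguous}
        for cat, ids in category_id_sets.items()
    }
    return resolved, ambiguous


def read_fastq(path) -> List[ReadRecord]:
    """Load a phred+33 FASTQ file into :class:`ReadRecord` objects.

    The mate role is inferred from ``/1`` / ``/2`` id suffixes (stripped
    from the stored read id); anything else is treated as ``single``.
    """
    from Bio import SeqIO

    records: List[ReadRecord] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        rid, mate = rec.id, "single"
        if rid.endswith("/1"):
            rid, mate = rid[:-2], "fwd"
        elif rid.endswith("/2"):
            rid, mate = rid[:-2], "rev"
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        records.append(ReadRecord(rid, mate, str(rec.seq), qual))
    return records


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    """Write reads as 4-line phred+33 FASTQ (byte-deterministic)."""
    suffix = {"fwd": "/1", "rev": "/2", "merged": "", "single": ""}
    with open(path, "w") as fh:
        for read in reads:
            fh.write(
                f"@{read.read_id}{suffix[read.mate]}\n{read.sequence}\n+\n{read.quality}\n"
            )
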