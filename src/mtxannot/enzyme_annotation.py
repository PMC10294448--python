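"""Ensemble Enzyme Commission (EC) annotation with co-occurrence validation.

Three predictor sources are combined per gene/protein: a high-precision
profile tool (DETECT-like, always kept), and the intersection of a
PSSM-based predictor (PRIAM-like) with protein similarity search hits
(DIAMOND-like). Two stringencies are reported: low (similarity e-value
< 1e-5) and high (e-value < 1e-10 and PRIAM probability >= 0.5). Genes
with more than two predicted ECs are reduced to the two highest-scoring,
and a surviving pair must be a known co-occurring pair (curated from
proteins annotated with both ECs) or only the higher-scoring EC is kept.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple

from .errors import ECParseError, InvariantError

EC_PATTERN = re.compile(r"^\d+\.[\d-]+\.[\d-]+\.[\d-]+$")

SOURCES = ("DETECT", "PRIAM", "DIAMOND")


def validate_ec(ec: str) -> str:
    """Return ``ec`` if it is a well-formed EC number, else raise."""
    if not EC_PATTERN.match(ec):
        raise ECParseError(f"malformed EC number {ec!r}")
    return ec


@dataclass(frozen=True)
class ECPrediction:
    """One per-gene EC call from a single source."""

    target_id: str
    ec: str
    source: str
    probability: Optional[float] = None
    evalue: Optional[float] = None

    def __post_init__(self) -> None:
        validate_ec(self.ec)
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")
        if self.source == "DIAMOND" and self.evalue is None:
            raise ValueError("DIAMOND predictions must carry an e-value")
        if self.source == "PRIAM" and self.probability is None:
            raise ValueError("PRIAM predictions must carry a probability")


@dataclass(frozen=True)
class StringencyPolicy:
    """Similarity-search e-value ceiling and optional PRIAM probability floor."""

    evalue_max: float
    priam_prob_min: Optional[float] = None

    @classmethod
    def low(cls) -> "StringencyPolicy":
        return cls(evalue_max=1e-5, priam_prob_min=None)

    @classmethod
    def high(cls) -> "StringencyPolicy":
        return cls(evalue_max=1e-10, priam_prob_min=0.5)


class ECCooccurrenceDB:
    """Unordered pairs of ECs observed together on curated proteins."""

    def __init__(self, pairs: Iterable[Tuple[str, str]] = ()):
        self._pairs: Set[FrozenSet[str]] = set()
        for a, b in pairs:
            self.add(a, b)

    def add(self, ec_a: str, ec_b: str) -> None:
        validate_ec(ec_a)
        validate_ec(ec_b)
        if ec_a == ec_b:
            raise ValueError(f"self-pair {ec_a!r} not allowed")
        self._pairs.add(frozenset((ec_a, ec_b)))

    def __len__(self) -> int:
        return len(self._pairs)

    def contains(self, ec_a: str, ec_b: str) -> bool:
        return frozenset((ec_a, ec_b)) in self._pairs

    @classmethod
    def load(cls, path) -> "ECCooccurrenceDB":
        db = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                a, b = line.split("\t")[:2]
                db.add(a, b)
        return db

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for pair in sorted(tuple(sorted(p)) for p in self._pairs):
                fh.write(f"{pair[0]}\t{pair[1]}\n")


def _group(predictions: Iterable[ECPrediction]) -> Dict[str, Dict[str, ECPrediction]]:
    grouped: Dict[str, Dict[str, ECPrediction]] = {}
    for p in predictions:
        grouped.setdefault(p.target_id, {})[p.ec] = p
    return grouped


def diamond_score(evalue: float) -> float:
    """Comparable scalar for similarity-only calls: 1 - min(evalue, 1)."""
    return 1.0 - min(evalue, 1.0)


def merge_predictions(
    detect: Iterable[ECPrediction],
    priam: Iterable[ECPrediction],
    diamond: Iterable[ECPrediction],
    policy: StringencyPolicy,
) -> Dict[str, Dict[str, float]]:
    """Combine sources per target: all DETECT calls plus the PRIAM-DIAMOND
    intersection passing the policy cutoffs.

    Returns ``{target_id: {ec: unified_score}}`` where the unified score is
    the DETECT probability when present, else the PRIAM probability, else
    a rank-comparable transform of the DIAMOND e-value.
    """
    d_by_target = _group(detect)
    p_by_target = _group(priam)
    x_by_target = _group(diamond)

    result: Dict[str, Dict[str, float]] = {}
    for target in sorted(set(d_by_target) | set(p_by_target) | set(x_by_target)):
        ecs: Dict[str, float] = {}
        detect_calls = d_by_target.get(target, {})
        priam_calls = p_by_target.get(target, {})
        diamond_calls = x_by_target.get(target, {})
        for ec in sorted(set(priam_calls) & set(diamond_calls)):
            pr, dx = priam_calls[ec], diamond_calls[ec]
            if dx.evalue >= policy.evalue_max:
                continue
            if (
                policy.priam_prob_min is not None
                and pr.probability < policy.priam_prob_min
            ):
                continue
            ecs[ec] = pr.probability
        for ec, call in detect_calls.items():
            if call.probability is not None:
                ecs[ec] = call.probability
            elif ec not in ecs:
                ecs[ec] = priam_calls[ec].probability if ec in priam_calls else 1.0
        if ecs:
            result[target] = ecs
    return result


def filter_cooccurrence(
    target_ecs: Mapping[str, float], db: ECCooccurrenceDB
) -> Dict[str, float]:
    """Reduce a multi-EC call to at most two curated-compatible ECs.

    Singletons pass unchanged. More than two ECs are first reduced to the
    two highest-scoring (ties broken by lexicographic EC order); a
    remaining pair absent from the curated database keeps only its
    higher-scoring member.
    """
    if len(target_ecs) <= 1:
        return dict(target_ecs)
    ranked = sorted(target_ecs.items(), key=lambda kv: (-kv[1], kv[0]))
    top = ranked[:2]
    (ec_a, score_a), (ec_b, score_b) = top
    if db.contains(ec_a, ec_b):
        return {ec_a: score_a, ec_b: score_b}
    return {ec_a: score_a}


def annotate_enzymes(
    detect: Iterable[ECPrediction],
    priam: Iterable[ECPrediction],
    diamond: Iterable[ECPrediction],
    db: ECCooccurrenceDB,
) -> Tuple[Dict[str, Dict[str, float]], Dict[str, Dict[str, float]]]:
    """Full per-gene EC annotation at both stringencies, co-occurrence filtered.

    Returns ``(low, high)`` per-target EC->score maps. The high report is
    the restriction of the co-occurrence-filtered low report to the ECs
    that also pass the high-stringency merge, so high is a subset of low
    for every target by construction.
    """
    detect, priam, diamond = list(detect), list(priam), list(diamond)
    low = {
        t: filter_cooccurrence(ecs, db)
        for t, ecs in merge_predictions(
            detect, priam, diamond, StringencyPolicy.low()
        ).items()
    }
    high_merged = merge_predictions(detect, priam, diamond, StringencyPolicy.high())
    high: Dict[str, Dict[str, float]] = {}
    for target, ecs in low.items():
        kept = {
            ec: score
            for ec, score in ecs.items()
            if ec in high_merged.get(target, {})
        }
        if kept:
            high[target] = kept
    return low, high


def write_ec_report(per_target: Mapping[str, Mapping[str, float]], path) -> int:
    """Write one stringency report as TSV; returns the distinct-EC count."""
    distinct: Set[str] = set()
    with open(path, "w") as fh:
        fh.write("target_id\tec\tscore\n")
        for target in sorted(per_target):
            for ec in sorted(per_target[target]):
                fh.write(f"{target}\t{ec}\t{per_target[target][ec]:.6g}\n")
                distinct.add(ec)
    return len(distinct)


def write_ec_reports(
    low: Mapping[str, Mapping[str, float]],
    high: Mapping[str, Mapping[str, float]],
    low_path,
    high_path,
) -> Tuple[int, int]:
    """Write both reports, enforcing the high-subset-of-low invariant."""
    for target, ecs in high.items():
        if not set(ecs) <= set(low.get(target, {})):
            raise InvariantError(
                f"high-stringency ECs for {target!r} not a subset of low-stringency"
            )
    return write_ec_report(low, low_path), write_ec_report(high, high_path)


# ---------------------------------------------------------------------------
# predictor-file loaders


def load_prediction_tsv(path, source: str) -> List[ECPrediction]:
    """Load a DETECT- or PRIAM-like TSV (target, ec, probability)."""
    preds: List[ECPrediction] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "target")):
                continue
            parts = line.split("\t")
            preds.append(
                ECPrediction(parts[0], parts[1], source, probability=float(parts[2]))
            )
    return preds


def load_diamond_ec(m8_path, protein_ec_map_path) -> List[ECPrediction]:
    """Turn a DIAMOND m8 report against an EC-labelled protein set into
    EC predictions via a protein->EC map TSV."""
    from .gene_annotation import read_m8

    protein_ec: Dict[str, List[str]] = {}
    with open(protein_ec_map_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "protein")):
                continue
            prot, ec = line.split("\t")[:2]
            protein_ec.setdefault(prot, []).append(ec)

    preds: List[ECPrediction] = []
    seen: Set[Tuple[str, str]] = set()
    for row in read_m8(m8_path).itertuples(index=False):
        for ec in protein_ec.get(str(row.subject_id), []):
            key = (str(row.query_id), ec)
            if key in seen:
                continue
            seen.add(key)
            preds.append(
                ECPrediction(
                    str(row.query_id), ec, "DIAMOND", evalue=float(row.evalue)
                )
            )
    return preds
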