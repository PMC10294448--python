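"""Pipeline configuration: printed default thresholds plus input paths.

Defaults are the pipeline's documented operating point: 90% CIGAR
coverage, 85% identity, 65% alignment-length fraction, bitscore 60,
EC e-value cutoffs 1e-5 (low) / 1e-10 (high), PRIAM probability 0.5,
consensus weights 0.6/0.2/0.2, 1% taxon rollup cutoff, 50,000-read
chunks. Configuration files are INI-style; keys may live in any section
and absent keys fall back to defaults.
"""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field, fields
from typing import Optional

from .errors import ConfigError
from .gene_annotation import BWA_CONTIG_PARAMS, HitThresholds
from .consensus import ConsensusWeights
from .readflow import FilterStringency

logger = logging.getLogger("mtxannot")

_PATH_FIELDS = (
    "fastq_fwd",
    "fastq_rev",
    "fastq_single",
    "host_hits",
    "vector_hits",
    "rrna_hits",
    "tier1_sam",
    "tier2_m8",
    "tier3_m8",
    "kaiju_votes",
    "centrifuge_votes",
    "detect",
    "priam",
    "diamond_ec_m8",
    "protein_ec_map",
    "ec_pairs",
    "ec_superpathways",
    "nodes_dmp",
    "names_dmp",
    "accession2taxid",
    "gene_lengths",
    "contig_lengths",
)


@dataclass
class PipelineConfig:
    """All knobs and input paths for one single-sample run."""

    # input paths (None = stage input not provided)
    fastq_fwd: Optional[str] = None
    fastq_rev: Optional[str] = None
    fastq_single: Optional[str] = None
    host_hits: Optional[str] = None
    vector_hits: Optional[str] = None
    rrna_hits: Optional[str] = None
    tier1_sam: Optional[str] = None
    tier2_m8: Optional[str] = None
    tier3_m8: Optional[str] = None
    kaiju_votes: Optional[str] = None
    centrifuge_votes: Optional[str] = None
    detect: Optional[str] = None
    priam: Optional[str] = None
    diamond_ec_m8: Optional[str] = None
    protein_ec_map: Optional[str] = None
    ec_pairs: Optional[str] = None
    ec_superpathways: Optional[str] = None
    nodes_dmp: Optional[str] = None
    names_dmp: Optional[str] = None
    accession2taxid: Optional[str] = None
    gene_lengths: Optional[str] = None
    contig_lengths: Optional[str] = None

    # filtering / annotation parameters (printed defaults)
    filter_stringency: str = "high"
    cigar_coverage_min: float = 0.90
    identity_min: float = 85.0
    aln_len_fraction_min: float = 65.0
    bitscore_min: float = 60.0
    ec_evalue_low: float = 1e-5
    ec_evalue_high: float = 1e-10
    priam_prob_min: float = 0.5
    weight_gene_lookup: float = 0.6
    weight_kaiju: float = 0.2
    weight_centrifuge: float = 0.2
    taxa_cutoff: float = 0.01
    heatmap_top_n: int = 20
    chunk_size: int = 50_000
    low_quality_mean_phred: float = 20.0
    keep_interim: str = "keep"

    #: informational BWA parameters for users aligning reads to contig genes
    bwa_contig_params: dict = field(default_factory=lambda: dict(BWA_CONTIG_PARAMS))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def check(cond: bool, name: str, msg: str) -> None:
            if not cond:
                raise ConfigError(f"{name}: {msg}")

        check(self.filter_stringency in ("high", "low"), "filter_stringency",
              "must be 'high' or 'low'")
        check(0.0 <= self.cigar_coverage_min <= 1.0, "cigar_coverage_min",
              "must be in [0, 1]")
        check(0.0 <= self.identity_min <= 100.0, "identity_min",
              "must be in [0, 100]")
        check(0.0 <= self.aln_len_fraction_min <= 100.0, "aln_len_fraction_min",
              "must be in [0, 100]")
        check(self.bitscore_min >= 0.0, "bitscore_min", "must be >= 0")
        check(self.ec_evalue_low > 0.0, "ec_evalue_low", "must be > 0")
        check(self.ec_evalue_high > 0.0, "ec_evalue_high", "must be > 0")
        check(self.ec_evalue_high <= self.ec_evalue_low, "ec_evalue_high",
              "must be <= ec_evalue_low")
        check(0.0 <= self.priam_prob_min <= 1.0, "priam_prob_min",
              "must be in [0, 1]")
        weights = (
            self.weight_gene_lookup, self.weight_kaiju, self.weight_centrifuge
        )
        check(all(w > 0 for w in weights), "consensus weights",
              "must all be positive")
        check(abs(sum(weights) - 1.0) <= 1e-9, "consensus weights",
              f"must sum to 1, got {sum(weights)}")
        check(0.0 <= self.taxa_cutoff <= 1.0, "taxa_cutoff", "must be in [0, 1]")
        check(self.heatmap_top_n >= 1, "heatmap_top_n", "must be >= 1")
        check(self.chunk_size >= 1, "chunk_size", "must be >= 1")
        check(self.keep_interim in ("keep", "compress", "delete"), "keep_interim",
              "must be keep, compress or delete")

    # typed views used by the pipeline stages
    def thresholds(self) -> HitThresholds:
        return HitThresholds(
            cigar_coverage_min=self.cigar_coverage_min,
            identity_min=self.identity_min,
            aln_len_fraction_min=self.aln_len_fraction_min,
            bitscore_min=self.bitscore_min,
        )

    def stringency(self) -> FilterStringency:
        return FilterStringency(self.filter_stringency)

    def consensus_weights(self) -> ConsensusWeights:
        return ConsensusWeights(
            gene_lookup=self.weight_gene_lookup,
            kaiju=self.weight_kaiju,
            centrifuge=self.weight_centrifuge,
        )


def validate_config(path) -> PipelineConfig:
    """Parse an INI-style configuration file into a :class:`PipelineConfig`.

    Keys may appear in any section; absent keys take the printed
    defaults; unknown keys emit a warning; out-of-range values raise
    :class:`~mtxannot.errors.ConfigError` naming the field.
    """
    parser = configparser.ConfigParser()
    read = parser.read(str(path))
    if not read:
        raise ConfigError(f"configuration file not found: {path}")
    known = {f.name: f for f in fields(PipelineConfig)}
    kwargs = {}
    sections = [parser.defaults()] + [
        parser[s] for s in parser.sections()
    ]
    for section in sections:
        for key, raw in section.items():
            key = key.lower()
            if key not in known:
                logger.warning("unknown configuration key %r ignored", key)
                continue
            if key in _PATH_FIELDS:
                kwargs[key] = raw or None
                continue
            default = getattr(PipelineConfig, key, None)
            try:
                if isinstance(default, bool):
                    kwargs[key] = raw.lower() in ("1", "true", "yes")
                elif isinstance(default, int):
                    kwargs[key] = int(raw)
                elif isinstance(default, float):
                    kwargs[key] = float(raw)
                else:
                    kwargs[key] = raw
            except ValueError as exc:
                raise ConfigError(f"{key}: cannot parse value {raw!r}") from exc
    return PipelineConfig(**kwargs)


def write_config(config: PipelineConfig, path) -> None:
    """Write a configuration back out as INI (paths + parameters sections)."""
    parser = configparser.ConfigParser()
    parser["paths"] = {
        name: str(getattr(config, name))
        for name in _PATH_FIELDS
        if getattr(config, name) is not None
    }
    parser["parameters"] = {
        f.name: str(getattr(config, f.name))
        for f in fields(PipelineConfig)
        if f.name not in _PATH_FIELDS and f.name != "bwa_contig_params"
    }
    with open(path, "w") as fh:
        parser.write(fh)
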