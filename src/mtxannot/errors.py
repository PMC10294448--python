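"""Exception hierarchy shared across the toolkit."""


class MtxAnnotError(Exception):
    """Base class for all toolkit errors."""


class TaxonomyError(MtxAnnotError):
    """Structural problem in a taxonomy tree (missing parent, cycle, no root)."""


class TaxonomyParseError(TaxonomyError):
    """Malformed NCBI-dialect dump file."""


class CigarError(MtxAnnotError):
    """Malformed CIGAR string."""


class ECParseError(MtxAnnotError):
    """String is not a valid Enzyme Commission identifier."""


class InvariantError(MtxAnnotError):
    """An internal bookkeeping invariant was violated (e.g. a read assigned twice)."""


class ConfigError(MtxAnnotError):
    """Invalid pipeline configuration value."""
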