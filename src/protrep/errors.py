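"""Exception hierarchy shared across the toolkit."""


class ProtrepError(Exception):
    """Base class for all toolkit errors."""


class FastaParseError(ProtrepError):
    """Malformed FASTA input (reports the offending line number)."""


class AnnotationParseError(ProtrepError):
    """Malformed annotation TSV input."""


class MatrixIntegrityError(ProtrepError):
    """A stored representation matrix fails its integrity checks."""


class TokenizationError(ProtrepError):
    """A sequence character is outside the model vocabulary."""
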