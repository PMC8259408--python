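"""Exception hierarchy for the dirpred package."""


class DirpredError(Exception):
    """Base class for all dirpred errors."""


class InputError(DirpredError):
    """Unreadable, empty or malformed input file."""


class AlignmentShapeError(DirpredError):
    """Rows of an alignment do not share a common length."""


class IdentityError(DirpredError):
    """Duplicate or missing sequence identifiers."""


class AlphabetError(DirpredError):
    """A residue outside the 20-letter amino-acid alphabet (after
    normalization) or outside a substitution matrix's alphabet."""


class DegenerateInputError(DirpredError):
    """Structurally valid input that is degenerate for the requested
    operation (e.g. an all-gap reference row)."""


class PairingError(DirpredError):
    """No species shared between two ortholog alignments."""


class ConsistencyError(DirpredError):
    """Cross-file disagreement, e.g. a paralog's sequence differing
    between the master alignment and its ortholog alignment."""


class ConfigError(DirpredError):
    """Invalid configuration value."""
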