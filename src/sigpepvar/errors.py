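"""Exception hierarchy for sigpepvar."""


class SigPepVarError(Exception):
    """Base class for all sigpepvar errors."""


class InvalidResidueError(SigPepVarError):
    """A character is not one of the 20 standard one-letter residue codes."""


class SequenceError(SigPepVarError):
    """A sequence-level precondition failed (empty, length mismatch,
    zero or multiple substitutions between a WT/mutant pair)."""


class AnnotationError(SigPepVarError):
    """Inconsistent signal-peptide annotation: region boundaries that do not
    tile the sequence, a variant whose reference residue disagrees with the
    stored sequence, or a position outside the annotated record."""


class ConfigError(SigPepVarError):
    """Invalid classification or generator configuration."""


class DesignError(SigPepVarError):
    """A synthetic planting design cannot be satisfied by the peptide set."""
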