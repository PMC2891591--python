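"""Exception hierarchy shared across the package."""


class TransatError(Exception):
    """Base class for all errors raised by this package."""


class AlignmentFormatError(TransatError):
    """A sequence alignment file could not be parsed."""


class ValidationError(TransatError):
    """An in-memory object violates one of its invariants."""


class LeafMismatchError(ValidationError):
    """Tree leaf labels and alignment row identifiers differ as sets."""


class TreeError(TransatError):
    """A phylogenetic tree is malformed (polytomy, missing branch length...)."""


class StructureParseError(TransatError):
    """A dot-bracket / WUSS structure string is malformed."""


class ModelError(TransatError):
    """A substitution model is malformed or fails its reversibility checks."""


class HookError(TransatError):
    """An external-command hook (e.g. realignment) failed."""
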