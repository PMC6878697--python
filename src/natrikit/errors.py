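"""Typed exception hierarchy.

Every parser and analysis stage raises a subclass of :class:`NatrikitError`,
so callers (and the CLI) can distinguish bad user input from internal bugs.
"""


class NatrikitError(Exception):
    """Base class for all package errors."""


class FormatError(NatrikitError):
    """Malformed input file (FASTA, GFF3, Newick, PDB, alignment...)."""


class ValidationError(NatrikitError):
    """Structurally well-formed input violating a domain invariant."""


class PocketDefinitionError(ValidationError):
    """Pocket config disagrees with the reference sequence."""


class SaturationError(NatrikitError):
    """A distance correction is undefined (p beyond its valid range)."""
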