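"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: validation errors exit 2, I/O errors exit 3.
"""


class ExomesiftError(Exception):
    """Base class for all package errors."""


class ValidationError(ExomesiftError):
    """A domain invariant or precondition was violated."""


class ParseError(ValidationError):
    """Malformed input (VCF record, manifest line, codon-change string...)."""


class IntegrityError(ExomesiftError):
    """Packaged fixture failed its checksum."""
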