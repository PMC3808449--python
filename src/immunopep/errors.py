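"""Exception hierarchy."""


class ImmunopepError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ImmunopepError, ValueError):
    """A file or table does not conform to the expected layout."""


class RecordError(ImmunopepError, ValueError):
    """A single record (row, peptide, protein) is invalid."""


class AmbiguousAnchorError(ImmunopepError, ValueError):
    """Anchor derivation hit a tie at the anchor/non-anchor rank boundary."""


class MaskLookupError(ImmunopepError, KeyError):
    """No anchor mask is available for an allele and fallback is disabled."""
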