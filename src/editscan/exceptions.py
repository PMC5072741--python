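"""Exception hierarchy for editscan."""


class EditScanError(Exception):
    """Base class for all editscan errors."""


class ParameterError(EditScanError, ValueError):
    """An argument is outside its documented domain."""


class LengthMismatchError(EditScanError, ValueError):
    """Sequences do not have the length an operation requires."""


class BoundaryError(EditScanError, ValueError):
    """A context window falls outside the contig."""


class NotAdenineCenteredError(EditScanError, ValueError):
    """The strand-resolved center base of a context is not adenine."""

    def __init__(self, site, base):
        self.site = site
        self.base = base
        super().__init__(
            f"context at {site.chrom}:{site.pos}:{site.strand} is not "
            f"adenine-centered (center base {base!r})"
        )


class AmbiguousSequenceError(EditScanError, ValueError):
    """A context window contains too many ambiguous (N) bases."""


class ModelFormatError(EditScanError, ValueError):
    """A model file is corrupt, truncated or of an unsupported version."""
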