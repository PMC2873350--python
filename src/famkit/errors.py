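"""Exception hierarchy shared across the package.

Every error raised on bad user data derives from :class:`FamkitError` so the
command-line layer can map data problems to a single exit code.
"""


class FamkitError(Exception):
    """Base class for all data/usage errors raised by famkit."""


class FormatError(FamkitError):
    """A file does not conform to its declared text format."""


class NewickParseError(FormatError):
    """Malformed Newick input; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character offset {offset})")
        self.offset = offset


class AlignmentError(FamkitError):
    """Invalid input to an alignment operation."""


class PhyloError(FamkitError):
    """Invalid input to a tree-building operation."""
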