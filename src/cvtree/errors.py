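"""Exception hierarchy shared across the package."""


class CVTreeError(Exception):
    """Base class for all package-specific errors."""


class LineageFormatError(CVTreeError):
    """A lineage line violates the tagged-rank dialect."""


class EmptyProteomeError(CVTreeError):
    """A FASTA file yielded no usable protein records."""


class DegenerateGenomeError(CVTreeError):
    """A genome produced no countable windows or a zero-norm vector."""


class OutgroupError(CVTreeError):
    """The designated outgroup does not form one side of a tree edge."""


class DataError(CVTreeError):
    """A matrix or tree fails a structural validity check."""
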