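"""Exception hierarchy shared by all cellanno modules."""


class CellAnnoError(Exception):
    """Base class for package-specific errors."""


class FormatError(CellAnnoError):
    """An input table does not conform to the expected dialect."""


class EmptyInputError(CellAnnoError):
    """An input file contained no usable rows."""


class EmptyDatabaseError(CellAnnoError):
    """A marker database is empty (possibly after filtering)."""


class ConfigError(CellAnnoError):
    """An invalid configuration value was supplied."""
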