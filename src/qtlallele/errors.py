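"""Exception hierarchy for the qtlallele pipeline."""


class QtlAlleleError(Exception):
    """Base class for all package errors."""


class ConfigError(QtlAlleleError):
    """An invalid configuration value; the message names the field."""


class DataError(QtlAlleleError):
    """Malformed or inconsistent input data."""


class GenerationError(QtlAlleleError):
    """The synthetic generator cannot satisfy the requested design."""


class DegenerateCheckError(DataError):
    """Tolerant and sensitive check means coincide in some replication."""
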