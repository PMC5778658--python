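"""Exception hierarchy.

All package-specific failures derive from :class:`TemposigError` so callers
can catch one type at the CLI boundary.  Data problems (malformed tables,
invariant violations) are distinguished from configuration problems
(incompatible scenario/test pairings, bad hyper-parameters) because they map
to different exit codes.
"""


class TemposigError(Exception):
    """Base class for all errors raised by temposig."""


class DataFormatError(TemposigError):
    """A table could not be parsed into a valid dataset (bad header, non-numeric cells)."""


class DataIntegrityError(TemposigError):
    """Parsed data violates a scenario invariant (duplicate measurement occasions,
    within-subject varying static target, repeated subjects in a distinct design)."""


class InsufficientSampleError(TemposigError):
    """Too few measurements, subjects or fold units for the requested operation."""


class ConfigurationError(TemposigError):
    """Invalid hyper-parameters or an incompatible scenario/test pairing."""


class StaleCacheError(TemposigError):
    """A cached univariate table was presented together with different data."""
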