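"""Exception hierarchy.

Every error raised by this package derives from :class:`CalshiftError` so
callers (and the CLI) can map failures to exit codes: config/spec problems,
data problems, and everything else.
"""


class CalshiftError(Exception):
    """Base class for all calshift errors."""


class ConfigError(CalshiftError):
    """Invalid run configuration or population/transient spec."""


class DataError(CalshiftError):
    """Invalid or inconsistent input data."""


class SchemaError(DataError):
    """A file does not conform to the documented on-disk schema."""


class ShapeError(DataError):
    """Tensor dimensions are inconsistent (e.g. ragged trial lengths)."""


class BoundsError(DataError):
    """A requested time window falls outside the recorded span."""


class MissingEventError(DataError):
    """A per-trial alignment event (e.g. head entry) is absent."""


class JoinError(DataError):
    """A registration pair cannot be resolved in a results table."""


class UndefinedMetricError(DataError):
    """A metric is undefined for this neuron (e.g. all-flagged baseline)."""
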