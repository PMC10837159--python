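"""Exception hierarchy for the blood sRNA pipeline.

All errors derive from :class:`BloodSRNAError` so callers can catch the
package's failures with a single except clause; each subclass marks the
pipeline stage or contract that was violated.
"""


class BloodSRNAError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(BloodSRNAError, ValueError):
    """A configuration field is out of its documented range."""


class DataConsistencyError(BloodSRNAError, ValueError):
    """Cross-referenced inputs disagree (e.g. a sample's component has no profile)."""


class VocabularyError(BloodSRNAError, ValueError):
    """A categorical value is outside its fixed vocabulary (RNA class, feature class)."""


class MetadataError(BloodSRNAError, ValueError):
    """Required sample metadata (component label, purity) is missing."""


class CoordinateError(BloodSRNAError, ValueError):
    """A transcript coordinate violates the 1-based convention."""


class UnitsError(BloodSRNAError, ValueError):
    """A matrix carries the wrong units for the requested operation."""


class NormalizationError(BloodSRNAError, ValueError):
    """A sample cannot be normalized (e.g. all-zero library)."""


class ParameterError(BloodSRNAError, ValueError):
    """An analysis parameter is invalid for the data at hand (k, perplexity...)."""


class StatisticsError(BloodSRNAError, ValueError):
    """A statistical routine received too few samples or degenerate groups."""


class SchemaError(BloodSRNAError, ValueError):
    """A table on disk does not match the expected column schema."""
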