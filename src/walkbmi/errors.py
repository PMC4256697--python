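"""Exception hierarchy for walkbmi."""


class WalkbmiError(Exception):
    """Base class for all walkbmi errors."""


class ConfigError(WalkbmiError):
    """Invalid run configuration (bad radius, malformed windows, missing paths)."""


class LayerError(WalkbmiError):
    """A geospatial input layer violates its schema or invariants."""


class OffNetworkError(WalkbmiError):
    """A point could not be attached to the street network within the
    allowed perpendicular offset."""


class RecordError(WalkbmiError):
    """A cohort record is malformed (unparseable dates, non-positive
    anthropometry, unknown codes)."""


class DegenerateInputError(WalkbmiError):
    """An operation received input on which its result is undefined
    (e.g. quartiles of a constant, sidewalk score with only median roads)."""
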