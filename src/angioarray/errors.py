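"""Exception hierarchy for the angioarray pipeline."""


class AngioArrayError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(AngioArrayError):
    """A structured input (panel CSV, layout JSON, config) violates its schema
    or an invariant (duplicate names, wrong spot counts, overlapping disks)."""


class ParameterError(AngioArrayError, ValueError):
    """A caller-supplied parameter is out of its valid range."""


class GeometryError(AngioArrayError):
    """A layout does not fit the image it is applied to."""


class DataError(AngioArrayError):
    """Assembled data are incomplete or inconsistent (missing replicate,
    missing time point, patient mismatch between tables)."""


class QualityControlError(AngioArrayError):
    """A membrane fails quality control and must be rejected, e.g. a
    non-positive reference denominator after background subtraction."""


class ConfigurationError(AngioArrayError):
    """A simulation/analysis plan references unknown entities."""
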