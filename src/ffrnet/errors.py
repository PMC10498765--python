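"""Exception hierarchy."""


class FFRNetError(Exception):
    """Base class for all package errors."""


class SchemaError(FFRNetError):
    """A tree file violates the documented schema; message names the field."""


class TreeStructureError(FFRNetError):
    """Cycle, multiple roots, duplicate ids or other structural defect."""


class DomainError(FFRNetError, ValueError):
    """A scalar input is outside its physical domain."""


class SingularGeometryError(FFRNetError):
    """Geometry with zero/negative lumen area where a resistance is needed."""


class CalibrationError(FFRNetError):
    """Microcirculation calibration produced a non-physical pressure."""


class InputError(FFRNetError, ValueError):
    """Malformed evaluation/physiology input (length mismatch, missing field...)."""
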