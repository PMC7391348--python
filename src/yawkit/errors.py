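"""Exception hierarchy for yawkit."""


class YawkitError(Exception):
    """Base class for all yawkit errors."""


class SchemaError(YawkitError):
    """A required column is missing or cannot be parsed."""


class ValidationError(YawkitError):
    """Input data violate a structural invariant (e.g. non-monotone time)."""


class InsufficientDataError(YawkitError):
    """Too few samples for the requested fit."""


class DegenerateGeometryError(YawkitError):
    """Point cloud is rank-deficient (coplanar/collinear) or otherwise
    cannot constrain an ellipsoid."""


class ConfigError(YawkitError):
    """Pipeline configuration is invalid or refers to missing inputs."""
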