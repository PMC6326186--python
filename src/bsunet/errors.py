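"""Exception types shared across the package."""


class BsunetError(Exception):
    """Base class for package errors."""


class ShapeError(BsunetError):
    """Spatial or channel dimensions violate a layer's preconditions."""


class ConfigError(BsunetError):
    """Invalid network or run configuration."""


class GeometryError(BsunetError):
    """Phantom geometry cannot be realized (overlap / out of frame)."""


class UndefinedMetricError(BsunetError):
    """Metric is undefined for the given inputs (e.g. two empty masks)."""


class NormalizationError(BsunetError):
    """Image cannot be min-max normalized (constant intensity)."""
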