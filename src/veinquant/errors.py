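"""Exception hierarchy for the vein-quantification pipeline."""


class VeinQuantError(Exception):
    """Base class for all package errors."""


class ConfigError(VeinQuantError, ValueError):
    """Invalid generator or run configuration."""


class GeometryError(VeinQuantError):
    """Infeasible or degenerate geometry (e.g. cells do not fit the frame)."""


class AdjacencyError(VeinQuantError, KeyError):
    """Requested cell pair shares no boundary."""


class AxisInferenceError(VeinQuantError):
    """Abaxial axis cannot be inferred from the label map."""


class ClassificationError(VeinQuantError):
    """Position classification impossible (e.g. no bundle-sheath cells)."""


class ProfileError(VeinQuantError):
    """Degenerate wall-thickness profile (e.g. zero baseline)."""


class UndefinedStatisticError(VeinQuantError, ZeroDivisionError):
    """A ratio statistic has a zero denominator."""


class EmptyInputError(VeinQuantError, ValueError):
    """Empty image, label map or ROI where content is required."""
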