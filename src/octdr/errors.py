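"""Named error types shared across the pipeline.

All validation failures raise a subclass of :class:`OctdrError` so callers
(and the CLI) can distinguish bad inputs (exit code 2) from runtime faults.
"""


class OctdrError(Exception):
    """Base class for all package errors."""


class MissingPathError(OctdrError, FileNotFoundError):
    """Input path does not exist."""


class UnsupportedFormatError(OctdrError, ValueError):
    """File extension / container not recognised."""


class ShapeMismatchError(OctdrError, ValueError):
    """Arrays that must share a shape do not."""


class GrayLevelError(OctdrError, ValueError):
    """Gray values fall outside the quantized range [0, Q-1]."""


class LabelValueError(OctdrError, ValueError):
    """Layer labels outside {0, ..., 12}."""


class FeatureSchemaError(OctdrError, ValueError):
    """Feature table missing required columns or layers."""


class EmptyLayerError(OctdrError, ValueError):
    """A retinal layer has no pixels in the volume."""


class GeometryError(OctdrError, ValueError):
    """Phantom layer boundaries would cross or leave the image."""


class ConfigError(OctdrError, ValueError):
    """Run configuration is invalid."""


class TrainingError(OctdrError, ValueError):
    """Classifier training preconditions violated (e.g. single-class data)."""


class FoldError(OctdrError, ValueError):
    """Cross-validation fold request infeasible for the cohort."""
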