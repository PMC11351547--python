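"""Exception hierarchy shared across the pipeline stages."""


class EchocalcError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(EchocalcError):
    """A synthetic scene element would cross the ultrasound cone boundary."""


class DetectionError(EchocalcError):
    """Cone extraction found no usable foreground."""


class FormatError(EchocalcError):
    """An input file is not in the expected format (e.g. non-image DICOM)."""


class SchemaError(EchocalcError):
    """A CSV/tabular input is missing required columns."""


class BoundsError(EchocalcError):
    """A bounding box exceeds the image extent."""


class BoxLostError(EchocalcError):
    """A geometric augmentation pushed the annotation box fully off-canvas."""

    def __init__(self, message: str, image_id: str | None = None):
        super().__init__(message if image_id is None else f"{message} (image {image_id!r})")
        self.image_id = image_id


class BalanceError(EchocalcError):
    """Class balancing is impossible (a class is empty)."""


class ConfigError(EchocalcError):
    """Unknown backbone/pooling or otherwise invalid model configuration."""


class DataError(EchocalcError):
    """A training split is empty or degenerate (e.g. one class only)."""


class LengthError(EchocalcError):
    """Paired label/prediction vectors have different lengths."""
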