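"""Exception hierarchy shared across the package."""


class MaskGanError(Exception):
    """Base class for all package-specific errors."""


class ShapeMismatch(MaskGanError):
    """Two arrays that must share a shape do not."""


class DegenerateImage(MaskGanError):
    """An image whose statistics make the requested operation undefined
    (e.g. zero variance under standardization)."""


class UnsupportedFormat(MaskGanError):
    """File format not handled by the readers/writers."""


class CorruptFile(MaskGanError):
    """A file that exists but cannot be decoded."""


class InfeasibleSpec(MaskGanError):
    """A phantom specification whose lesions cannot fit inside the organ."""


class EmptyMask(MaskGanError):
    """A tumor mask with no positive pixels where one is required."""


class EmptyInput(MaskGanError):
    """An empty collection where at least one element is required."""


class OutOfBounds(MaskGanError):
    """A stencil or crop that exceeds the image extent."""


class InvalidConfig(MaskGanError):
    """A network or training configuration violating its invariants."""


class EmptyDataset(MaskGanError):
    """Training requested on an empty dataset."""


class DivergedTraining(MaskGanError):
    """A loss became non-finite during training."""


class ConfigError(MaskGanError):
    """A run configuration file or override failed validation.

    The message names the offending field.
    """
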