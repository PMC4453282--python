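"""Exception hierarchy for the SILI pipelines.

Every error raised by the library derives from :class:`SiliError` so that
CLI entry points can map failures onto stage-labelled messages and exit
codes without catching bare ``Exception``.
"""


class SiliError(Exception):
    """Base class for all SILI errors."""


class ConfigurationError(SiliError):
    """Invalid phantom geometry or pipeline configuration."""


class ParameterError(SiliError):
    """Attack or operation parameter outside its documented range."""


class KeyLengthError(SiliError):
    """DES user key is not exactly 8 bytes."""


class DimensionError(SiliError):
    """Two images compared by a metric do not share a shape."""


class SegmentationError(SiliError):
    """Lung-field segmentation could not produce two lobes."""


class EmptyBandError(SegmentationError):
    """The two lobes leave no column gap, so there is no inter-lobe band."""


class GeometryError(SiliError):
    """A RoniMap does not belong to the image it is applied to."""


class CapacityError(SiliError):
    """Host capacity constraint violated; nothing was embedded."""


class MalformedIndexError(SiliError):
    """No character cap found while reading an embedded index."""


class AuthenticationAlert(SiliError):
    """Watermark header failed verification: wrong key or corrupted image.

    Raised fail-closed: no payload is ever returned alongside this alert.
    """
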