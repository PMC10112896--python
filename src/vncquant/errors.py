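"""Exception types shared across the package."""


class VncQuantError(Exception):
    """Base class for all vncquant errors."""


class ConfigurationError(VncQuantError, ValueError):
    """A spec/config field is invalid; the message names the field."""


class DegenerateImageError(VncQuantError, ValueError):
    """The image cannot be analysed (e.g. a constant image has a degenerate histogram)."""


class ShapeMismatchError(VncQuantError, ValueError):
    """Arrays that must share a shape do not."""


class LandmarkError(VncQuantError, ValueError):
    """Landmark tracts required to delimit the medial region were not found."""
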