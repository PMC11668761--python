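"""Exception hierarchy shared across the package."""


class LocmorphError(Exception):
    """Base class for all package errors."""


class FormatError(LocmorphError, ValueError):
    """A file does not conform to the expected on-disk format."""


class ShapeError(LocmorphError, ValueError):
    """Array dimensions or grids are incompatible."""


class ValidationError(LocmorphError, ValueError):
    """Input values violate a documented precondition."""
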