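"""Exception hierarchy for specchem."""


class SpecchemError(Exception):
    """Base class for all specchem errors."""


class FormatError(SpecchemError):
    """A file violates the expected on-disk dialect (non-uniform grid, bad cell)."""


class GridError(SpecchemError):
    """A wavelength or range does not lie on the spectral grid."""


class DesignError(SpecchemError):
    """Invalid or unsupported experimental-design specification."""


class ModelError(SpecchemError):
    """Calibration model cannot be fitted or applied as requested."""
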