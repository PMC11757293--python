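"""Exception hierarchy shared by all lpwave modules."""


class LPWaveError(Exception):
    """Base class for all lpwave errors."""


class ConfigurationError(LPWaveError):
    """Invalid option, unknown wavelet name, or inconsistent configuration."""


class DepthError(ConfigurationError):
    """Image too small for the requested decomposition depth."""


class InputError(LPWaveError):
    """Malformed input data: shape mismatch, empty grid, non-finite values."""


class StructuralError(LPWaveError):
    """Wavelet pyramid with inconsistent subband bookkeeping."""


class NumericalError(LPWaveError):
    """A numeric stage produced non-finite values."""
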