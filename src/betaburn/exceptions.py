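"""Exception hierarchy for betaburn."""


class BetaburnError(Exception):
    """Base class for all betaburn errors."""


class UnsupportedElementError(BetaburnError):
    """An element symbol has no cross-section data."""


class EnergyRangeError(BetaburnError):
    """Photon energy outside the supported 5-25 keV range."""


class InfeasibleProtocolError(BetaburnError):
    """The requested experiment cannot satisfy its constraints."""


class CalibrationError(BetaburnError):
    """Noise-gain calibration cannot reach the requested target."""


class InsufficientDataError(BetaburnError):
    """Too few observations for the requested fit."""


class DegenerateFitError(BetaburnError):
    """Fewer than two usable resolution shells for scale/B fitting."""


class ReflectionParseError(BetaburnError):
    """A reflection file could not be parsed."""


class XdsFormatError(ReflectionParseError):
    """An XDS_ASCII file is missing required header declarations."""
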