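"""Exception hierarchy for the REG Poincaré toolkit."""


class RegPoincareError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RegPoincareError, ValueError):
    """A synthesis or analysis configuration violates its invariants."""


class TooShortError(RegPoincareError, ValueError):
    """A record is too short for the requested operation."""


class LagError(RegPoincareError, ValueError):
    """The embedding lag is outside the admissible range for the series."""


class DegeneratePlotError(RegPoincareError, ValueError):
    """A Poincaré plot has zero variance along a required axis."""


class InsufficientPulsesError(RegPoincareError, ValueError):
    """Fewer than the minimum number of complete pulses were detected."""


class InsufficientDataError(RegPoincareError, ValueError):
    """A statistical operation received too few observations."""


class NoPeriodError(RegPoincareError, ValueError):
    """No dominant cycle period could be found in the physiological band."""


class CriterionNotFoundError(RegPoincareError, ValueError):
    """A lag-selection criterion was not reached within the scanned range."""


class ClassError(RegPoincareError, ValueError):
    """Class labels are missing or degenerate for a supervised operation."""
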