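"""Exception and warning hierarchy shared by all modules."""


class CoastalCH4Error(Exception):
    """Base class for all package errors."""


class SchemaError(CoastalCH4Error):
    """A required column or key is missing from an input file."""


class ValidationError(CoastalCH4Error):
    """Input values violate a structural invariant (e.g. non-monotone depths)."""


class UnitError(CoastalCH4Error):
    """A column declares an unknown unit, or units contradict each other."""


class ConfigError(CoastalCH4Error):
    """A site or run configuration is incomplete or inconsistent."""


class DataError(CoastalCH4Error):
    """Data are structurally valid but unusable for the requested computation."""


class ParameterError(CoastalCH4Error):
    """An unsupported solute, model name, or out-of-range parameter."""


class SyntheticSpecError(CoastalCH4Error):
    """A synthetic-site specification is physically infeasible."""


class CoastalCH4Warning(UserWarning):
    """Base warning category."""


class ExtrapolationWarning(CoastalCH4Warning):
    """A parameterization was evaluated outside its stated validity range."""


class NonLinearSeriesWarning(CoastalCH4Warning):
    """A chamber series departs from linearity (R^2 below threshold)."""


class InverseFractionationWarning(CoastalCH4Warning):
    """A Rayleigh fit implies alpha < 1 (inverse isotope effect)."""


class DegenerateDataWarning(CoastalCH4Warning):
    """Ranks or endmembers are degenerate; result is undefined or clipped."""
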