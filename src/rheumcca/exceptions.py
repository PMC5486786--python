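"""Exception hierarchy for rheumcca.

All package errors derive from :class:`RheumCCAError` so callers can catch a
single base class at tool boundaries (CLI, scripts) while library code raises
the most specific subclass.
"""


class RheumCCAError(Exception):
    """Base class for all rheumcca errors."""


class ValidationError(RheumCCAError, ValueError):
    """An input table violates a documented invariant.

    Where possible the message carries file/row (or key) coordinates so a
    failing deck cell can be located directly.
    """


class DeckIncompleteError(RheumCCAError, FileNotFoundError):
    """An input deck directory is missing one of its component files."""


class UnsupportedCountryError(RheumCCAError, KeyError):
    """A country code outside the bundled set {DE, IT, ES, US, CA} was requested."""


class MissingInputError(RheumCCAError, KeyError):
    """A (subgroup, arm) or event class lookup failed on an input table."""


class MissingPriceError(RheumCCAError, KeyError):
    """A drug or event class has no unit price in the country cost table."""


class ComparabilityError(RheumCCAError, ValueError):
    """Two arm-level results cannot be compared (different n, subgroup or currency)."""


class DomainError(RheumCCAError, ValueError):
    """A scalar argument is outside its mathematical domain (negative titre, etc.)."""


class NotVariableError(RheumCCAError, ValueError):
    """A fixed or zero-mean parameter was asked to vary in the sensitivity analysis."""


class BetaInfeasibleError(RheumCCAError, ValueError):
    """The requested (mean, SD) pair admits no beta distribution.

    With the SD-equal-to-mean convention this happens for every mean >= 0.5.
    ``clamped_sd`` carries the documented fallback: 95% of the maximum feasible
    standard deviation sqrt(mean*(1-mean)).
    """

    def __init__(self, mean: float, sd: float, clamped_sd: float):
        super().__init__(
            f"no beta distribution has mean={mean} and sd={sd} "
            f"(requires sd^2 < mean*(1-mean)); feasible fallback sd={clamped_sd:.6g}"
        )
        self.mean = mean
        self.sd = sd
        self.clamped_sd = clamped_sd
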