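"""Exception hierarchy shared across the pipeline stages."""


class EpisurgError(Exception):
    """Base class for all errors raised by episurg."""


class CountryNotFoundError(EpisurgError, LookupError):
    """Requested country is absent from a case-count file."""

    def __init__(self, country: str, available: list[str]):
        self.country = country
        self.available = sorted(available)
        preview = ", ".join(self.available[:15])
        more = "" if len(self.available) <= 15 else f", … ({len(self.available)} total)"
        super().__init__(f"country {country!r} not found; available: {preview}{more}")


class FormatError(EpisurgError, ValueError):
    """Input file does not follow the expected dialect."""


class InsufficientDataError(EpisurgError, ValueError):
    """Series too short for the requested operation."""


class DegenerateBandsError(EpisurgError, ValueError):
    """Tertile bands cannot be formed (e.g. all-zero incidence)."""


class CoverageError(EpisurgError, ValueError):
    """A requested date window falls outside the available series."""


class DegenerateComparisonError(EpisurgError, ValueError):
    """A group comparison has an empty group or otherwise cannot be tested."""


class DegenerateTestError(EpisurgError, ValueError):
    """A statistical test cannot be performed (constant variable, zero variance)."""


class ValidationError(EpisurgError, ValueError):
    """Invalid record, grade label or model specification."""


class NotConvergedError(EpisurgError, RuntimeError):
    """Downstream quantity requested from a non-converged model fit."""
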