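"""Exception hierarchy for the OFFL toolkit."""

from __future__ import annotations


class OfflError(Exception):
    """Base class for all errors raised by this package."""


class NameCollision(OfflError):
    """A species, interaction, or parameter name is already taken."""


class DomainError(OfflError):
    """A numeric argument is outside its allowed domain."""


class DanglingReference(OfflError):
    """An edge or expression refers to a species that does not exist."""


class GrammarError(OfflError):
    """A construction request violates the diagram grammar."""


class InvalidModel(OfflError):
    """A model failed grammar validation.

    Carries the list of error-severity violations in ``violations``.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(str(v) for v in self.violations)
        super().__init__(f"model failed validation: {lines}")


class MissingBinding(OfflError):
    """A free parameter was left without a numeric value."""


class IntegrationError(OfflError):
    """The numeric ODE solver failed to produce a trajectory."""


class ParseError(OfflError):
    """A model file or table could not be parsed.

    ``location`` identifies the file and, where known, the line or record.
    """

    def __init__(self, message: str, location: str | None = None):
        self.location = location
        super().__init__(f"{location}: {message}" if location else message)
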