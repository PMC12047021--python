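"""Exception hierarchy.

All package-specific failures derive from :class:`MixRiskError` so callers
can catch one base class at pipeline boundaries.  Domain violations on
numeric arguments (negative concentrations, zero hazard values, ...) raise
:class:`DomainError`, a ``ValueError`` subclass.
"""


class MixRiskError(Exception):
    """Base class for all mixrisk errors."""


class DomainError(MixRiskError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class InvalidConfigError(MixRiskError, ValueError):
    """A configuration object violates its invariants."""


class InvalidDesignError(MixRiskError, ValueError):
    """A test design is unusable (e.g. missing control levels)."""


class UnsupportedEndpointError(MixRiskError, ValueError):
    """An ecotoxicity endpoint type is not one of NOEC / EC50 / LC50."""


class MissingHazardError(MixRiskError, LookupError):
    """No hazard endpoint available for a pesticide.

    Carries the pesticide name so reports can say *which* substance lacks
    effect data.
    """

    def __init__(self, pesticide: str, message: str | None = None):
        self.pesticide = pesticide
        super().__init__(message or f"no hazard endpoint available for {pesticide!r}")


class UndefinedMECError(MixRiskError, ValueError):
    """A median measured concentration cannot be computed (no detects)."""


class SchemaError(MixRiskError, ValueError):
    """An input table does not match its declared schema."""


class ValidationError(MixRiskError, ValueError):
    """Row-level violations found while validating an input table."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "table validation failed:\n" + "\n".join(f"  - {v}" for v in self.violations)
        )


class StageError(MixRiskError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
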