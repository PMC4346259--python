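"""Exception types shared across the package."""


class TidalRiskError(Exception):
    """Base class for package errors."""


class DomainError(TidalRiskError, ValueError):
    """An input is outside its mathematically valid domain (e.g. a probability > 1)."""


class ConfigError(TidalRiskError, ValueError):
    """A configuration block is structurally invalid or infeasible."""


class ValidityError(TidalRiskError, ValueError):
    """A statistical validity rule is violated (e.g. too few observations per level)."""


class ScenarioValidationError(ConfigError):
    """A scenario configuration failed validation; carries every violation found."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "scenario configuration invalid:\n  - " + "\n  - ".join(self.violations)
        )
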