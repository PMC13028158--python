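"""Typed exceptions raised by fesnet."""


class FesnetError(Exception):
    """Base class for all package errors."""


class FormulaError(FesnetError):
    """Invalid or unparseable molecular formula."""


class BalanceError(FesnetError):
    """A formation reaction cannot be balanced against the reference set."""


class MissingEnergyError(FesnetError):
    """An operation required a free energy that is not available."""

    def __init__(self, missing_ids, message=None):
        self.missing_ids = sorted(missing_ids)
        super().__init__(
            message or f"missing free energies for: {', '.join(self.missing_ids)}"
        )


class ValidationError(FesnetError):
    """A domain-type invariant was violated."""


class TableError(FesnetError):
    """Malformed delimited-text input; carries a line number when known."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SimulationError(FesnetError):
    """ODE integration failed; carries the last valid state."""

    def __init__(self, message, t_last=None, y_last=None):
        self.t_last = t_last
        self.y_last = y_last
        super().__init__(message)
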