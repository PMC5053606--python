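"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A generator or model parameter is outside its admissible range."""


class EdgeListParseError(ValueError):
    """An edge-list file contains a malformed line."""

    def __init__(self, path, line_number, line):
        self.path = str(path)
        self.line_number = line_number
        self.line = line
        super().__init__(
            f"{self.path}:{line_number}: expected two whitespace-separated "
            f"node tokens, got {line!r}"
        )


class InfeasibleSeedingError(RuntimeError):
    """The requested seed budget cannot be filled from the population."""


class ConfigurationError(ValueError):
    """An experiment or estimator configuration is inconsistent."""


class UndefinedMetricError(ZeroDivisionError):
    """A metric denominator is zero (e.g. total resource of the network)."""
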