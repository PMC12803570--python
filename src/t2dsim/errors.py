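"""Exception hierarchy shared across the package."""


class T2DSimError(Exception):
    """Base class for all package errors."""


class ConfigError(T2DSimError):
    """Invalid configuration: bad coefficient file, missing factor limits, ..."""


class SchemaError(ConfigError):
    """A delimited input file does not match the expected column schema."""


class StratumError(ConfigError):
    """An imputation stratum is empty and no fallback is available."""


class EvaluationError(T2DSimError):
    """An equation referenced a covariate absent from the participant state."""
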