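"""Exception hierarchy shared across the package."""


class AffinityGanError(Exception):
    """Base class for all package errors."""


class ConfigError(AffinityGanError, ValueError):
    """Invalid configuration value (bad length, mode, k, interval...)."""


class InputError(AffinityGanError, ValueError):
    """Invalid runtime input (empty corpus, shape mismatch, NaN labels...)."""


class FormatError(AffinityGanError, ValueError):
    """Malformed input file (bad FASTA header, missing column, bad number)."""


class UndefinedStatisticError(AffinityGanError, ValueError):
    """A statistic is undefined for the given data (e.g. CI with all-equal y)."""


class StateError(AffinityGanError, RuntimeError):
    """Operation called in an invalid state (e.g. predict before training)."""
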