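"""Exception hierarchy shared across the toolkit."""


class EarError(Exception):
    """Base class for all earkit errors."""


class FormatError(EarError):
    """A tabular or FASTA input does not have the expected shape."""


class InputError(EarError):
    """Input values violate an operation's preconditions."""


class ResidueError(InputError):
    """A sequence contains a character outside the 20-letter alphabet."""


class ConfigurationError(EarError):
    """Inconsistent thresholds, modes or family parameters."""


class StratificationError(EarError):
    """A class-stratified split or fold cannot be formed."""


class EvaluationError(EarError):
    """A performance measure is undefined for the given inputs."""
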