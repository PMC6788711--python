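"""Exception hierarchy shared across the package."""


class RobustMcNemarError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RobustMcNemarError):
    """A configuration problem: missing column, malformed coarsening rule."""


class ValidationError(RobustMcNemarError):
    """Row- or value-level data problem: non-binary outcome, duplicate id."""


class NoCommonSupportError(RobustMcNemarError):
    """Every exact-match cell lacks one of the two arms; no pair can be formed."""


class NoDiscordantPairsError(RobustMcNemarError):
    """B_max + C_max = 0: the test statistic is undefined."""


class InfeasibleError(RobustMcNemarError):
    """A requested total discordant-pair count m lies outside [1, B_max + C_max]."""


class OracleSizeError(RobustMcNemarError):
    """Instance exceeds the exhaustive enumerator's size guard."""
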