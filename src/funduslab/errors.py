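"""Exception hierarchy shared across the pipeline.

The CLI maps these onto process exit codes (input 2, config 3,
generation/scoring 4); library callers catch them directly.
"""


class FunduslabError(Exception):
    """Base class for all package errors."""


class InputError(FunduslabError):
    """Unreadable, malformed or contract-violating input data."""


class ConfigError(FunduslabError):
    """Invalid configuration value or profile mismatch."""


class GenerationError(FunduslabError):
    """Synthetic scene construction could not satisfy its constraints."""


class ScoringError(FunduslabError):
    """A candidate region could not be scored (e.g. no usable outer ring)."""
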