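"""Exception types used across the pipeline."""


class TedynError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TedynError):
    """Invalid configuration values."""


class PlacementError(TedynError):
    """Simulated copies cannot be placed inside the background genome."""


class InputError(TedynError):
    """Malformed input data (bad FASTA, bad characters, bad tables)."""


class FitError(TedynError):
    """A statistical fit could not be carried out."""
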