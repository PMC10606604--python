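"""Exception hierarchy with stage-specific exit codes for the CLI."""


class DiamotionError(Exception):
    """Base class for all pipeline errors. ``exit_code`` identifies the stage."""

    exit_code = 1


class ReaderError(DiamotionError):
    """Mask series could not be read or failed its invariants."""

    exit_code = 2


class ProfileError(DiamotionError):
    """Profile extraction failed (e.g. too many invalid frames)."""

    exit_code = 3


class SelectionError(DiamotionError):
    """Common-range selection produced no usable range."""

    exit_code = 4


class InsufficientCyclesError(DiamotionError):
    """Fewer than two respiration peaks detected on a waveform."""

    exit_code = 5


class DegenerateWaveformError(DiamotionError):
    """A constant (zero-energy) waveform has no defined NCC."""

    exit_code = 6


class CoverageError(DiamotionError):
    """A sampled position is missing from the profile in too many frames."""

    exit_code = 7


class ConfigError(DiamotionError):
    """Invalid configuration value."""

    exit_code = 8
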