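"""Exception hierarchy shared across the pipeline stages."""


class CoreMKError(Exception):
    """Base class for all errors raised by this package."""


class InputError(CoreMKError):
    """Malformed or inconsistent user input (IDs, label sets, missing files)."""


class AlignmentError(InputError):
    """Sequences in an alignment do not have equal lengths."""


class FrameError(InputError):
    """Sequence length is not a multiple of three."""


class ConsistencyError(CoreMKError):
    """A protein alignment does not match the translation of its CDS."""


class QCError(CoreMKError):
    """Alignment is unusable after trimming (e.g. no gap-free flank)."""


class DistanceError(CoreMKError):
    """A pairwise distance is undefined (saturation or no comparable sites)."""


class CountError(CoreMKError):
    """No usable codon columns for polymorphism/divergence counting."""


class AggregateError(CoreMKError):
    """The pooled core-genome statistic is undefined (zero denominator)."""


class ConfigError(CoreMKError):
    """Invalid configuration value."""
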