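"""Exception hierarchy shared across the pipeline stages."""


class SeedViabError(Exception):
    """Base class for all seedviab errors."""


class AlphabetError(SeedViabError):
    """A sequence contains characters outside {A, C, G, U/T}."""


class ReadTooShortError(SeedViabError):
    """A read is shorter than 7 nt and carries no position 2-7 seed."""


class ViabilityTableError(SeedViabError):
    """The viability lookup is incomplete, duplicated or malformed."""


class AnnotationError(SeedViabError):
    """Reference matching or miRNA-name resolution failed."""


class ConfigError(SeedViabError):
    """A pipeline or simulation configuration value is out of its domain."""
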