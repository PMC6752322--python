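"""Exception hierarchy for the noamp pipeline."""


class NoampError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(NoampError):
    """A locus definition, template pool or run configuration is invalid."""


class InputError(NoampError):
    """An input (read set, file, argument) is empty, malformed or unreadable."""


class AmbiguousReadError(NoampError):
    """A read anchored to more than one locus; the loci are not distinguishable."""
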