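"""Exception hierarchy shared across the package."""


class TileMethError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(TileMethError, ValueError):
    """A simulation or run specification violates its invariants."""


class FormatError(TileMethError, ValueError):
    """An input file violates the documented dialect."""


class CompletenessError(TileMethError, ValueError):
    """A table is missing entries required by the design."""


class DomainError(TileMethError, ValueError):
    """A numerical operation received values outside its domain."""


class PipelineError(TileMethError, RuntimeError):
    """An end-to-end run failed; the message names the failing stage."""
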