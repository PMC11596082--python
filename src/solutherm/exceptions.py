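"""Exception hierarchy for solutherm."""


class SoluthermError(Exception):
    """Base class for all solutherm errors."""


class GridValidationError(SoluthermError, ValueError):
    """A solubility grid or point violates an invariant."""


class GridFormatError(SoluthermError, ValueError):
    """An input file cannot be parsed into a solubility grid."""


class InsufficientDataError(SoluthermError, ValueError):
    """Too few points for the requested fit."""


class DomainError(SoluthermError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class ConsistencyError(SoluthermError, ValueError):
    """Two results that must share a reference state do not."""
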