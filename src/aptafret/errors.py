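"""Exception hierarchy shared across analysis modules."""


class AptaFretError(Exception):
    """Base class for all package errors."""


class MissingDataError(AptaFretError, KeyError):
    """A required record (channel reading, band, replicate) is absent."""


class DegenerateInputError(AptaFretError, ValueError):
    """Input is formally valid but numerically unusable (zero denominator,
    collinear points, empty selection)."""


class DesignParseError(AptaFretError, ValueError):
    """An aptamer-placement design string does not match the grammar."""


class SelectorError(AptaFretError, ValueError):
    """A ligand selector matched nothing, or atom correspondence is broken."""
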