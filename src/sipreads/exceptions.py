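"""Exception hierarchy for sipreads.

All simulator errors derive from :class:`SipReadsError` so callers can catch
one base class; the CLI maps :class:`ConfigurationError` to exit code 1 and
everything else to exit code 2.
"""


class SipReadsError(Exception):
    """Base class for all sipreads errors."""


class DomainError(SipReadsError, ValueError):
    """A numeric argument is outside the physical/mathematical domain."""


class ConfigurationError(SipReadsError, ValueError):
    """Invalid configuration, table, or parameter specification."""


class InputError(SipReadsError, ValueError):
    """Malformed or empty input data (e.g. an empty FASTA file)."""


class GeometryError(SipReadsError, ValueError):
    """A tube position falls outside the centrifuge-tube geometry."""


class OutOfGradientError(GeometryError):
    """A buoyant density has no equilibrium position inside the gradient.

    Raised when the radicand of the equilibrium-position equation is
    negative, i.e. the fragment is lighter than any solution density in
    the tube and floats off-gradient.
    """

    def __init__(self, rho: float, message: str | None = None):
        self.rho = rho
        super().__init__(
            message
            or f"buoyant density {rho:.6g} g/ml has no equilibrium position in the gradient"
        )


class EmptyLibraryError(SipReadsError, ValueError):
    """No fragment carries positive read abundance in the requested window."""
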