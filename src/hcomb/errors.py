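"""Exception hierarchy."""


class HcombError(Exception):
    """Base class for all package errors."""


class ParseError(HcombError):
    """Structure input could not be parsed."""


class UnsupportedElement(ParseError):
    """Molecule contains an element outside H, B, C, N, O, P, S, Si, halogen."""


class UnknownAtomType(HcombError):
    """A backbone atom cannot be assigned an atom-type token."""


class GeometryRequired(HcombError):
    """A 3D-dependent special group was requested without coordinates."""


class DataIntegrityError(HcombError):
    """Packaged contribution table failed its count/checksum audit."""


class ElementNotSupported(HcombError):
    """No element-combustion constant available for a formula element."""


class ConvergenceError(HcombError):
    """Gauss-Seidel iteration did not converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None, n_iter=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.n_iter = n_iter


class NonIdentifiableError(ConvergenceError):
    """The normal-equation system is rank deficient (collinear group columns)."""
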