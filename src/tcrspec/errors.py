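"""Exception hierarchy."""


class TcrspecError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(TcrspecError, ValueError):
    """A physical parameter is outside its admissible range."""


class FitFailureError(TcrspecError, RuntimeError):
    """A least-squares fit did not converge; message carries diagnostics."""


class OutOfRangeError(TcrspecError, ValueError):
    """A measured response is outside the invertible range of the model."""


class MotifError(TcrspecError, ValueError):
    """A peptide does not match the anchored nonamer motif."""


class IncompleteLibraryError(TcrspecError, ValueError):
    """A positional-scanning library is missing cells; message lists gaps."""


class NoTransitionError(TcrspecError, ValueError):
    """A melt curve shows no detectable unfolding transition."""


class StructureError(TcrspecError, ValueError):
    """A structure file or chain annotation cannot be used as requested."""
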