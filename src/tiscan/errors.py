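"""Exception hierarchy.

``InputError`` covers malformed user inputs (bad FASTA, impossible
parameters); ``ModelMismatchError`` covers structurally valid models that
cannot be combined (motif/background with different L or r).  The CLI maps
the two onto distinct exit codes.
"""


class TiscanError(Exception):
    """Base class for all package errors."""


class InputError(TiscanError):
    """Malformed or inconsistent user input."""


class ModelMismatchError(TiscanError):
    """Motif and background models disagree on L or r."""


class UnscorableSiteError(TiscanError):
    """A training site has infinite transferred information.

    Raised when a background tuple probability is zero for a tuple that a
    training site contains, which makes the minimum-transferred-information
    threshold undefined.
    """
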