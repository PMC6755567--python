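"""Exception hierarchy shared across the pipeline."""


class ShiftkitError(Exception):
    """Base class for all package errors."""


class MoleculeError(ShiftkitError):
    """Invalid molecule input (unparseable InChI, bad XYZ, bad Molfile)."""


class DeckError(ShiftkitError):
    """Input-deck rendering failure (missing template placeholder, no 3D)."""


class ParseError(ShiftkitError):
    """Engine output or tabular input that cannot be interpreted."""


class BackendError(ShiftkitError):
    """Runner failure, annotated with the molecule/method it belongs to."""


class EngineUnavailableError(BackendError):
    """The configured external engine executable cannot be found."""


class ScalingError(ShiftkitError):
    """Degenerate regression, zero slope, or mismatched pairings."""


class EnsembleError(ShiftkitError):
    """Conformer ensembles with inconsistent topology or labels."""
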