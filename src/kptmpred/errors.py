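"""Exception types raised across the pipeline."""


class KptmpredError(Exception):
    """Base class for package errors."""


class CenterResidueError(KptmpredError):
    """The residue at the requested window center is not lysine."""


class AlphabetError(KptmpredError):
    """A residue is outside the 21-letter working alphabet."""


class EmptyInputError(KptmpredError):
    """An operation received an empty protein/sample collection."""


class WindowTooShortError(KptmpredError):
    """A spacing k is too large for the window length."""


class ShapeError(KptmpredError):
    """Inputs have mismatched lengths or incompatible column contracts."""


class DegenerateLabelsError(KptmpredError):
    """A binary task was given fewer than two classes."""


class ConfigError(KptmpredError):
    """A configuration is internally inconsistent or infeasible."""
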