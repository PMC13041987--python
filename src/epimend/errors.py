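"""Exception hierarchy shared across the package."""


class EpimendError(Exception):
    """Base class for all package-specific errors."""


class MovieFormatError(EpimendError):
    """Input array/file does not meet the label-movie format contract."""


class GeometryError(EpimendError):
    """Two artifacts that must share T x Y x X geometry do not."""


class IntegrityError(EpimendError):
    """A table or script violates an integrity invariant."""


class EditError(EpimendError):
    """A correction operator was called with invalid arguments or refused."""


class ScriptError(EditError):
    """An edit script failed at a given position.

    Attributes
    ----------
    position : int
        0-based index of the failing operation.
    """

    def __init__(self, position: int, message: str):
        super().__init__(f"edit script failed at op {position}: {message}")
        self.position = position
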