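"""Exception taxonomy shared across the package."""


class SgmechError(Exception):
    """Base class for all package errors."""


class ParameterError(SgmechError, ValueError):
    """A user-supplied parameter violates a documented precondition."""


class MeshFormatError(SgmechError, ValueError):
    """A mesh/field file could not be parsed under the named dialect."""


class StageError(SgmechError, RuntimeError):
    """A pipeline stage failed after its inputs validated."""
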