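"""Exception types shared across the package."""


class SpikeQuantError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SpikeQuantError, ValueError):
    """A model parameter violates its constraints (e.g. non-positive threshold)."""


class InvalidInputError(SpikeQuantError, ValueError):
    """An input array is malformed (shape mismatch, non-binary spikes, ...)."""


class UndefinedSignalError(SpikeQuantError, ValueError):
    """SQNR requested for an identically-zero reference signal."""


class DivergenceError(SpikeQuantError, RuntimeError):
    """An optimization run produced a non-finite loss.

    The partial trace recorded up to the failure is attached as ``trace``.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace
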