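"""Exception types shared across the package."""


class CipherGenoError(Exception):
    """Base class for package errors."""


class ParameterError(CipherGenoError):
    """Invalid or inconsistent encryption parameters."""


class CapacityError(CipherGenoError):
    """A vector does not fit in the available plaintext slots."""


class LevelError(CipherGenoError):
    """Level/modulus bookkeeping violation (e.g. rescaling at the bottom level)."""


class ScaleMismatchError(CipherGenoError):
    """Operands carry incompatible scaling factors."""


class MissingKeyError(CipherGenoError):
    """A required relinearization or Galois key is not available."""


class DigestMismatchError(CipherGenoError):
    """Artifacts were produced under different encryption parameters."""


class DegenerateModelError(CipherGenoError):
    """Training input admits no meaningful model (constant target, all-zero importance...)."""
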