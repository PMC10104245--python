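"""Encryption parameter sets for the leveled CKKS scheme.

The modulus chain follows the common RNS-CKKS layout: the *last* prime of the
chain is the key-switching ("special") prime used only inside hybrid key
switching, while the remaining primes form the data modulus. A fresh
ciphertext therefore lives at level ``len(chain) - 2`` and a three-prime chain
supports exactly one rescale — the depth-1 budget the inference circuit needs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import sympy

from .errors import ParameterError
from .ring import default_prime_chain


@dataclass(frozen=True)
class HEParams:
    """CKKS parameters: ring degree N, modulus chain, scale Δ and noise width σ."""

    ring_degree: int = 8192
    modulus_chain: tuple[int, ...] = ()
    scale: float = 2.0**45
    error_stddev: float = 3.2
    seed: int = 0
    modulus_bits: tuple[int, ...] = (60, 60, 60)

    def __post_init__(self):
        N = self.ring_degree
        if N < 8 or N & (N - 1):
            raise ParameterError("ring degree must be a power of two, at least 8")
        if not self.modulus_chain:
            chain = default_prime_chain(self.modulus_bits, N)
            object.__setattr__(self, "modulus_chain", chain)
        if len(self.modulus_chain) < 2:
            raise ParameterError("modulus chain needs at least one data prime "
                                 "and one key-switching prime")
        for p in self.modulus_chain:
            if p % (2 * N) != 1 or not sympy.isprime(p):
                raise ParameterError(
                    f"modulus {p} must be prime and ≡ 1 (mod 2N) for the NTT")
        if self.scale <= 0:
            raise ParameterError("scale must be positive")

    @property
    def slot_count(self) -> int:
        return self.ring_degree // 2

    @property
    def data_primes(self) -> tuple[int, ...]:
        return self.modulus_chain[:-1]

    @property
    def special_prime(self) -> int:
        return self.modulus_chain[-1]

    @property
    def top_level(self) -> int:
        """Level of a fresh ciphertext (number of data primes minus one)."""
        return len(self.data_primes) - 1

    def digest(self) -> str:
        """Short stable digest identifying this parameter set."""
        blob = json.dumps(
            {
                "N": self.ring_degree,
                "chain": list(self.modulus_chain),
                "scale": self.scale,
                "sigma": self.error_stddev,
            },
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_params() -> HEParams:
    """Production parameters: N = 8192 with three 60-bit primes."""
    return HEParams()


def small_test_params(N: int = 64) -> HEParams:
    """Tiny parameters for millisecond-scale property tests (same code paths)."""
    return HEParams(ring_degree=N, modulus_bits=(45, 45, 45), scale=2.0**33)
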