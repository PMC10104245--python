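"""Arithmetic in the negacyclic ring Z_q[X]/(X^N + 1), residue-number-system style.

Each prime q_i of the modulus chain gets its own :class:`PrimeField` holding
Montgomery constants and negacyclic number-theoretic-transform (NTT) tables.
A ring element at a given level is simply a ``(num_primes, N)`` uint64 array of
residues; all coefficient-wise and polynomial operations are vectorised numpy.

The NTT is the standard decimation-in-time Cooley–Tukey transform with the
2N-th root-of-unity powers folded in (so the transform is natively negacyclic
and no zero padding is required), paired with a Gentleman–Sande inverse.
Products of 60-bit residues are computed exactly with 32-bit limb splitting
and Montgomery reduction, entirely in uint64 numpy arrays.
"""

from __future__ import annotations

import numpy as np
import sympy

_M32 = np.uint64(0xFFFFFFFF)
_U64 = np.uint64


def _mul_hi(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """High 64 bits of the exact 128-bit product of two uint64 arrays."""
    a0 = a & _M32
    a1 = a >> _U64(32)
    b0 = b & _M32
    b1 = b >> _U64(32)
    lo_lo = a0 * b0
    m1 = a1 * b0
    m2 = a0 * b1
    cross = (lo_lo >> _U64(32)) + (m1 & _M32) + (m2 & _M32)
    return a1 * b1 + (m1 >> _U64(32)) + (m2 >> _U64(32)) + (cross >> _U64(32))


def _bit_reverse(i: int, bits: int) -> int:
    return int(f"{i:0{bits}b}"[::-1], 2)


def find_ntt_prime(bits: int, N: int, below: int | None = None) -> int:
    """Largest prime p < 2^bits with p ≡ 1 (mod 2N), optionally below a bound."""
    two_n = 2 * N
    p = (below if below is not None else (1 << bits)) - 1
    p -= (p - 1) % two_n
    while p > (1 << (bits - 1)):
        if sympy.isprime(p):
            return p
        p -= two_n
    raise ValueError(f"no {bits}-bit prime ≡ 1 mod {two_n}")


def default_prime_chain(bit_sizes: tuple[int, ...], N: int) -> tuple[int, ...]:
    """Deterministic chain of distinct NTT-friendly primes of the given bit sizes."""
    chain: list[int] = []
    for bits in bit_sizes:
        below = None
        while True:
            p = find_ntt_prime(bits, N, below=below)
            if p not in chain:
                chain.append(p)
                break
            below = p
    return tuple(chain)


class PrimeField:
    """Montgomery arithmetic and negacyclic NTT modulo one prime q ≡ 1 (mod 2N)."""

    def __init__(self, p: int, N: int):
        if p % (2 * N) != 1:
            raise ValueError(f"prime {p} is not ≡ 1 (mod {2 * N}); NTT unavailable")
        if not sympy.isprime(p):
            raise ValueError(f"modulus {p} is not prime")
        if p >= (1 << 62):
            raise ValueError("primes above 62 bits are not supported")
        self.p = p
        self.N = N
        self.logN = N.bit_length() - 1
        self._pv = _U64(p)
        # Montgomery constants: R = 2^64 mod p, ninv = -p^{-1} mod 2^64.
        self._ninv = _U64((-pow(p, -1, 1 << 64)) % (1 << 64))
        self._r2 = _U64(pow(1 << 64, 2, p))
        psi = self._find_psi()
        self.psi = psi
        logN = self.logN
        fwd = np.array(
            [pow(psi, _bit_reverse(i, logN), p) for i in range(N)], dtype=np.uint64
        )
        ipsi = pow(psi, -1, p)
        inv = np.array(
            [pow(ipsi, _bit_reverse(i, logN), p) for i in range(N)], dtype=np.uint64
        )
        self._psi_br = self.to_mont(fwd)
        self._ipsi_br = self.to_mont(inv)
        self._n_inv_mont = self.to_mont(np.array([pow(N, -1, p)], dtype=np.uint64))[0]

    def _find_psi(self) -> int:
        """Any primitive 2N-th root of unity mod p (order check: psi^N = -1)."""
        p, N = self.p, self.N
        exp = (p - 1) // (2 * N)
        for c in range(2, 10_000):
            psi = pow(c, exp, p)
            if pow(psi, N, p) == p - 1:
                return psi
        raise RuntimeError("no 2N-th root of unity found")  # pragma: no cover

    # -- Montgomery helpers -------------------------------------------------
    def mont_mul(self, a: np.ndarray, b_mont: np.ndarray) -> np.ndarray:
        """REDC(a * b_mont) = a*b mod p when b_mont is in Montgomery form."""
        lo = a * b_mont
        hi = _mul_hi(a, b_mont)
        m = lo * self._ninv
        u = hi + _mul_hi(m, self._pv) + np.where(lo != 0, _U64(1), _U64(0))
        return np.where(u >= self._pv, u - self._pv, u)

    def to_mont(self, a: np.ndarray) -> np.ndarray:
        return self.mont_mul(a, np.broadcast_to(self._r2, a.shape).copy())

    def mul_mod(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """General modular product of two residue arrays (two reductions)."""
        return self.mont_mul(a, self.to_mont(b))

    def add_mod(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        s = a + b
        return np.where(s >= self._pv, s - self._pv, s)

    def sub_mod(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return np.where(a >= b, a - b, a + self._pv - b)

    def neg_mod(self, a: np.ndarray) -> np.ndarray:
        return np.where(a == 0, a, self._pv - a)

    # -- negacyclic NTT ------------------------------------------------------
    def ntt(self, a: np.ndarray) -> np.ndarray:
        """Forward negacyclic NTT (natural order in, bit-reversed out)."""
        N = self.N
        x = a.copy()
        t = N
        m = 1
        while m < N:
            t //= 2
            S = self._psi_br[m : 2 * m, None]  # one twiddle per butterfly block
            blk = x.reshape(m, 2, t)
            U = blk[:, 0, :].copy()
            V = self.mont_mul(blk[:, 1, :], np.broadcast_to(S, (m, t)))
            s = U + V
            blk[:, 0, :] = np.where(s >= self._pv, s - self._pv, s)
            blk[:, 1, :] = np.where(U >= V, U - V, U + self._pv - V)
            x = blk.reshape(N)
            m *= 2
        return x

    def intt(self, a: np.ndarray) -> np.ndarray:
        """Inverse negacyclic NTT (bit-reversed in, natural order out)."""
        N = self.N
        x = a.copy()
        t = 1
        m = N
        while m > 1:
            h = m // 2
            S = self._ipsi_br[h : 2 * h, None]
            blk = x.reshape(h, 2, t)
            U = blk[:, 0, :].copy()
            V = blk[:, 1, :]
            s = U + V
            blk[:, 0, :] = np.where(s >= self._pv, s - self._pv, s)
            d = np.where(U >= V, U - V, U + self._pv - V)
            blk[:, 1, :] = self.mont_mul(d, np.broadcast_to(S, (h, t)))
            x = blk.reshape(N)
            t *= 2
            m = h
        return self.mont_mul(x, np.broadcast_to(self._n_inv_mont, x.shape).copy())

    def poly_mul(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Negacyclic product of two coefficient vectors mod p."""
        return self.intt(self.mul_mod(self.ntt(a), self.ntt(b)))


class RingBasis:
    """An ordered set of PrimeFields; ring elements are (k, N) uint64 arrays."""

    def __init__(self, fields: list[PrimeField]):
        self.fields = fields
        self.N = fields[0].N
        self.primes = tuple(f.p for f in fields)
        self.modulus = 1
        for p in self.primes:
            self.modulus *= p
        # CRT factors for lifting to centred big integers.
        self._crt = [
            (self.modulus // p) * pow(self.modulus // p, -1, p) % self.modulus
            for p in self.primes
        ]

    def __len__(self) -> int:
        return len(self.fields)

    def from_int_coeffs(self, coeffs) -> np.ndarray:
        """Residues of (possibly negative / multiprecision) integer coefficients."""
        out = np.empty((len(self.fields), self.N), dtype=np.uint64)
        arr = np.asarray(coeffs, dtype=object)
        for i, p in enumerate(self.primes):
            out[i] = np.array([int(c) % p for c in arr], dtype=np.uint64)
        return out

    def from_int64_coeffs(self, coeffs: np.ndarray) -> np.ndarray:
        """Fast path for int64 coefficient vectors (e.g. sampled noise)."""
        out = np.empty((len(self.fields), self.N), dtype=np.uint64)
        c = coeffs.astype(np.int64)
        for i, p in enumerate(self.primes):
            out[i] = np.mod(c, p).astype(np.uint64)
        return out

    def to_int_coeffs(self, elem: np.ndarray) -> list[int]:
        """CRT lift to centred integer coefficients in (-Q/2, Q/2]."""
        Q = self.modulus
        half = Q // 2
        acc = np.zeros(self.N, dtype=object)
        for i in range(len(self.fields)):
            acc += elem[i].astype(object) * self._crt[i]
        out = []
        for v in acc:
            v = int(v) % Q
            out.append(v - Q if v > half else v)
        return out

    # -- element-wise ops over the whole basis --------------------------------
    def add(self, a, b):
        return np.stack([f.add_mod(a[i], b[i]) for i, f in enumerate(self.fields)])

    def sub(self, a, b):
        return np.stack([f.sub_mod(a[i], b[i]) for i, f in enumerate(self.fields)])

    def neg(self, a):
        return np.stack([f.neg_mod(a[i]) for i, f in enumerate(self.fields)])

    def ntt(self, a):
        return np.stack([f.ntt(a[i]) for i, f in enumerate(self.fields)])

    def intt(self, a):
        return np.stack([f.intt(a[i]) for i, f in enumerate(self.fields)])

    def mul_ntt(self, a_ntt, b_ntt):
        """Pointwise product of two NTT-domain elements."""
        return np.stack(
            [f.mul_mod(a_ntt[i], b_ntt[i]) for i, f in enumerate(self.fields)]
        )

    def poly_mul(self, a, b):
        return self.intt(self.mul_ntt(self.ntt(a), self.ntt(b)))

    def mul_scalar(self, a, scalars: list[int]):
        """Multiply by a per-prime scalar residue list."""
        return np.stack(
            [
                f.mul_mod(a[i], np.broadcast_to(_U64(scalars[i] % f.p), a[i].shape).copy())
                for i, f in enumerate(self.fields)
            ]
        )

def automorphism_tables(N: int, g: int) -> tuple[np.ndarray, np.ndarray]:
    """Destination index and sign for coefficient i under X -> X^g mod X^N+1."""
    idx = np.arange(N, dtype=np.int64)
    j = (idx * g) % (2 * N)
    dest = np.where(j < N, j, j - N)
    sign = np.where(j < N, 1, -1).astype(np.int64)
    return dest.astype(np.int64), sign


def apply_automorphism(basis: RingBasis, a: np.ndarray, dest: np.ndarray,
                       sign: np.ndarray) -> np.ndarray:
    out = np.zeros_like(a)
    for i, f in enumerate(basis.fields):
        vals = np.where(sign == 1, a[i], f.neg_mod(a[i]))
        out[i, dest] = vals
    return out
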