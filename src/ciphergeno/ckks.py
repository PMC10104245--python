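"""A self-contained leveled CKKS scheme over Z_q[X]/(X^N + 1).

Implements encoding through the canonical embedding, RLWE key generation,
encryption/decryption, homomorphic addition, plaintext- and
ciphertext-multiplication with lazy (deferred) relinearization, slot rotation
via Galois automorphisms, and rescaling. Key switching is hybrid RNS: digits
are the per-prime residues of the switched polynomial and the switching keys
are raised by the special prime, which divides the key-switching noise back
down by ~2^60 at the default parameters.

Conventions: a ciphertext is a pair ``(c0, c1)`` decrypting as
``m ≈ c1 - s·c0``; the public key is ``(a, b)`` with ``b = s·a + e``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (CapacityError, LevelError, MissingKeyError,
                     ParameterError, ScaleMismatchError)
from .params import HEParams
from .ring import (PrimeField, RingBasis, apply_automorphism,
                   automorphism_tables)

_SCALE_RTOL = 1e-9


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------
@dataclass
class Plaintext:
    """An encoded vector: RNS residues of round(Δ·σ^{-1}(v)) plus metadata."""

    residues: np.ndarray  # (level+1, N) uint64
    level: int
    scale: float


@dataclass
class Ciphertext:
    c0: np.ndarray  # (level+1, N) uint64
    c1: np.ndarray
    level: int
    scale: float

    def copy(self) -> "Ciphertext":
        return Ciphertext(self.c0.copy(), self.c1.copy(), self.level, self.scale)


@dataclass
class TripleCiphertext:
    """Lazy product of two ciphertexts, decrypting as d1 - s·d0 + s²·d2."""

    d0: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    level: int
    scale: float


@dataclass
class KeySwitchKey:
    """Per-digit pairs (alpha_t, beta_t) over the extended basis, NTT domain."""

    alpha: list[np.ndarray]
    beta: list[np.ndarray]


@dataclass
class KeyBundle:
    """All key material of one party; the secret key never leaves the client."""

    params: HEParams
    secret: np.ndarray            # ternary s over the full chain basis
    public_a: np.ndarray          # over data primes
    public_b: np.ndarray
    relin: KeySwitchKey
    galois: dict[int, KeySwitchKey] = field(default_factory=dict)

    @property
    def digest(self) -> str:
        return self.params.digest()


class OpCounter:
    """Counts executed homomorphic operations (audit hook for the protocol)."""

    def __init__(self):
        self.counts: dict[str, int] = {}

    def tick(self, name: str, k: int = 1) -> None:
        self.counts[name] = self.counts.get(name, 0) + k

    def get(self, name: str) -> int:
        return self.counts.get(name, 0)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)


# --------------------------------------------------------------------------
# context
# --------------------------------------------------------------------------
class CkksContext:
    """Precomputed NTT tables, embedding tables and automorphism caches."""

    def __init__(self, params: HEParams):
        self.params = params
        N = params.ring_degree
        self.N = N
        self.slots = N // 2
        self.fields = [PrimeField(p, N) for p in params.modulus_chain]
        self._bases: dict[tuple[int, bool], RingBasis] = {}
        # canonical embedding: slot j sits at DFT bin t_j = (5^j - 1)/2 mod N
        tj = np.empty(self.slots, dtype=np.int64)
        g = 1
        for j in range(self.slots):
            tj[j] = (g - 1) // 2 % N
            g = (g * 5) % (2 * N)
        self._tj = tj
        self._tj_conj = (N - 1 - tj) % N
        k = np.arange(N)
        self._zeta = np.exp(1j * np.pi * k / N)       # e^{iπk/N}, the 2N-th root
        self._auto_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    # -- bases ---------------------------------------------------------------
    def basis(self, level: int, special: bool = False) -> RingBasis:
        key = (level, special)
        if key not in self._bases:
            fields = self.fields[: level + 1]
            if special:
                fields = fields + [self.fields[-1]]
            self._bases[key] = RingBasis(fields)
        return self._bases[key]

    @property
    def top_level(self) -> int:
        return self.params.top_level

    # -- encoding ------------------------------------------------------------
    def embed(self, v: np.ndarray, scale: float) -> np.ndarray:
        """Inverse canonical embedding: slots -> integer coefficient vector."""
        N, slots = self.N, self.slots
        v = np.asarray(v, dtype=np.complex128)
        if v.ndim != 1 or len(v) > slots:
            raise CapacityError(f"vector of length {len(v)} exceeds {slots} slots")
        if scale <= 0:
            raise ParameterError("scale must be positive")
        full = np.zeros(slots, dtype=np.complex128)
        full[: len(v)] = v
        F = np.empty(N, dtype=np.complex128)
        F[self._tj] = full
        F[self._tj_conj] = np.conj(full)
        b = np.fft.fft(F) / N
        coeffs = np.real(b * np.conj(self._zeta)) * scale
        if np.max(np.abs(coeffs)) < 2**62:
            return np.rint(coeffs).astype(np.int64)
        return np.array([int(round(c)) for c in coeffs], dtype=object)

    def unembed(self, coeffs, scale: float, length: int) -> np.ndarray:
        """Canonical embedding: integer coefficients -> first `length` slots."""
        b = np.array([float(c) for c in coeffs]) * self._zeta / scale
        F = np.fft.ifft(b) * self.N
        return F[self._tj][:length]

    def encode(self, v: np.ndarray, scale: float | None = None,
               level: int | None = None) -> Plaintext:
        scale = self.params.scale if scale is None else scale
        level = self.top_level if level is None else level
        coeffs = self.embed(v, scale)
        basis = self.basis(level)
        if coeffs.dtype == np.int64:
            res = basis.from_int64_coeffs(coeffs)
        else:
            res = basis.from_int_coeffs(coeffs)
        return Plaintext(res, level, scale)

    def decode(self, pt: Plaintext, length: int | None = None) -> np.ndarray:
        length = self.slots if length is None else length
        coeffs = self.basis(pt.level).to_int_coeffs(pt.residues)
        return self.unembed(coeffs, pt.scale, length)

    # -- sampling ------------------------------------------------------------
    def _gaussian(self, rng: np.random.Generator) -> np.ndarray:
        return np.rint(rng.normal(0.0, self.params.error_stddev, self.N)).astype(np.int64)

    def _ternary(self, rng: np.random.Generator) -> np.ndarray:
        return rng.integers(-1, 2, self.N).astype(np.int64)

    def _uniform(self, basis: RingBasis, rng: np.random.Generator) -> np.ndarray:
        return np.stack(
            [rng.integers(0, p, self.N, dtype=np.uint64) for p in basis.primes]
        )

    # -- key generation -------------------------------------------------------
    def _make_kskey(self, s_prime_ntt: np.ndarray, secret: np.ndarray,
                    rng: np.random.Generator) -> KeySwitchKey:
        """Hybrid key-switching key for target secret s' (NTT form, ext basis)."""
        ext = self.basis(self.top_level, special=True)
        Q = 1
        for p in self.params.data_primes:
            Q *= p
        P = self.params.special_prime
        s_ntt = ext.ntt(secret)
        alphas, betas = [], []
        for t, q_t in enumerate(self.params.data_primes):
            g_t = (Q // q_t) * pow(Q // q_t, -1, q_t) % Q
            factor = [(P * g_t) % p for p in ext.primes]
            a_t = self._uniform(ext, rng)
            e_t = ext.from_int64_coeffs(self._gaussian(rng))
            a_ntt = ext.ntt(a_t)
            b = ext.add(ext.mul_ntt(s_ntt, a_ntt), ext.ntt(e_t))
            b = ext.add(b, ext.mul_scalar(s_prime_ntt, factor))
            alphas.append(a_ntt)
            betas.append(b)
        return KeySwitchKey(alphas, betas)

    def keygen(self, seed: int, rotation_steps: tuple[int, ...] = ()) -> KeyBundle:
        """Generate secret/public/relinearization keys plus the requested Galois keys."""
        rng = np.random.default_rng(seed)
        full = self.basis(self.top_level, special=True)
        data = self.basis(self.top_level)
        s_int = self._ternary(rng)
        s_full = full.from_int64_coeffs(s_int)
        s_data = s_full[: self.top_level + 1]
        a = self._uniform(data, rng)
        e = data.from_int64_coeffs(self._gaussian(rng))
        b = data.add(data.poly_mul(s_data, a), e)
        s_sq = full.poly_mul(s_full, s_full)
        relin = self._make_kskey(full.ntt(s_sq), s_full, rng)
        bundle = KeyBundle(self.params, s_full, a, b, relin)
        for k in rotation_steps:
            self.add_galois_key(bundle, k, rng)
        return bundle

    def add_galois_key(self, bundle: KeyBundle, step: int,
                       rng: np.random.Generator) -> None:
        step = step % self.slots
        if step == 0 or step in bundle.galois:
            return
        full = self.basis(self.top_level, special=True)
        dest, sign = self._auto_tables(step)
        s_rot = apply_automorphism(full, bundle.secret, dest, sign)
        bundle.galois[step] = self._make_kskey(full.ntt(s_rot), bundle.secret, rng)

    def _auto_tables(self, step: int) -> tuple[np.ndarray, np.ndarray]:
        if step not in self._auto_cache:
            g = pow(5, step, 2 * self.N)
            self._auto_cache[step] = automorphism_tables(self.N, g)
        return self._auto_cache[step]

    # -- encryption -----------------------------------------------------------
    def encrypt(self, pt: Plaintext, bundle: KeyBundle,
                rng: np.random.Generator | None = None,
                seed: int | None = None) -> Ciphertext:
        if pt.level > self.top_level:
            raise LevelError("plaintext above the top modulus level")
        rng = np.random.default_rng(seed) if rng is None else rng
        basis = self.basis(pt.level)
        sl = slice(0, pt.level + 1)
        u = basis.from_int64_coeffs(rng.integers(0, 2, self.N).astype(np.int64))
        u_ntt = basis.ntt(u)
        e0 = basis.from_int64_coeffs(self._gaussian(rng))
        e1 = basis.from_int64_coeffs(self._gaussian(rng))
        c0 = basis.add(basis.intt(basis.mul_ntt(u_ntt, basis.ntt(bundle.public_a[sl]))), e0)
        c1 = basis.add(basis.intt(basis.mul_ntt(u_ntt, basis.ntt(bundle.public_b[sl]))), e1)
        c1 = basis.add(c1, pt.residues)
        return Ciphertext(c0, c1, pt.level, pt.scale)

    def decrypt(self, ct: Ciphertext, bundle: KeyBundle) -> Plaintext:
        basis = self.basis(ct.level)
        s = bundle.secret[: ct.level + 1]
        m = basis.sub(ct.c1, basis.poly_mul(s, ct.c0))
        return Plaintext(m, ct.level, ct.scale)

    def decrypt_decode(self, ct: Ciphertext, bundle: KeyBundle,
                       length: int | None = None) -> np.ndarray:
        return self.decode(self.decrypt(ct, bundle), length)

    # -- arithmetic -----------------------------------------------------------
    def _check_aligned(self, a, b) -> None:
        if a.level != b.level:
            raise LevelError(f"level mismatch: {a.level} vs {b.level}")
        if abs(a.scale - b.scale) > _SCALE_RTOL * max(a.scale, b.scale):
            raise ScaleMismatchError(f"scale mismatch: {a.scale} vs {b.scale}")

    def add(self, ct0: Ciphertext, ct1: Ciphertext) -> Ciphertext:
        self._check_aligned(ct0, ct1)
        basis = self.basis(ct0.level)
        return Ciphertext(basis.add(ct0.c0, ct1.c0), basis.add(ct0.c1, ct1.c1),
                          ct0.level, ct0.scale)

    def sub(self, ct0: Ciphertext, ct1: Ciphertext) -> Ciphertext:
        self._check_aligned(ct0, ct1)
        basis = self.basis(ct0.level)
        return Ciphertext(basis.sub(ct0.c0, ct1.c0), basis.sub(ct0.c1, ct1.c1),
                          ct0.level, ct0.scale)

    def add_plain(self, ct: Ciphertext, pt: Plaintext) -> Ciphertext:
        self._check_aligned(ct, pt)
        basis = self.basis(ct.level)
        return Ciphertext(ct.c0.copy(), basis.add(ct.c1, pt.residues),
                          ct.level, ct.scale)

    def mul_plain(self, ct: Ciphertext, pt: Plaintext) -> Ciphertext:
        if ct.level != pt.level:
            raise LevelError("plaintext and ciphertext at different levels")
        basis = self.basis(ct.level)
        p_ntt = basis.ntt(pt.residues)
        c0 = basis.intt(basis.mul_ntt(basis.ntt(ct.c0), p_ntt))
        c1 = basis.intt(basis.mul_ntt(basis.ntt(ct.c1), p_ntt))
        return Ciphertext(c0, c1, ct.level, ct.scale * pt.scale)

    def mul_lazy(self, ct0: Ciphertext, ct1: Ciphertext) -> TripleCiphertext:
        self._levels_equal(ct0, ct1)
        basis = self.basis(ct0.level)
        a0, b0 = basis.ntt(ct0.c0), basis.ntt(ct0.c1)
        a1, b1 = basis.ntt(ct1.c0), basis.ntt(ct1.c1)
        d0 = basis.intt(basis.add(basis.mul_ntt(a0, b1), basis.mul_ntt(a1, b0)))
        d1 = basis.intt(basis.mul_ntt(b0, b1))
        d2 = basis.intt(basis.mul_ntt(a0, a1))
        return TripleCiphertext(d0, d1, d2, ct0.level, ct0.scale * ct1.scale)

    def _levels_equal(self, ct0, ct1) -> None:
        if ct0.level != ct1.level:
            raise LevelError(f"level mismatch: {ct0.level} vs {ct1.level}")

    def add_triple(self, t0: TripleCiphertext, t1: TripleCiphertext) -> TripleCiphertext:
        if t0.level != t1.level:
            raise LevelError("triple level mismatch")
        if abs(t0.scale - t1.scale) > _SCALE_RTOL * max(t0.scale, t1.scale):
            raise ScaleMismatchError("triple scale mismatch")
        basis = self.basis(t0.level)
        return TripleCiphertext(basis.add(t0.d0, t1.d0), basis.add(t0.d1, t1.d1),
                                basis.add(t0.d2, t1.d2), t0.level, t0.scale)

    def relin(self, t: TripleCiphertext, bundle: KeyBundle,
              counter: OpCounter | None = None) -> Ciphertext:
        if bundle.relin is None:
            raise MissingKeyError("relinearization key unavailable")
        ka, kb = self._key_switch(t.d2, bundle.relin, t.level)
        basis = self.basis(t.level)
        if counter is not None:
            counter.tick("relin")
        return Ciphertext(basis.add(t.d0, ka), basis.add(t.d1, kb), t.level, t.scale)

    def mul(self, ct0: Ciphertext, ct1: Ciphertext, bundle: KeyBundle,
            counter: OpCounter | None = None) -> Ciphertext:
        return self.relin(self.mul_lazy(ct0, ct1), bundle, counter)

    # -- key switching --------------------------------------------------------
    def _key_switch(self, d: np.ndarray, ksk: KeySwitchKey,
                    level: int) -> tuple[np.ndarray, np.ndarray]:
        """Switch polynomial d from the key material's secret to s; returns
        (ka, kb) with kb - s·ka ≈ d·s'. Only supported at the top level, where
        all homomorphic products and rotations of the depth-1 circuit happen."""
        if level != self.top_level:
            raise LevelError("key switching is only supported at the top level")
        ext = self.basis(level, special=True)
        data = self.basis(level)
        P = self.params.special_prime
        acc_a = None
        acc_b = None
        for t, q_t in enumerate(self.params.data_primes):
            res = d[t]
            centered = np.where(res > q_t // 2, res.astype(np.int64) - q_t,
                                res.astype(np.int64))
            digit = ext.ntt(ext.from_int64_coeffs(centered))
            pa = ext.mul_ntt(digit, ksk.alpha[t])
            pb = ext.mul_ntt(digit, ksk.beta[t])
            acc_a = pa if acc_a is None else ext.add(acc_a, pa)
            acc_b = pb if acc_b is None else ext.add(acc_b, pb)
        ka_ext = ext.intt(acc_a)
        kb_ext = ext.intt(acc_b)
        return (self._mod_down(ka_ext, data, P), self._mod_down(kb_ext, data, P))

    def _mod_down(self, x_ext: np.ndarray, data: RingBasis, P: int) -> np.ndarray:
        """Divide by the special prime with rounding: round(x/P) mod each q_j."""
        r = x_ext[-1]
        r_c = np.where(r > P // 2, r.astype(np.int64) - P, r.astype(np.int64))
        out = np.empty((len(data.fields), self.N), dtype=np.uint64)
        for j, f in enumerate(data.fields):
            rj = np.mod(r_c, f.p).astype(np.uint64)
            diff = f.sub_mod(x_ext[j], rj)
            pinv = np.uint64(pow(P, -1, f.p))
            out[j] = f.mul_mod(diff, np.broadcast_to(pinv, diff.shape).copy())
        return out

    # -- rotation -------------------------------------------------------------
    def rotate(self, ct: Ciphertext, k: int, bundle: KeyBundle,
               counter: OpCounter | None = None) -> Ciphertext:
        """Cyclic left rotation of the slot vector by k positions."""
        k = k % self.slots
        if k == 0:
            return ct.copy()
        if k not in bundle.galois:
            raise MissingKeyError(f"no Galois key for rotation step {k}")
        basis = self.basis(ct.level)
        dest, sign = self._auto_tables(k)
        pa = apply_automorphism(basis, ct.c0, dest, sign)
        pb = apply_automorphism(basis, ct.c1, dest, sign)
        ka, kb = self._key_switch(pa, bundle.galois[k], ct.level)
        if counter is not None:
            counter.tick("rotation")
        # (kb - s·ka) ≈ φ(c0)·φ(s), so (-ka, φ(c1) - kb) decrypts to φ(c1 - s·c0)
        return Ciphertext(basis.neg(ka), basis.sub(pb, kb), ct.level, ct.scale)

    # -- rescale --------------------------------------------------------------
    def rescale(self, ct: Ciphertext, counter: OpCounter | None = None) -> Ciphertext:
        """Drop the top active prime, dividing the scale by it."""
        if ct.level == 0:
            raise LevelError("cannot rescale: no modulus remains below this level")
        p_drop = self.params.data_primes[ct.level]
        new_basis = self.basis(ct.level - 1)
        out0 = self._rescale_poly(ct.c0, new_basis, p_drop)
        out1 = self._rescale_poly(ct.c1, new_basis, p_drop)
        if counter is not None:
            counter.tick("rescale")
        return Ciphertext(out0, out1, ct.level - 1, ct.scale / p_drop)

    def _rescale_poly(self, x: np.ndarray, new_basis: RingBasis, p_drop: int) -> np.ndarray:
        r = x[-1]
        r_c = np.where(r > p_drop // 2, r.astype(np.int64) - p_drop, r.astype(np.int64))
        out = np.empty((len(new_basis.fields), self.N), dtype=np.uint64)
        for j, f in enumerate(new_basis.fields):
            rj = np.mod(r_c, f.p).astype(np.uint64)
            diff = f.sub_mod(x[j], rj)
            pinv = np.uint64(pow(p_drop, -1, f.p))
            out[j] = f.mul_mod(diff, np.broadcast_to(pinv, diff.shape).copy())
        return out
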