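"""Homomorphic linear evaluation: an encryption of M·z from packed diagonals.

Both variants — plaintext-encoded matrix × encrypted vector, and encrypted
matrix × encrypted vector — follow the same schedule:

1. baby steps: rotate the encrypted vector by i2 = 0..g-1;
2. inner sums: Hadamard-multiply diagonal i1·g+i2 with rotation i2 and sum
   over i2 *and over all submatrices* (so the subsequent rotations are
   executed once, not once per submatrix);
3. giant steps: rotate each inner sum left by i1·g and accumulate;
4. column fold: γ rotate-and-add halvings with steps l·2^{j-1} sum the
   n_sub/l column blocks;
5. a single rescale brings the result back to the input vector's scale.

In the encrypted-matrix variant the inner products are kept as lazy
three-component ciphertexts and summed before relinearization, so exactly one
relinearization runs per giant-step group regardless of the number of
submatrices or baby steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ckks import (Ciphertext, CkksContext, KeyBundle, OpCounter, Plaintext,
                   TripleCiphertext)
from .errors import ParameterError, ScaleMismatchError
from .packing import (BsgsPlan, PackedMatrix, complex_unpack, matrix_scale,
                      pack_diagonals)


@dataclass
class EncryptedVector:
    """Per-submatrix encryptions of the slices of z, self-repeated to N/2 slots."""

    plan: BsgsPlan
    cts: list[Ciphertext]
    scale: float


@dataclass
class EncryptedMatrix:
    """Encryptions of the pre-rotated encoded diagonals, per submatrix."""

    plan: BsgsPlan
    cts: list[list[Ciphertext]]  # [submatrix][i1*g + i2]
    scale: float


def vector_slices(z: np.ndarray, plan: BsgsPlan, N: int) -> list[np.ndarray]:
    """Chunk z by submatrix, zero-pad to n_sub and tile to fill N/2 slots."""
    z = np.asarray(z, dtype=np.float64)
    if len(z) != plan.n_cols:
        raise ParameterError(f"vector length {len(z)} != {plan.n_cols} columns")
    reps = (N // 2) // plan.n_sub
    out = []
    off = 0
    for _ in range(plan.s):
        width = min(N // 2, len(z) - off)
        sl = np.zeros(plan.n_sub)
        sl[:width] = z[off : off + width]
        off += width
        out.append(np.tile(sl, reps))
    return out


def encrypt_vector(ctx: CkksContext, z: np.ndarray, plan: BsgsPlan,
                   bundle: KeyBundle,
                   rng: np.random.Generator | None = None) -> EncryptedVector:
    rng = np.random.default_rng() if rng is None else rng
    cts = [ctx.encrypt(ctx.encode(sl), bundle, rng=rng)
           for sl in vector_slices(z, plan, ctx.N)]
    return EncryptedVector(plan, cts, ctx.params.scale)


def encrypt_matrix(ctx: CkksContext, M: np.ndarray, bundle: KeyBundle,
                   complex_packed: bool = True,
                   rng: np.random.Generator | None = None) -> EncryptedMatrix:
    rng = np.random.default_rng() if rng is None else rng
    scale = matrix_scale(ctx)
    plan, per_sub = pack_diagonals(M, ctx.N, complex_packed)
    cts = [[ctx.encrypt(ctx.encode(d, scale), bundle, rng=rng) for d in sub]
           for sub in per_sub]
    return EncryptedMatrix(plan, cts, scale)


def accumulate_submatrices(ctx: CkksContext, parts: list) -> "Ciphertext | TripleCiphertext":
    """Sum per-submatrix partial results before any rotation is executed."""
    if not parts:
        raise ParameterError("nothing to accumulate")
    acc = parts[0]
    for p in parts[1:]:
        acc = ctx.add_triple(acc, p) if isinstance(acc, TripleCiphertext) \
            else ctx.add(acc, p)
    return acc


def fold_columns(ctx: CkksContext, ct: Ciphertext, plan: BsgsPlan,
                 bundle: KeyBundle, counter: OpCounter | None = None) -> Ciphertext:
    """γ rotate-and-add halvings summing the n_sub/l column blocks."""
    for j in range(1, plan.gamma + 1):
        ct = ctx.add(ct, ctx.rotate(ct, plan.l * (1 << (j - 1)), bundle, counter))
    return ct


def _baby_rotations(ctx: CkksContext, ev: EncryptedVector, bundle: KeyBundle,
                    counter: OpCounter | None) -> list[list[tuple]]:
    """NTT forms of RotL^{i2}(ct_z) for each submatrix and i2 < g."""
    basis = ctx.basis(ev.cts[0].level)
    out = []
    for ct in ev.cts:
        rots = []
        for i2 in range(ev.plan.g):
            r = ctx.rotate(ct, i2, bundle, counter) if i2 else ct
            rots.append((basis.ntt(r.c0), basis.ntt(r.c1)))
        out.append(rots)
    return out


def eval_plain_matrix(ctx: CkksContext, pm: PackedMatrix, ev: EncryptedVector,
                      bundle: KeyBundle,
                      counter: OpCounter | None = None) -> Ciphertext:
    """Algorithm: encryption of M·z from an encoded (plaintext) matrix."""
    plan = _check_plans(pm.plan, ev.plan)
    level = ev.cts[0].level
    basis = ctx.basis(level)
    rot_ntt = _baby_rotations(ctx, ev, bundle, counter)
    pt_ntt = [[basis.ntt(pt.residues) for pt in sub] for sub in pm.diagonals]
    out_scale = ev.scale * pm.scale
    ct = None
    for i1 in range(plan.b):
        per_sub = []
        for mu in range(plan.s):
            acc0 = acc1 = None
            for i2 in range(plan.g):
                m_ntt = pt_ntt[mu][i1 * plan.g + i2]
                c0, c1 = rot_ntt[mu][i2]
                p0 = basis.mul_ntt(c0, m_ntt)
                p1 = basis.mul_ntt(c1, m_ntt)
                if counter is not None:
                    counter.tick("mult")
                acc0 = p0 if acc0 is None else basis.add(acc0, p0)
                acc1 = p1 if acc1 is None else basis.add(acc1, p1)
            per_sub.append(Ciphertext(basis.intt(acc0), basis.intt(acc1),
                                      level, out_scale))
        inner = accumulate_submatrices(ctx, per_sub)
        term = ctx.rotate(inner, i1 * plan.g, bundle, counter) if i1 else inner
        ct = term if ct is None else ctx.add(ct, term)
    ct = fold_columns(ctx, ct, plan, bundle, counter)
    return ctx.rescale(ct, counter)


def eval_encrypted_matrix(ctx: CkksContext, em: EncryptedMatrix,
                          ev: EncryptedVector, bundle: KeyBundle,
                          counter: OpCounter | None = None) -> Ciphertext:
    """Same evaluation with the matrix itself encrypted; lazy products are
    summed over submatrices and baby steps before each relinearization."""
    plan = _check_plans(em.plan, ev.plan)
    level = ev.cts[0].level
    basis = ctx.basis(level)
    rot_ntt = _baby_rotations(ctx, ev, bundle, counter)
    m_ntt = [[(basis.ntt(c.c0), basis.ntt(c.c1)) for c in sub] for sub in em.cts]
    out_scale = ev.scale * em.scale
    ct = None
    for i1 in range(plan.b):
        per_sub = []
        for mu in range(plan.s):
            d0 = d1 = d2 = None
            for i2 in range(plan.g):
                a0, b0 = m_ntt[mu][i1 * plan.g + i2]
                a1, b1 = rot_ntt[mu][i2]
                t0 = basis.add(basis.mul_ntt(a0, b1), basis.mul_ntt(a1, b0))
                t1 = basis.mul_ntt(b0, b1)
                t2 = basis.mul_ntt(a0, a1)
                if counter is not None:
                    counter.tick("mult")
                d0 = t0 if d0 is None else basis.add(d0, t0)
                d1 = t1 if d1 is None else basis.add(d1, t1)
                d2 = t2 if d2 is None else basis.add(d2, t2)
            per_sub.append(TripleCiphertext(basis.intt(d0), basis.intt(d1),
                                            basis.intt(d2), level, out_scale))
        inner = ctx.relin(accumulate_submatrices(ctx, per_sub), bundle, counter)
        term = ctx.rotate(inner, i1 * plan.g, bundle, counter) if i1 else inner
        ct = term if ct is None else ctx.add(ct, term)
    ct = fold_columns(ctx, ct, plan, bundle, counter)
    return ctx.rescale(ct, counter)


def add_intercept(ctx: CkksContext, ct_scores: Ciphertext,
                  ct_w0: Ciphertext) -> Ciphertext:
    """Shift every slot (both complex parts, if packed) by the intercept."""
    if abs(ct_scores.scale - ct_w0.scale) > 1e-9 * ct_scores.scale:
        raise ScaleMismatchError("intercept scale does not match scores")
    return ctx.add(ct_scores, ct_w0)


def extract_scores(ctx: CkksContext, ct: Ciphertext, plan: BsgsPlan,
                   bundle: KeyBundle) -> np.ndarray:
    """Decrypt, unpack complex rows to sample order, drop padding rows."""
    slots = ctx.decrypt_decode(ct, bundle, length=plan.l)
    if plan.complex_packed:
        return complex_unpack(slots)[: plan.m_rows]
    return np.real(slots)[: plan.m_rows]


def _check_plans(a: BsgsPlan, b: BsgsPlan) -> BsgsPlan:
    if a != b:
        raise ParameterError("matrix and vector were packed under different plans")
    return a
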