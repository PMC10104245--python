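"""Matrix packing for encrypted matrix–vector products.

A rectangular l×n matrix (l, n powers of two, l | n) is *tiled* — conceptually
repeated down the diagonal — so that its l generalized diagonals
``m_j[r] = M[r mod l, (r + j) mod n]`` carry the whole matrix and the product
M·z becomes ``Σ_j m_j ∘ (z ≪ j)``. The baby-step–giant-step (BSGS) split
``l = g·b`` regroups that sum so only ``g + b`` distinct rotations of the
encrypted vector are needed, with the inner ``≫ i1·g`` pre-rotations applied
to the *plaintext* diagonals before encoding, where rotation is free.

Wide matrices are split column-wise into submatrices of at most N/2 columns;
adjacent sample rows can be packed into complex numbers (real part = even row,
imaginary part = odd row), halving both ciphertext and multiplication counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ckks import CkksContext, Plaintext
from .errors import CapacityError, ParameterError


def next_pow2(x: int) -> int:
    return 1 << (int(x) - 1).bit_length()


def split_columns(n_cols: int, N: int) -> list[int]:
    """Split a column count into chunks of at most N/2 columns each."""
    if n_cols < 1:
        raise ParameterError("need at least one column")
    chunk = N // 2
    widths = [chunk] * (n_cols // chunk)
    if n_cols % chunk:
        widths.append(n_cols % chunk)
    return widths


def pad_to_pow2(M: np.ndarray) -> np.ndarray:
    """Zero-pad both dimensions up to the next powers of two."""
    m, n = M.shape
    if m == 0 or n == 0:
        raise ParameterError("empty matrix")
    out = np.zeros((next_pow2(m), next_pow2(n)), dtype=M.dtype)
    out[:m, :n] = M
    return out


def complex_pack(M: np.ndarray) -> np.ndarray:
    """Fold adjacent real rows into complex rows: row r = M[2r] + i·M[2r+1]."""
    if M.shape[0] % 2:
        raise ParameterError("complex packing needs an even row count")
    return M[0::2].astype(np.complex128) + 1j * M[1::2]


def complex_unpack(Mz: np.ndarray) -> np.ndarray:
    """Inverse of complex_pack, interleaving real/imaginary parts back."""
    out = np.empty(2 * Mz.shape[0], dtype=np.float64) if Mz.ndim == 1 else \
        np.empty((2 * Mz.shape[0],) + Mz.shape[1:], dtype=np.float64)
    out[0::2] = np.real(Mz)
    out[1::2] = np.imag(Mz)
    return out


def diagonals(M: np.ndarray) -> list[np.ndarray]:
    """Tiled generalized diagonals m_j[r] = M[r mod l, (r+j) mod n], j < l."""
    l, n = M.shape
    if l > n:
        raise ParameterError(f"need l ≤ n, got {l}×{n}")
    if l & (l - 1) or n & (n - 1):
        raise ParameterError("diagonal extraction needs power-of-two shapes")
    r = np.arange(n)
    return [M[r % l, (r + j) % n] for j in range(l)]


def reconstruct_from_diagonals(diags: list[np.ndarray], l: int, n: int) -> np.ndarray:
    """Invert the diagonal index map (exact bijection)."""
    M = np.empty((l, n), dtype=np.asarray(diags[0]).dtype)
    r = np.arange(n)
    for j, d in enumerate(diags):
        M[r % l, (r + j) % n] = d
    return M


def bsgs_split(l: int) -> tuple[int, int]:
    """Baby/giant factorization: g the smallest power of two ≥ √l, b = l/g."""
    if l < 1 or l & (l - 1):
        raise ParameterError("l must be a power of two")
    g = 1
    while g * g < l:
        g *= 2
    return g, l // g


@dataclass(frozen=True)
class BsgsPlan:
    """Shape bookkeeping for one packed matrix and its BSGS evaluation."""

    l: int            # packed row count (complex rows if complex_packed)
    n_sub: int        # columns per submatrix (power of two)
    g: int            # baby steps
    b: int            # giant steps
    gamma: int        # column-fold steps, log2(n_sub / l)
    s: int            # submatrix count
    complex_packed: bool
    m_rows: int       # original sample count
    n_cols: int       # original variant count

    def __post_init__(self):
        assert self.g * self.b == self.l and self.n_sub % self.l == 0

    @property
    def rotation_steps(self) -> tuple[int, ...]:
        """The exact set of Galois rotation steps the evaluation needs."""
        steps = set(range(1, self.g))
        steps |= {i1 * self.g for i1 in range(1, self.b)}
        steps |= {self.l * (1 << (j - 1)) for j in range(1, self.gamma + 1)}
        return tuple(sorted(steps))

    def multiplications(self) -> int:
        return self.s * self.l

    def rotations(self) -> int:
        """Rotation count under the shared-rotation accounting (independent of s)."""
        return self.g + self.b + self.gamma

    def as_dict(self) -> dict:
        return {
            "l": self.l, "n_sub": self.n_sub, "g": self.g, "b": self.b,
            "gamma": self.gamma, "s": self.s,
            "complex_packed": self.complex_packed,
            "m_rows": self.m_rows, "n_cols": self.n_cols,
            "multiplications": self.multiplications(),
            "rotations": self.rotations(),
        }


def make_plan(m_rows: int, n_cols: int, N: int,
              complex_packed: bool = True) -> BsgsPlan:
    """Derive the packing/evaluation plan for an m×n matrix at ring degree N."""
    widths = split_columns(n_cols, N)
    s = len(widths)
    row_pad = next_pow2(m_rows)
    if complex_packed and row_pad < 2:
        row_pad = 2
    l = row_pad // 2 if complex_packed else row_pad
    n_sub = N // 2 if s > 1 else max(next_pow2(widths[0]), l)
    if l > N // 2:
        raise CapacityError(f"{m_rows} samples exceed the {N // 2} slots")
    if l > n_sub:
        raise CapacityError("more packed rows than submatrix columns")
    g, b = bsgs_split(l)
    gamma = int(np.log2(n_sub // l))
    return BsgsPlan(l, n_sub, g, b, gamma, s, complex_packed, m_rows, n_cols)


def count_ops(m_rows: int, n_cols: int, N: int,
              complex_packed: bool) -> tuple[int, int]:
    """(homomorphic multiplications, rotations) for one linear evaluation."""
    plan = make_plan(m_rows, n_cols, N, complex_packed)
    return plan.multiplications(), plan.rotations()


def pack_diagonals(M: np.ndarray, N: int,
                   complex_packed: bool = True) -> tuple[BsgsPlan, list[list[np.ndarray]]]:
    """Pad, split, (complex-)pack and extract pre-rotated tiled diagonals.

    Returns the plan plus, per submatrix, the l diagonal vectors indexed
    i = i1·g + i2, each already right-rotated by i1·g and self-repeated to
    fill the N/2 slots.
    """
    M = np.asarray(M, dtype=np.float64)
    plan = make_plan(M.shape[0], M.shape[1], N, complex_packed)
    reps = (N // 2) // plan.n_sub
    per_sub: list[list[np.ndarray]] = []
    col0 = 0
    for _ in range(plan.s):
        width = min(N // 2, M.shape[1] - col0)
        sub = np.zeros((plan.l * (2 if complex_packed else 1), plan.n_sub))
        sub[: M.shape[0], :width] = M[:, col0 : col0 + width]
        col0 += width
        if complex_packed:
            sub = complex_pack(sub)
        diags = diagonals(sub)
        rotated = []
        for i1 in range(plan.b):
            for i2 in range(plan.g):
                d = np.roll(diags[i1 * plan.g + i2], i1 * plan.g)
                rotated.append(np.tile(d, reps))
        per_sub.append(rotated)
    return plan, per_sub


@dataclass
class PackedMatrix:
    """Encoded (plaintext) pre-rotated diagonals of a packed matrix."""

    plan: BsgsPlan
    diagonals: list[list[Plaintext]]  # [submatrix][i1*g + i2]
    scale: float


def matrix_scale(ctx: CkksContext) -> float:
    """Scale for matrix diagonals: the prime the final rescale drops, so the
    evaluation output lands exactly back at the vector's scale Δ."""
    return float(ctx.params.data_primes[ctx.top_level])


def encode_matrix(ctx: CkksContext, M: np.ndarray, complex_packed: bool = True,
                  scale: float | None = None) -> PackedMatrix:
    scale = matrix_scale(ctx) if scale is None else scale
    if scale <= 0:
        raise ParameterError("matrix scale must be positive")
    plan, per_sub = pack_diagonals(M, ctx.N, complex_packed)
    encoded = [[ctx.encode(d, scale) for d in sub] for sub in per_sub]
    return PackedMatrix(plan, encoded, scale)
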