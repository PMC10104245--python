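"""Homomorphic linear evaluation against the plaintext matrix–vector oracle."""

import numpy as np
import pytest

from ciphergeno import OpCounter
from ciphergeno.linear_eval import (add_intercept, encrypt_matrix,
                                    encrypt_vector, eval_encrypted_matrix,
                                    eval_plain_matrix, extract_scores)
from ciphergeno.packing import encode_matrix, make_plan
from ciphergeno.synthetic import fixture_small


def secure_matvec(ctx, bundle, M, z, complex_packed=True, encrypted=False,
                  counter=None, seed=11):
    plan = make_plan(M.shape[0], M.shape[1], ctx.N, complex_packed)
    rng = np.random.default_rng(seed)
    ev = encrypt_vector(ctx, z, plan, bundle, rng)
    if encrypted:
        em = encrypt_matrix(ctx, M, bundle, complex_packed, rng)
        out = eval_encrypted_matrix(ctx, em, ev, bundle, counter)
    else:
        pm = encode_matrix(ctx, M, complex_packed)
        out = eval_plain_matrix(ctx, pm, ev, bundle, counter)
    return out, extract_scores(ctx, out, plan, bundle)


def test_plaintext_bsgs_identity_holds_exactly(rng):
    """The regrouped baby-step/giant-step sum equals the diagonal sum."""
    for l, n in ((4, 16), (8, 8), (2, 32)):
        M = rng.uniform(-1, 1, (l, n))
        z = rng.uniform(-1, 1, n)
        from ciphergeno.packing import bsgs_split, diagonals
        d = diagonals(M)
        direct = sum(d[j] * np.roll(z, -j) for j in range(l))
        g, b = bsgs_split(l)
        regrouped = np.zeros(n)
        for i1 in range(b):
            inner = sum(np.roll(d[i1 * g + i2], i1 * g) * np.roll(z, -i2)
                        for i2 in range(g))
            regrouped += np.roll(inner, -(i1 * g))
        assert np.allclose(direct, regrouped, rtol=1e-12, atol=1e-12)


class TestEvalPlainMatrix:
    def test_worked_two_by_four_example(self, ctx, bundle):
        fx = fixture_small()
        _, scores = secure_matvec(ctx, bundle, fx["M"], fx["z"])
        assert np.allclose(scores, fx["expected_product"], atol=1e-4)

    def test_zero_matrix_evaluates_to_zero(self, ctx, bundle):
        _, scores = secure_matvec(ctx, bundle, np.zeros((4, 8)), np.ones(8))
        assert np.max(np.abs(scores)) < 1e-4

    def test_random_instances_match_oracle(self, ctx, bundle, rng):
        for t in range(5):
            M = rng.uniform(-1, 1, (8, 32))
            z = rng.uniform(-1, 1, 32)
            _, scores = secure_matvec(ctx, bundle, M, z, seed=t)
            ref = M @ z
            assert np.max(np.abs(scores - ref)) < 1e-4 * max(1, np.max(np.abs(ref)))

    def test_output_scale_returns_to_vector_scale(self, ctx, bundle, rng):
        M = rng.uniform(-1, 1, (4, 16))
        out, _ = secure_matvec(ctx, bundle, M, rng.uniform(-1, 1, 16))
        assert out.scale == pytest.approx(ctx.params.scale, rel=1e-9)

    def test_multiplication_count_equals_s_times_l(self, ctx, bundle, rng):
        M = rng.uniform(-1, 1, (8, 64))  # n=64 > N/2=32 -> s=2
        cnt = OpCounter()
        secure_matvec(ctx, bundle, M, rng.uniform(-1, 1, 64), counter=cnt)
        plan = make_plan(8, 64, ctx.N, True)
        assert plan.s == 2
        assert cnt.get("mult") == plan.s * plan.l


class TestFold:
    def test_gamma_zero_is_identity(self, ctx, bundle, rng):
        from ciphergeno.linear_eval import fold_columns
        M = rng.uniform(-1, 1, (8, 8))  # square packed: gamma may be zero
        plan = make_plan(8, 8, ctx.N, complex_packed=False)
        assert plan.gamma == 0
        ct = ctx.encrypt(ctx.encode(rng.uniform(-1, 1, ctx.slots)), bundle, seed=2)
        out = fold_columns(ctx, ct, plan, bundle)
        assert np.array_equal(out.c0, ct.c0)

    def test_plaintext_fold_recursion_sums_blocks(self):
        # l=1, gamma=2 on [a,b,c,d]: two rotate-and-add rounds give the total
        v = np.array([1.0, 2.0, 3.0, 4.0])
        ct = v.copy()
        for j in (1, 2):
            ct = ct + np.roll(ct, -(1 << (j - 1)))
        assert ct[0] == v.sum()

    def test_fold_step_count(self, ctx, bundle, rng):
        M = rng.uniform(-1, 1, (2, 4))
        plan = make_plan(2, 4, ctx.N, complex_packed=False)
        assert plan.gamma == 1  # one rotation by l=2 and one addition
        cnt = OpCounter()
        secure_matvec(ctx, bundle, M, rng.uniform(-1, 1, 4),
                      complex_packed=False, counter=cnt)
        # executed rotations: (g-1) baby + (b-1) giant + gamma fold
        assert cnt.get("rotation") == (plan.g - 1) + (plan.b - 1) + plan.gamma


class TestEvalEncryptedMatrix:
    def test_matches_plain_matrix_path(self, ctx, bundle, rng):
        for t in range(4):
            M = rng.uniform(-1, 1, (4, 16))
            z = rng.uniform(-1, 1, 16)
            _, s_plain = secure_matvec(ctx, bundle, M, z, seed=t)
            _, s_enc = secure_matvec(ctx, bundle, M, z, encrypted=True, seed=t)
            assert np.max(np.abs(s_enc - s_plain)) < 1e-3

    def test_identity_matrix_passes_vector_through(self, ctx, bundle):
        M = np.eye(2)
        _, scores = secure_matvec(ctx, bundle, M, np.array([5.0, 7.0]),
                                  encrypted=True)
        assert np.allclose(scores, [5.0, 7.0], atol=1e-3)

    @pytest.mark.parametrize("n_cols", [16, 32, 64, 96])
    def test_single_relin_regardless_of_submatrix_count(self, ctx, bundle, rng,
                                                        n_cols):
        M = rng.uniform(-1, 1, (4, n_cols))  # l=2 packed -> b=1
        cnt = OpCounter()
        secure_matvec(ctx, bundle, M, rng.uniform(-1, 1, n_cols),
                      encrypted=True, counter=cnt)
        plan = make_plan(4, n_cols, ctx.N, True)
        assert plan.s in (1, 2, 3)
        assert cnt.get("relin") == 1

    def test_relin_count_is_one_per_giant_step(self, ctx, bundle, rng):
        M = rng.uniform(-1, 1, (16, 32))  # l=8 -> g=4, b=2
        cnt = OpCounter()
        secure_matvec(ctx, bundle, M, rng.uniform(-1, 1, 32),
                      encrypted=True, counter=cnt)
        assert cnt.get("relin") == make_plan(16, 32, ctx.N, True).b


class TestSubmatrixAccumulation:
    def test_zero_second_submatrix_equals_single_chunk(self, ctx, bundle, rng):
        M1 = rng.uniform(-1, 1, (4, 32))
        z1 = rng.uniform(-1, 1, 32)
        M2 = np.hstack([M1, np.zeros((4, 32))])
        z2 = np.concatenate([z1, rng.uniform(-1, 1, 32)])  # columns are zero
        _, s1 = secure_matvec(ctx, bundle, M1, z1)
        _, s2 = secure_matvec(ctx, bundle, M2, z2)
        assert np.max(np.abs(s2 - s1)) < 1e-4

    def test_split_equals_unsplit_oracle(self, ctx, bundle, rng):
        M = rng.uniform(-1, 1, (4, 64))  # split into two 4x32 submatrices
        z = rng.uniform(-1, 1, 64)
        _, scores = secure_matvec(ctx, bundle, M, z)
        assert np.max(np.abs(scores - M @ z)) < 1e-4

    def test_giant_and_fold_rotations_independent_of_s(self, ctx, bundle, rng):
        counts = {}
        for n_cols in (32, 64, 96):
            M = rng.uniform(-1, 1, (16, n_cols))
            cnt = OpCounter()
            secure_matvec(ctx, bundle, M, rng.uniform(-1, 1, n_cols), counter=cnt)
            plan = make_plan(16, n_cols, ctx.N, True)
            # subtract the per-submatrix baby rotations: remainder is shared
            counts[n_cols] = cnt.get("rotation") - plan.s * (plan.g - 1)
        assert len(set(counts.values())) == 1


class TestIntercept:
    def _intercept_ct(self, ctx, bundle, w0, like, packed):
        value = w0 * (1 + 1j) if packed else w0
        pt = ctx.encode(np.full(ctx.slots, value), scale=like.scale,
                        level=like.level)
        return ctx.encrypt(pt, bundle, seed=3)

    def test_zero_intercept_is_identity(self, ctx, bundle):
        fx = fixture_small()
        out, _ = secure_matvec(ctx, bundle, fx["M"], fx["z"])
        shifted = add_intercept(ctx, out, self._intercept_ct(ctx, bundle, 0.0,
                                                             out, True))
        plan = make_plan(2, 4, ctx.N, True)
        assert np.allclose(extract_scores(ctx, shifted, plan, bundle),
                           [10, 26], atol=1e-3)

    def test_constant_shift(self, ctx, bundle):
        fx = fixture_small()
        out, _ = secure_matvec(ctx, bundle, fx["M"], fx["z"])
        shifted = add_intercept(ctx, out, self._intercept_ct(ctx, bundle, 1.0,
                                                             out, True))
        plan = make_plan(2, 4, ctx.N, True)
        assert np.allclose(extract_scores(ctx, shifted, plan, bundle),
                           [11, 27], atol=1e-3)

    def test_complex_packed_shifts_both_rows(self, ctx, bundle, rng):
        # rows 0 and 1 live in the real/imaginary parts of one slot
        M = rng.uniform(-1, 1, (2, 8))
        z = rng.uniform(-1, 1, 8)
        out, _ = secure_matvec(ctx, bundle, M, z)
        shifted = add_intercept(ctx, out, self._intercept_ct(ctx, bundle, 2.5,
                                                             out, True))
        plan = make_plan(2, 8, ctx.N, True)
        assert np.allclose(extract_scores(ctx, shifted, plan, bundle),
                           M @ z + 2.5, atol=1e-3)
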