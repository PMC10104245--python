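"""CKKS primitives against plaintext oracles at small-N parameters."""

import numpy as np
import pytest

from ciphergeno import small_test_params
from ciphergeno.ckks import CkksContext
from ciphergeno.errors import (CapacityError, LevelError, MissingKeyError,
                               ScaleMismatchError)
from ciphergeno.serialize import ciphertext_bytes, secret_key_bytes


def enc(ctx, bundle, v, seed=9):
    return ctx.encrypt(ctx.encode(v), bundle, seed=seed)


class TestEncoding:
    def test_roundtrip_random_vectors(self, ctx, rng):
        for _ in range(100):
            v = rng.uniform(-1, 1, ctx.slots)
            out = ctx.decode(ctx.encode(v))
            assert np.max(np.abs(out.real - v)) < 1e-5 * np.max(np.abs(v))

    def test_constant_vector_is_constant_polynomial(self, ctx):
        c = 0.8125
        pt = ctx.encode(np.full(ctx.slots, c))
        coeffs = ctx.basis(pt.level).to_int_coeffs(pt.residues)
        assert coeffs[0] == round(c * ctx.params.scale)
        assert all(x == 0 for x in coeffs[1:])

    def test_self_repeating_vector_decodes_to_single_copy(self, ctx, rng):
        v = rng.uniform(-1, 1, ctx.slots // 4)
        pt = ctx.encode(np.tile(v, 4))
        out = ctx.decode(pt, length=len(v))
        assert np.allclose(out.real, v, atol=1e-6)

    def test_complex_slots_roundtrip(self, ctx, rng):
        v = rng.uniform(-1, 1, ctx.slots) + 1j * rng.uniform(-1, 1, ctx.slots)
        out = ctx.decode(ctx.encode(v))
        assert np.max(np.abs(out - v)) < 1e-5

    def test_capacity_error_beyond_slot_count(self, ctx):
        with pytest.raises(CapacityError):
            ctx.encode(np.ones(ctx.slots + 1))


class TestKeygenEncrypt:
    def test_zero_vector_roundtrip(self, ctx, bundle):
        out = ctx.decrypt_decode(enc(ctx, bundle, np.zeros(ctx.slots)), bundle)
        assert np.max(np.abs(out)) < 1e-5

    def test_public_key_satisfies_rlwe_relation(self, ctx, bundle):
        # b - s·a must be the small sampled error
        basis = ctx.basis(ctx.top_level)
        s = bundle.secret[: ctx.top_level + 1]
        e = basis.to_int_coeffs(basis.sub(bundle.public_b,
                                          basis.poly_mul(s, bundle.public_a)))
        assert max(abs(x) for x in e) <= 6 * ctx.params.error_stddev

    def test_keygen_is_deterministic(self, ctx):
        k1 = ctx.keygen(seed=77, rotation_steps=(1,))
        k2 = ctx.keygen(seed=77, rotation_steps=(1,))
        assert secret_key_bytes(k1) == secret_key_bytes(k2)
        digest = ctx.params.digest()
        v = np.linspace(-1, 1, ctx.slots)
        c1 = ctx.encrypt(ctx.encode(v), k1, seed=5)
        c2 = ctx.encrypt(ctx.encode(v), k2, seed=5)
        assert ciphertext_bytes(c1, digest) == ciphertext_bytes(c2, digest)

    def test_encrypt_decrypt_roundtrip(self, ctx, bundle, rng):
        v = rng.uniform(-1, 1, ctx.slots)
        out = ctx.decrypt_decode(enc(ctx, bundle, v), bundle)
        assert np.max(np.abs(out.real - v)) < 1e-5

    def test_ciphertext_residues_look_uniform(self, ctx, bundle, rng):
        ct = enc(ctx, bundle, rng.uniform(-1, 1, ctx.slots))
        p = ctx.params.data_primes[0]
        # coarse frequency check: mean of residues near p/2
        mean = np.mean(ct.c0[0].astype(np.float64))
        assert abs(mean - p / 2) < p / 4

    def test_wrong_secret_key_decrypts_to_garbage(self, ctx, bundle, rng):
        v = rng.uniform(-1, 1, ctx.slots)
        other = ctx.keygen(seed=999)
        out = ctx.decrypt_decode(enc(ctx, bundle, v), other)
        assert np.max(np.abs(out.real - v)) > 1e3


class TestArithmetic:
    def test_add_matches_elementwise_sum(self, ctx, bundle, rng):
        v0, v1 = rng.uniform(-1, 1, (2, ctx.slots))
        out = ctx.decrypt_decode(
            ctx.add(enc(ctx, bundle, v0, 1), enc(ctx, bundle, v1, 2)), bundle)
        assert np.allclose(out.real, v0 + v1, atol=1e-4)

    def test_additive_inverse_cancels(self, ctx, bundle, rng):
        v = rng.uniform(-1, 1, ctx.slots)
        out = ctx.decrypt_decode(
            ctx.add(enc(ctx, bundle, v, 1), enc(ctx, bundle, -v, 2)), bundle)
        assert np.max(np.abs(out)) < 1e-4

    def test_add_plain_zero_is_identity(self, ctx, bundle, rng):
        v = rng.uniform(-1, 1, ctx.slots)
        ct = enc(ctx, bundle, v)
        out = ctx.add_plain(ct, ctx.encode(np.zeros(ctx.slots)))
        assert np.allclose(ctx.decrypt_decode(out, bundle).real,
                           ctx.decrypt_decode(ct, bundle).real)

    def test_add_rejects_scale_mismatch(self, ctx, bundle, rng):
        v = rng.uniform(-1, 1, ctx.slots)
        ct = enc(ctx, bundle, v)
        other = ctx.encrypt(ctx.encode(v, scale=2.0**20), bundle, seed=3)
        with pytest.raises(ScaleMismatchError):
            ctx.add(ct, other)

    def test_mul_plain_matches_hadamard(self, ctx, bundle):
        v = np.arange(1, ctx.slots + 1, dtype=float) / ctx.slots
        out = ctx.decrypt_decode(
            ctx.mul_plain(enc(ctx, bundle, v), ctx.encode(np.full(ctx.slots, 2.0))),
            bundle)
        assert np.allclose(out.real, 2 * v, atol=1e-4)

    def test_mul_plain_by_ones_and_zero(self, ctx, bundle, rng):
        v = rng.uniform(-1, 1, ctx.slots)
        ct = enc(ctx, bundle, v)
        ones = ctx.decrypt_decode(ctx.mul_plain(ct, ctx.encode(np.ones(ctx.slots))),
                                  bundle)
        assert np.allclose(ones.real, v, atol=1e-4)
        zero = ctx.decrypt_decode(ctx.mul_plain(ct, ctx.encode(np.zeros(ctx.slots))),
                                  bundle)
        assert np.max(np.abs(zero)) < 1e-4

    def test_mul_matches_hadamard_oracle(self, ctx, bundle, rng):
        v0, v1 = rng.uniform(-1, 1, (2, ctx.slots))
        out = ctx.decrypt_decode(
            ctx.mul(enc(ctx, bundle, v0, 1), enc(ctx, bundle, v1, 2), bundle), bundle)
        assert np.allclose(out.real, v0 * v1, atol=1e-4)

    def test_mul_by_encrypted_ones_is_identity(self, ctx, bundle, rng):
        v = rng.uniform(-1, 1, ctx.slots)
        out = ctx.decrypt_decode(
            ctx.mul(enc(ctx, bundle, v, 1), enc(ctx, bundle, np.ones(ctx.slots), 2),
                    bundle), bundle)
        assert np.allclose(out.real, v, atol=1e-4)

    def test_square_matches_oracle(self, ctx, bundle, rng):
        v = rng.uniform(-1, 1, ctx.slots)
        ct = enc(ctx, bundle, v)
        out = ctx.decrypt_decode(ctx.mul(ct, ct, bundle), bundle)
        assert np.allclose(out.real, v * v, atol=1e-4)

    def test_relin_after_sum_equals_sum_of_muls(self, ctx, bundle, rng):
        pairs = [(rng.uniform(-1, 1, ctx.slots), rng.uniform(-1, 1, ctx.slots))
                 for _ in range(8)]
        cts = [(enc(ctx, bundle, a, 2 * i), enc(ctx, bundle, b, 2 * i + 1))
               for i, (a, b) in enumerate(pairs)]
        lazy = None
        for c0, c1 in cts:
            t = ctx.mul_lazy(c0, c1)
            lazy = t if lazy is None else ctx.add_triple(lazy, t)
        via_lazy = ctx.decrypt_decode(ctx.relin(lazy, bundle), bundle)
        eager = None
        for c0, c1 in cts:
            m = ctx.mul(c0, c1, bundle)
            eager = m if eager is None else ctx.add(eager, m)
        via_eager = ctx.decrypt_decode(eager, bundle)
        ref = sum(a * b for a, b in pairs)
        assert np.allclose(via_lazy.real, via_eager.real, atol=1e-4)
        assert np.allclose(via_lazy.real, ref, atol=1e-4)


class TestRotation:
    def test_rotate_matches_cyclic_shift(self, ctx, bundle, rng):
        v = rng.uniform(-1, 1, ctx.slots)
        for k in (1, 2, 5, ctx.slots - 1):
            out = ctx.decrypt_decode(ctx.rotate(enc(ctx, bundle, v), k, bundle),
                                     bundle)
            assert np.allclose(out.real, np.roll(v, -k), atol=1e-4), k

    def test_rotate_zero_is_identity(self, ctx, bundle, rng):
        v = rng.uniform(-1, 1, ctx.slots)
        ct = enc(ctx, bundle, v)
        out = ctx.rotate(ct, 0, bundle)
        assert np.array_equal(out.c0, ct.c0) and np.array_equal(out.c1, ct.c1)

    def test_rotate_and_inverse_restore_vector(self, ctx, bundle, rng):
        v = rng.uniform(-1, 1, ctx.slots)
        k = 7
        ct = ctx.rotate(ctx.rotate(enc(ctx, bundle, v), k, bundle),
                        ctx.slots - k, bundle)
        assert np.allclose(ctx.decrypt_decode(ct, bundle).real, v, atol=1e-4)

    def test_missing_galois_key_raises(self, ctx, rng):
        kb = ctx.keygen(seed=5, rotation_steps=(1,))
        ct = ctx.encrypt(ctx.encode(rng.uniform(-1, 1, ctx.slots)), kb, seed=1)
        with pytest.raises(MissingKeyError):
            ctx.rotate(ct, 3, kb)


class TestRescale:
    def test_rescale_preserves_product(self, ctx, bundle, rng):
        v0, v1 = rng.uniform(-1, 1, (2, ctx.slots))
        prod = ctx.mul_plain(enc(ctx, bundle, v0), ctx.encode(v1))
        without = ctx.decrypt_decode(prod, bundle)
        with_rs = ctx.decrypt_decode(ctx.rescale(prod), bundle)
        assert np.allclose(with_rs.real, without.real, atol=1e-4)
        assert np.allclose(with_rs.real, v0 * v1, atol=1e-4)

    def test_scale_bookkeeping(self, ctx, bundle, rng):
        prod = ctx.mul_plain(enc(ctx, bundle, rng.uniform(-1, 1, ctx.slots)),
                             ctx.encode(np.ones(ctx.slots)))
        rs = ctx.rescale(prod)
        dropped = ctx.params.data_primes[prod.level]
        assert rs.scale == pytest.approx(prod.scale / dropped)
        assert rs.level == prod.level - 1

    def test_rescaling_past_bottom_level_raises(self, ctx, bundle, rng):
        prod = ctx.mul_plain(enc(ctx, bundle, rng.uniform(-1, 1, ctx.slots)),
                             ctx.encode(np.ones(ctx.slots)))
        once = ctx.rescale(prod)  # depth-1 budget on a 3-prime chain
        with pytest.raises(LevelError):
            ctx.rescale(once)
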