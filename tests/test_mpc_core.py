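"""Secret-sharing primitives: correctness on the ring, triples, conversions."""

import numpy as np
import pytest

from kepsolve.mpc import (
    BeaverTriple,
    MPCEngine,
    TripleReuseError,
    a2b,
    and_shares,
    b2a,
    bit_decompose,
    mul_shares,
    mux,
    not_share,
    or_shares,
    reconstruct,
    reconstruct_bool,
    share,
    share_bool,
    xor_shares,
)


class TestSharing:
    def test_round_trip_identity(self, rng):
        for _ in range(50):
            x = int(rng.integers(0, 2 ** 32))
            assert reconstruct(*share(x, 32, rng)) == x

    def test_zero_shares_sum_to_zero(self):
        s0, s1 = share(0, 32, 5)
        assert (s0.value + s1.value) % 2 ** 32 == 0

    def test_different_seeds_different_shares(self):
        a = share(5, 32, 1)[0].value
        b = share(5, 32, 2)[0].value
        assert a != b

    def test_single_share_uniformish(self, rng):
        """Party 0's share of a constant is spread over the ring."""
        vals = [share(42, 16, int(rng.integers(1 << 30)))[0].value for _ in range(400)]
        assert len(set(vals)) > 350

    def test_out_of_ring_rejected(self):
        with pytest.raises(ValueError):
            share(2 ** 32, 32, 0)


class TestMultiplication:
    @pytest.mark.parametrize("x, y, expected",
                             [(0, 12345, 0), (3, 4, 12),
                              (2 ** 31, 2, 0),           # ring wraparound
                              (2 ** 16, 2 ** 16, 0)])
    def test_products(self, rng, x, y, expected):
        z = mul_shares(share(x, 32, rng), share(y, 32, rng),
                       BeaverTriple.generate(rng, 32))
        assert reconstruct(*z) == expected

    def test_triple_reuse_rejected(self, rng):
        t = BeaverTriple.generate(rng, 32)
        x, y = share(3, 32, rng), share(4, 32, rng)
        mul_shares(x, y, t)
        with pytest.raises(TripleReuseError):
            mul_shares(x, y, t)

    def test_random_products(self, rng):
        for _ in range(100):
            x, y = (int(v) for v in rng.integers(0, 2 ** 32, size=2))
            z = mul_shares(share(x, 32, rng), share(y, 32, rng),
                           BeaverTriple.generate(rng, 32))
            assert reconstruct(*z) == (x * y) % 2 ** 32


class TestBooleanGates:
    def test_truth_tables(self, rng):
        for xa in (0, 1):
            for ya in (0, 1):
                xs, ys = share_bool(xa, rng), share_bool(ya, rng)
                assert reconstruct_bool(
                    *and_shares(xs, ys, BeaverTriple.generate_bool(rng))
                ) == (xa & ya)
                assert reconstruct_bool(
                    *or_shares(xs, ys, BeaverTriple.generate_bool(rng))
                ) == (xa | ya)
                assert reconstruct_bool(*xor_shares(xs, ys)) == xa ^ ya
        assert reconstruct_bool(*not_share(share_bool(1, rng))) == 0

    def test_mux_exhaustive(self, rng):
        for s in (0, 1):
            for a in (0, 1):
                for b in (0, 1):
                    out = mux(share_bool(s, rng), share_bool(a, rng),
                              share_bool(b, rng), BeaverTriple.generate_bool(rng))
                    assert reconstruct_bool(*out) == (a if s else b)


class TestConversions:
    def test_bit_decompose(self):
        assert bit_decompose(6, 4) == (0, 1, 1, 0)

    def test_a2b_b2a_round_trip(self, rng):
        for _ in range(200):
            x = int(rng.integers(0, 2 ** 32))
            bits = a2b(share(x, 32, rng), rng)
            assert reconstruct(*b2a(bits, 32, rng)) == x

    def test_a2b_bits_match_cleartext_decomposition(self, rng):
        for _ in range(50):
            x = int(rng.integers(0, 2 ** 16))
            bits = a2b(share(x, 16, rng), rng)
            assert tuple(reconstruct_bool(*b) for b in bits) == bit_decompose(x, 16)


class TestEngine:
    def test_vector_mul_and_matmul(self, rng):
        e = MPCEngine(seed=1)
        a = rng.integers(0, 1000, size=(4, 4))
        b = rng.integers(0, 1000, size=(4, 4))
        za = e.share_arith(a)
        zb = e.share_arith(b)
        prod = e.declassify(e.a_mul(za, zb), "test")
        assert (prod == (a * b) % 2 ** 32).all()
        mm = e.declassify(e.a_matmul(za, zb), "test")
        assert (mm == (a @ b) % 2 ** 32).all()

    def test_comparisons_match_cleartext(self, rng):
        e = MPCEngine(seed=2)
        x = rng.integers(0, 1000, size=200)
        y = rng.integers(0, 1000, size=200)
        sx, sy = e.share_arith(x), e.share_arith(y)
        lt = e.declassify(e.lt(sx, sy), "test")
        assert (lt == (x < y)).all()
        gt0 = e.declassify(e.gt_zero(sx), "test")
        assert (gt0 == (x > 0)).all()
        eq = e.declassify(e.eq(sx, sy), "test")
        assert (eq == (x == y)).all()

    def test_mux_arith_selects(self, rng):
        e = MPCEngine(seed=3)
        sel = rng.integers(0, 2, size=100)
        a = rng.integers(0, 1000, size=100)
        b = rng.integers(0, 1000, size=100)
        out = e.declassify(
            e.mux_arith(e.share_bool(sel), e.share_arith(a), e.share_arith(b)),
            "test",
        )
        assert (out == np.where(sel, a, b)).all()

    def test_or_tree_and_gate_counts(self):
        e = MPCEngine(seed=4)
        with e.phase("p"):
            bits = e.share_bool(np.array([[1, 0, 0, 0, 0], [0] * 5]))
            out = e.declassify(e.b_or_tree(bits), "test")
        assert out.tolist() == [1, 0]
        assert e.report.phases["p"].or_gates == 2 * 4  # size-1 per row

    def test_reconstruct_unsafe_is_audited(self):
        e = MPCEngine(seed=5)
        x = e.share_arith(np.array([7]))
        assert e.audit_violations == 0
        e.reconstruct_unsafe(x)
        assert e.audit_violations == 1
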