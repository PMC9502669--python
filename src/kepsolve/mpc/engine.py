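"""Vectorized two-party computation simulator.

Simulates both computation servers in one process, operating on additive
arithmetic shares over ``Z_{2^l}`` and XOR Boolean shares, with SIMD-style
numpy vectorization.  Correlated randomness (Beaver triples, arithmetic/
Boolean double-sharings for conversions) comes from a seeded trusted-dealer
abstraction, the standard semi-honest preprocessing model.

Accounting and auditing:

* every interactive operation is tallied per pipeline phase into a
  :class:`~kepsolve.mpc.costs.CostReport`;
* the only code paths that combine both shares of a value are
  ``_open_masked`` (values one-time-padded by dealer randomness, counted)
  and :meth:`declassify` (explicit, labelled reveals).  Any other
  reconstruction increments ``audit_violations``, which tests assert to be
  zero.

Communication model (per element): a Boolean AND/OR/MUX costs
``1.5 * kappa`` bits (garbled-circuit convention, free XOR); an A->B
conversion costs ``l - 1`` AND-equivalents (ripple-carry on shared bits); an
arithmetic multiplication, a B->A bit lift and an arithmetic MUX each open
two masked ring elements per party (``4l`` bits).
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

from .costs import CostReport, PhaseCost, DEFAULT_KAPPA

__all__ = ["MPCEngine", "AShared", "BShared"]

_U = np.uint64


class AShared:
    """Arithmetic shares of an ndarray: one share array per party."""

    __slots__ = ("s0", "s1")

    def __init__(self, s0: np.ndarray, s1: np.ndarray):
        self.s0 = s0
        self.s1 = s1

    @property
    def shape(self):
        return self.s0.shape


class BShared:
    """Boolean (XOR) shares of a 0/1 ndarray."""

    __slots__ = ("s0", "s1")

    def __init__(self, s0: np.ndarray, s1: np.ndarray):
        self.s0 = s0
        self.s1 = s1

    @property
    def shape(self):
        return self.s0.shape


class MPCEngine:
    """Both simulated parties, the trusted dealer, and the cost/audit books."""

    def __init__(self, bitlength: int = 32, kappa: int = DEFAULT_KAPPA,
                 seed: int = 0):
        if not 8 <= bitlength <= 63:
            raise ValueError("bitlength must be in 8..63")
        self.l = bitlength
        self.mask = _U((1 << bitlength) - 1)
        self.kappa = kappa
        seq = np.random.SeedSequence(seed)
        dealer_seq, input_seq = seq.spawn(2)
        self._dealer = np.random.default_rng(dealer_seq)
        self._input_rng = np.random.default_rng(input_seq)
        self.report = CostReport(kappa=kappa, bitlength=bitlength)
        self._phase = "setup"
        self.audit_violations = 0
        self.masked_opens = 0
        self.declassified: list[tuple[str, object]] = []

    # ------------------------------------------------------------------ admin
    @contextmanager
    def phase(self, name: str):
        prev, self._phase = self._phase, name
        try:
            yield self.report.phase(name)
        finally:
            self._phase = prev

    def _cost(self) -> PhaseCost:
        return self.report.phase(self._phase)

    def tally(self, *, and_gates=0, or_gates=0, mux_gates=0, comparisons=0,
              multiplications=0, additions=0, a2b=0, b2a=0) -> None:
        p = self._cost()
        p.and_gates += and_gates
        p.or_gates += or_gates
        p.mux_gates += mux_gates
        p.comparisons += comparisons
        p.multiplications += multiplications
        p.additions += additions
        p.conversions_a2b += a2b
        p.conversions_b2a += b2a
        kap = 1.5 * self.kappa
        p.comm_bits += kap * (and_gates + or_gates + mux_gates)
        p.comm_bits += kap * (self.l - 1) * a2b
        # arithmetic openings: 4l bits per multiplication / bit lift
        p.comm_bits += 4.0 * self.l * (multiplications + b2a)

    # ---------------------------------------------------------------- sharing
    def _rand_ring(self, shape) -> np.ndarray:
        return self._dealer.integers(0, 1 << self.l, size=shape, dtype=np.uint64)

    def share_arith(self, values) -> AShared:
        v = np.asarray(values, dtype=np.int64).astype(_U) & self.mask
        r = self._input_rng.integers(0, 1 << self.l, size=v.shape, dtype=np.uint64)
        return AShared(r, (v - r) & self.mask)

    def share_bool(self, bits) -> BShared:
        b = np.asarray(bits, dtype=np.uint8) & 1
        r = self._input_rng.integers(0, 2, size=b.shape, dtype=np.uint8)
        return BShared(r, b ^ r)

    def public_arith(self, values) -> AShared:
        """Trivial sharing of public data (party 0 holds the value)."""
        v = np.asarray(values, dtype=np.int64).astype(_U) & self.mask
        return AShared(v, np.zeros_like(v))

    def public_bool(self, bits) -> BShared:
        b = np.asarray(bits, dtype=np.uint8) & 1
        return BShared(b, np.zeros_like(b))

    # ---------------------------------------------------------------- opening
    def _open_masked(self, x) -> np.ndarray:
        """Combine shares of a value one-time-padded by dealer randomness."""
        self.masked_opens += 1
        if isinstance(x, AShared):
            return (x.s0 + x.s1) & self.mask
        return x.s0 ^ x.s1

    def declassify(self, x, label: str):
        """Explicit, labelled reveal of a shared value (audited)."""
        if isinstance(x, AShared):
            value = np.asarray((x.s0 + x.s1) & self.mask)
        else:
            value = np.asarray(x.s0 ^ x.s1)
        self.declassified.append((label, value))
        labels = self.report.declassified_labels
        if label not in labels:
            self.report.declassified_labels = labels + (label,)
        return value

    def reconstruct_unsafe(self, x) -> np.ndarray:
        """Raw reconstruction outside the protocol — counted as a violation."""
        self.audit_violations += 1
        self.report.audit_violations = self.audit_violations
        if isinstance(x, AShared):
            return (x.s0 + x.s1) & self.mask
        return x.s0 ^ x.s1

    # ------------------------------------------------------------- arithmetic
    def a_add(self, x: AShared, y: AShared) -> AShared:
        return AShared((x.s0 + y.s0) & self.mask, (x.s1 + y.s1) & self.mask)

    def a_sub(self, x: AShared, y: AShared) -> AShared:
        return AShared((x.s0 - y.s0) & self.mask, (x.s1 - y.s1) & self.mask)

    def a_add_pub(self, x: AShared, c) -> AShared:
        c = np.asarray(c, dtype=np.int64).astype(_U)
        return AShared((x.s0 + c) & self.mask, x.s1.copy())

    def a_mul_pub(self, x: AShared, c) -> AShared:
        c = np.asarray(c, dtype=np.int64).astype(_U)
        return AShared((x.s0 * c) & self.mask, (x.s1 * c) & self.mask)

    def _beaver(self, x: AShared, y: AShared) -> AShared:
        """Uncounted Beaver product (callers tally the right cost class)."""
        shape = np.broadcast_shapes(x.shape, y.shape)
        a, b = self._rand_ring(shape), self._rand_ring(shape)
        c = (a * b) & self.mask
        a0, b0, c0 = self._rand_ring(shape), self._rand_ring(shape), self._rand_ring(shape)
        a1, b1, c1 = (a - a0) & self.mask, (b - b0) & self.mask, (c - c0) & self.mask
        d = self._open_masked(AShared((x.s0 - a0) & self.mask, (x.s1 - a1) & self.mask))
        e = self._open_masked(AShared((y.s0 - b0) & self.mask, (y.s1 - b1) & self.mask))
        z0 = (c0 + d * b0 + e * a0 + d * e) & self.mask
        z1 = (c1 + d * b1 + e * a1) & self.mask
        return AShared(z0, z1)

    def a_mul(self, x: AShared, y: AShared) -> AShared:
        z = self._beaver(x, y)
        self.tally(multiplications=int(np.prod(z.shape) or 1))
        return z

    def a_matmul(self, x: AShared, y: AShared) -> AShared:
        """Matrix product via a matrix Beaver triple (c = a @ b)."""
        n, k = x.shape
        k2, m = y.shape
        assert k == k2
        a, b = self._rand_ring((n, k)), self._rand_ring((k, m))
        c = (a @ b) & self.mask
        a0, b0, c0 = self._rand_ring((n, k)), self._rand_ring((k, m)), self._rand_ring((n, m))
        a1, b1, c1 = (a - a0) & self.mask, (b - b0) & self.mask, (c - c0) & self.mask
        d = self._open_masked(AShared((x.s0 - a0) & self.mask, (x.s1 - a1) & self.mask))
        e = self._open_masked(AShared((y.s0 - b0) & self.mask, (y.s1 - b1) & self.mask))
        z0 = (c0 + d @ b0 + a0 @ e + d @ e) & self.mask
        z1 = (c1 + d @ b1 + a1 @ e) & self.mask
        self.tally(multiplications=n * k * m, additions=n * m * (k - 1))
        return AShared(z0, z1)

    # ---------------------------------------------------------------- boolean
    def b_xor(self, x: BShared, y: BShared) -> BShared:
        return BShared(x.s0 ^ y.s0, x.s1 ^ y.s1)

    def b_not(self, x: BShared) -> BShared:
        return BShared(x.s0 ^ 1, x.s1.copy())

    def _and_raw(self, x: BShared, y: BShared) -> BShared:
        shape = np.broadcast_shapes(x.shape, y.shape)
        a = self._dealer.integers(0, 2, size=shape, dtype=np.uint8)
        b = self._dealer.integers(0, 2, size=shape, dtype=np.uint8)
        c = a & b
        a0 = self._dealer.integers(0, 2, size=shape, dtype=np.uint8)
        b0 = self._dealer.integers(0, 2, size=shape, dtype=np.uint8)
        c0 = self._dealer.integers(0, 2, size=shape, dtype=np.uint8)
        a1, b1, c1 = a ^ a0, b ^ b0, c ^ c0
        d = self._open_masked(BShared(x.s0 ^ a0, x.s1 ^ a1))
        e = self._open_masked(BShared(y.s0 ^ b0, y.s1 ^ b1))
        z0 = c0 ^ (d & b0) ^ (e & a0) ^ (d & e)
        z1 = c1 ^ (d & b1) ^ (e & a1)
        return BShared(z0, z1)

    def b_and(self, x: BShared, y: BShared) -> BShared:
        z = self._and_raw(x, y)
        self.tally(and_gates=int(np.prod(z.shape) or 1))
        return z

    def b_or(self, x: BShared, y: BShared) -> BShared:
        z = self.b_not(self._and_raw(self.b_not(x), self.b_not(y)))
        self.tally(or_gates=int(np.prod(z.shape) or 1))
        return z

    def b_mux(self, sel: BShared, a: BShared, b: BShared) -> BShared:
        """Boolean multiplexer ``b ^ (sel & (a ^ b))`` — one AND-equivalent."""
        z = self.b_xor(b, self._and_raw(sel, self.b_xor(a, b)))
        self.tally(mux_gates=int(np.prod(z.shape) or 1))
        return z

    def b_or_tree(self, x: BShared, axis: int = -1) -> BShared:
        """OR-reduce along an axis in a balanced tree (depth ceil(log2 n))."""
        s0, s1 = np.moveaxis(x.s0, axis, -1), np.moveaxis(x.s1, axis, -1)
        cur = BShared(s0, s1)
        while cur.s0.shape[-1] > 1:
            w = cur.s0.shape[-1]
            half = w // 2
            left = BShared(cur.s0[..., :half], cur.s1[..., :half])
            right = BShared(cur.s0[..., half:2 * half], cur.s1[..., half:2 * half])
            merged = self.b_or(left, right)
            if w % 2:
                merged = BShared(
                    np.concatenate([merged.s0, cur.s0[..., -1:]], axis=-1),
                    np.concatenate([merged.s1, cur.s1[..., -1:]], axis=-1),
                )
            cur = merged
        return BShared(cur.s0[..., 0], cur.s1[..., 0])

    # ------------------------------------------------------------ conversions
    def a2b(self, x: AShared) -> BShared:
        """Arithmetic -> Boolean: shared bits (last axis, LSB first).

        Dealer supplies a double-sharing of a uniform ``r``; the parties open
        the padded ``x - r`` publicly and ripple-add its public bits onto the
        shared bits of ``r`` (``l - 1`` AND gates per element, charged to the
        conversion).
        """
        shape = x.shape
        r_bits = self._dealer.integers(0, 2, size=shape + (self.l,), dtype=np.uint8)
        weights = (_U(1) << np.arange(self.l, dtype=_U))
        r = (r_bits.astype(_U) * weights).sum(axis=-1) & self.mask
        r0 = self._rand_ring(shape)
        rb0 = self._dealer.integers(0, 2, size=shape + (self.l,), dtype=np.uint8)
        r_arith = AShared(r0, (r - r0) & self.mask)
        rb = BShared(rb0, r_bits ^ rb0)

        m = self._open_masked(
            AShared((x.s0 - r_arith.s0) & self.mask, (x.s1 - r_arith.s1) & self.mask)
        )
        m_bits = ((m[..., None] >> np.arange(self.l, dtype=_U)) & _U(1)).astype(np.uint8)

        out0 = np.empty(shape + (self.l,), dtype=np.uint8)
        out1 = np.empty(shape + (self.l,), dtype=np.uint8)
        carry = BShared(np.zeros(shape, dtype=np.uint8), np.zeros(shape, dtype=np.uint8))
        for i in range(self.l):
            mi = m_bits[..., i]
            ri = BShared(rb.s0[..., i], rb.s1[..., i])
            axb = BShared(ri.s0 ^ mi, ri.s1)  # public XOR is local
            s = self.b_xor(axb, carry)
            out0[..., i], out1[..., i] = s.s0, s.s1
            if i < self.l - 1:
                g = BShared(ri.s0 & mi, ri.s1 & mi)  # public AND is local
                carry = self.b_xor(g, self._and_raw(carry, axb))
        self.tally(a2b=int(np.prod(shape) or 1))
        return BShared(out0, out1)

    def b2a_bit(self, b: BShared) -> AShared:
        """Lift a Boolean-shared bit into the arithmetic ring.

        ``x = b0 + b1 - 2*b0*b1``; the cross term uses one triple (each party
        arithmetically shares its own Boolean share locally).
        """
        x = AShared(b.s0.astype(_U), np.zeros(b.shape, dtype=_U))
        y = AShared(np.zeros(b.shape, dtype=_U), b.s1.astype(_U))
        prod = self._beaver(x, y)
        two = _U(2)
        z = AShared(
            (x.s0 + y.s0 - two * prod.s0) & self.mask,
            (x.s1 + y.s1 - two * prod.s1) & self.mask,
        )
        self.tally(b2a=int(np.prod(b.shape) or 1))
        return z

    # ------------------------------------------------------ derived operators
    def msb(self, x: AShared) -> BShared:
        """Top bit of the ring representation (sign for small magnitudes)."""
        bits = self.a2b(x)
        return BShared(bits.s0[..., -1], bits.s1[..., -1])

    def gt_zero(self, x: AShared) -> BShared:
        """``x > 0`` for values in ``[0, 2^(l-1))``: OR over the shared bits."""
        return self.b_or_tree(self.a2b(x))

    def lt(self, x: AShared, y: AShared) -> BShared:
        """``x < y`` assuming ``|x - y| < 2^(l-1)``: sign of the difference."""
        return self.msb(self.a_sub(x, y))

    def eq(self, x: AShared, y: AShared) -> BShared:
        return self.b_not(self.b_or_tree(self.a2b(self.a_sub(x, y))))

    def mux_arith(self, sel: BShared, a, b) -> AShared:
        """Arithmetic MUX ``sel ? a : b``: one bit lift plus one masked product."""
        if not isinstance(a, AShared):
            a = self.public_arith(a)
        if not isinstance(b, AShared):
            b = self.public_arith(b)
        x = AShared(sel.s0.astype(_U), np.zeros(sel.shape, dtype=_U))
        y = AShared(np.zeros(sel.shape, dtype=_U), sel.s1.astype(_U))
        prod = self._beaver(x, y)
        two = _U(2)
        t = AShared(
            (x.s0 + y.s0 - two * prod.s0) & self.mask,
            (x.s1 + y.s1 - two * prod.s1) & self.mask,
        )
        diff = self.a_sub(a, b)
        gated = self._beaver(t, diff)
        self.tally(mux_gates=int(np.prod(np.broadcast_shapes(sel.shape, diff.shape)) or 1))
        return self.a_add(b, gated)

    def cswap_desc(self, swap: BShared, fields_i, fields_j):
        """Conditionally exchange two slot tuples (one bit lift, one product
        per field element); used by the oblivious exchange sort."""
        x = AShared(swap.s0.astype(_U), np.zeros(swap.shape, dtype=_U))
        y = AShared(np.zeros(swap.shape, dtype=_U), swap.s1.astype(_U))
        prod = self._beaver(x, y)
        two = _U(2)
        t = AShared(
            (x.s0 + y.s0 - two * prod.s0) & self.mask,
            (x.s1 + y.s1 - two * prod.s1) & self.mask,
        )
        out_i, out_j = [], []
        for fi, fj in zip(fields_i, fields_j):
            diff = self.a_sub(fj, fi)
            d = self._beaver(t, diff)
            out_i.append(self.a_add(fi, d))
            out_j.append(self.a_sub(fj, d))
            self.tally(mux_gates=int(np.prod(diff.shape) or 1))
        return out_i, out_j
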