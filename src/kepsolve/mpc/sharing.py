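"""Two-party additive and Boolean secret sharing, scalar protocol surface.

An arithmetic share of ``x`` over the ring ``Z_{2^l}`` is a pair of values
``(r, x - r mod 2^l)`` with ``r`` uniform; a single share is independent of
the secret.  Boolean sharing is the ``l = 1`` special case with XOR
reconstruction.  Addition/XOR are local; multiplication/AND consume one
dealer-supplied Beaver triple ``(a, b, c = a*b)`` in an interactive
exchange of masked differences.  These scalar functions simulate both
parties in one process and are the reference semantics for the vectorized
engine used by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArithShare", "BoolShare", "BeaverTriple", "TripleReuseError",
    "share", "reconstruct", "share_bool", "reconstruct_bool",
    "mul_shares", "xor_shares", "and_shares", "not_share", "or_shares",
    "mux", "bit_decompose", "a2b", "b2a",
]

DEFAULT_BITLENGTH = 32


class TripleReuseError(RuntimeError):
    """A Beaver triple was consumed twice — a protocol violation."""


@dataclass(frozen=True)
class ArithShare:
    """One party's additive share of an integer in ``Z_{2^l}``."""

    party: int
    value: int
    bitlength: int = DEFAULT_BITLENGTH

    def __post_init__(self) -> None:
        if self.party not in (0, 1):
            raise ValueError(f"party must be 0 or 1, got {self.party}")
        if not 0 <= self.value < (1 << self.bitlength):
            raise ValueError("share value outside the ring")


@dataclass(frozen=True)
class BoolShare:
    """One party's XOR share of a single bit."""

    party: int
    bit: int

    def __post_init__(self) -> None:
        if self.party not in (0, 1):
            raise ValueError(f"party must be 0 or 1, got {self.party}")
        if self.bit not in (0, 1):
            raise ValueError(f"bit share must be 0 or 1, got {self.bit}")


@dataclass
class BeaverTriple:
    """Dealer-issued correlated randomness: shares of ``(a, b, c = a*b)``.

    ``boolean=True`` triples multiply in ``Z_2`` (AND).  A triple is
    single-use; reusing one raises :class:`TripleReuseError`.
    """

    a: tuple[int, int]
    b: tuple[int, int]
    c: tuple[int, int]
    bitlength: int = DEFAULT_BITLENGTH
    boolean: bool = False
    _consumed: bool = field(default=False, repr=False)

    @classmethod
    def generate(cls, rng: np.random.Generator,
                 bitlength: int = DEFAULT_BITLENGTH) -> "BeaverTriple":
        mod = 1 << bitlength
        a, b = int(rng.integers(mod)), int(rng.integers(mod))
        c = (a * b) % mod
        ra, rb, rc = (int(rng.integers(mod)) for _ in range(3))
        return cls(a=(ra, (a - ra) % mod), b=(rb, (b - rb) % mod),
                   c=(rc, (c - rc) % mod), bitlength=bitlength)

    @classmethod
    def generate_bool(cls, rng: np.random.Generator) -> "BeaverTriple":
        a, b = int(rng.integers(2)), int(rng.integers(2))
        c = a & b
        ra, rb, rc = (int(rng.integers(2)) for _ in range(3))
        return cls(a=(ra, a ^ ra), b=(rb, b ^ rb), c=(rc, c ^ rc),
                   bitlength=1, boolean=True)

    def consume(self) -> None:
        if self._consumed:
            raise TripleReuseError("Beaver triple reused; triples are single-use")
        self._consumed = True


def _rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def share(x: int, bitlength: int = DEFAULT_BITLENGTH,
          rng_seed=None) -> tuple[ArithShare, ArithShare]:
    """Split ``x`` into two additive shares summing to ``x`` mod ``2^l``."""
    mod = 1 << bitlength
    if not 0 <= x < mod:
        raise ValueError(f"{x} outside the ring Z_2^{bitlength}")
    r = int(_rng(rng_seed).integers(mod))
    return (ArithShare(0, r, bitlength), ArithShare(1, (x - r) % mod, bitlength))


def reconstruct(s0: ArithShare, s1: ArithShare) -> int:
    if s0.bitlength != s1.bitlength or {s0.party, s1.party} != {0, 1}:
        raise ValueError("need one share per party with matching bitlength")
    return (s0.value + s1.value) % (1 << s0.bitlength)


def share_bool(bit: int, rng_seed=None) -> tuple[BoolShare, BoolShare]:
    if bit not in (0, 1):
        raise ValueError(f"bit must be 0 or 1, got {bit}")
    r = int(_rng(rng_seed).integers(2))
    return (BoolShare(0, r), BoolShare(1, bit ^ r))


def reconstruct_bool(b0: BoolShare, b1: BoolShare) -> int:
    if {b0.party, b1.party} != {0, 1}:
        raise ValueError("need one share per party")
    return b0.bit ^ b1.bit


SharePair = tuple[ArithShare, ArithShare]
BitPair = tuple[BoolShare, BoolShare]


def _check_pair(x: SharePair, bitlength: int | None = None) -> int:
    if {x[0].party, x[1].party} != {0, 1}:
        raise ValueError("a share pair must hold one share per party")
    if x[0].bitlength != x[1].bitlength:
        raise ValueError("mismatched bitlengths within a share pair")
    if bitlength is not None and x[0].bitlength != bitlength:
        raise ValueError("mismatched bitlengths across operands")
    return x[0].bitlength


def mul_shares(x: SharePair, y: SharePair, triple: BeaverTriple) -> SharePair:
    """Beaver multiplication: reconstructs to ``x * y`` mod ``2^l``.

    Each party opens its masked differences ``d_i = x_i - a_i`` and
    ``e_i = y_i - b_i`` (one round of communication); the opened values are
    one-time-padded by the triple and leak nothing.
    """
    l = _check_pair(x)
    _check_pair(y, l)
    if triple.boolean or triple.bitlength != l:
        raise ValueError("triple does not match the operand ring")
    triple.consume()
    mod = 1 << l
    d = (x[0].value - triple.a[0] + x[1].value - triple.a[1]) % mod
    e = (y[0].value - triple.b[0] + y[1].value - triple.b[1]) % mod
    z = []
    for i in (0, 1):
        zi = (triple.c[i] + d * triple.b[i] + e * triple.a[i]) % mod
        if i == 0:
            zi = (zi + d * e) % mod
        z.append(ArithShare(i, zi, l))
    return (z[0], z[1])


def xor_shares(x: BitPair, y: BitPair) -> BitPair:
    """Free local XOR."""
    return (BoolShare(0, x[0].bit ^ y[0].bit), BoolShare(1, x[1].bit ^ y[1].bit))


def not_share(x: BitPair) -> BitPair:
    """Free local NOT (party 0 flips its share)."""
    return (BoolShare(0, x[0].bit ^ 1), BoolShare(1, x[1].bit))


def and_shares(x: BitPair, y: BitPair, triple: BeaverTriple) -> BitPair:
    """Beaver AND over ``Z_2``; consumes one Boolean triple."""
    if not triple.boolean:
        raise ValueError("AND requires a Boolean triple")
    triple.consume()
    d = x[0].bit ^ triple.a[0] ^ x[1].bit ^ triple.a[1]
    e = y[0].bit ^ triple.b[0] ^ y[1].bit ^ triple.b[1]
    z = []
    for i in (0, 1):
        zi = triple.c[i] ^ (d & triple.b[i]) ^ (e & triple.a[i])
        if i == 0:
            zi ^= d & e
        z.append(BoolShare(i, zi))
    return (z[0], z[1])


def or_shares(x: BitPair, y: BitPair, triple: BeaverTriple) -> BitPair:
    """OR as ``not(and(not x, not y))`` — one AND-equivalent gate."""
    return not_share(and_shares(not_share(x), not_share(y), triple))


def mux(sel: BitPair, a: BitPair, b: BitPair, triple: BeaverTriple) -> BitPair:
    """Oblivious selector ``sel ? a : b``, realized as ``b ^ (sel & (a ^ b))``."""
    return xor_shares(b, and_shares(sel, xor_shares(a, b), triple))


def bit_decompose(x: int, bitlength: int) -> tuple[int, ...]:
    """Public little-endian binary expansion (LSB first)."""
    return tuple((x >> i) & 1 for i in range(bitlength))


def a2b(x: SharePair, rng_seed=None) -> list[BitPair]:
    """Convert an arithmetic share pair to Boolean shares of its bits.

    Uses dealer-supplied correlated randomness: arithmetic and bitwise
    Boolean shares of the same uniform ring element ``r``.  The parties open
    the one-time-padded value ``x - r`` and add its (public) bits to the
    shared bits of ``r`` with a ripple-carry adder, dropping the final carry.
    Returns bits LSB first.
    """
    l = _check_pair(x)
    rng = _rng(rng_seed)
    mod = 1 << l
    r = int(rng.integers(mod))
    r_arith = share(r, l, rng)
    r_bits = [share_bool(b, rng) for b in bit_decompose(r, l)]
    m = (x[0].value - r_arith[0].value + x[1].value - r_arith[1].value) % mod
    m_bits = bit_decompose(m, l)

    out: list[BitPair] = []
    carry: BitPair = (BoolShare(0, 0), BoolShare(1, 0))
    for i in range(l):
        mi = m_bits[i]
        # axb = m_i XOR r_i : public XOR is local (party 0 applies it)
        axb = (BoolShare(0, r_bits[i][0].bit ^ mi), r_bits[i][1])
        out.append(xor_shares(axb, carry))
        if i < l - 1:
            # carry' = (m_i AND r_i) XOR (carry AND axb); the first term is a
            # local masking by the public bit m_i, the second one AND gate.
            g = (BoolShare(0, r_bits[i][0].bit & mi), BoolShare(1, r_bits[i][1].bit & mi))
            t = and_shares(carry, axb, BeaverTriple.generate_bool(rng))
            carry = xor_shares(g, t)
    return out


def b2a(bits: list[BitPair], bitlength: int = DEFAULT_BITLENGTH,
        rng_seed=None) -> SharePair:
    """Convert Boolean shares of bits (LSB first) to one arithmetic pair.

    Each bit ``x = x0 XOR x1 = x0 + x1 - 2*x0*x1`` is lifted into the ring
    with one multiplication triple (each party arithmetically shares its own
    Boolean share locally); the weighted bit sum is then local.
    """
    rng = _rng(rng_seed)
    mod = 1 << bitlength
    acc = [0, 0]
    for i, bit in enumerate(bits):
        x = (ArithShare(0, bit[0].bit, bitlength), ArithShare(1, 0, bitlength))
        y = (ArithShare(0, 0, bitlength), ArithShare(1, bit[1].bit, bitlength))
        prod = mul_shares(x, y, BeaverTriple.generate(rng, bitlength))
        for p in (0, 1):
            arith_bit = (x[p].value + y[p].value - 2 * prod[p].value) % mod
            acc[p] = (acc[p] + (arith_bit << i)) % mod
    return (ArithShare(0, acc[0], bitlength), ArithShare(1, acc[1], bitlength))
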