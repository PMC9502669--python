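"""End-to-end exchange matching on secret shares.

Runs the four pipeline phases on the simulated two-party backend:

1. **Compatibility matching** (Boolean + arithmetic domains): per ordered
   pair, the crossmatch circuit (SIMD antigen/antibody ANDs, an OR
   reduction tree, one inversion) plus the five criterion subcircuits; the
   criterion scores are combined with the secret-shared criterion weights
   (five products, five sums), gated by crossmatch AND a positivity
   comparison through one arithmetic MUX into the shared weighted
   adjacency matrix.
2. **Cycle computation**: threshold the matrix to shared adjacency bits
   (one comparison + MUX per entry), raise it to the L-th power by naive
   repeated multiplication, and declassify the trace — the raw
   (duplicate-inclusive) cycle count, the protocol's one intermediate
   reveal.
3. **Cycle evaluation**: candidate vertex sequences of length L are public
   (canonical rotations, as in the recursion over all extensions); their
   validity bits and gated weights stay shared.  Slots (sort key, weight,
   vertex list) are ranked by an oblivious exchange sort whose key packs
   the weight with the public lexicographic rank, then truncated to the
   top k.
4. **Solution evaluation**: one oblivious greedy pass per seed slot;
   inclusion bits are secret, excluded slots write a sentinel vertex so
   later disjointness tests (pairwise equality circuits) stay oblivious.
   The best candidate set — by total weight, then fewer cycles, then
   lexicographically greatest inclusion bits — is chosen with comparison +
   MUX circuits, and only the final solution is declassified.

The reconstructed solution equals the cleartext backend's bit for bit.
"""

from __future__ import annotations

import math

import numpy as np

from ..cycles import DEFAULT_MAX_CYCLE_LENGTH, Cycle
from ..hla import LOCUS_GROUPS, ValidationError
from ..medical import CRITERIA, SENIOR_AGE, Pair, WeightConfig
from ..selection import Solution
from .costs import CostReport
from .engine import AShared, BShared, MPCEngine

__all__ = ["run_pipeline_mpc", "canonical_candidates", "required_bitlength"]

_U = np.uint64


def canonical_candidates(n: int, L: int) -> list[tuple[int, ...]]:
    """All canonical (min-vertex-first) simple cycle sequences of length L.

    Public information: depends only on the public pool size and cycle
    length, not on the compatibility graph.
    """
    if L == 2:
        return [(i, j) for i in range(n) for j in range(i + 1, n)]
    if L == 3:
        return [
            (i, j, k)
            for i in range(n)
            for j in range(i + 1, n)
            for k in range(i + 1, n)
            if k != j
        ]
    raise ValidationError(f"cycle length must be 2 or 3, got {L}")


def required_bitlength(n: int, L: int, cfg: WeightConfig) -> int:
    """Smallest ring bitlength with headroom for every intermediate value."""
    w_max = cfg.max_edge_weight
    m = max(len(canonical_candidates(n, L)), 1)
    bound = max(
        L * w_max * m + m,            # sort keys: weight * m + rank
        n * w_max * (m + 1) + m,      # seed keys: total * (m+1) + count
        n,                            # matrix-power path counts fit easily below
    )
    return bound.bit_length() + 1     # strict sign headroom: bound < 2^(l-1)


def _encode(pairs: list[Pair], cfg: WeightConfig):
    """Integer/bit encodings of the cohort for the ring circuits."""
    catalogue = pairs[0].donor.catalogue
    codes = catalogue.all_codes
    idx = {c: i for i, c in enumerate(codes)}
    n, H = len(pairs), len(codes)

    def bitvec(code_sets) -> np.ndarray:
        out = np.zeros((n, H), dtype=np.uint8)
        for row, cs in enumerate(code_sets):
            for c in cs:
                out[row, idx[c]] = 1
        return out

    d_ant = bitvec([p.donor.all_antigens for p in pairs])
    r_ant = bitvec([p.recipient.all_antigens for p in pairs])
    r_ab = bitvec([p.recipient.antibodies for p in pairs])

    def abo_bits(groups):
        has_a = np.array([g in ("A", "AB") for g in groups], dtype=np.uint8)
        has_b = np.array([g in ("B", "AB") for g in groups], dtype=np.uint8)
        return has_a, has_b

    d_abo = abo_bits([p.donor.abo for p in pairs])
    r_abo = abo_bits([p.recipient.abo for p in pairs])
    d_age = np.array([p.donor.age for p in pairs], dtype=np.int64)
    r_age = np.array([p.recipient.age for p in pairs], dtype=np.int64)
    d_male = np.array([p.donor.sex == "M" for p in pairs], dtype=np.uint8)
    r_male = np.array([p.recipient.sex == "M" for p in pairs], dtype=np.uint8)

    def int_weights(values, what):
        arr = np.asarray(values, dtype=float)
        if not np.all(arr == np.round(arr)):
            raise ValidationError(
                f"{what} must be whole numbers for the integer ring encoding"
            )
        return arr.astype(np.int64)

    d_wt = int_weights([p.donor.weight_kg for p in pairs], "donor body weights")
    r_wt = int_weights([p.recipient.weight_kg for p in pairs], "recipient body weights")
    margin = int_weights([cfg.weight_margin_kg], "the weight margin")[0]
    return dict(
        n=n, H=H, d_ant=d_ant, r_ant=r_ant, r_ab=r_ab,
        d_abo=d_abo, r_abo=r_abo, d_age=d_age, r_age=r_age,
        d_male=d_male, r_male=r_male, d_wt=d_wt, r_wt=r_wt, margin=int(margin),
    )


def _row(x: AShared, i) -> AShared:
    return AShared(x.s0[i], x.s1[i])


def _brow(x: BShared, i) -> BShared:
    return BShared(x.s0[i], x.s1[i])


def _table3(e: MPCEngine, same: BShared, mid: BShared, low: BShared, scores):
    """Arithmetic score from three exclusive condition bits and a 3-entry table."""
    total = e.public_arith(np.zeros(same.shape, dtype=np.int64))
    for bit, s in ((same, scores[0]), (mid, scores[1]), (low, scores[2])):
        if s:
            total = e.a_add(total, e.a_mul_pub(e.b2a_bit(bit), s))
        else:
            e.tally(b2a=int(np.prod(bit.shape) or 1))  # lift still evaluated
    return total


def _two_level(e: MPCEngine, bit: BShared, hi: int, lo: int):
    """``bit ? hi : lo`` with public table values (free constant product)."""
    t = e.b2a_bit(bit)
    return e.a_add_pub(e.a_mul_pub(t, hi - lo), np.int64(lo))


def run_pipeline_mpc(
    pairs: list[Pair],
    cfg: WeightConfig | None = None,
    L: int = 2,
    k: int | None = None,
    seed: int = 0,
    bitlength: int = 32,
    kappa: int = 128,
    max_length: int = DEFAULT_MAX_CYCLE_LENGTH,
) -> tuple[Solution, CostReport]:
    """Execute all four phases on shares and declassify only the outputs.

    Returns the reconstructed :class:`~kepsolve.selection.Solution` (equal to
    the cleartext backend's) and the per-phase :class:`CostReport` including
    the audit counters.
    """
    cfg = cfg or WeightConfig()
    if not 2 <= L <= max_length:
        raise ValidationError(f"cycle length must be in 2..{max_length}, got {L}")
    if len(pairs) < 2:
        raise ValidationError("need at least 2 donor-recipient pairs")
    ids = sorted(p.pair_id for p in pairs)
    if ids != list(range(len(pairs))):
        raise ValidationError(f"pair ids must be contiguous 0..{len(pairs)-1}")
    pairs = sorted(pairs, key=lambda p: p.pair_id)
    if k is not None and k < 1:
        raise ValidationError(f"top-k bound must be >= 1, got {k}")

    enc = _encode(pairs, cfg)
    n, H = enc["n"], enc["H"]
    need = required_bitlength(n, L, cfg)
    if bitlength < need:
        raise ValidationError(
            f"bitlength {bitlength} risks ring overflow for this instance; "
            f"use a bitlength of at least {need}"
        )

    e = MPCEngine(bitlength=bitlength, kappa=kappa, seed=seed)
    candidates = canonical_candidates(n, L)
    m = len(candidates)

    # ----------------------------------------------------------- share inputs
    with e.phase("input"):
        dAnt = e.share_bool(enc["d_ant"])
        rAnt = e.share_bool(enc["r_ant"])
        rAb = e.share_bool(enc["r_ab"])
        dA, dB = (e.share_bool(v) for v in enc["d_abo"])
        rA, rB = (e.share_bool(v) for v in enc["r_abo"])
        dAge = e.share_arith(enc["d_age"])
        rAge = e.share_arith(enc["r_age"])
        dMale = e.share_bool(enc["d_male"])
        rMale = e.share_bool(enc["r_male"])
        dWt = e.share_arith(enc["d_wt"])
        rWt = e.share_arith(enc["r_wt"])
        wVec = e.share_arith(np.array([cfg.w[c] for c in CRITERIA], dtype=np.int64))

    I, J = np.nonzero(~np.eye(n, dtype=bool))  # ordered pairs i != j
    P = len(I)

    # ------------------------------------------------- phase 1a: crossmatch
    with e.phase("match_hla") as pc:
        comp = e.b_and(_brow(dAnt, I), _brow(rAb, J))          # (P, H) SIMD
        combined = e.b_or_tree(comp, axis=-1)                  # OR tree
        xm = e.b_not(combined)                                 # invert: free
        pc.depth = math.ceil(math.log2(H)) + 1 if H > 1 else 1

    # -------------------------------------------- phase 1b: graph construction
    with e.phase("graph_build"):
        # HLA mismatch quality: count donor antigens the recipient lacks.
        # A donor carries at most two antigens per locus, so the per-group
        # cap of two is structural.
        mm = e.b_and(_brow(dAnt, I), e.b_not(_brow(rAnt, J)))  # (P, H)
        mm_arith = e.b2a_bit(mm)
        s0 = mm_arith.s0.sum(axis=-1, dtype=_U) & e.mask
        s1 = mm_arith.s1.sum(axis=-1, dtype=_U) & e.mask
        count = AShared(s0, s1)
        le4 = e.msb(e.a_add_pub(count, np.int64(-5)))          # count <= 4
        le2 = e.msb(e.a_add_pub(count, np.int64(-3)))          # count <= 2
        eq0 = e.b_not(e.b_or_tree(e.a2b(count)))               # count == 0
        b = cfg.bins_hla
        hla_q = e.public_arith(np.full(P, b[3], dtype=np.int64))
        for bit, delta in ((le4, b[2] - b[3]), (le2, b[1] - b[2]), (eq0, b[0] - b[1])):
            lift = e.b2a_bit(bit)
            if delta:
                hla_q = e.a_add(hla_q, e.a_mul_pub(lift, delta))

        # ABO: donor antigen set must be a subset of the recipient's.
        compat = e.b_and(
            e.b_or(e.b_not(_brow(dA, I)), _brow(rA, J)),
            e.b_or(e.b_not(_brow(dB, I)), _brow(rB, J)),
        )
        abo_s = _two_level(e, compat, cfg.scores_abo[0], cfg.scores_abo[1])

        # Age: junior/senior categories at the configured threshold.
        senior_d = e.b_not(e.msb(e.a_add_pub(dAge, np.int64(-SENIOR_AGE))))
        senior_r = e.b_not(e.msb(e.a_add_pub(rAge, np.int64(-SENIOR_AGE))))
        sd, sr = _brow(senior_d, I), _brow(senior_r, J)
        same_age = e.b_not(e.b_xor(sd, sr))
        js = e.b_and(e.b_not(sd), sr)
        sj = e.b_and(sd, e.b_not(sr))
        age_s = _table3(e, same_age, js, sj, cfg.scores_age)

        # Sex: same-sex best, then male donor -> female recipient.
        md, mr = _brow(dMale, I), _brow(rMale, J)
        same_sex = e.b_not(e.b_xor(md, mr))
        mf = e.b_and(md, e.b_not(mr))
        fm = e.b_and(e.b_not(md), mr)
        sex_s = _table3(e, same_sex, mf, fm, cfg.scores_sex)

        # Weight: donor at least recipient minus margin.
        diff = e.a_add_pub(e.a_sub(_row(dWt, I), _row(rWt, J)), np.int64(enc["margin"]))
        ge = e.b_not(e.msb(diff))
        wt_s = _two_level(e, ge, cfg.scores_weight[0], cfg.scores_weight[1])

        # Weighted combination: five products with the shared weights,
        # five sums, then gate through comparison + AND + MUX.
        scores = (hla_q, abo_s, age_s, sex_s, wt_s)
        total = e.public_arith(np.full(P, cfg.baseline, dtype=np.int64))
        for ci, sc in enumerate(scores):
            wk = AShared(
                np.broadcast_to(wVec.s0[ci], (P,)).copy(),
                np.broadcast_to(wVec.s1[ci], (P,)).copy(),
            )
            total = e.a_add(total, e.a_mul(sc, wk))
        pos = e.gt_zero(total)
        e.tally(comparisons=P)
        gate = e.b_and(xm, pos)
        edge = e.mux_arith(gate, total, np.zeros(P, dtype=np.int64))

        compg = AShared(np.zeros((n, n), dtype=_U), np.zeros((n, n), dtype=_U))
        compg.s0[I, J] = edge.s0
        compg.s1[I, J] = edge.s1

    # ------------------------------------------------ phase 2: cycle counting
    with e.phase("cycle_computation"):
        flat = AShared(compg.s0.reshape(-1), compg.s1.reshape(-1))
        adj_bit = e.gt_zero(flat)                              # (n*n,)
        e.tally(comparisons=n * n)
        adj = e.mux_arith(adj_bit, np.ones(n * n, dtype=np.int64),
                          np.zeros(n * n, dtype=np.int64))
        adjM = AShared(adj.s0.reshape(n, n), adj.s1.reshape(n, n))
        power = adjM
        for _ in range(L - 1):
            power = e.a_matmul(power, adjM)
        trace = AShared(
            np.array([np.diagonal(power.s0).sum() & e.mask], dtype=_U),
            np.array([np.diagonal(power.s1).sum() & e.mask], dtype=_U),
        )
        n_raw = int(e.declassify(trace, "cycle_count")[0])
        e.report.public_outputs["cycle_count"] = n_raw
        e.report.public_outputs["n_unique"] = n_raw // L
    adj_bits = BShared(adj_bit.s0.reshape(n, n), adj_bit.s1.reshape(n, n))

    # --------------------------------------------- phase 3: cycle evaluation
    if m == 0:
        report = e.report
        report.audit_violations = e.audit_violations
        return Solution(cycles=(), total_weight=0), report

    with e.phase("cycle_evaluation"):
        cand = np.array(candidates, dtype=np.int64)            # (m, L) public
        src = cand
        dst = np.roll(cand, -1, axis=1)
        edges_b = _brow(adj_bits, (src, dst))                  # (m, L)
        valid = BShared(*_and_fold(e, edges_b))                # (m,)

        wsum = AShared(
            compg.s0[src, dst].sum(axis=1, dtype=_U) & e.mask,
            compg.s1[src, dst].sum(axis=1, dtype=_U) & e.mask,
        )
        gated = e.mux_arith(valid, wsum, np.zeros(m, dtype=np.int64))
        rank = np.arange(m, dtype=np.int64)                    # lex rank, public
        key = e.a_add_pub(e.a_mul_pub(gated, np.int64(m)), (m - 1 - rank))

        # oblivious exchange sort, descending by key
        k0, k1 = key.s0.copy(), key.s1.copy()
        w0, w1 = gated.s0.copy(), gated.s1.copy()
        v0 = cand.astype(_U).copy()
        v1 = np.zeros_like(v0)
        for i in range(m):
            for j in range(i + 1, m):
                ki = AShared(k0[i:i + 1], k1[i:i + 1])
                kj = AShared(k0[j:j + 1], k1[j:j + 1])
                swap = e.lt(ki, kj)
                e.tally(comparisons=1)
                fi = [ki, AShared(w0[i:i + 1], w1[i:i + 1]), AShared(v0[i], v1[i])]
                fj = [kj, AShared(w0[j:j + 1], w1[j:j + 1]), AShared(v0[j], v1[j])]
                new_i, new_j = e.cswap_desc(swap, fi, fj)
                k0[i:i + 1], k1[i:i + 1] = new_i[0].s0, new_i[0].s1
                w0[i:i + 1], w1[i:i + 1] = new_i[1].s0, new_i[1].s1
                v0[i], v1[i] = new_i[2].s0, new_i[2].s1
                k0[j:j + 1], k1[j:j + 1] = new_j[0].s0, new_j[0].s1
                w0[j:j + 1], w1[j:j + 1] = new_j[1].s0, new_j[1].s1
                v0[j], v1[j] = new_j[2].s0, new_j[2].s1

        kk = m if k is None else min(k, m)
        w0, w1, v0, v1 = w0[:kk], w1[:kk], v0[:kk], v1[:kk]
        slot_w = AShared(w0, w1)
        slot_valid = e.gt_zero(slot_w)                         # (kk,)
        e.tally(comparisons=kk)

    # ------------------------------------------- phase 4: solution selection
    sentinel = np.int64(n)  # never equals a real vertex id
    with e.phase("solution_evaluation"):
        best = None
        for s in range(kk):
            order = [s] + [j for j in range(kk) if j != s]
            sel0 = np.empty(0, dtype=_U)
            sel1 = np.empty(0, dtype=_U)
            total_s = e.public_arith(np.zeros(1, dtype=np.int64))
            cnt_s = e.public_arith(np.zeros(1, dtype=np.int64))
            bits0 = np.zeros(kk, dtype=np.uint8)
            bits1 = np.zeros(kk, dtype=np.uint8)
            for j in order:
                vj = AShared(v0[j], v1[j])                     # (L,)
                if sel0.size == 0:
                    disj = e.public_bool(np.ones(1, dtype=np.uint8))
                else:
                    d0 = (vj.s0[:, None] - sel0[None, :]) & e.mask
                    d1 = (vj.s1[:, None] - sel1[None, :]) & e.mask
                    neq = e.b_or_tree(e.a2b(AShared(d0, d1)))  # (L, S)
                    eq_any = e.b_or_tree(
                        BShared(neq.s0.reshape(1, -1) ^ 1, neq.s1.reshape(1, -1))
                    )
                    e.tally(comparisons=int(np.prod(d0.shape)))
                    disj = e.b_not(eq_any)
                vslot = BShared(slot_valid.s0[j:j + 1], slot_valid.s1[j:j + 1])
                include = e.b_and(vslot, disj)
                newv = e.mux_arith(
                    BShared(include.s0, include.s1), vj,
                    np.full(L, sentinel, dtype=np.int64),
                )
                sel0 = np.concatenate([sel0, newv.s0])
                sel1 = np.concatenate([sel1, newv.s1])
                wj = AShared(w0[j:j + 1], w1[j:j + 1])
                total_s = e.a_add(total_s, e.mux_arith(include, wj,
                                                       np.zeros(1, dtype=np.int64)))
                cnt_s = e.a_add(cnt_s, e.mux_arith(include,
                                                   np.ones(1, dtype=np.int64),
                                                   np.zeros(1, dtype=np.int64)))
                bits0[j], bits1[j] = include.s0[0], include.s1[0]

            neg_cnt = e.a_add_pub(e.a_mul_pub(cnt_s, np.int64(-1)), np.int64(kk))
            skey = e.a_add(e.a_mul_pub(total_s, np.int64(kk + 1)), neg_cnt)
            entry = dict(key=skey, total=total_s,
                         bits=BShared(bits0, bits1))
            if best is None:
                best = entry
                continue
            gt = e.lt(best["key"], skey)
            eqk = e.eq(skey, best["key"])
            e.tally(comparisons=2)
            lex = _lex_greater(e, entry["bits"], best["bits"], kk)
            better = e.b_or(gt, e.b_and(eqk, lex))
            best = dict(
                key=e.mux_arith(better, skey, best["key"]),
                total=e.mux_arith(better, total_s, best["total"]),
                bits=e.b_mux(BShared(
                    np.broadcast_to(better.s0, (kk,)).copy(),
                    np.broadcast_to(better.s1, (kk,)).copy(),
                ), entry["bits"], best["bits"]),
            )

        bsel = best["bits"]
        sel2d = BShared(bsel.s0[:, None], bsel.s1[:, None])
        out_v = e.mux_arith(sel2d, AShared(v0, v1),
                            np.full((kk, L), sentinel, dtype=np.int64))
        out_w = e.mux_arith(bsel, AShared(w0, w1), np.zeros(kk, dtype=np.int64))
        inc = e.declassify(bsel, "solution").astype(int)
        verts = e.declassify(out_v, "solution").astype(np.int64)
        weights = e.declassify(out_w, "solution").astype(np.int64)
        total = int(e.declassify(best["total"], "solution")[0])

    cycles = tuple(
        Cycle(vertices=tuple(int(x) for x in verts[j]), weight=int(weights[j]))
        for j in range(kk)
        if inc[j]
    )
    solution = Solution(cycles=cycles, total_weight=total)
    assert total == sum(c.weight for c in cycles)

    report = e.report
    report.audit_violations = e.audit_violations
    return solution, report


def _and_fold(e: MPCEngine, bits: BShared):
    """AND-reduce the last axis pairwise (helper for validity over edges)."""
    cur = bits
    while cur.s0.shape[-1] > 1:
        w = cur.s0.shape[-1]
        half = w // 2
        left = BShared(cur.s0[..., :half], cur.s1[..., :half])
        right = BShared(cur.s0[..., half:2 * half], cur.s1[..., half:2 * half])
        merged = e.b_and(left, right)
        if w % 2:
            merged = BShared(
                np.concatenate([merged.s0, cur.s0[..., -1:]], axis=-1),
                np.concatenate([merged.s1, cur.s1[..., -1:]], axis=-1),
            )
        cur = merged
    return cur.s0[..., 0], cur.s1[..., 0]


def _lex_greater(e: MPCEngine, a: BShared, b: BShared, width: int) -> BShared:
    """1 iff bit sequence ``a`` is lexicographically greater than ``b``."""
    undecided = e.public_bool(np.ones(1, dtype=np.uint8))
    result = e.public_bool(np.zeros(1, dtype=np.uint8))
    for j in range(width):
        aj = BShared(a.s0[j:j + 1], a.s1[j:j + 1])
        bj = BShared(b.s0[j:j + 1], b.s1[j:j + 1])
        win = e.b_and(aj, e.b_not(bj))
        result = e.b_or(result, e.b_and(undecided, win))
        undecided = e.b_and(undecided, e.b_not(e.b_xor(aj, bj)))
    return result
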