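# Methods

## The matching model

A cohort is a set of `n` incompatible donor–recipient pairs, collapsed to
one vertex each.  The ordered pairing "donor of pair *i* gives to
recipient of pair *j*" receives an integer weight

```
w_e(i, j) = crossmatch(i, j) ? ( baseline + p(i, j) · w ) : 0
```

where `p(i, j)` is the vector of five criterion scores and `w` the
expert-tunable criterion weights.  All scores, weights and the baseline
are non-negative integers, so every intermediate quantity is exact in the
arithmetic ring `Z_{2^ℓ}` used by the secret-sharing backend (no fixed
point needed).  The default score tables are the *smallest* integers
respecting the ordinal constraints of the underlying clinical evidence;
they are placeholders for expert-supplied values, not clinically
validated weights:

| criterion | default table | ordering encoded |
|---|---|---|
| HLA mismatch bins (0 / 1–2 / 3–4 / ≥5) | 3, 2, 1, 0 | fewer mismatches better |
| ABO (compatible / incompatible) | 1, 0 | incompatibility penalized, not excluded |
| age (same cat. / junior→senior / senior→junior) | 2, 1, 0 | intra-category best |
| sex (same / M→F / F→M) | 2, 1, 0 | female-donor→male-recipient worst |
| weight (donor ≥ recipient − margin / lighter) | 1, 0 | lighter donors riskier |
| criterion weights `w` | all 1 | — |
| baseline | 1 | keeps compatible edges above the `> 0` adjacency threshold |

Two boundary conventions are deliberate and configurable only in code:

* a mismatch count of exactly **5** falls in the worst bin (the bins
  0, 1–2, 3–4 leave 5 otherwise unassigned);
* age exactly **55** counts as senior (the junior/senior definitions
  "below 55" / "older than 55" leave 55 unassigned).

Mismatch counting uses *distinct* donor antigens per locus group, so a
homozygous donor contributes at most one mismatch per group and the
printed per-group cap of two is structural (a person carries at most two
antigens per locus).

Only the crossmatch excludes: a positive virtual crossmatch (any donor
antigen in the recipient's antibody panel) zeroes the edge.

## Cycle algebra

With a zero diagonal, every closed walk of length 2 or 3 visits distinct
vertices, so `trace(A^L)` — computed by naive repeated multiplication, as
the share-domain backend must — equals exactly `L` times the number of
simple exchange cycles of length `L` (one count per rotation start).
Deduplication canonicalizes by rotating the minimum vertex first;
direction is preserved because congruent duplicates differ only in start
vertex.  Ranking is by weight descending with ties broken by ascending
lexicographic canonical form, which makes the order total and
platform-independent.  Cycle lengths above 3 are rejected by default
(simultaneous-surgery logistics); the cap is an explicit parameter.

## Greedy selection and tie-breaking

Each of the ranked unique cycles seeds one candidate set; the set is
extended by scanning the remaining cycles in ranked order, adding every
cycle disjoint from the members.  The best set wins by

1. maximal total weight,
2. fewer cycles,
3. lexicographically **greatest inclusion-bit sequence** over the ranked
   cycle list (the set holding the higher-priority cycle at the first
   divergence).

Rule 3 was a genuinely open design point.  We chose the inclusion-bit
order rather than, say, comparing concatenated vertex lists, because it
is evaluable *inside* the oblivious backend with one prefix circuit over
the secret inclusion bits — any rule that needs the selected vertex
sequences in compacted form would require an oblivious compaction
network, breaking the cost envelope — and both backends therefore apply
literally the same deterministic rule.  When weights at the first
divergence are equal the two formulations coincide.

The greedy result is locally optimal.  `brute_force_optimum` (exhaustive
over disjoint subsets, guarded at 20 cycles) provides the optimality-gap
oracle; the CLI reports the gap under `solve --exact`.

## The simulated secure backend

The backend simulates two semi-honest computation servers in one process:
additive arithmetic sharing over `Z_{2^ℓ}` (default ℓ = 32), Boolean XOR
sharing, and Beaver-triple multiplication, with all correlated randomness
(triples, double-sharings for conversions) drawn from a seeded
trusted-dealer abstraction — the standard preprocessing model.  Phases
that a deployment would run as garbled circuits execute here on the
Boolean-share engine while the cost report charges the garbled-circuit
model: 1.5κ bits per AND-equivalent (AND, OR, MUX), free XOR/NOT,
κ = 128.  The functionality is identical; nothing here is
cryptographically secure.

Circuit realizations worth noting:

* **crossmatch** — per ordered pair, `|HLA|` SIMD ANDs of donor-antigen ×
  recipient-antibody bit vectors, an OR reduction tree, one free
  inversion: `2·|HLA| − 1` AND-equivalents at depth `⌈log2|HLA|⌉ + 1`
  (the closed-form model prints the rounded bound `2·|HLA|`; the engine
  reports the literal count, and the tests accept either);
* **criterion subcircuits** — mismatch bits `d ∧ ¬r` summed after bit
  lifting; thresholds (`≤2`, `≤4`, `= 0`, age ≥ 55, donor ≥ recipient)
  as sign/zero tests on ring differences via A→B conversion; table
  lookups as bit lifts times public score deltas;
* **A→B conversion** — open `x − r` one-time-padded by a dealer
  double-sharing, then ripple-add the public bits onto the shared bits of
  `r` (ℓ − 1 ANDs, charged to the conversion);
* **comparisons** — `x > 0` is an OR tree over the converted bits;
  `x < y` is the top bit of `x − y`, valid because an analytic bound on
  every intermediate (computed from the weight config, cohort size and
  cycle length) is checked against `2^(ℓ−1)` up front, with an error
  advising a larger ℓ otherwise;
* **cycle evaluation** — candidate vertex sequences of length L are
  *public* (they depend only on `n` and `L`); validity bits and gated
  weights stay secret.  Slots are sorted by an oblivious exchange sort
  whose key `weight·m + (m − 1 − rank)` folds the public lexicographic
  rank into the secret weight so the sort is total without a secondary
  comparator;
* **greedy selection** — one oblivious pass per seed slot; excluded slots
  write a sentinel vertex (`n`) so disjointness stays a fixed-shape
  pairwise-equality circuit; the best-set comparator packs
  `total·(m+1) + (m − count)` into one key plus the inclusion-bit prefix
  circuit.

Declassified values are exactly the raw cycle count (revealed, as in the
modeled protocol, to size the later phases) and the final solution.  An
audit counter records any other code path that combines both shares; the
test suite asserts it is zero, and that the reconstructed solution equals
the cleartext pipeline's bit for bit on fixtures and random cohorts.

### Cost accounting caveats

The closed-form model reproduces the printed formulas verbatim.  Two
places where the measured simulator deliberately differs:

* the printed cycle-computation multiplication count `|pairs|³` covers
  one matrix product; the L-th power needs `L − 1` of them, so measured
  equals closed-form only at L = 2 (the property test pins this case);
* the printed costs of the dedup/sort/greedy phases describe the original
  oblivious recursion whose subcircuits are not reproduced here; the
  simulator's reconstruction (public candidates, exchange sort, multi-seed
  greedy) reports its own measured counts side by side rather than
  pretending to match.  Conversions are likewise counted separately —
  there is no printed formula for them.

Protocol-level "comparison" tallies count the comparisons the phase
descriptions place (edge positivity, adjacency thresholding, sort and
disjointness tests); the gates inside a comparison are charged to their
conversion/OR primitives.

## Synthetic cohorts

The generator emulates the statistical shape of an exchange pool: two
uniform antigen draws with replacement per locus (homozygosity allowed),
antibody panels as independent Bernoulli(PRA) draws over the catalogue
excluding the recipient's own antigens, categorical ABO frequencies
(0.43 / 0.40 / 0.12 / 0.05), ages uniform on 18–75, sex fair-coin, body
weights normal (80, 15²) truncated to 40–150 kg and rounded to whole kg
for ring exactness.  These defaults are plausible placeholders — the
model deliberately ignores population HLA haplotype frequencies, linkage
disequilibrium between loci, antibody cross-reactivity groups, and any
correlation between demographics.  A green equivalence or property test
therefore establishes algorithmic correctness on structurally realistic
inputs, not clinical performance on real registries.

Engineered fixtures (`two_cycle`, `triangle`, `star_conflict`,
`no_match`) realize known topologies by giving donors unique tag antigens
and recipients antibody panels that delete exactly the unwanted edges.

## Known limitations

* Greedy selection is locally optimal only; no ILP solver is included.
* Altruistic donors, chains, and dynamic pool management beyond repeated
  runs are out of scope.
* The secure backend models functionality and cost, not security: no
  oblivious transfer, no garbled tables, no network layer, semi-honest
  only.
* Runtime of the share-domain simulator grows steeply with cohort size
  (the oblivious sort and greedy are quadratic-to-cubic in the candidate
  count); it is meant for desk-scale validation, roughly n ≤ 10.
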