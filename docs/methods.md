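# Methods

## Model

A drug-target dataset over n drugs and m targets is a map from the n·m
ordered pairs to one of three states: active, inactive, unknown. The package
stores this as a dense int8 matrix (+1/0/−1) with ordered, pairwise-distinct
label tuples on each side; drug and target label sets must be disjoint
(bipartiteness). All quantities are pure functions of this matrix:

- the three binary indicator matrices A₊, A₋, A⋆ partition the pair set
  (their elementwise sum is the all-ones matrix);
- colored degrees are row/column sums of one indicator; with the active
  indicator they are the degrees of polypharmacology (drugs) and
  polyspecificity (targets);
- transposition swaps the two perspectives, so polyspecificity in a network
  equals polypharmacology in its transpose — the duality every release is
  property-tested against;
- global completeness is C_DT = (μ̂₊ + μ̂₋)/(n·m); local uncertainty ε̂ is
  an entity's unknown count, computed here by the rearrangement
  |opposite side| − active − inactive and cross-checked against direct
  counting in the tests;
- degree bounds are [active, active + unknown]. They bracket the true
  degree only when the underlying determinations are correct; measurement
  error can push the truth below the nominal lower bound, and the package
  makes no attempt to model that.

The model is purely phenomenological: entities are opaque labels, and no
structural or chemical information enters anywhere.

## Parameters that matter

- **threshold** (μM, default 10): cutoff for classifying a measured value.
  The 1–10 μM range is the conventional potency window; 10 μM is the
  permissive end of it.
- **direction** (`at_most` default / `at_least`): for potency readouts such
  as IC50, *lower* values mean stronger binding, so the conventional reading
  is active when value ≤ threshold; the literal "meets or exceeds" reading
  is kept available as `at_least`. The boundary is inclusive either way, and
  the choice is always explicit in the API and CLI rather than hidden.
- **conflict_policy** (`error` default): contradictory records for one pair
  fail loudly, because interaction data aggregated from multiple sources is
  of non-uniform quality and silent resolution should be opt-in.
  `any_active` prefers ACTIVE over INACTIVE over UNKNOWN; `majority` takes
  the most frequent status with ties breaking to UNKNOWN (a tie carries no
  usable signal). Source-reliability weighting is deliberately not
  implemented — there is no standard scheme to implement.
- **missing_status** (UNKNOWN default): absent pairs are unknown by
  omission. Setting INACTIVE emulates decoy-style datasets that treat
  unreported pairs as inactive; this discards information and is off by
  default.
- **normalize** (off) in `local_uncertainty`: divides ε̂ by the opposite
  side's cardinality, giving a per-entity incompleteness fraction. The plain
  counts are the primary quantities; the fraction is an extension.
- **digits** (3, half-up) for printed fractions: 26/32 = 0.8125 prints as
  0.813. Ties round away from zero (banker's rounding would print 0.812);
  internally everything is carried at full precision.

## Synthetic data

`generate_random_network` draws each pair's status independently from a
categorical distribution (p_active, p_inactive, p_unknown), seeded and fully
reproducible. `mask_network` converts a fully determined ground truth into a
database-style view: a hide fraction f of the pairs loses its determination,
and `drop_inactives` additionally withholds every inactive pair (actives-only
reporting). Statuses are hidden, never flipped.

Two deliberate choices make the tests sharp rather than merely plausible:

- **exact-count masking** — exactly round(f·n·m) pairs (half-up) are hidden,
  so masked completeness is a known constant, with per-pair Bernoulli
  hiding available behind `mode="bernoulli"`;
- **nested masks** — the pairs are put in one seeded random order and the
  first round(f·N) hidden, so for a fixed seed a larger f hides a superset
  of pairs. Completeness is then non-increasing and every entity's bound
  width non-decreasing in f exactly, not just in expectation.

What the generator does *not* emulate: target-class popularity bias (GPCRs
and kinases are over-studied in real databases), correlated measurement
campaigns (real determinations arrive in row/column blocks, not uniformly),
and erroneous determinations (real actives can be false). Passing tests
therefore demonstrate the combinatorial guarantees — partition, duality,
containment, monotonicity — under correct-but-incomplete data; they say
nothing about robustness to wrong determinations, which the bounds formalism
itself does not claim.

Default test conditions: the property suites use 100 seeded networks up to
50×30 with mixed status frequencies, and the masking suite uses 100 ground
truths at 30 drugs × 15 targets with p_active = 0.3 masked at hide fractions
0.1/0.3/0.6 — sizes at which every invariant is checked entity-by-entity in
seconds while remaining far larger than the shipped 8×4 example.

## Numerical and degenerate-input choices

- Counts are exact integers throughout; the only floating-point quantities
  are C_DT, normalized uncertainties, and profile distances.
- Cosine similarity of profile vectors is clipped into [0, 1] against
  round-off and is an **error** for an all-zero profile (an entity with no
  pairs at all cannot occur, but a zero vector could be constructed by
  hand); returning a convention value would silently corrupt downstream
  clustering.
- Networks require n ≥ 1 and m ≥ 1; empty sides are rejected at
  construction.
- Labels are case-sensitive and whitespace-trimmed; a label occurring on
  both sides is rejected unless the `suffix` collision policy is chosen,
  which renames the colliding target labels by appending `#target`.
- Ordering is first-seen (or universe order) everywhere, and every output —
  tables, files, GraphML — is deterministically ordered.
- Edge lists omit unknown rows by default, mirroring real exports; status
  matrices always carry all n·m cells, so the matrix format (or an edge
  list written with `include_unknown=True`) is the lossless interchange
  form.

## Known limitations

- The bounds assume correct determinations; no error model is provided.
- Dense storage only: fine up to millions of pairs, wasteful for the very
  sparse matrices of web-scale datasets.
- Distances/similarities between profile vectors are exposed, but clustering
  itself, degree-distribution statistics, null models, weighted or fuzzy
  edge states, and higher-order interactions are out of scope.
- No connectors to live databases; inputs are local files with opaque
  labels.
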