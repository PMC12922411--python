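# Methods

This note documents the statistical model behind `alertminer`, the
concrete algorithmic choices where the underlying ideas admit more than
one reading, and what the synthetic benchmark does and does not show.

## The mining model

A structural-alert miner is a pipeline over a labelled compound set
`D = {(m_i, y_i)}`, `y ∈ {0,1}`:

1. **Candidate enumeration** produces a set of substructure patterns per
   molecule; dataset-level support counts `(N_sub, N_sub_positive)` are
   accumulated with at most one count per molecule per pattern
   ("contains" = at least one substructure embedding).
2. **Filtering** retains patterns that are frequent, precise and
   statistically enriched in the positive class.
3. **Scoring** attaches precision (PR), coverage rate (CR) and information
   gain (IG) to every retained alert.

### Enumeration strategies

- **circular** — for every atom and every bond radius `r ∈ [1, 4]`, the
  environment subgraph of all atoms/bonds within `r` bonds of the centre,
  emitted as a canonical fragment SMILES. An atom whose environment
  saturates before `r_max` contributes each distinct environment once;
  isolated atoms contribute nothing (the radius counts bonds).
- **path** — all simple linear paths of 1–7 bonds; a path and its
  reverse are one fragment; ring round-trips (walks revisiting an atom)
  are rejected. Branched subgraphs are deliberately left to the
  bond-breaking strategy.
- **group** — functional groups seeded on heteroatoms and on carbons
  multiply bonded to heteroatoms. Adjacent non-aromatic seeds merge into
  one component, which then absorbs its multiply-bonded neighbours (a
  carbonyl keeps its oxygen); aromatic ring systems (fused rings merged)
  are emitted whole; skeleton carbons are never emitted alone. This seed
  rule set is one concrete reading of "groups based on heteroatoms and
  aromatic atoms" and is isolated in a single function so an alternative
  can be swapped in.
- **bondbreak** — all combinations of up to 3 simultaneous cuts of
  acyclic single bonds; every connected product with 2–15 heavy atoms is
  a candidate. Exhaustive recursion over cut sets is exponential, so
  enumeration proceeds breadth-first in the number of cuts and truncates
  deterministically at 10,000 distinct fragments per molecule (warned).
  Three cuts reproduce the exact fragment set for typical drug-sized
  molecules while bounding the combinatorics.
- **catalogue** — support counting of a user-supplied SMARTS list
  (KRFP-style); patterns matching nothing are absent from the table.

### Pattern matching semantics

Mined fragments are stored as canonical fragment SMILES and matched as
RDKit *molecule* queries. Two consequences are intended:

- matching is attachment-free: hydrogen-count artifacts created by cutting
  a fragment out of its parent (e.g. `[NH+]` from a cut nitro N–O bond)
  do not constrain the match. Radical electrons assigned to unfilled
  valences at former attachment points are cleared in the compiled query
  for the same reason.
- partial aromatic fragments that are not valid molecules (e.g. `ccc`)
  fall back to SMARTS parsing.

Catalogue patterns are genuine SMARTS and keep full SMARTS semantics,
including hydrogen-count constraints such as `[OH]`.

### Filtering

Significance mode keeps a fragment iff

- `N_sub ≥ min_hits` (default 5),
- `PR ≥ min_precision` (default 0.75, inclusive),
- Bonferroni-adjusted `p ≤ alpha` (default 0.05), where `p` is the
  one-sided exact binomial tail `P(X ≥ N_sub_positive | N_sub, p0)` with
  `p0` the dataset's positive fraction, and the multiplicity `m` counts
  only fragments that reached `min_hits` — fragments below the hit floor
  were never candidate hypotheses. The test is configuration-isolated;
  the binomial choice follows the established practice of
  circular-fragment alert miners.

Support mode (the closed-subgraph miners' filter) keeps a fragment iff
focus support `N_sub_positive / N_positive ≥ 0.10` and complement support
`(N_sub − N_sub_positive) / N_negative ≤ 0.05`.

A run that retains nothing is a *reportable outcome* (failure flag with
reason), never an exception: tolerance bookkeeping across endpoints and
strategies requires failures to flow through the reporting layer.

An external screen (`screen_external`, `N_sub ≥ 5` and `PR ≥ 0.75`, both
inclusive) makes rule sets mined under non-uniform constraints comparable.

### Scoring

Entropy uses log base 2 (bits); the base only scales reported magnitudes
and never changes IG rankings, and is configurable. IG is computed by the
standard decomposition

```
IG = E(p_all) − P(t)·E(p_match) − P(t̄)·E(p_nomatch)
```

with `0·log 0 ≡ 0`, `p_match ≡ 0` when `N_sub = 0` and `p_nomatch ≡ 0`
when the complement is empty; negative floating-point dust is clamped to
zero. IG is invariant under swapping the class labels and bounded by the
total label entropy — both are property-tested against a brute-force
oracle that physically partitions the record list and recomputes the
entropies.

Ranking is by IG descending with a deterministic tie chain: higher PR,
then higher CR, then lexicographic pattern.

## Alert sets as classifiers

Prediction is the disjunction "toxic iff any alert matches" — no vote
counting. Evaluation is five repetitions of a simple random 8:2 split
(train `floor(0.8·n)`, remainder test; seeds recorded; optional
stratification for imbalanced endpoints). Alerts are re-mined on each
training split alone, so test molecules never influence the alert set.
Metrics are ACC, PPV and MCC computed directly from the confusion counts;
PPV with no positive predictions is reported as *missing* (means skip it
with a count), and MCC with a zero denominator factor is reported as 0.
Repetitions whose mining fails are excluded from means with a warning.

## Consensus construction

Normalization strips atom maps (dropping the bracket-atom H/valence
constraints the markup introduced) and emits canonical SMILES;
non-reducible query patterns keep a canonical text form and are flagged.
Consolidation collapses any inclusion-related pair (tested by substructure
matching in both directions) to the *simpler* pattern — fewer heavy atoms,
ties broken by fewer rings, then lexicographic canonical SMILES — applied
to a fixed point; the result is order-independent. The benchmark set for
an endpoint is the intersection (by normalized canonical equality) of the
consolidated sets of every strategy that produced at least 20 alerts.
Intersection by strict normalized equality, rather than by cross-set
inclusion, is a deliberate reading of an ambiguous rule; overlap counting
uses the same normalization so both analyses are consistent. An empty
benchmark is a legitimate outcome, as the consensus example demonstrates.

## QSAR integration

The score model is a random forest (500 trees by default, fixed seed) on
2048-bit radius-2 binary circular fingerprints (ECFP4-equivalent). Neither
size is prescribed by the method; both are configurable and the defaults
are conventional for this model class. The integrated rule is the strict
conjunction `score > 0.5 AND alert present`; the boundary is strict by
definition. Alerts are mined on the same training split as the forest to
avoid leakage, and all three predictors (score-only, alerts-only,
integrated) are compared on the identical test split.

## The synthetic generator

The generator emulates a mid-sized binary toxicity endpoint: molecules
are assembled by attaching 1–2 benign substituents (from a 15-substituent
pool) to one of 20 drug-like scaffolds by single bonds at hydrogen-bearing
atoms, validated by sanitization; designated positives additionally carry
a toxicophore fragment (default: nitroaromatic). Ground truth is
re-derived from the assembled structure, so "truth-positive" always means
the toxicophore is genuinely present as a substructure, even if a benign
assembly forms one by accident. Pre-noise labels equal toxicophore
carriage; noise is independent label flipping, symmetric by default with
configurable asymmetric rates. Everything is deterministic per seed, and
SMILES are unique by construction (regeneration on collision).

Default conditions: n = 500, positive fraction 0.4, label noise 0.05,
implant probability 1.0, one toxicophore. Under these conditions the
toxicophore's fragments have PR ≈ 0.95 (capped exactly by the noise) and
CR ≈ 0.4, and both the circular and bond-breaking strategies place a
toxicophore-matching alert at the top of the IG ranking.

The **imbalanced regime** (`imbalanced_spec`) models an idiosyncratic,
weakly structural endpoint at ~1:10 class balance: only a quarter of the
designated positives carry the toxicophore, half of the carriers are
flipped to negative (low penetrance), and 8% of negatives are flipped to
positive (structureless background toxicity). In this regime no fragment
reaches the 0.75 precision floor with Bonferroni-surviving significance,
so mining reports tolerance failures — the behaviour real imbalanced
endpoints show under these default thresholds.

What the generator does **not** emulate: realistic ADMET property
distributions, activity cliffs, tautomerism, stereochemistry, scaffold
bias of real assay collections, or multiple interacting toxicophores per
molecule. Passing tests on synthetic data therefore demonstrate the
correctness and statistical behaviour of the pipeline, not predictive
performance on any real endpoint.

## Problem sizes and numerical conventions

- Tests and the acceptance script run at n = 120–1000 molecules, 5
  generator seeds, and forests of 100–500 trees — sizes at which every
  computation is exact and each stage completes in seconds on one core.
- All thresholds compare inclusively (`≥` / `≤`); the QSAR score cutoff
  is the one strict comparison (`>`).
- Splits use `floor`/remainder rounding; split, forest and generator
  randomness all derive from explicit integer seeds.
- IG oracle agreement is asserted to 1e−12; metric identities to 1e−12.
- Salt stripping keeps the fragment with the most heavy atoms, ties
  broken by lexicographic canonical SMILES; canonicalization is RDKit's,
  applied uniformly (cross-toolkit canonical equality is not promised).

## Known limitations

- The functional-group seed rules and the bond-break depth cap are
  explicit stand-ins for under-specified algorithms; both are
  configuration-isolated.
- Closed frequent-subgraph mining is not implemented; only its
  focus/complement support filter is, applied over fragment tables from
  the other strategies.
- Fragments are counted per molecule, not per occurrence; stereochemistry
  is ignored in fragment identity.
- Wall-clock efficiency comparisons between strategies are
  hardware-dependent and are logged for information only, never asserted.
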