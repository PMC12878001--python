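# Methods

## Reaction model

A reaction line is `reactants>agents>products` SMILES with integer atom
maps. Records are kept only if they have exactly one product species and
2–10 precursor species. Roles are assigned by map intersection: a
precursor is a **starting material (SM)** iff at least one of its nonzero
map numbers appears in the product, otherwise a **reagent (R)**. The
field position in the input is advisory only — a mapped species found in
the agents field is reclassified as SM. This rule is the standard one for
USPTO-style corpora and makes the SM/R partition deterministic and
permutation-stable. Canonicalization (RDKit) retains stereochemistry; two
records that differ only in stereo descriptors are distinct. A
`stereo=False` escape hatch exists on `canonical_smiles` for corpora where
that convention is too strict.

Deduplication uses two views: `SM → P` (conditions ignored) and
`SM + R → P` (exact). Keys are canonical, map-stripped and
fragment-sorted, so they are invariant to input atom and fragment order,
and `SM + R → P` equality implies `SM → P` equality by construction.

## Changed-atom detection

An atom participates in the reaction center iff, comparing its occurrence
on the two sides by map number, any of the following differ: the multiset
of (neighbor map number, bond order) pairs, the formal charge, or the
total hydrogen count. Atoms present on one side only (leaving groups,
incoming reagent-derived atoms) are changed on that side. If an
environment difference involves an unmapped heavy neighbor the center is
undecidable and the record is rejected rather than guessed. This explicit
rule reproduces textbook reaction centers on the fixture families and is
the contract all downstream stages (template radius, `!` tagging, tag
counts) build on.

## Template extraction and canonical numbering

A radius-0 template's product pattern covers exactly the changed product
atoms; radius 1 adds their first-shell neighbors. Atom queries are written
with side-specific primitives: element, aromaticity, degree and charge for
every pattern atom, plus the hydrogen count for changed atoms only. Shell
atoms deliberately omit the H count — that is the generality knob the
correction step exploits, and it keeps r1 templates applicable to
homologues of the source reaction while the degree constraint still
excludes different scaffolds. Every product matching an r1 pattern also
matches the parent r0 pattern (monotone specificity).

Pattern atom maps are renumbered canonically so that the same abstract
transformation always serializes identically: changed product atoms get
maps `1..n_tags` ordered by canonical rank, then shell atoms, then
reactant-only atoms (ordered by BFS distance from the mapped atoms, with
ties broken on atom invariants). Canonical ranks are computed on a
map-stripped copy of the product in which each atom's *reactant-side*
environment is encoded as an isotope label; without this, symmetric
product patterns (the two ipso carbons of a biaryl coupling, the O–O of a
peroxide reagent) would be numbered by an arbitrary product-side tie-break
and mirror-image source reactions would yield different pattern strings.
The template hash is a SHA-256 digest (16 hex chars) of radius plus the
canonical patterns; it is invariant to atom renumbering and reordering of
the source reaction.

## Template application

Application in both directions goes through RDKit `RunReactants`. RDKit's
creation heuristics for hydrogen counts on mapped atoms are
version-sensitive, so after every application the package re-imposes the
hydrogen count and formal charge recorded in the pattern for every changed
atom (`SetNoImplicit` + explicit H), then sanitizes; unsanitizable
outcomes are dropped and counted, not raised. Retro application returns
one map-annotated SM-set per distinct match site, deduplicated by the
map-stripped canonical key and sorted for determinism. Forward application
requires a *unique* sanitizable product over all assignments of SM to
pattern slots; an ambiguous outcome returns nothing. Extraction
self-verifies by default: the freshly extracted template must regenerate
the recorded SM-set from the source product.

## Hierarchical correction

Radius-1 templates are compared only within the group sharing a parent r0
hash. Equivalence is *behavioral*, not graph-isomorphic: two templates are
equivalent iff each one's retro application reproduces the recorded SM-set
for every example reaction of the other. Mutually equivalent templates are
merged transitively and represented by the member with the fewest
specified atom primitives (ties: lexicographically smallest pattern), with
example counts summed. Partial subsumption (A covers B's examples but not
vice versa) does not merge — only mutual equivalence does.

## Tagging (SM*)

Changed SM atoms are marked with a `!` token inserted immediately after
the atom token in the canonical token stream (bracket atoms are single
tokens; ring-closure digits follow the tag). Tagging on the canonical
serialization makes the tagged string unique; a `canonical=False` flag
serializes in the RDKit input order instead for consumers that randomize
SMILES. Tokenization is the standard atom-wise sequence-model
tokenization (bracket atoms intact, two-letter elements intact).
`untag ∘ tag` is the identity, and the number of `!` tokens over an SM-set
equals the number of reactant-side changed atoms present in it.

## Predictors and the confidence gate

The reagent predictor and forward validator are structural protocols. Two
implementations ship:

* **TemplateOracle** — a deterministic test double. Reagents come from a
  fixed per-template table; the forward prediction untags SM*, re-applies
  the *generating* template, and reports `base_confidence` plus optional
  Gaussian jitter (sd `noise_sd`), clipped to [0, 1]. The jitter is a pure
  function of (seed, input), so results are independent of evaluation
  order. The oracle makes the campaign's control flow exactly testable:
  with zero noise, the acceptance rate factorizes into
  `1{base_confidence > threshold} ×` (forward-consistency rate).
* **External adapter** — a line protocol (`tagged-SM tokens [SEP] reagent
  tokens` in, `product-SMILES<TAB>confidence` out) for sequence models.
  The confidence of such models is taken as `exp(Σ log p_token)`, the
  product of top-beam token probabilities; whether a length-normalized
  variant is preferable is left to the adapter, which is the single place
  the formula lives.

The gate accepts a candidate iff the predicted product equals the target
(map-stripped canonical comparison) **and** the confidence is strictly
above the threshold. The threshold default is 0.95 with a strict `>`,
matching the convention that a score of exactly 95% is not enough.

## Generation campaign

Defaults: 5000 validated reactions per template, confidence threshold
0.95, pool split into 1000 subsets, one reagent candidate per SM-set.
The pool is sharded deterministically (balanced sizes, seeded
permutation); each template visits the subsets in its own seeded random
order and stops at the cap or pool exhaustion. Candidates are
deduplicated by their `SM + R → P` key before counting, so the cap counts
distinct validated reactions. Duplicates *across* templates are kept and
reported — removing them is a dataset-ops decision, not a generation one.
Checkpointing is per template: a manifest fingerprints the configuration,
template set and pool, and a resumed campaign yields byte-identical
output; a mismatched checkpoint is refused.

## Dataset operations

* **Equilibration**: per template, keep everything at or under the cap,
  otherwise a seeded uniform sample without replacement (the least-biased
  reading of "select a maximum of N per template"); input order preserved.
* **Template-grouped split**: templates in descending reaction count are
  greedily assigned to the most-underfilled split, so no template
  straddles splits and realized ratios deviate from the targets by at
  most the largest template's weight. Ties in count are broken by a
  seeded shuffle.
* **Overlap**: key-set intersections in both views; "same SM, different
  conditions" is the set of shared `SM → P` keys with no shared
  `SM + R → P` key. Fractions are computed over distinct keys by default
  (well-defined under duplicates); a raw-row mode is available.
* **Novelty**: distinct map-stripped species absent from the reference,
  for SM and reagents separately, plus reverse coverage.
* **Element frequency**: fraction of reactions with at least one reagent
  containing a given element, matched on atoms so "Na" never matches an
  amine nitrogen or tin.
* **Percentages** are reported at one decimal, rounded half-away-from-zero
  in exact integer arithmetic, so printed statistics are reproducible to
  the digit.

## Evaluation

`record_success` compares forward-predicted product keys against the
target within the top-n proposals; RTA averages over records, TA-RTA
averages per-template means with equal template weight (the only reading
consistent with being independent of examples-per-template). Both are
monotone non-decreasing in n. Success ignores the forward confidence by
default; a `require_confidence` option applies the gate during evaluation
instead. Per-tag-count stratification reports per-bucket RTA, TA-RTA,
record and template counts, and the population standard deviation of
per-template means (0 for single-template buckets, a convention needed to
report sd at all).

## The toy world

Six hand-coded families — esterification, amide coupling, Williamson
ether synthesis, aryl–aryl (Suzuki-type) coupling, Markovnikov
hydrobromination and syn-dihydroxylation — applied to an enumerated
substituent library (C1–C8 chains, isopropyl, benzyl, phenyl, tolyl, plus
anisyl/chlorophenyl for the aryl family) give ~600 distinct products and
fully mapped reactions with construction-time ground truth: changed-atom
sets, SM/R partition, generating family, tag counts spanning 2–4. The
hydrobromination family uses trisubstituted alkenes so the Markovnikov
orientation — and hence the forward re-application — is unambiguous.
Reagent lists are fixed per family and include Na- and P-containing
species so element-frequency reporting has signal.

What the toy world does *not* emulate: stereochemistry, protecting-group
chemistry, competing reaction channels, mapping noise, and the long-tail
template distribution of patent data. Passing tests therefore demonstrate
the correctness of the machinery (extraction, application, gating,
accounting, metrics) — not chemical validity of generated reactions on
real corpora, which is exactly what the pluggable forward validator is
for.

Test and acceptance runs use desk-scale problem sizes chosen to exercise
every code path: 216 fixture reactions (40 per family where the
combinatorial space allows), a 300-molecule pool in 4 subsets, and
campaigns over the six radius-0 templates (radius-1 templates are
deliberately near-exact on this small world, so the broad r0 rules are
what give campaigns interesting match counts).

## Known limitations

* Behavioral template equivalence is only as strong as the example pool;
  two templates with disjoint, non-overlapping applicability are never
  merged even if a chemist would consider them the same rule.
* Canonical numbering of reactant-only atoms falls back to an
  input-order tie-break for atoms that are genuinely automorphic *within
  their species*; this cannot change the emitted pattern string but is
  noted for completeness.
* Two identical SM species carrying different reactant-only atoms could
  in principle order ambiguously during extraction; no fixture or corpus
  record exercises this.
* The oracle validates against the generating template only; it cannot
  measure chemical plausibility, by design.
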