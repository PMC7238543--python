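# Methods

## The model

`fcmkit` analyses *fuzzy cognitive maps* (FCMs): signed, weighted digraphs in
which nodes are factors a stakeholder group believes affect an outcome (here,
safe maternity) and edges are perceived causal influences.  Edge strength is
elicited on an ordinal 1–5 consensus scale and signed: excitatory (+, source
up ⇒ target up) or inhibitory (−, source up ⇒ target down).  These are soft
models of stakeholder reasoning, not fitted statistical models; the pipeline
summarizes and compares them rather than estimating parameters from data.

The analysis chain is:

1. **Scaling.** Raw weights 1–5 are divided by a constant *c* (default 5),
   giving fuzzy magnitudes in (0, 1].
2. **Signed max–min transitive closure.**  For nodes *i*, *j*, a walk's
   strength is the minimum edge magnitude along it (bottleneck rule) and its
   character is its parity: an even number of inhibitory edges acts
   excitatory, odd acts inhibitory.  We track
   `P(i,j) = max strength over even-parity walks` and
   `N(i,j) = max strength over odd-parity walks`
   and report the signed influence `P − N ∈ [−1, 1]`.
3. **Category aggregation.**  A factor→category mapping (the thematic
   pattern-matching table, a human judgment taken as input) condenses the
   closure: `cumulative(C1, C2) = Σ_{a∈C1, b∈C2} closure(a, b)`, with
   within-category influence on the diagonal (the category map's self-loop).
4. **Cumulative net influence (CNI).**  Cumulative weights are divided by the
   maximum absolute cumulative weight over a *scope*, so the strongest
   category scores 1.
5. **Group combination.**  Maps from several groups are combined as a weighted
   average of pre-normalization cumulative weights, the weight being each
   group's participant count (here 18 and 11), then re-normalized.
6. **Comparison.**  Per category in the union of two groups' universes:
   *validated* (present in both, signs not opposing), *non-validated*
   (present in one), *conflicting* (present in both, strictly opposite
   nonzero signs).  Agreement is summarized by the *average difference* —
   the mean absolute CNI difference over rows; values nearer 1 mean less
   agreement.
7. **Sensitivity.**  A contested edge (one on which participants reached no
   consensus) is scanned over raw weights 0–5 (0 removes the edge), re-running
   the whole chain per value.

## Design choices where the procedure was open

* **Sign propagation through closure.**  Max–min closure is defined on
  magnitudes; signed influences require a rule.  We use the dual-parity
  closure above because it (a) reduces exactly to plain max–min on
  all-excitatory maps, (b) yields one signed value in [−1, 1], and (c) makes
  the `P = N` stalemate an explicit 0 instead of an arbitrary tie-break.
  Cells with both parities nonzero carry an **ambiguity flag**, written as a
  sidecar matrix next to every closure export, so a net value is never
  mistaken for an uncontested one.
* **Diagonal.**  No implicit self-strength of 1: `closure(i,i)` is nonzero
  only via genuine cycles.  Category self-loops then emerge from
  within-category cross-factor influence, which is the interpretation the
  elicitation supports.
* **Walks may revisit nodes.**  With max–min this cannot raise strength
  beyond the fixed point of repeated composition, but revisits *can* matter
  for parity (a cycle can flip a walk's character), so the fixed-point
  iteration runs to stability rather than stopping at n compositions.
* **Normalization scope.**  Two scopes are provided: `outcome-column`
  (normalize by the strongest influence on the outcome category — the scope
  for per-category outcome-CNI tables) and `whole-matrix` ("1 is the highest
  influence in the map" — the scope for full category-map exports).  Under
  `outcome-column`, off-column CNI cells may exceed 1; the scope is recorded
  on every result and comparing maps normalized under different scopes is an
  error.
* **Combination level.**  Groups share no factor universe, only the category
  universe, so combination defaults to the category level after aggregation;
  a factor-level alternative (union of canonicalized factor labels,
  weighted-average closure) is available via `combine_at: factor`.
* **Validation is decided by presence, not magnitude.**  A category is
  "present" in a group when it has at least one member factor in that group's
  map; a zero CNI with presence is non-opposing (so a 0.00/0.00 pair is
  validated, while a category with factors in only one map is non-validated
  regardless of CNI).
* **File conventions.**  Adjacency CSV cells are single signed numbers (−4 ≡
  inhibitory strength 4); factor identity is by label after trimming and
  case-folding; zero-weight cells mean "no edge".  GraphML weights are looked
  up in a numeric `weight` attribute first, then in the first numeric token
  of the edge label, because diagram-editor exports vary.

## Numerical behaviour

Closure values are *copied*, never multiplied or summed, so they always equal
some edge magnitude; two independent implementations agree exactly (no
tolerance needed).  The implementation is a parity-aware max–min fixed-point
iteration; the test oracle (`enumerate_walks_oracle`) is a pruned walk
enumeration that extends a walk prefix only while it strictly improves the
best known strength for its (end node, parity) state — exact, and independent
of the matrix route.  Aggregation and combination are ordinary sums/averages
in float64.  Reports print CNI and differences at 2 decimals; internal values
keep full precision, and differences are computed before rounding.

Degenerate inputs: an empty map closes to an empty matrix; an all-zero
cumulative scope passes through normalization undivided; a category with no
member factors has all-zero row and column; comparing two maps both lacking a
category simply omits that row.

## What the synthetic generator emulates — and what it does not

The study's raw adjacency matrices were never published; only the category
tables were.  The generator therefore emulates the *reported shape* of the
maps: risk maps of ~44 nodes/87 edges and protective maps of ~12–18 nodes/
31–38 edges, integer weights 1–5 (unimodal around 3, the consensus middle),
overwhelmingly excitatory edges (`inhibitory_prob = 0.02`; the study had a
single contested inhibitory influence), every category non-empty, one
designated outcome category, all randomness from one seed.
`generate_group_pair` additionally constructs two maps with an exact shared-
category fraction and conflict count (each category influencing the outcome
through one direct edge, so closure preserves the constructed signs), giving
ground truth for the comparison taxonomy.

Passing tests on these maps show the *algorithms* are correct under the
reported study conditions; they cannot show that real elicited maps have this
topology (real maps have hubs, chains of symptoms, and correlated weights),
nor validate the human thematic judgment embedded in the category mapping.
Quantities that would require the unpublished matrices — the final-map CNI
column, original node/edge counts, figure edge values — are deliberately not
reproduced; they are replaced by exact structural properties (oracle
equivalence on 100 seeded 6-node maps, closure idempotence and the min-rule
cap, single-edge monotonicity on all-excitatory maps, comparison structure
recovery, byte-identical pipeline re-runs).

Problem sizes in the test suite and acceptance script (6–20 node maps, 100
oracle seeds, 10-category group pairs) were chosen as the smallest sizes that
exercise every code path, including cycles and parity flips; results are
identical at larger sizes because closure values are exact.

## Known limitations

* The dual-parity net rule is this package's documented choice; the source
  procedure asserted signed closure values without specifying one.
* Ordinal 1–5 weights are treated as interpretable magnitudes after division
  by 5 — standard FCM practice, but still an ordinal-to-ratio leap.
* The average-difference statistic has no sampling distribution here; no
  significance test is offered (none is defined for consensus maps).
* No activation dynamics (sigmoid/threshold state simulation): the analysis
  is closure-based, and simulation semantics would be a different model.
* The packaged factor *labels* for the largest risk category are a
  best-effort transcription; their per-category counts, CNI values,
  validation labels and differences are authoritative.
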