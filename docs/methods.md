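# Methods

## The model

The package works with three mathematically linked representations of a set
of dichotomous "items" (here: gradations of motivation regulations, but
nothing is specific to that interpretation):

* **Co-occurrence (surmise) relation** ⊑ — a reflexive, transitive binary
  relation on the item domain Q. A stored pair (p, q), read p ⊑ q, asserts
  that anyone who possesses q also possesses p. One orientation is used
  everywhere in storage; the implication arrow q ⟶ p drawn in graphs is
  derived at render time. This convention is load-bearing: the matrix
  transpose bugs it prevents are the classic failure mode of this material.
* **State space** — a family of subsets of Q ("states") containing ∅ and Q.
  When closed under union and intersection (quasi-ordinal), Birkhoff's
  theorem makes it equivalent to a quasi-order: p ⊑ q iff every state
  containing q contains p, and the states are exactly the subsets closed
  downward under ⊑. `states_from_relation` enumerates downsets of the
  quotient poset and expands equivalence blocks afterwards, so the cost is
  linear in the number of states, not 2^m; a configurable cap (default
  10^6) guards against near-diagonal relations on many items.
* **Quotient poset** — the partial order on blocks of mutually implying
  items. Items in one block ("parallel", equally informative) occur in
  exactly the same states and cannot be separated by any data.

## Dichotomization

Likert scores 1–5 are split at the balanced mid-value: ≤ 2 → 0, ≥ 4 → 1,
and a 3 or a missing value makes the cell indeterminate. Filtering is
listwise *relative to the analyzed subset*: a respondent is dropped only if
an indeterminate cell falls inside the subset under analysis. This is what
makes the per-analysis sample sizes differ (948–1168 for single subscales,
180 for all 19 items jointly) and is the only filtering rule that
reproduces those printed sizes. Thresholds are parameters (`low_max`,
`high_min`) for instruments with other scale widths; no imputation is
offered by design.

## The IITA engine

For observed data, b[i][j] counts respondents with item i positive and
item j negative — counterexamples to the implication i ⟶ j. The candidate
ladder starts from ⊑₀ (all unviolated implications; provably transitive,
which the code re-validates on every construction) and, for tolerance
L+1 = 1…N, adds all absent pairs with at most L+1 counterexamples, then
repairs transitivity: a candidate pair is marked iff it participates as a
link in a violating composition with the current union, all marked pairs
are deleted simultaneously, and the scan repeats until stable. Only
candidate pairs are ever deleted — the previous level is immutable — so the
loop terminates and the union is transitive on exit (a violation with both
links in the previous level is impossible since that level is transitive).
Identical consecutive levels are collapsed, keeping the smallest L, and
construction stops at the complete relation.

Each distinct candidate is scored by
`diff = Σ_{i≠j} (b_ij − t_ij)² / (m(m−1))` with the single error rate
γ = mean of b_ij/(p_i·N) over the candidate's non-reflexive pairs
(p_i ≠ 0; γ = 0 if there are none), and expectations

* t = γ·p_i·N where the implication holds,
* t = (1 − p_j)·p_i·N for incomparable pairs (independence),
* t = max(0, (p_i − p_j + p_j·γ)·N) where only the reverse holds.

The minimum-diff candidate wins; ties break toward the earlier, sparser
ladder entry (the conservative choice — the selection rule itself does not
prescribe one). Candidates are scored by one code path in a fixed order, so
exact float comparison is deterministic. All counts are integers; γ, t and
diff are doubles.

## Structure interpretation

Width (combinatorial dimensionality) is the maximum antichain of the
quotient, computed exactly via Dilworth's theorem as k minus a maximum
bipartite matching on the strict order. The distance to unidimensionality
is the set of minimum vertex covers of the quotient's incomparability
graph — all minimum-cardinality block sets whose removal leaves a chain —
found by exact search over the vertices incident to incomparable pairs
(capped at 22 blocks; the structures here have ≤ 10). Meshing of
overlapping subset solutions is explicit configuration, never automatic:
`append` unions pair sets, `replace` first clears the base's pairs internal
to the patch's subdomain; both close transitively and log removed and
newly induced pairs. Whether closure may re-induce a replaced pair across
the patch boundary is genuinely underdetermined; this implementation lets
closure win and reports the fact in the log.

## Synthetic data generator

Respondents are drawn i.i.d. from the states of a given relation (uniform
over states by default — no population distribution is part of the model,
and uniform is the declared least-informative choice), then each item
response is corrupted independently. The default `violation_rate` is the
**careless-error** rate: a possessed item answered negatively, the
mechanism that violates a true implication and precisely the quantity the
γ estimator is consistent for (at rate g, E[b_ij/(p_i·N)] = g for every
true implication). A lucky-guess rate (absent item answered positively) is
available separately for robustness studies; guesses generate
counterexamples through the premise item and bias γ upward by roughly a
factor of two at these prevalences, which is why they are not part of the
calibrated default. The Likert surface layer re-encodes the (noisy) binary
truth as draws from {4,5} / {1,2}, replacing cells by the mid score 3 or a
missing marker at configurable rates, so the expected number of rows
surviving subset filtering is n·(1 − mid − miss)^m.

What the generator does *not* emulate: respondent heterogeneity in error
rates, item-specific careless/guess rates (the BLIM's per-item β, η),
local dependence between items, and any ordinal information in the Likert
surface beyond the dichotomy. Passing recovery tests therefore show that
the algorithm inverts its own generative assumptions at realistic sizes —
not that those assumptions hold in real questionnaire data.

## Problem sizes and numerical choices

Relations are dense boolean m×m matrices (m ≤ 19 here); closure is
iterated boolean squaring — exact and microseconds at this size. The
property suites use 1,000 random quasi-orders (m ≤ 7) for the Birkhoff
round trips and 1,000 random datasets for the ⊑₀-transitivity check; the
exhaustive IITA oracle enumerates all 355 quasi-orders at m = 4. The
recovery experiment uses the external-regulation chain as truth with
n = 500, careless rate 0.05, 100 replicates, and γ calibration at
n = 1,000 with 20 replicates; the whole suite runs in seconds. Replicate
seeds are spawned from one user-supplied seed through a single generator;
no global random state is used anywhere.

## The figure-derived final relation

The meshed overall relation ships as an edge-list fixture whose quotient is
two chains — autonomous {d1,d2,d3} < {i2,d4} < {i1,i3,i4,i5} and controlled
{e3} < {e4} < {j1} < {j2} < {e5} < {j3,j4,d5} < {e1,e2} — joined by one
edge placing the intrinsic block below j1. This is a *transcription of a
published figure*, not of a data table: the prose constrains the structure
(17 states; removal of {e3,e4} leaves a chain; d5 parallel with j3,j4; e5
implied by j3, j4, d5, e1, e2) but does not print the pair set, and the
chosen reading is the one consistent with all of those constraints at
once. Re-deriving the mesh from the packaged subset solutions reproduces
this relation up to two equivalence assertions (e4 ⊑ j1, i2 ⊑ d4) that the
refined subset analyses do not force; `analysis/04` prints the exact
disagreement rather than hiding it. Tests against this fixture check
structural properties (width, pruning, chain-after-restriction), never
numbers.

## Known limitations

* Only the corrected-estimator IITA variant implemented here is offered;
  the "original" and "minimized corrected" variants from the wider
  literature are out of scope, and published solutions obtained with a
  sibling variant could differ. When a reproduction target disagrees, the
  pipeline reports both the selected relation's diff and the diff of the
  target's relation instead of forcing agreement. (On the packaged data no
  disagreement occurs.)
* Polytomous (graded) analysis, surmise functions / AND-OR graphs,
  union-closed-only spaces (bases/atoms), and probabilistic model fitting
  (BLIM estimation) are out of scope.
* The pruning search is exponential in the worst case; it is exact and
  instantaneous on near-chain quotients but refuses domains whose quotient
  exceeds 22 blocks.
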