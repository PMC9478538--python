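# Methods

## Model

The universe is a pair of finite ordered label sets, data D = {d₁…d_N} and
hypotheses H = {h₁…h_N}.  Three probabilistic objects evolve:

* the belief P^t(h) over hypotheses (a `ProbVector`),
* the fixed likelihood P(dᵢ|hⱼ) (a `LikelihoodMatrix`; the *ideal* family
  puts mass α on the diagonal and (1−α)/(N−1) elsewhere, so each
  hypothesis predicts "its" datum almost surely),
* the displayed joint P^t(d,h) (a `JointMatrix`).

**Bayesian phase.**  At each step a datum is drawn i.i.d. uniformly from
the experienced subset D_E.  The posterior is computed by Bayes' rule and
adopted as the next prior.  The data marginal is the *cumulative* empirical
frequency of the draws, and the displayed joint is the product of the two
marginals P^{t+1}(d)·P^{t+1}(h) — the simulation recipe as stated, not the
likelihood-times-prior joint (that one, P(d|h)P(h), is available separately
and is what the N=7 worked example thresholds).  At t = 0, before any
observation, the data marginal is taken uniform so the initial joint is
well formed.  The free-energy objective KLD(prior ∥ posterior) − ln P(s)
is evaluated as a per-step diagnostic only; no optimization loop exists,
since posterior → prior updating already realizes the minimum.

**Excess phase.**  After the warm-up, each step (i) binarizes the current
joint at `relation_threshold` (strict >), (ii) partitions the indices 1..N
into maximal runs of constant diagonal membership — the boundary set is the
list of flip indices plus the sentinel N, and blocks run from one flip to
the next — and (iii) divides every row (per datum, over the hypotheses of
its block) or every column (per hypothesis, over the data of its block) by
the in-block sum, alternating between the two, starting with the per-datum
operation.  The whole row/column is divided, not only the in-block part,
so mass outside the experienced diagonal is amplified whenever the in-block
sum is below the total.

**Rough-set lattice.**  For a relation R ⊆ H × D, H\*(X) = {h : ∃ d ∈ X,
(h,d) ∈ R} and D\*(Y) = {d : all h related to d lie in Y}.  The two maps
form an adjunction (H\*(X) ⊆ Y ⟺ X ⊆ D\*(Y)), so D\*∘H\* is a closure
operator and its fixed points, ordered by inclusion, form a complete
lattice: meet is intersection, join is the closure of the union.
Enumeration is by join-generation — seed with closure(∅) and the singleton
closures, close under pairwise joins — which is complete because every
closed set is the join of the singleton closures it contains.  A power-set
filter (all 2^N subsets tested for closure-fixedness) serves as the
independent oracle in tests up to N = 12.

**Logic classification.**  All checkers are exhaustive on the finite
lattice: distributivity over all triples, complements over all pairs, the
orthomodular law over all comparable pairs.  The Boolean-block
decomposition connects proper elements by the *non-complement* graph
(cross-block proper elements of a fused lattice are always mutual
complements, within-block elements generally are not); two-element blocks,
invisible to that graph, are re-joined by deterministic complement pairing,
and every block is then verified to be a Boolean sublattice.  The canonical
orthocomplement is the unique within-block complement (bottom ↦ top); a
backtracking search over complement pairs is the fallback for lattices that
do not decompose, and returns none when no order-reversing involutive
complementation exists (e.g. chains).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n` | — | universe dimension (10 and 20 in the reference protocols) |
| `alpha` | 0.8 | diagonal likelihood mass; 1.0 = exact one-to-one (used by the N=7 worked example) |
| `experienced` | — | 1-based indices of data that can be drawn |
| `theta` | 0.1 | strict threshold for relations from ideal joints |
| `relation_threshold` | 0.0006 | binarization level for simulation joints (strict during the excess steps, inclusive ≥ for the final display) |
| `bayes_steps` | 30 | warm-up length (2000 for the pure convergence runs) |
| `excess_steps` | 0 | excess-phase length; 30 is used for the 20-dimensional protocol — the relation stabilizes well within the final 10 steps on all tested seeds |
| `heatmap_edges` | 0.01, 0.008, 0.002, 0.0006 | five-bin display edges (black/pink/orange/pale_yellow/white), inclusive from above |
| `smoothing` | none | cumulative data marginal; `none` keeps never-drawn data at exactly 0, `laplace` adds one pseudo-count per datum |
| `alternation_start` | data | which renormalization the first excess step applies |
| `sum_upper_inclusive` | false | widen each in-block sum by the next block's first index (the printed-formula reading of the summation bound; the worked block squares fix the default) |
| `zero_block_sum` | skip | rows/columns with zero in-block mass are left untouched (logged at debug level — this is the expected path for never-experienced lines) or, optionally, raise |

Normalization invariants are enforced at 1e-9 absolute; all divergences and
entropies are in nats (0·ln 0 = 0).  Labels are 1-based (`d1…dN`,
`h1…hN`); internal bitmask/array storage is invisible at the interfaces.

## Design choices in genuinely open territory

* **Final relation of the excess phase.**  The two renormalizations are
  row/column scalings, so the evolved joint is always D₁·J₀·D₂ for the
  warm-up joint J₀.  Thresholding such a matrix can never show diagonal
  squares over a *fully related* background: if cross-block cells (i,k) and
  (k,j) are above a threshold while in-block cells (i,j) and the other
  block's cells are below it, the products of the corresponding scale
  factors contradict each other.  The operative construction is therefore
  the *articulation*: the final block partition (from the ≥-binarized final
  joint) is rendered as one diagonal square per block with everything
  outside the squares related.  This is also what keeps the claim honest:
  the block structure itself is discovered by the dynamics (never-presented
  rows stay at exactly zero and keep their diagonal cells off; experienced
  rows are amplified above threshold), while the articulation only renders
  that partition as a relation.  The raw thresholded relation remains
  available as a diagnostic and in the snapshots.
* **Which "experience" articulates.**  In `all_blocks` mode the partition
  follows the thresholded relation's diagonal (every block becomes a
  diagonal square).  In `experienced_only` mode it follows the realized
  experience — which data have been drawn at least once — because
  relation-diagonal flags would freeze the partition around whichever
  hypothesis happened to lead after the warm-up; never-experienced blocks
  are absorbed into the background, and removing redundant (fully related)
  rows and columns then leaves exactly the experienced diagonal blocks.
* **Smoothing default.**  `none` is the default because the protocols'
  defining feature is that never-presented data have probability exactly
  zero; with additive smoothing every diagonal cell eventually binarizes on
  and the block structure collapses into a single block.  The zero rows
  this creates are precisely what the zero-block-sum skip rule handles.
* **Upper summation bound.**  The in-block sums run over the block
  [s_k, s_{k+1}−1]; the alternative reading that includes index s_{k+1} is
  implemented behind `sum_upper_inclusive` but off by default, because the
  worked block squares ([1,2], [3,5], [6,11], [12,20]) pin the geometry to
  maximal runs.
* **Bottom of the lattice.**  closure(∅) can exceed ∅ when some datum is
  related to no hypothesis (sub-diagonal relations): the bottom is then the
  set of unrelated data, and the lattice is isomorphic to — not equal to —
  the power set of the experienced data.
* **Orthocomplement non-uniqueness.**  In a fused lattice every proper
  element has many complements (all proper elements of other blocks); the
  within-block complement is chosen as canonical, which is the choice under
  which the orthomodular law is verified.  For lattices whose 2-element
  blocks admit several valid pairings, any deterministic pairing yields an
  equivalent orthocomplementation; the element-order-first pairing is used.

## What the generator emulates — and what it does not

The synthetic protocols reproduce the study conditions exactly: uniform
i.i.d. draws from D_E, fixed likelihood throughout a run (no likelihood
learning, no inverse-Bayesian step, no active/embodied control loop), and
the stated dimensions, thresholds and warm-up lengths.  Real cognitive data
would add non-uniform presentation frequencies, drifting likelihoods and
observation noise, none of which are modeled; a passing suite shows the
mathematical chain (inference → relation → lattice → logic) behaves as
claimed under the stated conditions, not that human data follow it.  The
20-dimensional protocol's block partition is seed-dependent in detail
(occasionally an experienced index lags below threshold and splits a run),
but the qualitative outcome — at least two diagonal blocks over a fully
related background, hence a non-distributive orthomodular lattice — held on
every seed tested.

## Numerical and degenerate-input notes

* Probability comparisons in tests use 1e-6 unless a printed value fixes a
  rounding; normalization checks are 1e-9 absolute.
* KLD raises on absolute-continuity violations rather than returning inf;
  the per-step diagnostic catches this for degenerate (α = 1) likelihoods.
* Thresholding uses strict > during the dynamics and inclusive ≥ for final
  displays; both conventions are explicit parameters.
* Lattice enumeration is guarded at 2^16 elements by default (override via
  `guard`); the N ≤ 63 fast path uses uint64 bitmasks with a pure-Python
  fallback above that.
* Renormalization preserves zeros and within-line ratios exactly (it is a
  scalar division per line); skipped zero lines are bit-identical copies.

## Known limitations

* The logic checkers are exhaustive, not structural proofs: orthomodularity
  is verified for the enumerated instance, quantifier-free, which is the
  appropriate standard for finite lattices but does not generalize by
  itself.
* The Boolean-block decomposition targets lattices that are (near-)
  horizontal sums of Boolean blocks; for other non-distributive lattices it
  reports a partial decomposition rather than searching all maximal Boolean
  subalgebras.
* Hilbert-space constructions, entanglement, concept-conjunction
  (guppy-effect) probabilities, formal-concept-analysis lattices and
  embodied-robotics loops are out of scope.
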