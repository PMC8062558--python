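# Methods

## Model

A clone-structured cognitive graph (CSCG) is a hidden Markov model over H
hidden states with two structural commitments:

1. **Clone-structured emission.** Each state deterministically emits one
   observation symbol; the states emitting symbol j form a contiguous index
   block C(j) (symbol-major, 0-based).  The emission matrix is the implied 0/1
   block structure and is never materialized, except in *dense emission mode*
   (schema transfer), where a row-stochastic P(x | z) is learned explicitly.
2. **Action-augmented transitions.** The stored parameter is the joint
   conditional T(i, k, j) = P(z' = j, a = k | z = i), so every state's
   (action, next-state) block sums to one and the action-free cloned HMM is
   recovered by summing over actions.

Because the emission support of step n is C(x_n), every forward/backward or
Viterbi step touches only the M_{x_n} × M_{x_{n+1}} block of T selected by the
observed symbols and action: inference and learning cost O(M²N) for M clones
per symbol, independent of alphabet size.  The kernels (numba) normalize
messages per step and accumulate log-normalizers, so 10⁵-step sequences do not
underflow.

## Learning

**EM with pseudocount.** Baum–Welch with expected transition counts
ξ_{ikj}(n); the M-step adds a pseudocount κ to every count before
normalizing (a Dirichlet/MAP prior), which keeps all transitions positive and
regularizes when data are scarce.  The prior π is re-estimated from γ(1)
counts smoothed with the same κ.  Convergence is declared when the relative
change of the penalized log-likelihood (log-likelihood + κ Σ log T + κ Σ log π)
falls below `tol` (default 1e-6; the experiment harnesses use 1e-9..1e-13
because clone consolidation proceeds through long shallow plateaus), or after
`max_iters`.  With `n_restarts > 1` the restart with the best final penalized
log-likelihood wins; this selection reliably identifies runs that found the
minimal-state solution, because redundant clones dilute transition estimates
and pay a smoothing cost.

**Conditional vs joint normalization.** The joint parameterization P(z', a|z)
is what the model stores, but the default *EM dynamics* optimize the
action-conditioned likelihood P(x | a): the E-step runs on
P(z' | z, a) (per state-action row normalization), and the final tensor is
converted back to the joint form through the empirical per-state action
frequencies (equivalently, a joint M-step of the final expected counts), so
all stored-model invariants hold.  The reason is empirical and large:
on navigation data, joint-normalization EM stalls with many redundant
context-split clones (64+ states on the 6×8 room task), because a clone shared
across contexts must also average their action-feasibility profiles — sharing
is penalized.  Conditional dynamics make sharing free and consolidate to the
minimal map.  Both modes are exposed (`EMConfig.normalization`).

**Two-phase schedule** (`fit_two_phase`): EM with κ > 0 to convergence,
then *Viterbi training* — hard EM that decodes the MAP clone path, counts its
transitions, renormalizes with κ = 0, and repeats until the decoded paths are
stable.  The refinement removes the smoothing mass and the redundant clones it
keeps alive; states never visited by a decoded path retain their previous rows
and can be pruned (`prune_model`, which re-indexes and never changes the
likelihood of decoded paths).

**Rapid memorization** (`memorize`). Strictly repeating data — laps around a
track, prototypical routes — make the collapsed first-order solution a strong
attractor: randomly initialized EM reaches it from every seed we tested
(including a minimal 2-lap × 4-position task), although the higher-order chain
is a stable fixed point with a strictly better objective once constructed.
`memorize` performs one dynamic-Markov-coding pass over the data, allocating a
fresh clone of the upcoming symbol whenever the (current clone, action, next
symbol) context is new (wrapping round-robin when a symbol's clones are
exhausted), and returns the lightly smoothed count model.  EM refinement then
merges the clones this pass over-allocates ("memorize rapidly, generalize
gradually").  Random-walk data do not need it; the lap and route experiments
use it.

**Split-merge refinement** (`split_refine`, `split_merge_refine`).  EM merges
clones readily but possesses no move that un-merges them: once two locations
share a clone, the merged state is a stable fixed point even when splitting
would raise the objective, and large aliased worlds (the 4×4 maze: ~33 cells
per symbol) end up with self-consistent cross-room merges — co-merged
neighborhoods whose boundaries never expose a local inconsistency, including
pairs of corner cells with complementary legal-action sets, which the
action-conditioned likelihood cannot distinguish at all.  The refinement
supplies the missing moves on worlds where each (location, action) has a
deterministic outcome: group the MAP decode of each clone by incoming context
(previous clone, previous action); contexts that disagree on the majority
successor of a shared action, or whose well-sampled observed action sets
differ, cannot be one location and are separated onto free clones of the
symbol.  The dual merge move folds clones of one symbol with identical
successor maps and action sets, returning their clones to the free pool so
splitting is never starved.  `split_merge_refine` alternates these moves with
short warm EM consolidations and Viterbi training until the transition tensor
is stable — on the hierarchical maze this converges to exactly one clone per
cell.  On genuinely stochastic worlds the split test would over-split, so the
routine is reserved for deterministic-under-action environments.

**Emission-only EM** (`learn_emission`) freezes the transition tensor
(bit-identical before/after) and learns a dense emission from uniform
initialization — schema transfer to a new environment with the same layout.
The transfer model's prior is reset to uniform: the agent does not know where
in the new environment it starts.

**Online EM** (`online_em_update`): running statistics
A ← λA + (1−λ) Σ ξ with memory λ ∈ (0, 1), transition update by row
normalization of A (dead rows keep the previous model's rows); the prior is
left untouched, since for long streams the initial state is immaterial.
Default batch length in examples: 1,000 steps.

## Inference

Collapsing (a_n, z_{n+1}) into one variable makes the model a chain, so belief
propagation is exact.  Soft evidence enters as per-step likelihood vectors
over symbols (one-hot = hard evidence); absent actions are integrated out.
Viterbi ties break toward the lowest state index, so decodes are reproducible.

**Error correction** models a channel that replaces a symbol with probability
p uniformly over wrong symbols; per step the evidence is (1−p) on the observed
symbol and p/(E−1) elsewhere, a single forward pass yields the filtered
posterior over the *true* symbol, and the output is its argmax.  The
evaluation protocol in `remapping` gives each test walk a 10-step clean
prefix before corruption begins and a uniform state prior: an online corrector
operates on a localized agent, and under a cold start with corrupted context
the Bayes-optimal argmax occasionally (≈1 per 100 sequences) overrides a clean
symbol in the first ~5 steps — correct behavior under the channel model, but a
different regime from the one the headline numbers describe.

**Dwell augmentation** (`CSCGModel.with_dwell`). Uniform smoothing prices a
self-transition and an arbitrary state jump identically, which makes posterior
parses on temporally stretched inputs (elongated corridors) degenerate across
lap assignments.  Mixing an explicit self-transition probability ρ into the
inference model — T' = (1−ρ)T + (ρ/N_a)I — is a standard duration
augmentation that represents "the agent lingers here" without retraining; the
lap-elongation analysis uses ρ = 0.3.

**Remapping metrics.** Active-clone sets threshold the filtered posterior at
0.01; overlap between environments is the Jaccard index of active sets,
averaged over pairs.  Rate-remapping evidence softening is
(1−ε)·one-hot + ε/E with ε = 0.3.  Environment identity sums filtered
posterior mass over per-environment clone sets obtained by argmax of the
training walks' summed forward messages.

## Planning

Feasibility must ignore pseudocount-only edges, so planning runs on the
support graph: an edge survives if its probability exceeds 10× its row's
minimum entry (pseudocount-only entries sit at the row minimum; for κ = 0
models the minimum is 0 and all positive edges survive; a never-updated
uniform row yields no edges).  The minimal-horizon plan is breadth-first
search over (state, action) edges — the deterministic specialization of
"forward sweep until the goal has support, max-product backward for the
actions" — with ties toward the lowest action id.  Goals are an observation
symbol (any clone) or a specific clone.  Closed-loop execution replans after
a rejected action by removing the failed (clone, action) edge and
re-localizing via exact filtering of the executed history.

## Hierarchy

The action-marginalized transition tensor over Viterbi-used clones, with edges
stripped at pseudocount scale, is a directed weighted graph.  The clone-level
partition comes from the map equation (InfoMap, via python-igraph, seeded).
Collapsing each community to a node sums edge weights and keeps
within-community mass as a self-loop (the dwell flow of the underlying walk).
On the collapsed graphs, the few contracted nodes leave too little flow
structure for the map equation's granularity to settle on the coarse modules
(it reliably returns hyper-pure but over-split partitions), so upper levels
use modularity (Leiden) instead; both objectives are exposed through
``detect_communities(method=...)``.

Hierarchical planning first computes shortest routes at the top level and
takes as corridor every community lying on *any* shortest top route — a single
route would break hop-count ties arbitrarily, which at block scale can commit
to the long way around.  Lower levels search only inside the corridor;
intermediate-level paths provide the sub-goal sequence.  Node expansions of
the counter-instrumented Dijkstra, summed over levels, are the effort measure
compared against flat search — in aggregate over start/goal pairs, since a
nearby goal lets flat search terminate almost immediately.  Surrogate
partitions permute community labels over nodes, preserving sizes, as the
control for whether room-aligned structure (not mere partitioning) is what
helps.

## Synthetic environments

The generators emulate the classic testbeds and are pure functions of their
seeds.

- **Aliased rooms**: rectangular grids with few unique symbols, optionally
  with a uniform interior (distinct sensations only near walls).
- **Overlapping rooms**: two 8×6 rooms realized as windows of one coherent
  global map sharing a 3×3 corner region, plus an interior confounder copy in
  room 1.  The interior placement keeps the confounder's movement context
  distinct from the corner patch, so only temporal context separates them —
  two identical *corner* patches are nearly symmetric to an action-conditioned
  learner and routinely merge.
- **Hierarchical maze**: a 4×4 tiling of 5×5 aliased rooms; rooms inside each
  2×2 block are joined by two bridge cells, adjacent blocks by one — the
  denser in-block wiring is the second level of structure the abstraction is
  meant to discover.  The i.i.d. symbol draw is rebalanced so no symbol's
  cell count exceeds ~1.1× its expected share: an unconstrained draw
  occasionally assigns one symbol more cells than any fixed clone allocation
  provides, making exact recovery impossible rather than merely hard.
- **Modular graph**: 15 nodes in three ring-linked five-node clusters, every
  node of degree 4, the five observation labels reused in every cluster.
- **Routes and laps**: an alternating figure-eight T-maze (shared stem,
  alternating arms); overlapping odor sequences; two stochastic routes to a
  common destination overlapping in seven locations (observations
  4-5-11-12-13-5-17); the four-lap track (start + 4×(1..12) + reward,
  0-based symbols internally).
- **Remapping sets**: five 5×5 rooms as permutations of 25 shared symbols,
  and five closed-loop tracks of different proportions over 6 symbols.

Random walks choose uniformly among legal moves and never leave the world;
the corruption process replaces symbols independently with uniform wrong
symbols.  The constructions reproduce stated structural properties (overlaps,
aliasing, hierarchy), not the pixel geometry of any published figure.

What the generators do **not** emulate: sensory noise during training,
continuous space, non-uniform behavioral policies, or multi-modal cues.
Passing tests therefore demonstrate the representational and algorithmic
claims on clean discrete worlds, not robustness to real sensor statistics.

## Problem sizes and defaults

Experiment harness defaults (all overridable): 6×8 room, 18 symbols, 20
clones/symbol, κ = 2e-3, 50,000 steps, ≤2500 EM iterations (tol stops near
~1100-1600); overlap rooms 2×10,000 steps, κ = 1e-2, ≤500 iterations, 10
restarts; transfer room 10,000 steps, 20 symbols, 5 restarts; T-maze 1,600
steps and 2×200 route episodes, κ = 1e-3; lap track single 50-symbol sequence
(memorized), κ = 1e-3; remapping/correction: five rooms × 10,000 steps, 10
clones, κ = 1e-3, full EM 100 iterations vs partial 10; hierarchy: modular
graph 20,000 steps; maze 120,000 steps, 40 clones/symbol, consolidation on a
30,000-step prefix before fine-tuning on the full walk (a coarse-to-fine data
schedule: clone consolidation is iteration-hungry but data-cheap, so most
iterations run on the prefix).

## Known limitations

- EM consolidation to the minimal state count is a local search; restart
  selection makes it reliable at these scales but offers no guarantee, and
  larger or more aliased worlds degrade gracefully rather than sharply.
- Cold-start error correction can override clean symbols while delocalized
  (see above); the corrector reports posteriors so callers can gate on
  confidence if they prefer missed corrections over false ones.
- `memorize` wraps around when a symbol's clones are exhausted, which on large
  random-walk worlds produces colliding chains; it is intended for
  prototypical-sequence data, not as a general initializer.
- Hierarchical plans are shortest within the selected community corridor;
  they can exceed the flat shortest path (bounded in practice well under the
  1.5× we assert) when a room is split across communities.
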