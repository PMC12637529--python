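# Methods

This note records the models, conventions and numerical choices behind
nemagraph, and what the synthetic-data tests do and do not establish.

## Graph model

A nervous system is a directed multi-relational graph. We keep **one
aggregated connection per (pre, post, kind)** — duplicate input rows are
weight-summed — because all analyses here operate on neuron-pair
connections with synapse counts as weights, not on individual synapse
instances. Gap junctions are stored as two mirrored directed edges of
equal weight so a single directed-traversal machinery serves every
connection kind; motif and chain analyses nevertheless run on the
chemical graph only. Chemical (and gap) self-loops are dropped at load
because the motif and null-model machinery assumes a simple digraph;
peptidergic self-edges (autocrine signalling) are allowed and flagged.

Paths are **node-simple** (no repeated node). This is stricter than
forbidding only repeated edges, but it bounds enumeration and is what the
shell layout and the mono-/disynaptic path queries need.

Folding aggregates member edges losslessly and order-independently:
weight = sum, (ligand, receptor) annotations = union, scalar edge
properties collected into lists; within-group edges are retained as group
self-loops; a folded node's members are recorded in its properties. Group
connectivity defaults to "any member connects" (an `all`-members variant
can be expressed through `select` + subnetworks).

## Motif search

The triad census uses *induced* classification of every weakly connected
node triple into the 13 connected directed classes. We use the standard
MAN (mutual/asymmetric/null dyad) nomenclature — `030T` = feed-forward
loop, `030C` = 3-cycle, `021D` = out-star — rather than an index 1–13,
since index conventions vary between tools.

Chain matching, by contrast, is **non-induced subgraph monomorphism**: an
injective template-node → neuron mapping must preserve the 3L template
edges, and extra connectome edges among the mapped neurons are permitted.
An induced 7-node, exactly-9-edge subgraph would be vanishingly rare in a
dense connectome, which is incompatible with the whole-network coverage
such chains achieve. Chain templates carry no nontrivial automorphism
(every node is distinguishable by its degree signature within the
template), so injective mappings and motif instances coincide; triads are
counted per node-set.

The matcher enumerates FFL instances once, indexes them by input node and
composes chains depth-first, sharing exactly the chaining node (the
previous FFL's output in sequential mode, its intermediate in
intermediate mode) and enforcing global distinctness of all 2L+1 mapped
neurons. Arbitrary (non-chain) templates fall back to VF2 subgraph
monomorphism. Both routes are checked in the tests against an independent
brute-force backtracking search over injective label assignments.

Matching runs on the unweighted chemical digraph by default; a
`min_weight` filter is available where analyses restrict to strong
(e.g. >5-synapse) connections.

## Hierarchical alignment

Forward = sensory→interneuron, sensory→motorneuron,
interneuron→motorneuron; backward = the three reverses; lateral =
same-type. H = (C_f − C_b)/(C_f + C_l + C_b). Each direction of a
reciprocal connection contributes one tally. Neurons typed outside
{sensory, interneuron, motorneuron} (e.g. pharyngeal "other") are
excluded and the excluded count is reported. When no edge is tallied, H
is flagged undefined rather than propagated as NaN.

## Null models and statistics

Degree-preserving randomization uses the double-edge swap
(a→b), (c→d) ⇒ (a→d), (c→b), rejecting proposals that would create a
self-loop or duplicate an existing edge; each edge's weight travels with
its source endpoint, so out-strength per node is conserved along with the
exact in- and out-degree sequences. The default number of **successful**
swaps is round(|E|·ln|E|) — natural log: for |E| = 3,709 this is 30,482,
i.e. the "about 30,000" regime appropriate for mixing at that size,
whereas log₁₀ would give only ≈13,200. Rejected proposals are capped at
20× the target; exhausting the cap (a structure with essentially no
admissible swap, such as a single reciprocal pair) returns the network
randomized so far with a warning, or raises under `strict`.

The z-test uses the sample standard deviation (ddof = 1) of the null
values; one-sided p-values come from the standard normal tail, with the
side chosen by the sign of the deviation (both over- and
under-representation are of interest). A zero-variance ensemble yields a
flagged degenerate result: significant iff the observation differs from
the constant null. Families of statistics are corrected with the
Benjamini–Yekutieli procedure (valid under arbitrary dependence),
delegated to statsmodels and verified against a hand-computed example.

## Annotation

A chemical connection a→b is annotated with every (L, R) such that a
expresses ligand L, b expresses receptor R and (L, R) is in the
ligand–receptor map. "Unique transmitter" is judged on **distinct
ligands**, not distinct pairs: one transmitter acting through several
receptor subtypes still identifies the connection's chemistry uniquely.
Neurons missing from an expression table are treated as expressing
nothing (their connections come out unannotated) rather than erroring,
because real expression atlases never cover every neuron; the count of
such neurons is logged. Expression tables can be binarized at a
confidence threshold, and class-level columns can be expanded to member
neurons via an explicit, opt-in class→members map (imputation under the
assumption that same-class neurons share a transcriptome).

The neuropeptide connectome uses the **long-range model**: an edge for
every expressing sender × receiver pair with no spatial constraint.
Enrichment of a pair within a neuron subset compares directed connection
density inside the subset (edges with both endpoints inside ÷
|S|·(|S|−1)) against the density over all other ordered pairs with a
pooled two-proportion z-test, right-sided, BY-corrected across pairs.
The density-based two-proportion formulation is our interpretation of a
subset-vs-rest z-test; self-edges are excluded from both denominators.

## Rate model

dr_i/dt = (1/τ_i)[−r_i + g_i φ_i(Σ_j w_ji r_j + I_i(t) + b_i)], forward
Euler with fixed dt = t_max/n_steps, inputs applied on half-open
[t_start, t_end). The activation defaults to **identity**, which keeps
the feed-forward chain linear and analytically checkable (tanh and relu
are provided). The sweep conditions are: sequential chain of L = 3 FFLs
(7 nodes), weights drawn per iteration from U(−1, 1) on an
iteration-specific substream of the seed, τ = 1 s, g = 10^0.1 ≈ 1.26,
b = 0, r(0) = 0, unit step to node 1 on [2, 4) s, 30 s in 1500 steps
(dt = 0.02 s), 1000 iterations.

Accuracy: the single-node step response converges to the closed-form
solution at first order in dt, and the 7-node linear chain is checked
against a 10×-finer-dt reference. At dt = 0.02 the max-norm relative
error of the chain is ≈ 4×10⁻³, dominated by the input discontinuity, so
the 10⁻³-level agreement check is run at dt = 0.002 vs 0.0002; the sweep
itself uses dt = 0.02, where the onset/sustain metrics (resolution one
dt) are insensitive to this error.

"Onset" is the first time a trace deviates from its initial value by more
than 5 % of its peak deviation (configurable; a flat trace has no onset).
Sustain is reported as time above half-peak deviation plus the final
value as a fraction of peak. The push–pull property — opposing weights
converging on node 3 shrink and delay its response — is asserted against
a common absolute response level (5 % of the aligned-case peak), since an
onset defined relative to each trace's own tiny peak would not capture
the physical delay of the output.

## Synthetic data

The fixture generator emulates the *shape* of the study system: 300
neurons by default, type fractions (0.30, 0.27, 0.43)
sensory/inter/motor, background edges drawn independently per ordered
pair with probability 0.0413 (≈3,700 expected connections), synapse-count
weights uniform on 1–9. Planted chains are embedded on disjoint neuron
sets oriented sensory → interneurons → motorneuron when the type budget
permits, and expression fixtures assign each edge a distinct synthetic
cognate (ligand, receptor) pair so the true annotation of every edge is
known exactly; decoy ligands/receptors absent from the pair map act as
noise that can never annotate.

What passing these tests shows: the algorithms are correct on graphs of
realistic size, sparsity and type structure, with exactly known ground
truth. What they do not show: behaviour under real-data features the
generator does not emulate — degree heterogeneity and hub structure,
spatially correlated wiring, heavy-tailed synapse counts, correlated and
incomplete expression calls. Conclusions about a real connectome require
running the pipeline on the real tables through the provided readers.

## Known limitations

- Motif analyses cover the chemical graph only; gap-junction or
  peptidergic motif search is out of scope.
- No parallel same-kind multi-edges; synapse-instance-level analyses
  would need a different aggregation.
- The neuropeptide model has no short/mid-range spatial variant.
- The enrichment null is density-based; count-based or undirected
  variants would need their own calibration.
- Layouts are pure coordinate generators; styling (edge colour by
  annotation, width by weight) is left to the caller or the thin
  `render` helper.
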