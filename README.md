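# nemagraph

Connectome graph analysis for small nervous systems: multi-relational
neuron graphs, feed-forward-loop hyper-motif chains, degree-preserving null
models, expression-based neurotransmitter and neuropeptide annotation, and
firing-rate simulation of chained circuits.

## Who this is for

Systems neuroscientists working with cellular-resolution connectomes — the
*C. elegans* hermaphrodite chemical connectome being the archetype
(~300 neurons, ~3,700 directed chemical connections, every neuron typed
sensory / interneuron / motorneuron) — who want to ask how network
structure relates to the sensory-to-motor flow of information, which
transmitters carry which connections, and how stereotyped circuit motifs
transform inputs in time.

## What it computes

**Graph container.** A `NervousSystem` holds typed `Neuron`s and directed
`Connection`s keyed by `(pre, post, kind)` with
`kind ∈ {chemical, gap, peptidergic, functional}` and synapse counts as
weights. Gap junctions are stored as mirrored directed pairs; duplicate
edge rows are weight-summed; chemical self-loops are dropped. Subnetworks,
folding (merging neurons into class nodes with weights summed and
annotations unioned), simple-path enumeration, predicate-based groups, and
CSV / adjacency / node-link JSON / GraphML I/O are provided.

**Motifs and hyper-motif chains.** The triad census classifies every
weakly connected neuron triple into the 13 connected directed classes
(`030T` is the feed-forward loop, FFL: input → intermediate → output plus
the input → output shortcut). FFLs chain into *simple hierarchical
chains*: a **sequential hierarchy** joins each FFL's output node to the
next FFL's input, an **intermediate node-chain** joins the intermediate
node instead; a chain of L FFLs has 2L+1 nodes and 3L edges. Matching is
subgraph monomorphism (injective mapping preserving all template edges,
extra connectome edges allowed), implemented by enumerating FFLs once and
composing them depth-first under global node-distinctness — verified
against brute-force search in the test suite.

**Hierarchical alignment.** Edges among matched neurons are tallied as
forward (sensory→inter, sensory→motor, inter→motor), backward (the
reverses) or lateral (same type), giving

    H = (C_forward − C_backward) / (C_forward + C_lateral + C_backward) ∈ [−1, 1],

+1 for a perfectly sensory-to-motor-aligned structure, −1 for the reverse.

**Null models and significance.** Degree-preserving randomization by
double-edge swaps — (a→b), (c→d) ⇒ (a→d), (c→b), rejecting self-loops and
duplicates — with a default of round(|E|·ln|E|) successful swaps (30,482
for |E| = 3,709). Observed statistics are compared to the null ensemble
(default 50 randomizations) with a one-sided z-test (critical value 1.96)
and Benjamini–Yekutieli FDR correction.

**Connection annotation.** A chemical connection a→b gets the putative
pair (L, R) when a expresses ligand L, b expresses receptor R, and (L, R)
is in the ligand–receptor map; connections are classified unannotated /
unique-transmitter / multiple-transmitter. The same sender/receiver logic
without an anatomical constraint builds the long-range neuropeptide
connectome, with per-pair enrichment testing (two-proportion z, BY-corrected)
for neuron subsets such as the pharynx.

**Rate model.** Each node integrates
`dr_i/dt = (1/τ_i)[−r_i + g_i φ(Σ_j w_ji r_j + I_i(t) + b_i)]`
by forward Euler. The hierarchy sweep simulates the 7-node sequential
chain under many uniform random weight draws in (−1, 1) (defaults: 1000
iterations, τ = 1 s, g = 10^0.1, a unit step input to node 1 on [2, 4) s,
30 s in 1500 steps) and summarizes each node's onset and sustain — the
push–pull behaviour at the shared nodes 3 and 5 shapes the output timing.

## Worked example

Generate a 50-neuron synthetic connectome with one planted length-3
sequential hierarchy on a sparse random background, then search for it:

```sh
$ nemagraph fixtures --n 50 --plant 3:sequential --background 0.02 --seed 7 --out-prefix demo
wrote demo_neurons.csv, demo_edges.csv, demo_truth.json (50 neurons, 54 connections)

$ nemagraph motifs chain demo_edges.csv --neurons demo_neurons.csv --length 3
{
 "chain_length": 3,
 "mode": "sequential",
 "n_matches": 1,
 "template_nodes": 7,
 "template_edges": 9,
 "covered_neurons": 7,
 "covered_connections": 9,
 "alignment": {"c_forward": 4, "c_backward": 0, "c_lateral": 5, "h": 0.4444444444444444},
 ...
}
```

The one match is the planted chain: 7 neurons and 9 connections covered,
and its edges point forward (4 forward, 0 backward; the 5 lateral edges
run between the interneurons at depths 2–6), giving H = 4/9 ≈ 0.44.
Testing the chain count against 50 degree-preserving randomizations:

```sh
$ nemagraph nullmodel test demo_edges.csv --neurons demo_neurons.csv --stat chain --length 3 --n-rand 50 --seed 1
{
 "statistic": {
  "observed": 1.0, "null_mean": 0.0, "z": null, "p": 0.0, "p_adj": 0.0,
  "side": "right", "degenerate": true, "significant": true
 }
}
```

No randomized network contains a single length-3 chain (a degenerate,
zero-variance null), so the planted chain is reported as significantly
over-represented. `nemagraph simulate --length 3 --iters 1000 --seed 1
--out metrics.csv` runs the rate-model sweep and writes per-node onset and
sustain metrics for each weight draw.

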