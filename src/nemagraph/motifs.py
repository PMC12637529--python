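"""Motif analysis on the chemical connectome.

Covers the triad census (the 13 weakly connected directed 3-node
isomorphism classes), feed-forward-loop (FFL) enumeration, construction and
matching of FFL *hyper-motif chains*, neuron-type role composition of
matches, the hierarchical-alignment statistic H, and match coverage.

Two ways of chaining FFLs into simple hierarchical chains are supported:

* ``sequential`` — each FFL's *output* node is the next FFL's input node.
  For chain length L the template has nodes 1..2L+1 with FFL k on
  (2k-1, 2k, 2k+1); e.g. L=3 gives FFLs (1,2,3), (3,4,5), (5,6,7).
* ``intermediate`` — each FFL's *intermediate* node is the next FFL's input
  node; e.g. L=2 gives FFLs (1,2,3) and (2,4,5).

Both templates have 2L+1 nodes and 3L edges.

Matching is subgraph *monomorphism*: an injective template-node ->
neuron mapping preserving every template edge, with extra connectome edges
among the mapped neurons permitted.  (Induced matching of a 7-node,
exactly-9-edge subgraph would be vanishingly rare in a dense connectome.)
Chain templates carry no nontrivial automorphism — every node is
distinguishable by its degree signature — so injective mappings coincide
with motif instances.  The matcher enumerates FFLs once, indexes them by
input node, and depth-first composes chains under global node
distinctness; this is verified against brute-force monomorphism search in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .core import ConnectionKey, NervousSystem

#: The 13 weakly connected triad classes in the standard MAN
#: (mutual/asymmetric/null dyad census) nomenclature; '030T' is the FFL,
#: '030C' the 3-cycle, '021D' the out-star.
CONNECTED_TRIAD_CLASSES = (
    "021D",
    "021U",
    "021C",
    "111D",
    "111U",
    "030T",
    "030C",
    "201",
    "120D",
    "120U",
    "120C",
    "210",
    "300",
)

FFL_CLASS = "030T"

CHAIN_MODES = ("sequential", "intermediate")


@dataclass(frozen=True)
class MotifTemplate:
    """A small labelled directed graph with role-labelled nodes."""

    node_ids: tuple[int, ...]
    edges: frozenset[tuple[int, int]]
    roles: Mapping[int, str] = field(default_factory=dict)
    chain_length: int | None = None
    chain_mode: str | None = None

    def __post_init__(self) -> None:
        nodes = set(self.node_ids)
        for u, v in self.edges:
            if u == v:
                raise ValueError("template self-loop")
            if u not in nodes or v not in nodes:
                raise ValueError(f"template edge ({u},{v}) uses unknown node")
        g = nx.DiGraph(self.edges)
        g.add_nodes_from(self.node_ids)
        if len(self.node_ids) > 1 and not nx.is_weakly_connected(g):
            raise ValueError("template must be weakly connected")

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(self.edges)
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class MotifMatch:
    """An injective embedding of a template into the network."""

    template: MotifTemplate
    mapping: Mapping[int, str]

    def neurons(self) -> set[str]:
        return set(self.mapping.values())

    def edge_keys(self, kind: str = "chemical") -> set[ConnectionKey]:
        return {
            (self.mapping[u], self.mapping[v], kind) for u, v in self.template.edges
        }


@dataclass
class AlignmentCounts:
    """Forward/backward/lateral tallies and the alignment score H.

    H = (c_forward - c_backward) / (c_forward + c_lateral + c_backward),
    in [-1, 1]; ``h`` is None (``defined`` False) when no edge was tallied.
    """

    c_forward: int
    c_backward: int
    c_lateral: int
    n_excluded: int = 0

    @property
    def defined(self) -> bool:
        return (self.c_forward + self.c_lateral + self.c_backward) > 0

    @property
    def h(self) -> float | None:
        denom = self.c_forward + self.c_lateral + self.c_backward
        if denom == 0:
            return None
        return (self.c_forward - self.c_backward) / denom


# ---------------------------------------------------------------------------
# triad census
# ---------------------------------------------------------------------------


def triad_census(net: NervousSystem, min_weight: float | None = None) -> dict[str, int]:
    """Counts of the 13 connected triad classes on the chemical digraph.

    Every unordered neuron triple whose induced subgraph is weakly connected
    falls in exactly one class; counting is per node-set.
    """
    if len(net.neurons) < 3:
        raise ValueError("triad census needs at least 3 neurons")
    g = net.to_digraph("chemical", min_weight=min_weight)
    census = nx.triadic_census(g)
    return {cls: census[cls] for cls in CONNECTED_TRIAD_CLASSES}


# ---------------------------------------------------------------------------
# chain templates
# ---------------------------------------------------------------------------


def ffl_template() -> MotifTemplate:
    """The plain feed-forward loop with input/intermediate/output roles."""
    return build_chain_template(1, "sequential")


def chain_ffls(chain_length: int, mode: str) -> list[tuple[int, int, int]]:
    """The (input, intermediate, output) label triples of each FFL unit."""
    if chain_length < 1:
        raise ValueError("chain length must be >= 1")
    if mode not in CHAIN_MODES:
        raise ValueError(f"unknown chain mode {mode!r}")
    ffls = [(1, 2, 3)]
    for k in range(2, chain_length + 1):
        prev_in, prev_mid, prev_out = ffls[-1]
        join = prev_out if mode == "sequential" else prev_mid
        ffls.append((join, 2 * k, 2 * k + 1))
    return ffls


def build_chain_template(chain_length: int, mode: str = "sequential") -> MotifTemplate:
    """Template for a simple hierarchical chain of ``chain_length`` FFLs.

    2L+1 nodes and 3L edges for either mode.  Node roles record depth and
    FFL role; for L=1 the roles are input/intermediate/output.
    """
    ffls = chain_ffls(chain_length, mode)
    edges: set[tuple[int, int]] = set()
    roles: dict[int, str] = {}
    for k, (i, m, o) in enumerate(ffls, start=1):
        edges |= {(i, m), (m, o), (i, o)}
        roles.setdefault(i, f"input_{k}")
        roles[m] = f"intermediate_{k}"
        roles[o] = f"output_{k}"
    if chain_length == 1:
        roles = {1: "input", 2: "intermediate", 3: "output"}
    node_ids = tuple(range(1, 2 * chain_length + 2))
    return MotifTemplate(
        node_ids=node_ids,
        edges=frozenset(edges),
        roles=roles,
        chain_length=chain_length,
        chain_mode=mode,
    )


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------


def enumerate_ffls(g: nx.DiGraph) -> list[tuple[str, str, str]]:
    """All (input, intermediate, output) FFL instances of a simple digraph."""
    out = []
    for i in sorted(g.nodes):
        succ_i = set(g.successors(i))
        for m in sorted(succ_i):
            if m == i:
                continue
            for o in sorted(succ_i & set(g.successors(m))):
                if o not in (i, m):
                    out.append((i, m, o))
    return out


def _compose_chains(
    g: nx.DiGraph, chain_length: int, mode: str
) -> list[tuple[tuple[str, str, str], ...]]:
    """Depth-first composition of FFL instances into chains.

    Successive FFLs share exactly the chaining node (output or intermediate
    of the previous unit); all 2L+1 mapped nodes are globally distinct.
    """
    ffls = enumerate_ffls(g)
    if chain_length == 1:
        return [(f,) for f in ffls]
    by_input: dict[str, list[tuple[str, str, str]]] = {}
    for f in ffls:
        by_input.setdefault(f[0], []).append(f)

    chains: list[tuple[tuple[str, str, str], ...]] = []

    def extend(chain: list[tuple[str, str, str]], used: set[str]) -> None:
        if len(chain) == chain_length:
            chains.append(tuple(chain))
            return
        i, m, o = chain[-1]
        join = o if mode == "sequential" else m
        for nxt in by_input.get(join, ()):
            _, m2, o2 = nxt
            if m2 in used or o2 in used or m2 == o2:
                continue
            chain.append(nxt)
            used.update((m2, o2))
            extend(chain, used)
            chain.pop()
            used.difference_update((m2, o2))

    for f in ffls:
        extend([f], set(f))
    return chains


def match_template(
    net: NervousSystem,
    template: MotifTemplate,
    min_weight: float | None = None,
) -> list[MotifMatch]:
    """All injective monomorphic embeddings of ``template`` into the
    chemical digraph, in deterministic (lexicographic) order.

    Chain templates are matched by FFL composition; arbitrary templates
    fall back to VF2 subgraph monomorphism.
    """
    g = net.to_digraph("chemical", min_weight=min_weight)
    if template.n_nodes > g.number_of_nodes():
        return []  # a template larger than the network trivially has no match
    if template.chain_length is not None and template.chain_mode is not None:
        label_ffls = chain_ffls(template.chain_length, template.chain_mode)
        matches = []
        for chain in _compose_chains(g, template.chain_length, template.chain_mode):
            mapping: dict[int, str] = {}
            for (li, lm, lo), (ni, nm, no) in zip(label_ffls, chain):
                mapping[li] = ni
                mapping[lm] = nm
                mapping[lo] = no
            matches.append(MotifMatch(template=template, mapping=mapping))
    else:
        gm = nx.isomorphism.DiGraphMatcher(g, template.to_digraph())
        matches = []
        for host_to_label in gm.subgraph_monomorphisms_iter():
            mapping = {label: host for host, label in host_to_label.items()}
            matches.append(MotifMatch(template=template, mapping=mapping))
    matches.sort(key=lambda m: tuple(m.mapping[n] for n in template.node_ids))
    return matches


def count_chains(
    net: NervousSystem,
    chain_length: int,
    mode: str = "sequential",
    min_weight: float | None = None,
) -> int:
    """Number of chain-motif instances (injective embeddings)."""
    g = net.to_digraph("chemical", min_weight=min_weight)
    return len(_compose_chains(g, chain_length, mode))


# ---------------------------------------------------------------------------
# alignment, roles, coverage
# ---------------------------------------------------------------------------

_SIM_TYPES = ("sensory", "interneuron", "motorneuron")
_FORWARD = {
    ("sensory", "interneuron"),
    ("sensory", "motorneuron"),
    ("interneuron", "motorneuron"),
}
_BACKWARD = {
    ("motorneuron", "interneuron"),
    ("motorneuron", "sensory"),
    ("interneuron", "sensory"),
}


def hierarchical_alignment(
    typed_edges: Iterable[tuple[str, str]],
) -> AlignmentCounts:
    """Tally (pre_type, post_type) edges as forward / backward / lateral.

    Forward: sensory->interneuron, sensory->motorneuron,
    interneuron->motorneuron; backward the reverses; lateral same-type.
    Edges touching types outside {sensory, interneuron, motorneuron} are
    excluded and counted in ``n_excluded``.  Each direction of a
    bidirectional connection contributes its own tally.
    """
    fwd = bwd = lat = excl = 0
    for pre_t, post_t in typed_edges:
        if pre_t not in _SIM_TYPES or post_t not in _SIM_TYPES:
            excl += 1
        elif pre_t == post_t:
            lat += 1
        elif (pre_t, post_t) in _FORWARD:
            fwd += 1
        else:
            assert (pre_t, post_t) in _BACKWARD
            bwd += 1
    return AlignmentCounts(c_forward=fwd, c_backward=bwd, c_lateral=lat, n_excluded=excl)


def alignment_of_matches(
    matches: Sequence[MotifMatch], net: NervousSystem
) -> AlignmentCounts:
    """Hierarchical alignment of all network edges covered by the matches."""
    typed = []
    for key in coverage(matches, net)[1]:
        pre, post, _ = key
        typed.append(
            (net.neurons[pre].neuron_type, net.neurons[post].neuron_type)
        )
    return hierarchical_alignment(typed)


def role_composition(
    matches: Sequence[MotifMatch], net: NervousSystem
) -> dict[int, dict[str, float]]:
    """Per-template-node neuron-type fractions across the matches."""
    if not matches:
        raise ValueError("empty match list")
    out: dict[int, dict[str, float]] = {}
    n = len(matches)
    for node in matches[0].template.node_ids:
        counts: dict[str, int] = {}
        for m in matches:
            t = net.neurons[m.mapping[node]].neuron_type
            counts[t] = counts.get(t, 0) + 1
        out[node] = {t: c / n for t, c in sorted(counts.items())}
    return out


def coverage(
    matches: Sequence[MotifMatch], net: NervousSystem, kind: str = "chemical"
) -> tuple[set[str], set[ConnectionKey]]:
    """(neurons, connections) of the network touched by any match."""
    neurons: set[str] = set()
    edges: set[ConnectionKey] = set()
    for m in matches:
        neurons |= m.neurons()
        edges |= m.edge_keys(kind)
    return neurons, edges & set(net.connections)
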