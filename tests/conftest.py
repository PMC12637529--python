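"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own algorithms: motif
counts are recomputed by backtracking over injective label->node
assignments, and triads are classified by explicit isomorphism checks
against reference graphs.
"""

from __future__ import annotations

import itertools

import networkx as nx
import pytest

from nemagraph.core import NervousSystem, build_network


# ---------------------------------------------------------------------------
# oracle: subgraph monomorphism by injective-assignment backtracking
# ---------------------------------------------------------------------------


def brute_force_monomorphisms(
    host: nx.DiGraph, template_edges: list[tuple], template_nodes: list
) -> list[dict]:
    """All injective template-node -> host-node maps preserving every
    template edge (extra host edges permitted).  Pure depth-first search
    over partial assignments; independent of the package's matcher."""
    template_nodes = list(template_nodes)
    host_nodes = sorted(host.nodes)
    results: list[dict] = []

    def extend(assignment: dict) -> None:
        if len(assignment) == len(template_nodes):
            results.append(dict(assignment))
            return
        label = template_nodes[len(assignment)]
        for cand in host_nodes:
            if cand in assignment.values():
                continue
            ok = True
            for u, v in template_edges:
                if u == label and v in assignment and not host.has_edge(cand, assignment[v]):
                    ok = False
                    break
                if v == label and u in assignment and not host.has_edge(assignment[u], cand):
                    ok = False
                    break
            if ok:
                assignment[label] = cand
                extend(assignment)
                del assignment[label]

    extend({})
    return results


# ---------------------------------------------------------------------------
# oracle: triad classification by isomorphism against reference graphs
# ---------------------------------------------------------------------------

_TRIAD_REFERENCES = {
    "021D": [(0, 1), (0, 2)],
    "021U": [(1, 0), (2, 0)],
    "021C": [(0, 1), (1, 2)],
    "111D": [(0, 1), (1, 0), (2, 1)],
    "111U": [(0, 1), (1, 0), (1, 2)],
    "030T": [(0, 1), (1, 2), (0, 2)],
    "030C": [(0, 1), (1, 2), (2, 0)],
    "201": [(0, 1), (1, 0), (0, 2), (2, 0)],
    "120D": [(0, 1), (1, 0), (2, 0), (2, 1)],
    "120U": [(0, 1), (1, 0), (0, 2), (1, 2)],
    "120C": [(0, 1), (1, 0), (2, 0), (1, 2)],
    "210": [(0, 1), (1, 0), (1, 2), (2, 1), (0, 2)],
    "300": [(0, 1), (1, 0), (1, 2), (2, 1), (0, 2), (2, 0)],
}


def classify_triad(g: nx.DiGraph, triple) -> str | None:
    """MAN class of the induced subgraph on a node triple, or None when
    the triple is not weakly connected."""
    sub = g.subgraph(triple)
    if not nx.is_weakly_connected(sub):
        return None
    for name, edges in _TRIAD_REFERENCES.items():
        ref = nx.DiGraph(edges)
        ref.add_nodes_from(range(3))
        if nx.is_isomorphic(sub, ref):
            return name
    raise AssertionError(f"unclassifiable triad on {triple}")


def brute_force_triad_census(g: nx.DiGraph) -> dict[str, int]:
    census = {name: 0 for name in _TRIAD_REFERENCES}
    for triple in itertools.combinations(sorted(g.nodes), 3):
        cls = classify_triad(g, triple)
        if cls is not None:
            census[cls] += 1
    return census


# ---------------------------------------------------------------------------
# shared toy networks
# ---------------------------------------------------------------------------


def net_from_edges(edges, types=None, kind="chemical") -> NervousSystem:
    """Small network from (pre, post[, weight]) tuples; default type other."""
    names = sorted({e[0] for e in edges} | {e[1] for e in edges})
    neuron_rows = [
        {"name": n, "neuron_type": (types or {}).get(n, "other")} for n in names
    ]
    edge_rows = [
        {"pre": e[0], "post": e[1], "kind": kind,
         "weight": e[2] if len(e) > 2 else 1}
        for e in edges
    ]
    return build_network(neuron_rows, edge_rows)


@pytest.fixture
def ffl_net() -> NervousSystem:
    return net_from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def triangle_cycle_net() -> NervousSystem:
    return net_from_edges([("A", "B"), ("B", "C"), ("C", "A")])
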