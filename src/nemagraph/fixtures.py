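"""Deterministic synthetic connectome and expression generators.

These emulate the shape of a small nervous system — a few hundred typed
neurons, a few thousand directed chemical connections — while planting
known ground truth (FFL chains, per-edge ligand/receptor assignments) so
that every downstream analysis can be checked exactly.

Defaults mirror the study system: 300 neurons split roughly 30 % sensory,
27 % interneuron, 43 % motorneuron, with a background edge probability of
0.0413 giving about 3,700 expected directed chemical connections.
Background edges are drawn independently per ordered pair (an
Erdos-Renyi digraph) for analyzable null behaviour; planted chains are
oriented sensory -> interneuron -> motorneuron whenever the type budget
permits.  The same seed always yields the identical network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Connection, NervousSystem, Neuron, build_network
from .io import PairMap
from .motifs import build_chain_template


@dataclass
class FixtureSpec:
    """Recipe for a synthetic connectome with planted ground truth."""

    n_neurons: int = 300
    type_fractions: tuple[float, float, float] = (0.30, 0.27, 0.43)
    background_edge_prob: float = 0.0413
    planted_chains: Sequence[tuple[int, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.type_fractions) - 1.0) > 1e-9:
            raise ValueError("type fractions must sum to 1")
        if not 0.0 <= self.background_edge_prob <= 1.0:
            raise ValueError("background_edge_prob must lie in [0, 1]")


def make_random_connectome(
    spec: FixtureSpec,
) -> tuple[NervousSystem, dict]:
    """Synthetic typed connectome with planted FFL chains.

    Returns the network and a ground-truth record with, per planted chain,
    the template-label -> neuron mapping and the planted edge list.
    Planted chain edges always carry weight >= 1 and are a subset of the
    network's chemical edges.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_neurons
    n_sens = int(round(spec.type_fractions[0] * n))
    n_inter = int(round(spec.type_fractions[1] * n))
    n_motor = n - n_sens - n_inter
    names = (
        [f"S{i:03d}" for i in range(n_sens)]
        + [f"I{i:03d}" for i in range(n_inter)]
        + [f"M{i:03d}" for i in range(n_motor)]
    )
    types = (
        ["sensory"] * n_sens + ["interneuron"] * n_inter + ["motorneuron"] * n_motor
    )
    positions = rng.uniform(0.0, 1.0, size=(n, 3))

    # plant chains on disjoint neuron sets, typed sensory -> inter -> motor
    by_type = {
        "sensory": [nm for nm, t in zip(names, types) if t == "sensory"],
        "interneuron": [nm for nm, t in zip(names, types) if t == "interneuron"],
        "motorneuron": [nm for nm, t in zip(names, types) if t == "motorneuron"],
    }
    used: set[str] = set()

    def take(preferred: str) -> str:
        for t in (preferred, "interneuron", "sensory", "motorneuron"):
            for nm in by_type[t]:
                if nm not in used:
                    used.add(nm)
                    return nm
        raise ValueError("planted chains need more neurons than available")

    truth_chains = []
    planted_edges: set[tuple[str, str]] = set()
    for length, mode in spec.planted_chains:
        template = build_chain_template(length, mode)
        if template.n_nodes > n:
            raise ValueError(
                f"planted chain needs {template.n_nodes} neurons, have {n}"
            )
        mapping: dict[int, str] = {}
        last = template.node_ids[-1]
        for label in template.node_ids:
            if label == 1:
                mapping[label] = take("sensory")
            elif label == last:
                mapping[label] = take("motorneuron")
            else:
                mapping[label] = take("interneuron")
        edges = [(mapping[u], mapping[v]) for u, v in sorted(template.edges)]
        planted_edges.update(edges)
        truth_chains.append(
            {"length": length, "mode": mode, "mapping": mapping, "edges": edges}
        )

    # background Erdos-Renyi digraph, weights emulating synapse counts
    adj = rng.random((n, n)) < spec.background_edge_prob
    np.fill_diagonal(adj, False)
    weights = rng.integers(1, 10, size=(n, n))
    edge_rows = []
    for i, j in zip(*np.nonzero(adj)):
        edge_rows.append(
            {"pre": names[i], "post": names[j], "kind": "chemical",
             "weight": int(weights[i, j])}
        )
    background = {(r["pre"], r["post"]) for r in edge_rows}
    for pre, post in sorted(planted_edges - background):
        edge_rows.append({"pre": pre, "post": post, "kind": "chemical", "weight": 1})

    neuron_rows = [
        {"name": nm, "neuron_type": t,
         "x": positions[i, 0], "y": positions[i, 1], "z": positions[i, 2]}
        for i, (nm, t) in enumerate(zip(names, types))
    ]
    net = build_network(neuron_rows, edge_rows, metadata={"fixture_seed": spec.seed})
    truth = {"chains": truth_chains, "spec": spec}
    return net, truth


def make_expression_fixture(
    net: NervousSystem,
    pair_map_size: int | None = None,
    noise_prob: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, set[str]], dict[str, set[str]], PairMap, dict]:
    """Ligand/receptor expression with known per-edge ground truth.

    Each chemical edge k is assigned the synthetic cognate pair
    (Lk, Rk): the presynaptic neuron expresses the ligand and the
    postsynaptic neuron the receptor.  With ``pair_map_size`` >= the edge
    count (the default: one distinct pair per edge) the true annotation of
    every edge is exactly its planted pair; smaller maps reuse pairs
    cyclically and the planted pair remains a subset of the true
    annotation.  Noise adds, per neuron with probability ``noise_prob``,
    decoy ligands/receptors absent from the pair map, so they can never
    produce an annotation.  Returns (ligands per neuron, receptors per
    neuron, pair map, per-edge truth).
    """
    rng = np.random.default_rng(seed)
    edges = sorted(c.key for c in net.connections_of_kind("chemical"))
    if pair_map_size is None:
        pair_map_size = max(len(edges), 1)
    pairs = [(f"L{k:04d}", f"R{k:04d}") for k in range(pair_map_size)]
    nt_expr: dict[str, set[str]] = {}
    rec_expr: dict[str, set[str]] = {}
    truth: dict[tuple[str, str, str], set[tuple[str, str]]] = {}
    for k, key in enumerate(edges):
        pre, post, _ = key
        ligand, receptor = pairs[k % pair_map_size]
        nt_expr.setdefault(pre, set()).add(ligand)
        rec_expr.setdefault(post, set()).add(receptor)
        truth[key] = {(ligand, receptor)}
    for i, name in enumerate(sorted(net.neurons)):
        if noise_prob > 0 and rng.random() < noise_prob:
            nt_expr.setdefault(name, set()).add(f"XL{i:04d}")
        if noise_prob > 0 and rng.random() < noise_prob:
            rec_expr.setdefault(name, set()).add(f"XR{i:04d}")
    pair_map = PairMap(pairs=set(pairs), kind="neurotransmitter")
    return nt_expr, rec_expr, pair_map, truth
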