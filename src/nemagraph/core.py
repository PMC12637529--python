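"""Multi-relational nervous-system graph.

The central container is :class:`NervousSystem`: a directed graph whose nodes
are :class:`Neuron` objects (typed sensory / interneuron / motorneuron /
other, optionally carrying a 3-D anatomical position, expressed genes and
neurotransmitters) and whose edges are :class:`Connection` objects keyed by
``(pre, post, kind)`` with ``kind`` one of chemical, gap, peptidergic or
functional.  One aggregated connection is kept per (pre, post, kind); weights
of duplicate input rows are summed.  Gap junctions are stored as mirrored
directed pairs with equal weight so that a single directed-traversal
machinery serves every connection kind.

Self-loops on the chemical and gap graphs are dropped at build time (the
motif and null-model machinery assumes a simple digraph); peptidergic
self-edges (autocrine signalling) are allowed.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

NEURON_TYPES = ("sensory", "interneuron", "motorneuron", "other")
CONNECTION_KINDS = ("chemical", "gap", "peptidergic", "functional")

#: Connection kinds for which self-loops are disallowed and silently dropped.
_SIMPLE_KINDS = frozenset({"chemical", "gap"})

ConnectionKey = tuple[str, str, str]


@dataclass
class Neuron:
    """A single neuron: identity, type, anatomy and molecular annotations.

    ``position`` is an (anterior-posterior, dorso-ventral, left-right)
    triple in arbitrary but network-consistent length units, or ``None``.
    """

    name: str
    neuron_type: str = "other"
    subtype: str = ""
    position: tuple[float, float, float] | None = None
    expressed_genes: set[str] = field(default_factory=set)
    neurotransmitters: set[str] = field(default_factory=set)
    properties: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.neuron_type not in NEURON_TYPES:
            raise ValueError(
                f"unknown neuron type {self.neuron_type!r} for {self.name!r}; "
                f"expected one of {NEURON_TYPES}"
            )
        if self.position is not None:
            self.position = tuple(float(x) for x in self.position)  # type: ignore[assignment]
            if len(self.position) != 3:
                raise ValueError(f"position of {self.name!r} must be a 3-vector")


@dataclass
class Connection:
    """A directed connection between two neurons of a given kind.

    ``weight`` is a non-negative strength (synapse count for chemical
    connections); ``nt_pairs`` holds putative (ligand, receptor) annotations.
    """

    pre: str
    post: str
    kind: str = "chemical"
    weight: float = 1.0
    nt_pairs: set[tuple[str, str]] = field(default_factory=set)
    properties: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CONNECTION_KINDS:
            raise ValueError(f"unknown connection kind {self.kind!r}")
        self.weight = float(self.weight)
        if self.weight < 0:
            raise ValueError(
                f"negative weight {self.weight} on {self.pre}->{self.post} ({self.kind})"
            )

    @property
    def key(self) -> ConnectionKey:
        return (self.pre, self.post, self.kind)


@dataclass
class Path:
    """A simple directed path: an ordered sequence of connection keys."""

    edge_sequence: list[ConnectionKey]

    @property
    def source(self) -> str:
        return self.edge_sequence[0][0]

    @property
    def target(self) -> str:
        return self.edge_sequence[-1][1]

    @property
    def nodes(self) -> list[str]:
        return [self.edge_sequence[0][0]] + [e[1] for e in self.edge_sequence]

    def __len__(self) -> int:
        return len(self.edge_sequence)


class NervousSystem:
    """Directed multi-relational graph of neurons and connections.

    Named neuron groups and connection groups (sets of names / keys) can be
    registered on the network; arbitrary metadata lives in ``metadata``.
    """

    def __init__(self, metadata: dict | None = None) -> None:
        self.neurons: dict[str, Neuron] = {}
        self.connections: dict[ConnectionKey, Connection] = {}
        self.neuron_groups: dict[str, set[str]] = {}
        self.connection_groups: dict[str, set[ConnectionKey]] = {}
        self.metadata: dict = dict(metadata or {})

    # -- construction -------------------------------------------------

    def add_neuron(self, neuron: Neuron, overwrite: bool = False) -> Neuron:
        if neuron.name in self.neurons and not overwrite:
            raise ValueError(f"neuron {neuron.name!r} already exists")
        self.neurons[neuron.name] = neuron
        return neuron

    def add_connection(
        self,
        conn: Connection,
        on_duplicate: str = "error",
        allow_self_loop: bool = False,
    ) -> Connection | None:
        """Insert a connection; ``on_duplicate`` is 'error' or 'sum'.

        Self-loops on chemical/gap graphs are dropped (with a warning)
        unless ``allow_self_loop`` (used for folded group self-edges).
        """
        for end in (conn.pre, conn.post):
            if end not in self.neurons:
                raise KeyError(f"connection endpoint {end!r} not in network")
        if conn.pre == conn.post and conn.kind in _SIMPLE_KINDS and not allow_self_loop:
            logger.warning("dropping %s self-loop on %r", conn.kind, conn.pre)
            return None
        existing = self.connections.get(conn.key)
        if existing is not None:
            if on_duplicate == "sum":
                existing.weight += conn.weight
                existing.nt_pairs |= conn.nt_pairs
                existing.properties.update(conn.properties)
                return existing
            raise ValueError(f"duplicate connection {conn.key}")
        self.connections[conn.key] = conn
        return conn

    # -- accessors -----------------------------------------------------

    def connections_of_kind(self, kind: str) -> list[Connection]:
        return [c for c in self.connections.values() if c.kind == kind]

    def to_digraph(self, kind: str = "chemical", min_weight: float | None = None) -> nx.DiGraph:
        """Simple directed graph of one connection kind (weights as 'weight')."""
        g = nx.DiGraph()
        g.add_nodes_from(self.neurons)
        for c in self.connections_of_kind(kind):
            if min_weight is not None and c.weight < min_weight:
                continue
            if c.pre != c.post:
                g.add_edge(c.pre, c.post, weight=c.weight)
        return g

    def copy(self) -> "NervousSystem":
        return copy.deepcopy(self)

    def __len__(self) -> int:
        return len(self.neurons)

    def __contains__(self, name: str) -> bool:
        return name in self.neurons

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<NervousSystem: {len(self.neurons)} neurons, "
            f"{len(self.connections)} connections>"
        )

    # -- groups --------------------------------------------------------

    def register_neuron_group(
        self, name: str, members: Iterable[str], overwrite: bool = False
    ) -> set[str]:
        members = set(members)
        unknown = members - set(self.neurons)
        if unknown:
            raise KeyError(f"unknown neurons in group {name!r}: {sorted(unknown)}")
        if name in self.neuron_groups and not overwrite:
            raise ValueError(f"neuron group {name!r} already exists")
        self.neuron_groups[name] = members
        return members

    def register_connection_group(
        self, name: str, members: Iterable[ConnectionKey], overwrite: bool = False
    ) -> set[ConnectionKey]:
        members = {tuple(m) for m in members}
        unknown = members - set(self.connections)
        if unknown:
            raise KeyError(f"unknown connections in group {name!r}: {sorted(unknown)}")
        if name in self.connection_groups and not overwrite:
            raise ValueError(f"connection group {name!r} already exists")
        self.connection_groups[name] = members  # type: ignore[assignment]
        return members  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# construction from tabular records
# ---------------------------------------------------------------------------


def build_network(
    neuron_table: Iterable[Mapping] | None,
    edge_table: Iterable[Mapping],
    strict: bool = True,
    metadata: dict | None = None,
) -> NervousSystem:
    """Assemble a :class:`NervousSystem` from neuron and connection records.

    ``neuron_table`` rows need a ``name`` and may carry ``neuron_type``,
    ``subtype``, ``position`` (or ``x``/``y``/``z`` columns), and
    ``neurotransmitters``.  ``edge_table`` rows need ``pre`` and ``post``;
    ``kind`` defaults to chemical and ``weight`` to 1.  Duplicate
    (pre, post, kind) rows are weight-summed; chemical/gap self-loops are
    dropped with a warning.  With ``strict=False``, edge endpoints missing
    from the neuron table are auto-created as type ``other`` stubs.
    """
    net = NervousSystem(metadata=metadata)
    for row in neuron_table or ():
        row = dict(row)
        position = row.get("position")
        if position is None and all(k in row and row[k] is not None for k in ("x", "y", "z")):
            position = (row["x"], row["y"], row["z"])
        nts = row.get("neurotransmitters") or set()
        if isinstance(nts, str):
            nts = {s.strip() for s in nts.split(";") if s.strip()}
        genes = row.get("expressed_genes") or set()
        if isinstance(genes, str):
            genes = {s.strip() for s in genes.split(";") if s.strip()}
        net.add_neuron(
            Neuron(
                name=str(row["name"]).strip(),
                neuron_type=str(row.get("neuron_type") or "other").strip(),
                subtype=str(row.get("subtype") or "").strip(),
                position=position,
                expressed_genes=set(genes),
                neurotransmitters=set(nts),
            )
        )

    gap_rows: list[tuple[str, str, float]] = []
    for row in edge_table:
        row = dict(row)
        pre = str(row["pre"]).strip()
        post = str(row["post"]).strip()
        kind = str(row.get("kind") or "chemical").strip()
        if kind not in CONNECTION_KINDS:
            raise ValueError(f"unknown connection kind {kind!r} on {pre}->{post}")
        weight = row.get("weight")
        weight = 1.0 if weight is None or weight == "" else float(weight)
        for end in (pre, post):
            if end not in net.neurons:
                if strict:
                    raise KeyError(f"edge endpoint {end!r} missing from neuron table")
                net.add_neuron(Neuron(name=end, neuron_type="other"))
        if kind == "gap":
            if pre == post:
                logger.warning("dropping gap self-loop on %r", pre)
                continue
            gap_rows.append((pre, post, weight))
            continue
        net.add_connection(
            Connection(pre=pre, post=post, kind=kind, weight=weight),
            on_duplicate="sum",
        )

    # gap junctions: aggregate per unordered pair, then mirror
    gap_weight: dict[tuple[str, str], float] = {}
    for pre, post, w in gap_rows:
        pair = (pre, post) if pre <= post else (post, pre)
        gap_weight[pair] = gap_weight.get(pair, 0.0) + w
    for (a, b), w in gap_weight.items():
        net.add_connection(Connection(pre=a, post=b, kind="gap", weight=w))
        net.add_connection(Connection(pre=b, post=a, kind="gap", weight=w))
    return net


# ---------------------------------------------------------------------------
# subnetworks, folding, paths, selection
# ---------------------------------------------------------------------------


def subnetwork(
    net: NervousSystem,
    nodes: Iterable[str] | None = None,
    edges: Iterable[ConnectionKey] | None = None,
) -> NervousSystem:
    """Independent sub-network by node induction or explicit edge list.

    Node mode returns the induced graph on ``nodes`` (all connections with
    both endpoints inside); edge mode returns exactly the listed connections
    plus their endpoint neurons.  All attribute data is deep-copied, so
    mutating the result never alters the source.
    """
    if (nodes is None) == (edges is None):
        raise ValueError("provide exactly one of nodes= or edges=")
    sub = NervousSystem(metadata=copy.deepcopy(net.metadata))
    if nodes is not None:
        nodes = set(nodes)
        unknown = nodes - set(net.neurons)
        if unknown:
            raise KeyError(f"unknown neurons: {sorted(unknown)}")
        keep_edges = [k for k in net.connections if k[0] in nodes and k[1] in nodes]
        keep_nodes = nodes
    else:
        keep_edges = [tuple(e) for e in edges]  # type: ignore[union-attr]
        unknown_e = set(keep_edges) - set(net.connections)
        if unknown_e:
            raise KeyError(f"unknown connections: {sorted(unknown_e)}")
        keep_nodes = {k[0] for k in keep_edges} | {k[1] for k in keep_edges}
    for name in keep_nodes:
        sub.add_neuron(copy.deepcopy(net.neurons[name]))
    for key in keep_edges:
        sub.connections[key] = copy.deepcopy(net.connections[key])
    return sub


def fold_network(net: NervousSystem, mapping: Mapping[str, str]) -> NervousSystem:
    """Merge neurons into group nodes; aggregate member connections.

    Neurons absent from ``mapping`` map to themselves.  Folded edge weight
    is the sum of member edge weights; nt_pairs are unioned; scalar edge
    properties are collected into lists.  Within-group edges become retained
    group self-loops.  Each group node stores its member names under
    ``properties['members']``.
    """
    if mapping is not None and len(mapping) == 0:
        raise ValueError("empty folding mapping")
    full = {name: mapping.get(name, name) for name in net.neurons}
    members_of: dict[str, list[str]] = {}
    for name, label in full.items():
        members_of.setdefault(label, []).append(name)

    folded = NervousSystem(metadata=copy.deepcopy(net.metadata))
    for label, members in sorted(members_of.items()):
        types = {net.neurons[m].neuron_type for m in members}
        ntype = types.pop() if len(types) == 1 else "other"
        positions = [net.neurons[m].position for m in members]
        position = None
        if all(p is not None for p in positions):
            position = tuple(
                sum(p[i] for p in positions) / len(positions) for i in range(3)  # type: ignore[index]
            )
        folded.add_neuron(
            Neuron(
                name=label,
                neuron_type=ntype,
                position=position,
                expressed_genes=set().union(
                    *(net.neurons[m].expressed_genes for m in members)
                ),
                neurotransmitters=set().union(
                    *(net.neurons[m].neurotransmitters for m in members)
                ),
                properties={"members": sorted(members)},
            )
        )

    for key in sorted(net.connections):
        conn = net.connections[key]
        g1, g2 = full[conn.pre], full[conn.post]
        fkey = (g1, g2, conn.kind)
        target = folded.connections.get(fkey)
        if target is None:
            target = Connection(pre=g1, post=g2, kind=conn.kind, weight=0.0)
            folded.connections[fkey] = target
        target.weight += conn.weight
        target.nt_pairs |= conn.nt_pairs
        for k, v in conn.properties.items():
            target.properties.setdefault(k, []).append(v)
    return folded


def enumerate_paths(
    net: NervousSystem,
    source: str,
    target: str,
    max_len: int,
    kind: str = "chemical",
) -> list[Path]:
    """All simple directed paths of length 1..max_len on one connection kind.

    Paths repeat neither edges nor nodes and are returned in lexicographic
    order of their node sequences.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    for n in (source, target):
        if n not in net.neurons:
            raise KeyError(f"unknown neuron {n!r}")
    if source == target:
        raise ValueError("source and target must differ")
    g = net.to_digraph(kind)
    node_paths = sorted(nx.all_simple_paths(g, source, target, cutoff=max_len))
    return [
        Path(edge_sequence=[(p[i], p[i + 1], kind) for i in range(len(p) - 1)])
        for p in node_paths
    ]


def select_neurons(
    net: NervousSystem,
    predicate: Callable[[Neuron], bool],
    name: str,
    overwrite: bool = False,
) -> set[str]:
    """Register (and return) the group of neurons satisfying ``predicate``."""
    members = {n for n, neuron in net.neurons.items() if predicate(neuron)}
    return net.register_neuron_group(name, members, overwrite=overwrite)


def select_connections(
    net: NervousSystem,
    predicate: Callable[[Connection], bool],
    name: str,
    overwrite: bool = False,
) -> set[ConnectionKey]:
    """Register (and return) the group of connections satisfying ``predicate``."""
    members = {k for k, c in net.connections.items() if predicate(c)}
    return net.register_connection_group(name, members, overwrite=overwrite)
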