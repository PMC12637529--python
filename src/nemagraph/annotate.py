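"""Expression-based annotation of connections.

A chemical connection a->b receives a putative (ligand, receptor) pair
(L, R) when (1) the anatomical connection exists, (2) the presynaptic
neuron a expresses the neurotransmitter ligand L, and (3) the postsynaptic
neuron b expresses a cognate receptor R, with (L, R) listed in the
ligand-receptor map.  A connection is *unique* when all its pairs share a
single ligand (several receptor subtypes for one transmitter still count
as unique), *multiple* when two or more distinct ligands qualify, and
*unannotated* when no pair qualifies.

The same sender-ligand / receiver-receptor logic, applied without any
anatomical or spatial constraint, yields the long-range neuropeptide
connectome: a directed peptidergic edge for every expressing sender and
receiver, autocrine self-edges included and flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from statsmodels.stats.proportion import proportions_ztest

from .core import Connection, NervousSystem, Neuron, subnetwork
from .io import PairMap
from .motifs import MotifMatch
from .nullmodels import StatsConfig, by_adjust

logger = logging.getLogger(__name__)


@dataclass
class AnnotationSummary:
    """Network-level annotation class counts.

    ``n_unannotated + n_unique_nt + n_multi_nt == n_edges`` and the
    pairs-per-edge histogram sums to ``n_edges``.
    """

    n_edges: int
    n_unannotated: int
    n_unique_nt: int
    n_multi_nt: int
    pair_count_histogram: dict[int, int] = field(default_factory=dict)

    def fraction(self, which: str) -> float:
        n = {
            "unannotated": self.n_unannotated,
            "unique": self.n_unique_nt,
            "multiple": self.n_multi_nt,
        }[which]
        return n / self.n_edges if self.n_edges else 0.0


def annotate_nt(
    net: NervousSystem,
    nt_expression: Mapping[str, set[str]],
    receptor_expression: Mapping[str, set[str]],
    pair_map: PairMap,
) -> AnnotationSummary:
    """Annotate every chemical connection with putative (ligand, receptor)
    pairs in place and return the summary.

    Neurons missing from an expression map are treated as expressing
    nothing (counted and logged), so their connections come out
    unannotated rather than erroring.
    """
    if not pair_map.pairs:
        raise ValueError("empty ligand-receptor pair map")
    missing = set()
    hist: dict[int, int] = {}
    n_un = n_uni = n_multi = n_edges = 0
    for c in net.connections_of_kind("chemical"):
        if c.pre not in nt_expression:
            missing.add(c.pre)
        if c.post not in receptor_expression:
            missing.add(c.post)
        ligands = nt_expression.get(c.pre, set())
        receptors = receptor_expression.get(c.post, set())
        c.nt_pairs = {
            (l, r) for l in ligands for r in receptors if (l, r) in pair_map.pairs
        }
        n_edges += 1
        hist[len(c.nt_pairs)] = hist.get(len(c.nt_pairs), 0) + 1
        distinct_ligands = {l for l, _ in c.nt_pairs}
        if not c.nt_pairs:
            n_un += 1
        elif len(distinct_ligands) == 1:
            n_uni += 1
        else:
            n_multi += 1
    if missing:
        logger.info(
            "%d neurons had no expression data and were treated as empty",
            len(missing),
        )
    return AnnotationSummary(
        n_edges=n_edges,
        n_unannotated=n_un,
        n_unique_nt=n_uni,
        n_multi_nt=n_multi,
        pair_count_histogram=dict(sorted(hist.items())),
    )


def extract_nt_connectome(net: NervousSystem, ligand: str) -> NervousSystem:
    """Edge-subnetwork of chemical connections carrying ``ligand``.

    Endpoint neurons are retained; neurons that themselves release the
    ligand are flagged via ``properties['releases_ligand']``.
    """
    keys = [
        c.key
        for c in net.connections_of_kind("chemical")
        if any(l == ligand for l, _ in c.nt_pairs)
    ]
    if not keys:
        logger.warning("ligand %r matches no annotated connection", ligand)
        sub = NervousSystem(metadata=dict(net.metadata))
    else:
        sub = subnetwork(net, edges=keys)
    for name, neuron in sub.neurons.items():
        releases = any(
            l == ligand
            for c in net.connections_of_kind("chemical")
            if c.pre == name
            for l, _ in c.nt_pairs
        )
        neuron.properties["releases_ligand"] = releases
    sub.metadata["ligand"] = ligand
    return sub


def chain_nt_profile(
    matches: Sequence[MotifMatch], net: NervousSystem
) -> dict[tuple[int, int], dict[tuple[str, str] | str, float]]:
    """Pooled (ligand, receptor) frequencies per template edge.

    For each template edge, the nt_pairs of the corresponding network
    connections are pooled over all matches; an edge with no annotation
    contributes to an explicit ``"unannotated"`` mass.  Frequencies per
    template edge sum to 1.
    """
    if not matches:
        raise ValueError("empty match list")
    template = matches[0].template
    profile: dict[tuple[int, int], dict] = {}
    for u, v in sorted(template.edges):
        counts: dict = {}
        total = 0
        for m in matches:
            key = (m.mapping[u], m.mapping[v], "chemical")
            conn = net.connections.get(key)
            pairs = conn.nt_pairs if conn is not None else set()
            if not pairs:
                counts["unannotated"] = counts.get("unannotated", 0) + 1
                total += 1
            else:
                for pair in pairs:
                    counts[pair] = counts.get(pair, 0) + 1
                    total += 1
        profile[(u, v)] = {k: c / total for k, c in counts.items()}
    return profile


def build_np_connectome(
    npp_expression: Mapping[str, set[str]],
    receptor_expression: Mapping[str, set[str]],
    np_pair_map: PairMap,
    neurons: Mapping[str, Neuron] | None = None,
) -> NervousSystem:
    """Long-range neuropeptide connectome from expression alone.

    A directed peptidergic edge a->b labelled (P, R) exists for every
    neuron a expressing peptide P and neuron b expressing receptor R with
    (P, R) in the map — no spatial constraint.  Autocrine self-edges are
    included and flagged.  Edge weight = number of supporting pairs.
    """
    if not np_pair_map.pairs:
        raise ValueError("empty neuropeptide pair map")
    net = NervousSystem(metadata={"model": "long-range"})
    universe = set(npp_expression) | set(receptor_expression)
    if neurons:
        universe |= set(neurons)
    for name in sorted(universe):
        template = (neurons or {}).get(name)
        net.add_neuron(
            Neuron(
                name=name,
                neuron_type=template.neuron_type if template else "other",
                position=template.position if template else None,
            )
        )
    for peptide, receptor in sorted(np_pair_map.pairs):
        senders = sorted(n for n, g in npp_expression.items() if peptide in g)
        receivers = sorted(n for n, g in receptor_expression.items() if receptor in g)
        for a in senders:
            for b in receivers:
                key = (a, b, "peptidergic")
                conn = net.connections.get(key)
                if conn is None:
                    conn = Connection(
                        pre=a, post=b, kind="peptidergic", weight=0.0,
                        properties={"autocrine": a == b},
                    )
                    net.connections[key] = conn
                conn.weight += 1.0
                conn.nt_pairs.add((peptide, receptor))
    return net


@dataclass
class EnrichmentResult:
    """Within-subset vs outside connection-density comparison for one pair."""

    pair: tuple[str, str]
    inside_edges: int
    inside_possible: int
    outside_edges: int
    outside_possible: int
    z: float
    p: float
    p_adj: float | None = None

    @property
    def inside_density(self) -> float:
        return self.inside_edges / self.inside_possible

    @property
    def outside_density(self) -> float:
        return self.outside_edges / self.outside_possible

    @property
    def significant(self) -> bool:
        p = self.p if self.p_adj is None else self.p_adj
        return p < 0.05


def np_enrichment(
    np_net: NervousSystem,
    subset: set[str],
    config: StatsConfig | None = None,
) -> list[EnrichmentResult]:
    """Per-pair enrichment of peptidergic connections within a neuron subset.

    For each (peptide, receptor) pair, the directed connection density
    among ordered pairs inside the subset is compared to the density over
    all other ordered pairs with a pooled two-proportion z-test
    (right-sided), Benjamini-Yekutieli-adjusted across pairs.  Self-edges
    are excluded from both denominators.
    """
    config = config or StatsConfig()
    subset = set(subset)
    unknown = subset - set(np_net.neurons)
    if unknown:
        raise KeyError(f"unknown neurons in subset: {sorted(unknown)}")
    if len(subset) < 2:
        raise ValueError("subset must contain at least 2 neurons")
    n_total = len(np_net.neurons)
    n_in = len(subset) * (len(subset) - 1)
    n_out = n_total * (n_total - 1) - n_in
    if n_out <= 0:
        raise ValueError("subset covers the whole network")

    pairs = sorted(
        {p for c in np_net.connections_of_kind("peptidergic") for p in c.nt_pairs}
    )
    results = []
    for pair in pairs:
        k_in = k_out = 0
        for c in np_net.connections_of_kind("peptidergic"):
            if pair not in c.nt_pairs or c.pre == c.post:
                continue
            if c.pre in subset and c.post in subset:
                k_in += 1
            else:
                k_out += 1
        if k_in + k_out == 0 or k_in + k_out == n_in + n_out:
            z, p = 0.0, 1.0  # identical (degenerate) proportions
        else:
            z, p = proportions_ztest(
                [k_in, k_out], [n_in, n_out], alternative="larger"
            )
        results.append(
            EnrichmentResult(
                pair=pair,
                inside_edges=k_in,
                inside_possible=n_in,
                outside_edges=k_out,
                outside_possible=n_out,
                z=float(z),
                p=float(p),
            )
        )
    for r, adj in zip(results, by_adjust([r.p for r in results])):
        r.p_adj = adj
    return results
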