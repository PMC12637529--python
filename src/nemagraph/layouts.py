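"""Pure coordinate computation for the standard connectome views.

All layouts are deterministic functions of the network and options; they
return ``{neuron name: (x, y)}`` maps.  Rendering is a thin optional layer
(:func:`render`) over the coordinates.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import networkx as nx

from .core import NervousSystem

logger = logging.getLogger(__name__)

_PLANES = {
    "AP-DV": (0, 1),
    "AP-LR": (0, 2),
    "DV-LR": (1, 2),
}


def anatomical_layout(
    net: NervousSystem, plane: str = "AP-DV"
) -> dict[str, tuple[float, float]]:
    """Orthographic projection of stored 3-D positions onto a body plane.

    Neurons lacking a position are omitted (and logged).  Raises when no
    neuron has a position at all.
    """
    if plane not in _PLANES:
        raise ValueError(f"unknown plane {plane!r}; expected one of {sorted(_PLANES)}")
    i, j = _PLANES[plane]
    coords = {}
    missing = []
    for name in sorted(net.neurons):
        pos = net.neurons[name].position
        if pos is None:
            missing.append(name)
        else:
            coords[name] = (pos[i], pos[j])
    if not coords:
        raise ValueError("no neuron has a position")
    if missing:
        logger.info("%d neurons lack positions: %s...", len(missing), missing[:5])
    return coords


def layered_layout(
    net: NervousSystem,
    layer_assignment: Mapping[str, tuple[int, int]],
    strict: bool = True,
) -> dict[str, tuple[float, float]]:
    """Layered view: x = layer index, y = rank within (layer, sublayer).

    Neurons are stacked alphabetically within each sublayer; sublayers of a
    layer are stacked on top of each other, so no two neurons share a
    coordinate.  With ``strict`` every plotted neuron must be assigned;
    otherwise unassigned neurons are omitted.
    """
    names = sorted(net.neurons)
    unassigned = [n for n in names if n not in layer_assignment]
    if unassigned and strict:
        raise KeyError(f"unassigned neurons: {unassigned[:5]}...")
    buckets: dict[tuple[int, int], list[str]] = {}
    for n in names:
        if n in layer_assignment:
            buckets.setdefault(tuple(layer_assignment[n]), []).append(n)
    coords = {}
    offsets: dict[int, int] = {}
    for (layer, sublayer) in sorted(buckets):
        members = sorted(buckets[(layer, sublayer)])
        base = offsets.get(layer, 0)
        for rank, n in enumerate(members):
            coords[n] = (float(layer), float(base + rank))
        offsets[layer] = base + len(members) + 1  # gap between sublayers
    return coords


def shell_layout(
    net: NervousSystem,
    focal: Iterable[str],
    max_depth: int = 2,
    direction: str = "out",
    kind: str = "chemical",
) -> dict[str, tuple[float, float]]:
    """Concentric shells of BFS distance from (or to) a focal neuron set.

    Shell k holds the neurons at shortest directed-path distance k from
    the focal set (``direction='out'``) or to it (``'in'``), for
    k <= max_depth; unreachable neurons are omitted.  Focal neurons sit on
    a small inner circle, shells on concentric circles with angular
    positions evenly spaced alphabetically.
    """
    focal = sorted(set(focal))
    if not focal:
        raise ValueError("focal set must be nonempty")
    g = net.to_digraph(kind)
    if direction == "in":
        g = g.reverse(copy=False)
    dist: dict[str, int] = {f: 0 for f in focal}
    frontier = list(focal)
    depth = 0
    while frontier and depth < max_depth:
        depth += 1
        nxt = []
        for u in frontier:
            for v in g.successors(u):
                if v not in dist:
                    dist[v] = depth
                    nxt.append(v)
        frontier = nxt
    shells: dict[int, list[str]] = {}
    for n, d in dist.items():
        shells.setdefault(d, []).append(n)
    coords = {}
    for d in sorted(shells):
        members = sorted(shells[d])
        radius = float(d) if d > 0 else 0.3 if len(members) > 1 else 0.0
        for k, n in enumerate(members):
            theta = 2 * math.pi * k / len(members)
            coords[n] = (radius * math.cos(theta), radius * math.sin(theta))
    return coords


def circular_group_layout(
    folded_net: NervousSystem, radius: float = 1.0
) -> dict[str, tuple[float, float]]:
    """Group nodes evenly spaced on a circle, alphabetically from +x."""
    names = sorted(folded_net.neurons)
    if not names:
        return {}
    if len(names) == 1:
        return {names[0]: (radius, 0.0)}
    return {
        n: (
            radius * math.cos(2 * math.pi * k / len(names)),
            radius * math.sin(2 * math.pi * k / len(names)),
        )
        for k, n in enumerate(names)
    }


def render(
    net: NervousSystem,
    coords: Mapping[str, tuple[float, float]],
    path,
    kind: str | None = None,
    node_color_by_type: bool = True,
) -> None:
    """Minimal matplotlib rendering of a coordinate layout to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    type_colors = {
        "sensory": "tab:orange",
        "interneuron": "gold",
        "motorneuron": "tab:blue",
        "other": "gray",
    }
    fig, ax = plt.subplots(figsize=(6, 6))
    for c in net.connections.values():
        if kind is not None and c.kind != kind:
            continue
        if c.pre in coords and c.post in coords:
            (x0, y0), (x1, y1) = coords[c.pre], coords[c.post]
            ax.annotate(
                "",
                xy=(x1, y1),
                xytext=(x0, y0),
                arrowprops=dict(arrowstyle="->", color="0.7", lw=0.5),
            )
    xs = [coords[n][0] for n in coords]
    ys = [coords[n][1] for n in coords]
    colors = [
        type_colors.get(net.neurons[n].neuron_type, "gray") if node_color_by_type else "C0"
        for n in coords
    ]
    ax.scatter(xs, ys, c=colors, s=30, zorder=3)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
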