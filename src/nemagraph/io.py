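"""Readers and writers for the tabular and graph formats the toolkit touches.

Dialect rules: CSV vs TSV is autodetected from the file extension
(``.tsv``/``.tab`` means tab), files are UTF-8 and must carry a header row.
Supported formats: edge-list CSV/TSV, adjacency-matrix CSV, gene x cell
expression CSV, ligand->receptor pair-map CSV, node-link JSON (round-trip
lossless for the full data model) and GraphML export.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path as FilePath
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .core import Connection, NervousSystem, Neuron

logger = logging.getLogger(__name__)


def _sep(path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","


@dataclass
class ExpressionTable:
    """A gene x cell expression matrix with ordered name lists."""

    genes: list[str]
    cells: list[str]
    values: np.ndarray
    threshold_level: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("expression matrix shape does not match name lists")
        if len(set(self.genes)) != len(self.genes) or len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate gene or cell names in expression table")
        if (self.values < 0).any():
            raise ValueError("negative expression values")


@dataclass
class PairMap:
    """A set of cognate (ligand, receptor) pairs of one signalling kind."""

    pairs: set[tuple[str, str]]
    kind: str = "neurotransmitter"

    def __post_init__(self) -> None:
        if self.kind not in ("neurotransmitter", "neuropeptide"):
            raise ValueError(f"unknown pair-map kind {self.kind!r}")
        self.pairs = {(str(l), str(r)) for l, r in self.pairs}
        if any(not l or not r for l, r in self.pairs):
            raise ValueError("empty ligand or receptor name in pair map")

    def ligands(self) -> set[str]:
        return {l for l, _ in self.pairs}

    def receptors(self) -> set[str]:
        return {r for _, r in self.pairs}


# ---------------------------------------------------------------------------
# tabular readers
# ---------------------------------------------------------------------------


def read_edge_list(path, column_map: Mapping[str, str] | None = None) -> list[dict]:
    """Connection records from an edge-list CSV/TSV.

    ``column_map`` maps the roles ``pre``/``post``/``kind``/``weight`` to
    column names; unmapped roles default to same-named columns.  A missing
    kind column defaults every row to chemical, a missing/blank weight to 1.
    """
    colmap = {"pre": "pre", "post": "post", "kind": "kind", "weight": "weight"}
    colmap.update(column_map or {})
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    for role in ("pre", "post"):
        if colmap[role] not in df.columns:
            raise KeyError(f"missing mapped column {colmap[role]!r} for {role!r}")
    records = []
    for _, row in df.iterrows():
        rec = {
            "pre": str(row[colmap["pre"]]).strip(),
            "post": str(row[colmap["post"]]).strip(),
        }
        if colmap["kind"] in df.columns and not pd.isna(row[colmap["kind"]]):
            rec["kind"] = str(row[colmap["kind"]]).strip()
        raw_w = row[colmap["weight"]] if colmap["weight"] in df.columns else None
        if raw_w is None or (isinstance(raw_w, float) and np.isnan(raw_w)) or str(raw_w).strip() == "":
            rec["weight"] = 1.0
        else:
            try:
                rec["weight"] = float(raw_w)
            except ValueError as exc:
                raise ValueError(f"unparseable weight {raw_w!r}") from exc
        records.append(rec)
    return records


def read_neuron_table(path) -> list[dict]:
    """Neuron metadata records (name, neuron_type, subtype, x/y/z, ...)."""
    df = pd.read_csv(path, sep=_sep(path))
    if "name" not in df.columns:
        raise KeyError("neuron table needs a 'name' column")
    return df.astype(object).where(pd.notna(df), None).to_dict("records")


def read_adjacency(path, kind: str = "chemical") -> list[dict]:
    """Connection records from an adjacency CSV (rows = pre, cols = post).

    One record per strictly positive cell; zeros/blanks mean no edge.
    """
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    rows = [str(r).strip() for r in df.index]
    cols = [str(c).strip() for c in df.columns]
    if len(set(rows)) != len(rows) or len(set(cols)) != len(cols):
        raise ValueError("duplicate neuron names in adjacency matrix")
    values = df.to_numpy(dtype=float, na_value=0.0)
    if (values < 0).any():
        raise ValueError("negative cell in adjacency matrix")
    records = []
    for i, pre in enumerate(rows):
        for j, post in enumerate(cols):
            if values[i, j] > 0:
                records.append(
                    {"pre": pre, "post": post, "kind": kind, "weight": values[i, j]}
                )
    return records


def read_expression_table(path, threshold_level: int | None = None) -> ExpressionTable:
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    return ExpressionTable(
        genes=[str(g).strip() for g in df.index],
        cells=[str(c).strip() for c in df.columns],
        values=df.to_numpy(dtype=float, na_value=0.0),
        threshold_level=threshold_level,
    )


def expression_to_gene_sets(
    table: ExpressionTable,
    threshold: float = 0.0,
    class_members: Mapping[str, list[str]] | None = None,
) -> dict[str, set[str]]:
    """Binarize an expression table into a neuron -> expressed-gene-set map.

    A gene is assigned to a cell when its value exceeds ``threshold`` (for
    pre-binarized tables 0/1 this reduces to value > 0).  Columns naming a
    neuron class listed in ``class_members`` are expanded to every member
    neuron (opt-in imputation across a class, e.g. left/right pairs).
    """
    out: dict[str, set[str]] = {}
    binary = table.values > threshold
    for j, cell in enumerate(table.cells):
        genes = {table.genes[i] for i in np.nonzero(binary[:, j])[0]}
        targets = (class_members or {}).get(cell, [cell])
        for t in targets:
            out.setdefault(t, set()).update(genes)
    return {k: v for k, v in out.items() if v}


def read_expression(
    path,
    threshold: float = 0.0,
    class_members: Mapping[str, list[str]] | None = None,
) -> dict[str, set[str]]:
    """Read a gene x cell table and binarize it (see expression_to_gene_sets)."""
    return expression_to_gene_sets(
        read_expression_table(path), threshold=threshold, class_members=class_members
    )


def read_pair_map(path, kind: str = "neurotransmitter") -> PairMap:
    """(ligand, receptor) pairs from a two-column CSV (ligand, receptor)."""
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    for col in ("ligand", "receptor"):
        if col not in df.columns:
            raise KeyError(f"pair map needs a {col!r} column")
    pairs = {
        (str(l).strip(), str(r).strip()) for l, r in zip(df["ligand"], df["receptor"])
    }
    return PairMap(pairs=pairs, kind=kind)


# ---------------------------------------------------------------------------
# node-link JSON (lossless round trip for the data model)
# ---------------------------------------------------------------------------


def _neuron_to_json(n: Neuron) -> dict:
    return {
        "name": n.name,
        "neuron_type": n.neuron_type,
        "subtype": n.subtype,
        "position": list(n.position) if n.position is not None else None,
        "expressed_genes": sorted(n.expressed_genes),
        "neurotransmitters": sorted(n.neurotransmitters),
        "properties": n.properties,
    }


def _conn_to_json(c: Connection) -> dict:
    return {
        "pre": c.pre,
        "post": c.post,
        "kind": c.kind,
        "weight": c.weight,
        "nt_pairs": sorted([list(p) for p in c.nt_pairs]),
        "properties": c.properties,
    }


def write_node_link_json(net: NervousSystem, path) -> None:
    doc = {
        "metadata": net.metadata,
        "nodes": [_neuron_to_json(net.neurons[n]) for n in sorted(net.neurons)],
        "links": [_conn_to_json(net.connections[k]) for k in sorted(net.connections)],
        "neuron_groups": {g: sorted(m) for g, m in net.neuron_groups.items()},
        "connection_groups": {
            g: sorted([list(k) for k in m]) for g, m in net.connection_groups.items()
        },
    }
    FilePath(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def read_node_link_json(path) -> NervousSystem:
    doc = json.loads(FilePath(path).read_text(encoding="utf-8"))
    for key in ("nodes", "links"):
        if key not in doc:
            raise ValueError(f"node-link JSON missing {key!r} key")
    net = NervousSystem(metadata=doc.get("metadata", {}))
    for nd in doc["nodes"]:
        net.add_neuron(
            Neuron(
                name=nd["name"],
                neuron_type=nd.get("neuron_type", "other"),
                subtype=nd.get("subtype", ""),
                position=tuple(nd["position"]) if nd.get("position") else None,
                expressed_genes=set(nd.get("expressed_genes", [])),
                neurotransmitters=set(nd.get("neurotransmitters", [])),
                properties=nd.get("properties", {}),
            )
        )
    for ld in doc["links"]:
        conn = Connection(
            pre=ld["pre"],
            post=ld["post"],
            kind=ld.get("kind", "chemical"),
            weight=ld.get("weight", 1.0),
            nt_pairs={tuple(p) for p in ld.get("nt_pairs", [])},
            properties=ld.get("properties", {}),
        )
        net.add_connection(conn, allow_self_loop=conn.pre == conn.post)
    for g, members in doc.get("neuron_groups", {}).items():
        net.register_neuron_group(g, members)
    for g, members in doc.get("connection_groups", {}).items():
        net.register_connection_group(g, [tuple(k) for k in members])
    return net


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------


def export_graphml(net: NervousSystem, path) -> None:
    """GraphML export; nt_pairs serialized as 'L:R;L:R' edge attribute."""
    g = nx.MultiDiGraph()
    for name in sorted(net.neurons):
        n = net.neurons[name]
        attrs = {"neuron_type": n.neuron_type, "subtype": n.subtype}
        if n.position is not None:
            attrs.update(zip(("x", "y", "z"), n.position))
        g.add_node(name, **attrs)
    for key in sorted(net.connections):
        c = net.connections[key]
        g.add_edge(
            c.pre,
            c.post,
            key=c.kind,
            kind=c.kind,
            weight=c.weight,
            nt_pairs=";".join(f"{l}:{r}" for l, r in sorted(c.nt_pairs)),
        )
    nx.write_graphml(g, path)


def write_edge_list(net: NervousSystem, path) -> None:
    rows = [
        {"pre": c.pre, "post": c.post, "kind": c.kind, "weight": c.weight}
        for k, c in sorted(net.connections.items())
    ]
    pd.DataFrame(rows, columns=["pre", "post", "kind", "weight"]).to_csv(
        path, sep=_sep(path), index=False
    )


def write_neuron_table(net: NervousSystem, path) -> None:
    rows = []
    for name in sorted(net.neurons):
        n = net.neurons[name]
        row = {"name": name, "neuron_type": n.neuron_type, "subtype": n.subtype}
        if n.position is not None:
            row.update(zip(("x", "y", "z"), n.position))
        row["neurotransmitters"] = ";".join(sorted(n.neurotransmitters))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False)
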