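"""Seed-based induced network module extraction.

Given a typed molecular interaction network and a list of seed genes, the
module consists of the seeds plus "connector" nodes: non-seed nodes adjacent
to at least one seed whose seed-adjacency is higher than expected for their
degree. For a candidate v with degree d(v) in a network of N nodes and n
seeds present, the null model is binomial: each of the n seeds is a neighbor
of v with probability q = d(v)/(N-1), so with o observed seed neighbors

    z = (o - n*q) / sqrt(n*q*(1-q)).

Candidates at or above the z threshold (default 20, a deliberately stringent
compactness setting) join the module; module edges are all source-network
edges between module nodes. Nodes carry display attributes (role,
expression state, neighborhood connectivity, z) and the module exports to
GraphML or XGMML for Cytoscape.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "EDGE_TYPES",
    "load_network",
    "candidate_zscores",
    "induce_module",
    "neighborhood_connectivity",
    "annotate_module",
    "annotate_and_export",
    "load_exported",
]

EDGE_TYPES = frozenset({"protein-protein", "gene-regulatory", "biochemical"})

#: node colour keys used for expression states in exports
EXPR_COLOURS = {"up": "wine-red", "down": "dark-green", "absent": "grey"}


def _canon_type(raw: str) -> str:
    t = raw.strip().lower().replace("–", "-").replace("_", "-").replace(" ", "-")
    aliases = {
        "ppi": "protein-protein",
        "protein-protein": "protein-protein",
        "gene-regulatory": "gene-regulatory",
        "gene-protein": "gene-regulatory",
        "regulatory": "gene-regulatory",
        "biochemical": "biochemical",
        "protein-metabolite": "biochemical",
    }
    if t not in aliases:
        raise ValueError(f"unknown edge type {raw!r}")
    return aliases[t]


def load_network(path: str | Path) -> nx.Graph:
    """Read an interaction network from edge-list TSV (source, target, type)
    or SIF (source, type, target).

    Self-loops are dropped with a warning; duplicate identical edges collapse
    to one. Parallel edges of different types are kept as a single edge whose
    ``edge_type`` is the sorted ';'-join of the types seen.
    """
    import logging

    log = logging.getLogger(__name__)
    path = Path(path)
    is_sif = path.suffix.lower() == ".sif"
    g = nx.Graph()
    types: dict[tuple[str, str], set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 3:
                raise ValueError(f"line {lineno}: expected 3 fields, got {len(fields)}")
            if is_sif:
                src, etype, dst = fields
            else:
                src, dst, etype = fields
            etype = _canon_type(etype)
            if src == dst:
                log.warning("line %d: self-loop %r dropped", lineno, src)
                g.add_node(src)
                continue
            key = (min(src, dst), max(src, dst))
            types.setdefault(key, set()).add(etype)
    for (u, v), ts in types.items():
        g.add_edge(u, v, edge_type=";".join(sorted(ts)))
    return g


def candidate_zscores(net: nx.Graph, seeds: Iterable[str]) -> pd.Series:
    """Binomial z-score of seed-adjacency for every non-seed neighbor of a seed.

    Unknown seeds are ignored (reported via the returned series' attrs).
    Candidates adjacent to every other node (q = 1) get +inf when they touch
    all seeds; q = 0 cannot occur for a candidate.
    """
    seeds = set(seeds)
    present = seeds & set(net.nodes)
    missing = sorted(seeds - present)
    if not present:
        raise ValueError("no seed present in network")
    N = net.number_of_nodes()
    n = len(present)
    candidates = sorted(
        {v for s in present for v in net.neighbors(s)} - present
    )
    z: dict[str, float] = {}
    for v in candidates:
        d = net.degree(v)
        q = d / (N - 1)
        o = sum(1 for u in net.neighbors(v) if u in present)
        if q >= 1.0:
            z[v] = float("inf") if o == n else float("-inf")
            continue
        z[v] = (o - n * q) / (n * q * (1 - q)) ** 0.5
    out = pd.Series(z, name="z", dtype=float).sort_index()
    out.attrs["missing_seeds"] = missing
    out.attrs["n_seeds_present"] = n
    return out


def induce_module(net: nx.Graph, seeds: Iterable[str], z_threshold: float = 20.0) -> nx.Graph:
    """Build the induced module: seeds present in the network plus candidates
    with z >= z_threshold, with all source edges among them.

    Node attributes: ``role`` ("seed" / "connector") and, for connectors,
    ``z_score``.
    """
    seeds = set(seeds)
    z = candidate_zscores(net, seeds)
    present = seeds & set(net.nodes)
    connectors = [v for v, zv in z.items() if zv >= z_threshold]
    module = net.subgraph(sorted(present) + connectors).copy()
    for v in module.nodes:
        if v in present:
            module.nodes[v]["role"] = "seed"
        else:
            module.nodes[v]["role"] = "connector"
            module.nodes[v]["z_score"] = float(z[v])
    module.graph["z_threshold"] = float(z_threshold)
    module.graph["missing_seeds"] = ";".join(z.attrs["missing_seeds"])
    return module


def neighborhood_connectivity(module: nx.Graph) -> pd.Series:
    """Mean degree of each node's neighbors within the module; isolated -> 0."""
    vals = {}
    for v in module.nodes:
        nbrs = list(module.neighbors(v))
        vals[v] = (
            sum(module.degree(u) for u in nbrs) / len(nbrs) if nbrs else 0.0
        )
    return pd.Series(vals, name="neighborhood_connectivity", dtype=float).sort_index()


def annotate_module(module: nx.Graph, degs: pd.DataFrame | None) -> nx.Graph:
    """Attach expression_state (up/down/absent) and neighborhood_connectivity."""
    nconn = neighborhood_connectivity(module)
    dir_of: dict[str, str] = {}
    if degs is not None:
        sel = degs.loc[degs["selected"]]
        dir_of = {str(g): str(d) for g, d in sel["direction"].items()}
    for v in module.nodes:
        state = dir_of.get(v, "absent")
        module.nodes[v]["expression_state"] = state
        module.nodes[v]["colour"] = EXPR_COLOURS[state]
        module.nodes[v]["neighborhood_connectivity"] = float(nconn[v])
    return module


# ---------------------------------------------------------------------------
# Export / round-trip
# ---------------------------------------------------------------------------

_NODE_ATTRS = ("role", "expr", "z", "nconn")


def _canonical_edges(module: nx.Graph):
    """Edges with endpoints ordered lexicographically, sorted — byte-stable
    regardless of the in-memory adjacency order."""
    return sorted(
        (min(u, v), max(u, v), d) for u, v, d in module.edges(data=True)
    )


def _write_xgmml(module: nx.Graph, path: Path) -> None:
    root = ET.Element(
        "graph",
        attrib={
            "label": "induced-module",
            "directed": "0",
            "xmlns": "http://www.cs.rpi.edu/XGMML",
        },
    )
    for v in sorted(module.nodes):
        a = module.nodes[v]
        node = ET.SubElement(root, "node", attrib={"id": str(v), "label": str(v)})
        ET.SubElement(node, "att", attrib={"name": "role", "type": "string", "value": a.get("role", "seed")})
        ET.SubElement(node, "att", attrib={"name": "expr", "type": "string", "value": a.get("expression_state", "absent")})
        ET.SubElement(node, "att", attrib={"name": "z", "type": "real", "value": repr(float(a.get("z_score", 0.0)))})
        ET.SubElement(node, "att", attrib={"name": "nconn", "type": "real", "value": repr(float(a.get("neighborhood_connectivity", 0.0)))})
    for u, v, data in _canonical_edges(module):
        edge = ET.SubElement(root, "edge", attrib={"source": str(u), "target": str(v)})
        ET.SubElement(edge, "att", attrib={"name": "etype", "type": "string", "value": data.get("edge_type", "protein-protein")})
    ET.indent(ET.ElementTree(root))
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)
    with open(path, "a") as fh:
        fh.write("\n")


def _read_xgmml(path: Path) -> nx.Graph:
    ns = {"x": "http://www.cs.rpi.edu/XGMML"}
    root = ET.parse(path).getroot()
    g = nx.Graph()
    for node in root.findall("x:node", ns):
        attrs = {a.get("name"): a.get("value") for a in node.findall("x:att", ns)}
        g.add_node(
            node.get("id"),
            role=attrs.get("role", "seed"),
            expression_state=attrs.get("expr", "absent"),
            z_score=float(attrs.get("z", 0.0)),
            neighborhood_connectivity=float(attrs.get("nconn", 0.0)),
        )
    for edge in root.findall("x:edge", ns):
        attrs = {a.get("name"): a.get("value") for a in edge.findall("x:att", ns)}
        g.add_edge(edge.get("source"), edge.get("target"), edge_type=attrs.get("etype", "protein-protein"))
    return g


def annotate_and_export(
    module: nx.Graph,
    degs: pd.DataFrame | None,
    path: str | Path,
    fmt: str = "graphml",
) -> Path:
    """Annotate display attributes and write GraphML or XGMML.

    The written attributes are role, expr (expression state), z, nconn per
    node and etype per edge; exports round-trip through :func:`load_exported`.
    """
    path = Path(path)
    module = annotate_module(module, degs)
    if fmt == "graphml":
        out = nx.Graph()
        out.add_nodes_from(
            (
                v,
                {
                    "role": a.get("role", "seed"),
                    "expr": a.get("expression_state", "absent"),
                    "z": float(a.get("z_score", 0.0)),
                    "nconn": float(a.get("neighborhood_connectivity", 0.0)),
                },
            )
            for v, a in sorted(module.nodes(data=True))
        )
        out.add_edges_from(
            (u, v, {"etype": d.get("edge_type", "protein-protein")})
            for u, v, d in _canonical_edges(module)
        )
        nx.write_graphml(out, path)
    elif fmt == "xgmml":
        _write_xgmml(module, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path


def load_exported(path: str | Path, fmt: str | None = None) -> nx.Graph:
    """Re-load an exported module; inverse of :func:`annotate_and_export`."""
    path = Path(path)
    fmt = fmt or ("xgmml" if path.suffix.lower() == ".xgmml" else "graphml")
    if fmt == "graphml":
        g = nx.read_graphml(path)
        out = nx.Graph()
        for v, a in g.nodes(data=True):
            out.add_node(
                v,
                role=a.get("role", "seed"),
                expression_state=a.get("expr", "absent"),
                z_score=float(a.get("z", 0.0)),
                neighborhood_connectivity=float(a.get("nconn", 0.0)),
            )
        for u, v, d in g.edges(data=True):
            out.add_edge(u, v, edge_type=d.get("etype", "protein-protein"))
        return out
    return _read_xgmml(path)
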