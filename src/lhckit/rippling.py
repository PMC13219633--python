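"""Membrane rippling graphs and hydrophobic-mismatch statistics.

Each transmembrane helix becomes a node placed at its stromal end
projected onto the membrane midplane, colour-binned by helix height in
5 Å steps from 20 Å to 45+ Å.  Edges join neighbouring helices
(stromal-projection distance within a cutoff) and carry the absolute
helix-height difference, binned in 5 Å steps from 5 to 20+ Å;
differences below 5 Å are kept but flagged suppressed, matching how
such graphs are usually displayed while leaving statistics exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from lhckit.membrane_geometry import MembraneFrame, TMHelixMeasure

__all__ = [
    "RippleNode", "RippleEdge", "RippleGraph",
    "build_graph", "mismatch_between", "export_graph", "load_graph",
    "height_bin", "delta_bin",
]

HEIGHT_BIN_LOW = 20.0
HEIGHT_BIN_HIGH = 45.0
DELTA_BIN_LOW = 5.0
DELTA_BIN_HIGH = 20.0
BIN_STEP = 5.0


def height_bin(height: float) -> int:
    """5 Å height bins: [20,25) -> 0 ... [45, inf) -> 5; <20 clamped to 0."""
    h = np.clip(height, HEIGHT_BIN_LOW, HEIGHT_BIN_HIGH)
    return int(min((h - HEIGHT_BIN_LOW) // BIN_STEP,
                   (HEIGHT_BIN_HIGH - HEIGHT_BIN_LOW) // BIN_STEP))


def delta_bin(delta: float) -> int:
    """5 Å difference bins from 5 Å: [5,10) -> 0 ... [20, inf) -> 3.

    Differences below 5 Å (suppressed in display) return -1.
    """
    if delta < DELTA_BIN_LOW:
        return -1
    d = min(delta, DELTA_BIN_HIGH)
    return int(min((d - DELTA_BIN_LOW) // BIN_STEP,
                   (DELTA_BIN_HIGH - DELTA_BIN_LOW) // BIN_STEP))


@dataclass
class RippleNode:
    node_id: str                 # chain:start_res, unique and sortable
    chain_id: str
    subunit_label: str
    residue_start: int
    xy: np.ndarray               # stromal-end projection on the midplane
    height: float

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float)

    @property
    def height_bin(self) -> int:
        return height_bin(self.height)


@dataclass
class RippleEdge:
    source: str
    target: str
    delta_height: float

    @property
    def suppressed(self) -> bool:
        return self.delta_height < DELTA_BIN_LOW

    @property
    def delta_bin(self) -> int:
        return delta_bin(self.delta_height)


@dataclass
class RippleGraph:
    nodes: list[RippleNode]
    edges: list[RippleEdge]
    frame: MembraneFrame
    provenance: dict = field(default_factory=dict)

    def node(self, node_id: str) -> RippleNode:
        return next(n for n in self.nodes if n.node_id == node_id)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n.node_id, subunit=n.subunit_label, chain=n.chain_id,
                       x=float(n.xy[0]), y=float(n.xy[1]),
                       height=float(n.height), bin=n.height_bin)
        for e in self.edges:
            g.add_edge(e.source, e.target, delta=float(e.delta_height),
                       bin=e.delta_bin, suppressed=e.suppressed)
        return g


def build_graph(measures: Sequence[TMHelixMeasure], frame: MembraneFrame,
                neighbor_cutoff: float = 16.0,
                structure_id: str = "") -> RippleGraph:
    """Build the rippling graph from measured transmembrane helices.

    Nodes are ordered deterministically by (chain, residue_start); an
    edge joins two helices whose stromal-end midplane projections are
    within ``neighbor_cutoff`` Å.
    """
    if len(measures) < 2:
        raise ValueError("need at least two transmembrane helices")
    ms = sorted(measures, key=lambda m: (m.helix.chain_id, m.helix.start_res))
    nodes = []
    for m in ms:
        xy = frame.project_in_plane(m.stromal_end)[0]
        nodes.append(RippleNode(
            node_id=f"{m.helix.chain_id}:{m.helix.start_res}",
            chain_id=m.helix.chain_id,
            subunit_label=m.subunit_label,
            residue_start=m.helix.start_res,
            xy=xy,
            height=m.height,
        ))
    pts = np.array([n.xy for n in nodes])
    tree = cKDTree(pts)
    pairs = sorted(tree.query_pairs(r=neighbor_cutoff))
    edges = [RippleEdge(nodes[i].node_id, nodes[j].node_id,
                        abs(nodes[i].height - nodes[j].height))
             for i, j in pairs]
    prov = {"structure_id": structure_id,
            "neighbor_cutoff_A": neighbor_cutoff,
            "n_helices": len(nodes)}
    return RippleGraph(nodes=nodes, edges=edges, frame=frame, provenance=prov)


def mismatch_between(graph: RippleGraph, group_a: set[str], group_b: set[str],
                     statistic: str = "max") -> float:
    """Hydrophobic-mismatch statistic over cross-group edges.

    Groups are sets of subunit labels; the statistic (max, mean or min)
    is taken over |Δheight| of edges with one endpoint in each group.
    """
    if statistic not in ("max", "mean", "min"):
        raise ValueError(f"unknown statistic {statistic!r}")
    label = {n.node_id: n.subunit_label for n in graph.nodes}
    deltas = []
    for e in graph.edges:
        la, lb = label[e.source], label[e.target]
        if (la in group_a and lb in group_b) or (la in group_b and lb in group_a):
            deltas.append(e.delta_height)
    if not deltas:
        raise ValueError(f"no edges between groups {sorted(group_a)} and "
                         f"{sorted(group_b)}")
    return float({"max": np.max, "mean": np.mean, "min": np.min}[statistic](deltas))


# ---------------------------------------------------------------------------
# serialization

def _graph_dict(graph: RippleGraph) -> dict:
    return {
        "provenance": graph.provenance,
        "frame": graph.frame.to_dict(),
        "nodes": [{"id": n.node_id, "chain": n.chain_id,
                   "subunit": n.subunit_label,
                   "residue_start": n.residue_start,
                   "x": float(n.xy[0]), "y": float(n.xy[1]),
                   "height": float(n.height), "bin": n.height_bin}
                  for n in graph.nodes],
        "edges": [{"source": e.source, "target": e.target,
                   "delta": float(e.delta_height), "bin": e.delta_bin,
                   "suppressed": e.suppressed}
                  for e in graph.edges],
    }


def export_graph(graph: RippleGraph, path, format: str = "json") -> None:
    """Write the graph as json (lossless), graphml, or csv node/edge tables.

    For csv, two files are written: ``<path>`` with nodes and a sibling
    ``<stem>_edges.csv`` with edges.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_graph_dict(graph), indent=1))
    elif format == "graphml":
        nx.write_graphml(graph.to_networkx(), path)
    elif format == "csv":
        d = _graph_dict(graph)
        pd.DataFrame(d["nodes"]).to_csv(path, index=False)
        edge_path = path.with_name(path.stem + "_edges.csv")
        cols = ["source", "target", "delta", "bin", "suppressed"]
        pd.DataFrame(d["edges"], columns=cols).to_csv(edge_path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def load_graph(path) -> RippleGraph:
    """Read back a json export (round-trip partner of export_graph)."""
    d = json.loads(Path(path).read_text())
    frame = MembraneFrame.from_dict(d["frame"])
    nodes = [RippleNode(node_id=n["id"], chain_id=n["chain"],
                        subunit_label=n["subunit"],
                        residue_start=n["residue_start"],
                        xy=np.array([n["x"], n["y"]]), height=n["height"])
             for n in d["nodes"]]
    edges = [RippleEdge(e["source"], e["target"], e["delta"])
             for e in d["edges"]]
    return RippleGraph(nodes=nodes, edges=edges, frame=frame,
                       provenance=d.get("provenance", {}))
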