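"""Charge-interaction network: filtered edges, ranks, lone charges, patches.

A probe pair becomes an edge when its r_id falls below the selection cutoff
(0.6 nm) in at least a minimum fraction of frames (5% by default — the
boundary is inclusive). Nodes are *all* charged residues, so residues with no
retained interaction appear as lone charges (rank 0). Patches are the
connected components over the non-isolated nodes, interpreted as groups of
charges whose short-distance approaches are concerted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .charge_probes import ProbeAtom, pair_sign_class
from .distance_map import (DistanceSeries, HBOND_CUTOFF, INTERACTION_CUTOFF,
                           hbond_fraction, occupancy_fraction)

DEFAULT_F_MIN = 0.05

_NodeKey = tuple[str, int, str]


def _node_key(p: ProbeAtom) -> _NodeKey:
    return p.residue_key


def node_label(key: _NodeKey) -> str:
    chain, num, name = key
    return f"{name}{num}:{chain}"


@dataclass(frozen=True)
class InteractionEdge:
    """A retained short-distance interaction between two charged residues."""

    residue_a: _NodeKey
    residue_b: _NodeKey
    occupancy_06: float      # fraction of frames with r_id < selection cutoff
    hbond_04: float          # fraction with r_id < 0.4 nm
    mean_distance: float     # nm, over all frames
    sign_class: str

    def __post_init__(self) -> None:
        if self.hbond_04 > self.occupancy_06 + 1e-12:
            raise ValueError("hbond fraction cannot exceed selection occupancy")

    @property
    def key(self) -> tuple[_NodeKey, _NodeKey]:
        return tuple(sorted((self.residue_a, self.residue_b)))  # type: ignore[return-value]


@dataclass
class ChargeNetwork:
    """Nodes = charged residues; edges = filtered interactions."""

    graph: nx.Graph
    edges: list[InteractionEdge] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def select_interactions(all_series: dict[frozenset[int], DistanceSeries] | list[DistanceSeries],
                        probes: list[ProbeAtom] | None = None,
                        f_min: float = DEFAULT_F_MIN,
                        cutoff: float = INTERACTION_CUTOFF,
                        hbond_cutoff: float = HBOND_CUTOFF) -> list[InteractionEdge]:
    """Apply the occupancy filter: keep pairs with ≥ f_min of r_id below cutoff.

    ``all_series`` is either the mapping returned by
    :func:`~chargenet.distance_map.compute_distance_series` (with ``probes``
    supplying the index space) or a plain list of series carrying their own
    pair metadata. The ≥ boundary is inclusive: occupancy exactly f_min is
    retained.
    """
    if not 0 < f_min <= 1:
        raise ValueError("f_min must be in (0, 1]")
    if isinstance(all_series, dict):
        if probes is None:
            raise ValueError("probes required when series are keyed by index")
        items = []
        for key in sorted(all_series, key=sorted):
            i, j = sorted(key)
            items.append(((probes[i], probes[j]), all_series[key]))
    else:
        items = []
        for s in all_series:
            if s.pair is None:
                raise ValueError("series without pair metadata cannot be selected")
            items.append((s.pair, s))
    edges: list[InteractionEdge] = []
    for (pa, pb), series in items:
        occ = occupancy_fraction(series, cutoff)
        if occ >= f_min:
            a, b = sorted((pa, pb), key=_node_key)
            edges.append(InteractionEdge(
                residue_a=_node_key(a),
                residue_b=_node_key(b),
                occupancy_06=occ,
                hbond_04=occupancy_fraction(series, hbond_cutoff),
                mean_distance=series.mean,
                sign_class=pair_sign_class(pa, pb),
            ))
    edges.sort(key=lambda e: e.key)
    return edges


def build_network(probes: list[ProbeAtom], edges: list[InteractionEdge],
                  depth: dict[_NodeKey, float] | None = None,
                  dssp: dict[_NodeKey, str] | None = None) -> ChargeNetwork:
    """Assemble the charge network from probes and filtered edges.

    Every probe becomes a node (including degree-0 lone charges); edge weight
    is the selection occupancy — this package's operationalisation of average
    proximity — with mean distance and hydrogen-bond fraction stored as
    secondary attributes. Depth indexes and DSSP labels annotate nodes when
    provided.
    """
    g = nx.Graph()
    for p in sorted(probes, key=_node_key):
        key = _node_key(p)
        attrs = {"sign": p.sign, "probe_atom": p.probe_atom_name,
                 "label": node_label(key)}
        if depth and key in depth:
            attrs["depth_index"] = float(depth[key])
        if dssp and key in dssp:
            attrs["dssp"] = dssp[key]
        g.add_node(key, **attrs)
    for e in edges:
        for end in (e.residue_a, e.residue_b):
            if end not in g:
                raise ValueError(f"edge endpoint {node_label(end)} is not a probe node")
        g.add_edge(e.residue_a, e.residue_b,
                   weight=e.occupancy_06, occupancy_06=e.occupancy_06,
                   hbond_04=e.hbond_04, mean_distance=e.mean_distance,
                   sign_class=e.sign_class)
    return ChargeNetwork(graph=g, edges=list(edges))


def interaction_rank(net: ChargeNetwork) -> dict[_NodeKey, int]:
    """Per-residue interaction rank = degree in the network."""
    return {n: int(d) for n, d in net.graph.degree()}


def lone_charges(net: ChargeNetwork) -> list[_NodeKey]:
    """Charged residues with no retained interaction (rank 0), sorted."""
    return sorted(n for n, d in net.graph.degree() if d == 0)


def find_patches(net: ChargeNetwork) -> list[set[_NodeKey]]:
    """Connected components over non-isolated nodes, largest first.

    Lone charges are excluded — they are reported separately, not as
    single-node patches.
    """
    sub = net.graph.subgraph(n for n, d in net.graph.degree() if d >= 1)
    comps = [set(c) for c in nx.connected_components(sub)]
    return sorted(comps, key=lambda c: (-len(c), sorted(c)))


def tally_sign_classes(net: ChargeNetwork) -> dict[str, dict[str, float]]:
    """Counts and fractions of opposite / same-sign edges."""
    counts = {"opposite": 0, "positive-positive": 0, "negative-negative": 0}
    for e in net.edges:
        counts[e.sign_class] += 1
    total = sum(counts.values())
    fractions = {k: (v / total if total else 0.0) for k, v in counts.items()}
    return {"counts": counts, "fractions": fractions, "total": total}


def edge_table(net: ChargeNetwork) -> str:
    """TSV edge report (res_i, res_j, occupancy, hbond fraction, mean r_id, class)."""
    lines = ["res_i\tres_j\toccupancy_06\thbond_04\tmean_distance_nm\tsign_class"]
    for e in sorted(net.edges, key=lambda e: e.key):
        lines.append(f"{node_label(e.residue_a)}\t{node_label(e.residue_b)}\t"
                     f"{e.occupancy_06:.6f}\t{e.hbond_04:.6f}\t"
                     f"{e.mean_distance:.6f}\t{e.sign_class}")
    return "\n".join(lines) + "\n"


def network_summary(net: ChargeNetwork) -> dict:
    """JSON-ready summary: ranks, lone charges, patches, sign-class tally."""
    ranks = interaction_rank(net)
    return {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "ranks": {node_label(k): v for k, v in sorted(ranks.items())},
        "lone_charges": [node_label(k) for k in lone_charges(net)],
        "patches": [sorted(node_label(k) for k in patch)
                    for patch in find_patches(net)],
        "sign_classes": tally_sign_classes(net),
    }


def _stringify(net: ChargeNetwork) -> nx.Graph:
    # GraphML/GEXF need scalar attribute values and hashable string node ids
    g = nx.Graph()
    for n, attrs in net.graph.nodes(data=True):
        g.add_node(node_label(n), **attrs)
    for u, v, attrs in net.graph.edges(data=True):
        g.add_edge(node_label(u), node_label(v), **attrs)
    return g


def export_graph(net: ChargeNetwork, path: str | Path, fmt: str | None = None) -> None:
    """Write the network as GraphML or GEXF (inferred from the suffix)."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    g = _stringify(net)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "gexf":
        nx.write_gexf(g, path)
    else:
        raise ValueError(f"unsupported graph format: {fmt!r} (use graphml or gexf)")


def write_summary(net: ChargeNetwork, path: str | Path) -> None:
    Path(path).write_text(json.dumps(network_summary(net), indent=2) + "\n")
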