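"""Occupancy filter, network assembly, ranks, lone charges, patches, exports."""

import itertools

import networkx as nx
import numpy as np
import pytest

from chargenet import (DistanceSeries, build_network, export_graph,
                       find_patches, interaction_rank, lone_charges,
                       select_interactions, select_probe_atoms,
                       tally_sign_classes)
from chargenet.charge_probes import PROBE_ATOMS, ProbeAtom
from chargenet.interaction_network import (InteractionEdge, network_summary,
                                           edge_table)
from chargenet.synthetic_data import (PairSpec, SyntheticSpec,
                                      generate_planted_system)
from chargenet.distance_map import compute_distance_series


def _probe(i: int, res: str = "LYS") -> ProbeAtom:
    name, sign = PROBE_ATOMS[res]
    return ProbeAtom(residue_key=("A", i, res), probe_atom_name=name,
                     sign=sign, atom_index=i)


def _series(pa, pb, values):
    return DistanceSeries(pair=(pa, pb), values=np.asarray(values, dtype=float))


def _edge(i, j, occ=0.5, res_i="LYS", res_j="GLU"):
    pa, pb = _probe(i, res_i), _probe(j, res_j)
    from chargenet import pair_sign_class
    return InteractionEdge(residue_a=pa.residue_key, residue_b=pb.residue_key,
                           occupancy_06=occ, hbond_04=occ / 2,
                           mean_distance=0.5,
                           sign_class=pair_sign_class(pa, pb))


def test_filter_boundary_is_inclusive_at_5_percent():
    """Occupancy exactly 0.05 is retained; 0.049 is dropped."""
    pa, pb = _probe(1), _probe(2, "GLU")
    exactly = np.concatenate([np.full(1, 0.3), np.full(19, 1.0)])   # 1/20
    kept = select_interactions([_series(pa, pb, exactly)])
    assert len(kept) == 1 and kept[0].occupancy_06 == pytest.approx(0.05)

    below = np.concatenate([np.full(49, 0.3), np.full(951, 1.0)])   # 0.049
    assert select_interactions([_series(pa, pb, below)]) == []


def test_planted_edges_recovered_exactly():
    """12 paired probes + 3 decoys, 5000 frames: only planted pairs pass."""
    planted = {(2 * k, 2 * k + 1):
               PairSpec.from_occupancy(0.15 + 0.1 * k, switch_rate=0.2)
               for k in range(6)}
    spec = SyntheticSpec(n_residues=15, planted=planted, n_frames=5000, seed=7)
    traj, truth = generate_planted_system(spec)
    probes, _ = select_probe_atoms(traj.frames[0])
    series = compute_distance_series(traj, probes)
    edges = select_interactions(series, probes)
    got = {tuple(sorted((e.residue_a[1] - 1, e.residue_b[1] - 1)))
           for e in edges}
    assert got == {tuple(p) for p in truth["adjacency"]}
    net = build_network(probes, edges)
    patches = find_patches(net)
    assert len(patches) == 6 and all(len(p) == 2 for p in patches)
    assert len(lone_charges(net)) == 3


def test_build_network_isolated_nodes_and_dangling_edge():
    probes = [_probe(1), _probe(2, "GLU"), _probe(3, "ASP")]
    net = build_network(probes, [])
    assert net.n_nodes == 3 and net.n_edges == 0
    assert len(lone_charges(net)) == 3
    with pytest.raises(ValueError, match="not a probe node"):
        build_network(probes[:2], [_edge(1, 99)])


def test_handshake_identity_on_random_graphs(rng):
    for _ in range(20):
        n = int(rng.integers(2, 12))
        probes = [_probe(i) for i in range(1, n + 1)]
        pairs = list(itertools.combinations(range(1, n + 1), 2))
        chosen = [pairs[i] for i in
                  rng.choice(len(pairs), size=min(len(pairs), 6), replace=False)]
        edges = [_edge(i, j, res_j="LYS") for i, j in chosen]
        net = build_network(probes, edges)
        ranks = interaction_rank(net)
        assert sum(ranks.values()) == 2 * net.n_edges


def test_star_graph_center_rank():
    k = 5
    probes = [_probe(i) for i in range(0, k + 1)]
    edges = [_edge(0, i, res_j="LYS") for i in range(1, k + 1)]
    net = build_network(probes, edges)
    assert interaction_rank(net)[("A", 0, "LYS")] == k
    assert lone_charges(net) == []


def test_lone_charge_is_the_isolated_probe():
    probes = [_probe(1), _probe(2, "GLU"), _probe(3, "ASP")]
    net = build_network(probes, [_edge(1, 2)])
    assert lone_charges(net) == [("A", 3, "ASP")]


def test_patches_toy_cases():
    probes = [_probe(i) for i in range(1, 5)]
    # two disjoint edges -> 2 patches of size 2
    net = build_network(probes, [_edge(1, 2, res_j="LYS"),
                                 _edge(3, 4, res_j="LYS")])
    assert sorted(len(p) for p in find_patches(net)) == [2, 2]
    # path of 4 -> one patch of size 4
    net = build_network(probes, [_edge(1, 2, res_j="LYS"),
                                 _edge(2, 3, res_j="LYS"),
                                 _edge(3, 4, res_j="LYS")])
    patches = find_patches(net)
    assert len(patches) == 1 and len(patches[0]) == 4


def _reachability_components(nodes, edges):
    """Brute-force transitive-closure oracle for connected components."""
    adj = {n: {n} for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    changed = True
    while changed:
        changed = False
        for n in nodes:
            new = set().union(*(adj[m] for m in adj[n]))
            if new != adj[n]:
                adj[n] = new
                changed = True
    comps = {frozenset(adj[n]) for n in nodes}
    return {c for c in comps if len(c) > 1 or _degree(edges, next(iter(c))) > 0}


def _degree(edges, n):
    return sum(n in e for e in edges)


def test_patches_match_reachability_oracle(rng):
    for trial in range(25):
        n = int(rng.integers(2, 13))
        ids = list(range(1, n + 1))
        pairs = list(itertools.combinations(ids, 2))
        m = int(rng.integers(0, min(len(pairs), 10) + 1))
        chosen = [pairs[i] for i in rng.choice(len(pairs), size=m, replace=False)]
        probes = [_probe(i) for i in ids]
        net = build_network(probes, [_edge(i, j, res_j="LYS")
                                     for i, j in chosen])
        got = {frozenset(k[1] for k in patch) for patch in find_patches(net)}
        expected = _reachability_components(ids, chosen)
        assert got == expected


def test_tally_single_opposite_edge():
    probes = [_probe(1, "LYS"), _probe(2, "GLU")]
    net = build_network(probes, [_edge(1, 2)])
    tally = tally_sign_classes(net)
    assert tally["counts"] == {"opposite": 1, "positive-positive": 0,
                               "negative-negative": 0}
    assert tally["fractions"]["opposite"] == 1.0


def test_tally_mixed_network():
    probes = ([_probe(i, "LYS") for i in range(1, 6)]
              + [_probe(i, "GLU") for i in range(6, 11)])
    edges = [_edge(i, i + 5) for i in range(1, 5)]                 # 4 opposite
    edges.append(_edge(1, 2, res_i="LYS", res_j="LYS"))            # K-K
    edges.append(_edge(6, 7, res_i="GLU", res_j="GLU"))            # E-E
    net = build_network(probes, edges)
    tally = tally_sign_classes(net)
    assert tally["counts"] == {"opposite": 4, "positive-positive": 1,
                               "negative-negative": 1}
    assert sum(tally["fractions"].values()) == pytest.approx(1.0, abs=1e-12)


def test_filter_monotone_in_fmin_and_cutoff(rng):
    probes = [_probe(i, res) for i, res in
              zip(range(1, 7), ["LYS", "GLU", "ASP", "ARG", "HIS", "GLU"])]
    all_series = []
    for i, j in itertools.combinations(range(6), 2):
        values = rng.uniform(0.2, 1.4, size=400)
        all_series.append(_series(probes[i], probes[j], values))

    def keys(f_min, cutoff):
        return {e.key for e in select_interactions(all_series, f_min=f_min,
                                                   cutoff=cutoff)}

    assert keys(0.05, 0.6) <= keys(0.03, 0.6)    # lowering f_min only adds
    assert keys(0.05, 0.6) <= keys(0.05, 0.8)    # raising cutoff only adds


def test_export_round_trip_graphml_and_gexf(tmp_path, rng):
    probes = [_probe(i, res) for i, res in
              zip(range(1, 6), ["LYS", "GLU", "ASP", "ARG", "HIS"])]
    edges = [_edge(1, 2), _edge(2, 3, res_i="GLU", res_j="ASP"), _edge(4, 5,
             res_i="ARG", res_j="HIS")]
    net = build_network(probes, edges)
    for fmt in ("graphml", "gexf"):
        path = tmp_path / f"net.{fmt}"
        export_graph(net, path)
        back = nx.read_graphml(path) if fmt == "graphml" else nx.read_gexf(path)
        assert back.number_of_nodes() == net.n_nodes
        assert back.number_of_edges() == net.n_edges
        for u, v, attrs in back.edges(data=True):
            assert float(attrs["occupancy_06"]) == pytest.approx(0.5)
            assert attrs["sign_class"] in ("opposite", "positive-positive",
                                           "negative-negative")
        signs = {int(d["sign"]) for _, d in back.nodes(data=True)}
        assert signs <= {-1, 1}


def test_export_empty_network_and_bad_format(tmp_path):
    net = build_network([_probe(1)], [])
    export_graph(net, tmp_path / "empty.graphml")
    back = nx.read_graphml(tmp_path / "empty.graphml")
    assert back.number_of_edges() == 0
    with pytest.raises(ValueError, match="unsupported"):
        export_graph(net, tmp_path / "net.dot")


def test_summary_and_edge_table():
    probes = [_probe(1), _probe(2, "GLU"), _probe(3, "ASP")]
    net = build_network(probes, [_edge(1, 2)])
    summary = network_summary(net)
    assert summary["n_nodes"] == 3 and summary["n_edges"] == 1
    assert summary["lone_charges"] == ["ASP3:A"]
    assert summary["sign_classes"]["counts"]["opposite"] == 1
    table = edge_table(net)
    assert "LYS1:A\tGLU2:A" in table


def test_edge_invariant_hbond_below_occupancy():
    with pytest.raises(ValueError):
        InteractionEdge(residue_a=("A", 1, "LYS"), residue_b=("A", 2, "GLU"),
                        occupancy_06=0.1, hbond_04=0.5, mean_distance=0.5,
                        sign_class="opposite")
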