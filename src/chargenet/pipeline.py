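"""End-to-end run: structure → probes → distance map → network → depth → motifs.

One :func:`run_pipeline` call produces the full report bundle (TSV tables,
GraphML/GEXF graphs, JSON summary and manifest) in an output directory.
Reruns with the same config and inputs are byte-identical when the grid depth
estimator is used; the manifest records config, package versions, and input
checksums so a run can be audited.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

from . import __version__
from .atom_depth import depth_profile, write_depth_table
from .charge_probes import select_probe_atoms, write_probe_table
from .distance_map import bin_distances, compute_distance_series
from .interaction_network import (build_network, edge_table, export_graph,
                                  network_summary, select_interactions,
                                  node_label, write_summary)
from .sequence_motifs import annotate_dssp, motif_table, read_dssp, \
    scan_charged_dipeptides
from .structure_io import extract_sequence, read_structure, read_trajectory

logger = logging.getLogger("chargenet")


@dataclass
class RunConfig:
    """Parameters of one pipeline run (all thresholds in nm, times in ps)."""

    trajectory: str
    structure: str | None = None      # defaults to frame 0 of the trajectory
    chains: tuple[str, ...] | None = None
    f_min: float = 0.05
    cutoff: float = 0.6
    hbond_cutoff: float = 0.4
    bin_width: float = 0.02
    bin_range: float = 2.0
    depth_radius: float = 0.9         # 1.2 nm is the coarser surface option
    estimator: str = "grid"
    grid_resolution: float = 0.05
    mc_samples: int = 100_000
    sampling_interval: float = 1.0
    dssp: str | None = None
    out_dir: str = "chargenet_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.f_min <= 1:
            raise ValueError("f_min must be in (0, 1]")
        for name in ("cutoff", "hbond_cutoff", "bin_width", "depth_radius",
                     "sampling_interval"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage and write the report bundle.

    Returns the run manifest (also written as ``manifest.json``). Any stage
    failure aborts with a stage-attributed error message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "read trajectory"
        traj = read_trajectory(config.trajectory,
                               sampling_interval=config.sampling_interval,
                               chains=config.chains)
        logger.info("trajectory: %d frames, %d atoms", len(traj),
                    len(traj.frames[0]))

        stage = "read structure"
        if config.structure:
            structure = read_structure(config.structure, chains=config.chains)
        else:
            structure = traj.frames[0]

        stage = "select probes"
        probes, missing = select_probe_atoms(structure, config.chains)
        for chain, num, name in missing:
            logger.warning("charged residue %s%d:%s lacks its probe atom; skipped",
                           name, num, chain)
        # probe indices must refer to trajectory atom order
        traj_probes, traj_missing = select_probe_atoms(traj.frames[0], config.chains)
        logger.info("probes: %d (%d missing probe atoms)", len(traj_probes),
                    len(missing) + len(traj_missing))
        write_probe_table(out / "probes.tsv", probes, missing)

        stage = "distance map"
        series = compute_distance_series(traj, traj_probes)
        logger.info("distance series: %d pairs x %d frames", len(series), len(traj))

        stage = "interaction selection"
        edges = select_interactions(series, traj_probes, f_min=config.f_min,
                                    cutoff=config.cutoff,
                                    hbond_cutoff=config.hbond_cutoff)

        stage = "depth indexes"
        depth_results = depth_profile(
            structure, probes, probe_radius=config.depth_radius,
            estimator=config.estimator, resolution=config.grid_resolution,
            n_samples=config.mc_samples, seed=config.seed,
        )
        write_depth_table(depth_results, out / "depth.tsv")
        depth_by_res = {(r.atom_key[0], r.atom_key[1], r.residue_name):
                        r.depth_index for r in depth_results}

        stage = "sequence motifs"
        dssp_map = read_dssp(config.dssp) if config.dssp else None
        hits = []
        dssp_by_res: dict = {}
        for chain in structure.chains():
            seq, numbers = extract_sequence(structure, chain)
            chain_hits = scan_charged_dipeptides(seq, numbers, chain_id=chain)
            if dssp_map is not None:
                chain_hits = annotate_dssp(chain_hits, dssp_map)
            hits.extend(chain_hits)
        if dssp_map is not None:
            for p in probes:
                label = dssp_map.get((p.chain_id, p.residue_number))
                if label is not None:
                    dssp_by_res[p.residue_key] = label
        (out / "motifs.tsv").write_text(motif_table(hits))

        stage = "network assembly"
        net = build_network(probes, edges, depth=depth_by_res,
                            dssp=dssp_by_res or None)
        (out / "edges.tsv").write_text(edge_table(net))
        export_graph(net, out / "network.graphml")
        export_graph(net, out / "network.gexf")
        write_summary(net, out / "summary.json")

        stage = "r_id profiles"
        profile_dir = out / "profiles"
        profile_dir.mkdir(exist_ok=True)
        edge_keys = {e.key for e in edges}
        for key in sorted(series, key=sorted):
            i, j = sorted(key)
            pa, pb = traj_probes[i], traj_probes[j]
            ekey = tuple(sorted((pa.residue_key, pb.residue_key)))
            if ekey not in edge_keys:
                continue
            profile = bin_distances(series[key], config.bin_width, config.bin_range)
            name = f"{node_label(ekey[0])}__{node_label(ekey[1])}.tsv".replace(":", "")
            (profile_dir / name).write_text(profile.to_tsv())
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    summary = network_summary(net)
    manifest = {
        "chargenet_version": __version__,
        "config": asdict(config),
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in (("trajectory", config.trajectory),
                            ("structure", config.structure),
                            ("dssp", config.dssp))
            if p
        },
        "n_frames": len(traj),
        "n_probes": len(probes),
        "missing_probe_atoms": [f"{name}{num}:{chain}"
                                for chain, num, name in missing],
        "n_pairs": len(series),
        "n_edges": summary["n_edges"],
        "n_patches": len(summary["patches"]),
        "n_lone_charges": len(summary["lone_charges"]),
        "sign_classes": summary["sign_classes"],
        "n_motif_hits": len(hits),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
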