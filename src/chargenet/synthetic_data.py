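"""Synthetic charge-pair dynamics with a planted interaction network.

Per-pair probe distances are emulated as a two-state (bound/unbound)
telegraph process: a Markov chain switches between a bound state (short
distances, transient-salt-bridge-like) and an unbound state, and the emitted
distance is the state mean plus Gaussian noise, truncated at 0.05 nm. The
stationary bound occupancy is p_on / (p_on + p_off), so a planted pair's
expected selection occupancy is known exactly — every pipeline stage can be
validated against ground truth without running molecular dynamics.

3D systems embed each planted pair as an isolated two-residue dimer (planted
pairs must form a matching) and each lone residue as a far-separated decoy,
inside a cubic periodic box; trajectories can be written as multi-model PDB.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .charge_probes import PROBE_ATOMS
from .distance_map import DistanceSeries
from .structure_io import NM_TO_A, Atom, Frame, Trajectory

MIN_DISTANCE = 0.05   # nm, truncation floor for emitted distances

# residue types cycled over synthetic residues (probe atom + backbone stub)
_RESIDUE_CYCLE = ("LYS", "GLU", "ASP", "ARG", "HIS")

# fixed local geometry of a synthetic residue: offsets from the probe atom, nm
_RESIDUE_TEMPLATE: tuple[tuple[str, str, tuple[float, float, float]], ...] = (
    ("N",  "N", (0.35, 0.10, 0.00)),
    ("CA", "C", (0.25, 0.00, 0.00)),
    ("C",  "C", (0.30, -0.12, 0.05)),
    ("O",  "O", (0.40, -0.15, 0.05)),
    ("CB", "C", (0.15, 0.05, 0.10)),
)


@dataclass(frozen=True)
class PairSpec:
    """Telegraph parameters for one probe pair."""

    p_on: float                 # per-frame unbound → bound probability
    p_off: float                # per-frame bound → unbound probability
    bound_mean: float = 0.35    # nm
    bound_sd: float = 0.03
    unbound_mean: float = 1.20  # nm
    unbound_sd: float = 0.15

    def __post_init__(self) -> None:
        for name in ("p_on", "p_off"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_on + self.p_off == 0:
            raise ValueError("p_on and p_off cannot both be zero")
        if not self.bound_mean < 0.6 < self.unbound_mean - 2 * self.unbound_sd:
            raise ValueError(
                "state distances must straddle the 0.6 nm cutoff: need "
                f"bound_mean < 0.6 < unbound_mean - 2*sd "
                f"(got {self.bound_mean}, {self.unbound_mean - 2 * self.unbound_sd:.3f})"
            )

    @property
    def p_bound(self) -> float:
        """Stationary bound occupancy p_on / (p_on + p_off)."""
        return self.p_on / (self.p_on + self.p_off)

    @classmethod
    def from_occupancy(cls, p_bound: float, switch_rate: float = 0.02,
                       **kwargs) -> "PairSpec":
        """Build from a target occupancy; ``switch_rate`` is p_on + p_off."""
        if not 0.0 <= p_bound <= 1.0:
            raise ValueError("p_bound must be in [0, 1]")
        if not 0 < switch_rate <= 1:
            raise ValueError("switch_rate must be in (0, 1]")
        return cls(p_on=p_bound * switch_rate, p_off=(1 - p_bound) * switch_rate,
                   **kwargs)

    def stationary_stderr(self, n_frames: int) -> float:
        """Std. error of the empirical bound fraction, autocorrelation-corrected.

        The lag-1 autocorrelation of the state sequence is
        rho = 1 - p_on - p_off; the variance of the mean of n correlated
        frames inflates by (1 + rho) / (1 - rho).
        """
        p = self.p_bound
        rho = 1.0 - self.p_on - self.p_off
        inflation = (1.0 + rho) / (1.0 - rho) if abs(1.0 - rho) > 1e-12 else np.inf
        return math.sqrt(p * (1.0 - p) / n_frames * inflation)


@dataclass
class SyntheticSpec:
    """A planted charge-interaction system.

    ``planted`` maps residue-index pairs (a matching: each residue appears in
    at most one pair) to their telegraph parameters; residues in no pair are
    decoys whose probes never approach anything.
    """

    n_residues: int
    planted: dict[tuple[int, int], PairSpec] = field(default_factory=dict)
    n_frames: int = 5000
    sampling_interval: float = 1.0    # ps
    box_edge: float | None = None     # nm; None → smallest grid that fits
    separation: float = 3.0           # nm, minimum inter-unit gap
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be ≥ 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be ≥ 1")
        seen: set[int] = set()
        for (a, b) in self.planted:
            if not (0 <= a < self.n_residues and 0 <= b < self.n_residues and a != b):
                raise ValueError(f"invalid planted pair ({a}, {b})")
            if a in seen or b in seen:
                raise ValueError("planted pairs must form a matching "
                                 f"(residue reused in ({a}, {b}))")
            seen.update((a, b))

    @property
    def adjacency(self) -> list[tuple[int, int]]:
        return sorted(tuple(sorted(p)) for p in self.planted)


def generate_state_sequence(pair: PairSpec, n_frames: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Boolean bound/unbound telegraph sequence, started from stationarity."""
    states = np.empty(n_frames, dtype=bool)
    u = rng.random(n_frames)
    states[0] = u[0] < pair.p_bound
    for t in range(1, n_frames):
        states[t] = (u[t] >= pair.p_off) if states[t - 1] else (u[t] < pair.p_on)
    return states


def generate_pair_series(pair: PairSpec, n_frames: int, seed: int = 0,
                         sampling_interval: float = 1.0) -> DistanceSeries:
    """Telegraph distance series for one pair: state mean + Gaussian noise."""
    rng = np.random.default_rng(seed)
    states = generate_state_sequence(pair, n_frames, rng)
    noise = rng.standard_normal(n_frames)
    values = np.where(states,
                      pair.bound_mean + pair.bound_sd * noise,
                      pair.unbound_mean + pair.unbound_sd * noise)
    return DistanceSeries(pair=None, values=np.maximum(values, MIN_DISTANCE),
                          sampling_interval=sampling_interval)


def _unit_extent(pairs: dict[tuple[int, int], PairSpec]) -> float:
    """Worst-case reach of a unit from its anchor: pair extension + residue size."""
    d_max = max((p.unbound_mean + 5 * p.unbound_sd for p in pairs.values()),
                default=0.0)
    return d_max + 0.5   # 0.5 nm covers the backbone-stub offsets


def _anchor_grid(n_units: int, spacing: float) -> tuple[np.ndarray, float]:
    m = max(1, math.ceil(n_units ** (1.0 / 3.0)))
    while m ** 3 < n_units:
        m += 1
    pts = []
    for ix in range(m):
        for iy in range(m):
            for iz in range(m):
                pts.append(((ix + 0.5) * spacing, (iy + 0.5) * spacing,
                            (iz + 0.5) * spacing))
    return np.array(pts[:n_units]), m * spacing


_TEMPLATE_OFFSETS = tuple((name, el, np.array(off))
                          for name, el, off in _RESIDUE_TEMPLATE)


def _residue_atoms(index: int, residue_number: int, probe_pos: np.ndarray,
                   serial_start: int) -> list[Atom]:
    res_name = _RESIDUE_CYCLE[index % len(_RESIDUE_CYCLE)]
    probe_name, _ = PROBE_ATOMS[res_name]
    atoms = []
    serial = serial_start
    for name, element, off in _TEMPLATE_OFFSETS:
        atoms.append(Atom(serial=serial, name=name, residue_name=res_name,
                          chain_id="A", residue_number=residue_number,
                          insertion_code="",
                          position=probe_pos + off, element=element))
        serial += 1
    atoms.append(Atom(serial=serial, name=probe_name, residue_name=res_name,
                      chain_id="A", residue_number=residue_number,
                      insertion_code="",
                      position=probe_pos.copy(),
                      element="N" if probe_name == "NZ" else "C"))
    return atoms


def generate_planted_system(spec: SyntheticSpec) -> tuple[Trajectory, dict]:
    """Embed the planted system in 3D and return (trajectory, ground truth).

    Each planted pair is an isolated dimer: the first residue's probe sits at
    a fixed anchor, the partner's probe at the sampled telegraph distance
    along a fixed random direction. Dimers and decoy residues occupy a cubic
    anchor grid whose spacing guarantees at least ``spec.separation`` nm
    between units even at maximal pair extension.
    """
    rng = np.random.default_rng(spec.seed)
    units: list[tuple[int, ...]] = []        # residue indices per unit
    for (a, b), pspec in sorted(spec.planted.items()):
        a, b = min(a, b), max(a, b)
        units.append((a, b))
    in_pair = {r for u in units for r in u}
    units += [(r,) for r in range(spec.n_residues) if r not in in_pair]
    units.sort(key=lambda u: u[0])

    spacing = spec.separation + 2 * _unit_extent(spec.planted)
    anchors, min_box = _anchor_grid(len(units), spacing)
    if spec.box_edge is None:
        box = min_box
    else:
        if spec.box_edge < min_box:
            raise ValueError(
                f"box too small: {len(units)} units at {spec.separation} nm "
                f"separation need a box edge ≥ {min_box:.1f} nm, "
                f"got {spec.box_edge} nm"
            )
        box = spec.box_edge

    # per-pair telegraph distance series and fixed random orientations
    pair_series: dict[tuple[int, int], np.ndarray] = {}
    pair_dirs: dict[tuple[int, int], np.ndarray] = {}
    for (a, b), pspec in sorted(spec.planted.items()):
        key = (min(a, b), max(a, b))
        states = generate_state_sequence(pspec, spec.n_frames, rng)
        noise = rng.standard_normal(spec.n_frames)
        d = np.where(states, pspec.bound_mean + pspec.bound_sd * noise,
                     pspec.unbound_mean + pspec.unbound_sd * noise)
        pair_series[key] = np.maximum(d, MIN_DISTANCE)
        v = rng.standard_normal(3)
        pair_dirs[key] = v / np.linalg.norm(v)

    # static probe positions; the second residue of each pair moves rigidly
    base_probe = np.empty((spec.n_residues, 3))
    for unit, anchor in zip(units, anchors):
        base_probe[unit[0]] = anchor
        if len(unit) == 2:
            base_probe[unit[1]] = anchor   # displaced per frame below

    frames: list[Frame] = []
    for t in range(spec.n_frames):
        probe_pos = base_probe.copy()
        for key, dists in pair_series.items():
            probe_pos[key[1]] = probe_pos[key[0]] + dists[t] * pair_dirs[key]
        atoms: list[Atom] = []
        serial = 1
        for r in range(spec.n_residues):
            res_atoms = _residue_atoms(r, r + 1, probe_pos[r], serial)
            serial += len(res_atoms)
            atoms.extend(res_atoms)
        frames.append(Frame(atoms=atoms, box=box,
                            time=t * spec.sampling_interval))
    traj = Trajectory(frames=frames, sampling_interval=spec.sampling_interval)

    truth = {
        "seed": spec.seed,
        "n_residues": spec.n_residues,
        "n_frames": spec.n_frames,
        "box_edge_nm": box,
        "adjacency": [list(p) for p in spec.adjacency],
        "p_bound": {f"{a}-{b}": spec.planted[next(k for k in spec.planted
                                                  if tuple(sorted(k)) == (a, b))].p_bound
                    for (a, b) in spec.adjacency},
        "residue_numbers": {str(r): r + 1 for r in range(spec.n_residues)},
        "residue_names": {str(r): _RESIDUE_CYCLE[r % len(_RESIDUE_CYCLE)]
                          for r in range(spec.n_residues)},
    }
    return traj, truth


def write_ground_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2) + "\n")


def write_multimodel_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file (coordinates nm → Å)."""
    st = gemmi.Structure()
    boxes = traj.boxes()
    if boxes is not None:
        if np.ptp(boxes) > 1e-9:
            raise ValueError("PDB CRYST1 cannot express per-frame boxes; "
                             "box must be constant along the trajectory")
        edge = boxes[0] * NM_TO_A
        st.cell = gemmi.UnitCell(edge, edge, edge, 90, 90, 90)
    for i, frame in enumerate(traj.frames):
        model = gemmi.Model(i + 1)
        # gemmi's add_* methods copy, so build residues and chains bottom-up
        chain_order: list[str] = []
        grouped: dict[str, list[tuple[tuple, list]]] = {}
        for a in frame.atoms:
            if a.chain_id not in grouped:
                grouped[a.chain_id] = []
                chain_order.append(a.chain_id)
            residues = grouped[a.chain_id]
            rkey = (a.residue_number, a.insertion_code, a.residue_name)
            if not residues or residues[-1][0] != rkey:
                residues.append((rkey, []))
            residues[-1][1].append(a)
        for chain_id in chain_order:
            chain = gemmi.Chain(chain_id)
            for (num, icode, res_name), res_atoms in grouped[chain_id]:
                residue = gemmi.Residue()
                residue.name = res_name
                residue.seqid = gemmi.SeqId(num, icode or " ")
                residue.het_flag = "A"
                for a in res_atoms:
                    atom = gemmi.Atom()
                    atom.name = a.name
                    atom.pos = gemmi.Position(*(a.position * NM_TO_A))
                    atom.element = gemmi.Element(a.element or a.name[:1])
                    atom.occ = 1.0
                    atom.serial = a.serial
                    residue.add_atom(atom)
                chain.add_residue(residue)
            model.add_chain(chain)
        st.add_model(model)
    st.write_pdb(str(path))


def read_spec_config(path: str | Path) -> SyntheticSpec:
    """Read a SyntheticSpec from a plain key=value config file.

    Recognised keys: n_residues, n_frames, seed, box_edge, separation,
    sampling_interval, pairs (e.g. ``0-1, 2-3``), p_bound (one value or one
    per pair), switch_rate. Lines starting with ``#`` are ignored.
    """
    kv: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        k, v = line.split("=", 1)
        kv[k.strip()] = v.strip()
    pairs = []
    if kv.get("pairs"):
        for tok in kv["pairs"].split(","):
            a, b = tok.strip().split("-")
            pairs.append((int(a), int(b)))
    p_bounds = [float(x) for x in kv.get("p_bound", "0.3").split(",")]
    if len(p_bounds) == 1:
        p_bounds *= len(pairs)
    if len(p_bounds) != len(pairs):
        raise ValueError("p_bound must give one value, or one per pair")
    switch = float(kv.get("switch_rate", "0.02"))
    planted = {p: PairSpec.from_occupancy(pb, switch)
               for p, pb in zip(pairs, p_bounds)}
    return SyntheticSpec(
        n_residues=int(kv["n_residues"]),
        planted=planted,
        n_frames=int(kv.get("n_frames", "5000")),
        sampling_interval=float(kv.get("sampling_interval", "1.0")),
        box_edge=float(kv["box_edge"]) if "box_edge" in kv else None,
        separation=float(kv.get("separation", "3.0")),
        seed=int(kv.get("seed", "0")),
    )
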