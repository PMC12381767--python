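"""Structures and trajectories from PDB files.

All coordinates are stored in nanometres; PDB files carry ångström and are
converted on read/write. A :class:`Frame` is a flat, ordered atom list (protein
ATOM records only — waters and other heteroatoms are excluded), optionally with
a cubic periodic box. A :class:`Trajectory` is an ordered frame sequence with a
uniform sampling interval, read from multi-model PDB files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np
from Bio.SeqUtils import seq1

A_TO_NM = 0.1
NM_TO_A = 10.0

_WATER_NAMES = {"HOH", "WAT", "SOL", "TIP3", "TIP4", "SPC", "DOD"}


@dataclass(frozen=True)
class Atom:
    """One protein atom. ``position`` is a length-3 array in nm."""

    serial: int
    name: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    position: np.ndarray
    element: str = ""

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """(chain_id, residue_number, insertion_code) — residue identity."""
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def atom_key(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.residue_number, self.insertion_code, self.name)


@dataclass
class Frame:
    """An ordered atom list with an optional cubic box edge (nm) and time (ps)."""

    atoms: list[Atom]
    box: float | None = None
    time: float = 0.0
    _coords: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.box is not None and not self.box > 0:
            raise ValueError(f"box edge must be positive, got {self.box}")
        keys = [a.atom_key for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen: set = set()
            dup = next(k for k in keys if k in seen or seen.add(k))
            raise ValueError(f"duplicate atom identity in frame: {dup}")

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in nm (cached)."""
        if self._coords is None:
            self._coords = np.array([a.position for a in self.atoms], dtype=float)
            if self._coords.size and not np.all(np.isfinite(self._coords)):
                raise ValueError("non-finite coordinates in frame")
        return self._coords

    def atom_index(self, chain_id: str, residue_number: int, name: str,
                   insertion_code: str = "") -> int:
        key = (chain_id, residue_number, insertion_code, name)
        for i, a in enumerate(self.atoms):
            if a.atom_key == key:
                return i
        raise KeyError(f"atom not in frame: {key}")

    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class Trajectory:
    """Ordered frame sequence with uniform sampling interval (ps)."""

    frames: list[Frame]
    sampling_interval: float = 1.0

    def __post_init__(self) -> None:
        if not self.sampling_interval > 0:
            raise ValueError("sampling_interval must be > 0")
        if not self.frames:
            raise ValueError("trajectory has no frames")
        times = [f.time for f in self.frames]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        ref = [a.atom_key for a in self.frames[0].atoms]
        for i, f in enumerate(self.frames[1:], start=1):
            if [a.atom_key for a in f.atoms] != ref:
                raise ValueError(
                    f"frame {i} atom identities differ from frame 0; "
                    "all frames of a trajectory must share one atom set"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked coordinates, nm."""
        return np.stack([f.coords for f in self.frames])

    def boxes(self) -> np.ndarray | None:
        """Per-frame cubic box edges, or None for a non-periodic trajectory."""
        boxes = [f.box for f in self.frames]
        if all(b is None for b in boxes):
            return None
        if any(b is None for b in boxes):
            raise ValueError("mixed periodic/non-periodic frames in trajectory")
        return np.array(boxes, dtype=float)


def _cubic_box_nm(cell: gemmi.UnitCell, periodic: bool) -> float | None:
    # gemmi reports a dummy 1x1x1 P1 cell when CRYST1 is absent
    if cell.a <= 1.0 and cell.b <= 1.0 and cell.c <= 1.0:
        return None
    angles_ok = all(abs(x - 90.0) < 1e-3 for x in (cell.alpha, cell.beta, cell.gamma))
    cubic = angles_ok and abs(cell.a - cell.b) < 1e-3 and abs(cell.a - cell.c) < 1e-3
    if cubic:
        return cell.a * A_TO_NM
    if periodic:
        raise ValueError(
            f"periodic treatment requested but cell is not cubic: "
            f"a,b,c = {cell.a:.2f},{cell.b:.2f},{cell.c:.2f} Å, "
            f"angles = {cell.alpha:.1f},{cell.beta:.1f},{cell.gamma:.1f}°"
        )
    return None


def _pick_altloc(atoms: Sequence[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altLoc identifier order
    return min(atoms, key=lambda a: (-a.occ, a.altloc))


def _model_to_frame(model: gemmi.Model, box: float | None, time: float,
                    chains: set[str] | None) -> Frame:
    atoms: list[Atom] = []
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        for residue in chain:
            if residue.het_flag != "A" or residue.name in _WATER_NAMES:
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in residue:
                by_name.setdefault(atom.name, []).append(atom)
            for name, variants in by_name.items():
                a = _pick_altloc(variants)
                atoms.append(Atom(
                    serial=a.serial,
                    name=name,
                    residue_name=residue.name,
                    chain_id=chain.name,
                    residue_number=residue.seqid.num,
                    insertion_code=(residue.seqid.icode or "").strip(),
                    position=np.array([a.pos.x, a.pos.y, a.pos.z]) * A_TO_NM,
                    element=a.element.name,
                ))
    return Frame(atoms=atoms, box=box, time=time)


def read_structure(path: str | Path, model_index: int = 0,
                   chains: Sequence[str] | None = None,
                   periodic: bool = False) -> Frame:
    """Read one model of a PDB file as a :class:`Frame`.

    Coordinates are converted Å → nm. HETATM records and waters are excluded;
    alternate locations are resolved to the highest-occupancy conformer. The
    box edge is taken from CRYST1 when the cell is cubic; a non-cubic cell is
    rejected only when ``periodic=True`` (otherwise the frame is non-periodic).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    if not 0 <= model_index < len(st):
        raise IndexError(f"model_index {model_index} out of range (file has {len(st)} models)")
    box = _cubic_box_nm(st.cell, periodic)
    chain_set = set(chains) if chains is not None else None
    frame = _model_to_frame(st[model_index], box, float(model_index), chain_set)
    if not frame.atoms:
        raise ValueError(f"no protein ATOM records read from {path}")
    return frame


def read_trajectory(path: str | Path, sampling_interval: float = 1.0,
                    chains: Sequence[str] | None = None,
                    periodic: bool = False) -> Trajectory:
    """Read a multi-model PDB file as a :class:`Trajectory`.

    One frame per MODEL, timestamped ``i * sampling_interval`` (ps, default
    1 ps spacing). All models must contain the same atoms in the same order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trajectory file not found: {path}")
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    box = _cubic_box_nm(st.cell, periodic)
    chain_set = set(chains) if chains is not None else None
    frames = [
        _model_to_frame(model, box, i * sampling_interval, chain_set)
        for i, model in enumerate(st)
    ]
    if not frames[0].atoms:
        raise ValueError(f"no protein ATOM records read from {path}")
    return Trajectory(frames=frames, sampling_interval=sampling_interval)


def extract_sequence(frame: Frame, chain_id: str) -> tuple[str, list[int]]:
    """One-letter sequence and residue numbers for a chain, in residue order.

    Nonstandard residues map to ``"X"``. Residues are sorted by
    (residue_number, insertion_code), so record order in the file is irrelevant.
    """
    residues: dict[tuple[int, str], str] = {}
    for a in frame.atoms:
        if a.chain_id != chain_id:
            continue
        residues.setdefault((a.residue_number, a.insertion_code), a.residue_name)
    if not residues:
        raise KeyError(f"chain {chain_id!r} not found in frame "
                       f"(chains present: {frame.chains()})")
    order = sorted(residues)
    letters = []
    for key in order:
        one = seq1(residues[key], undef_code="X")
        if len(one) != 1 or not one.isalpha():
            one = "X"
        letters.append(one.upper())
    return "".join(letters), [num for num, _ in order]
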