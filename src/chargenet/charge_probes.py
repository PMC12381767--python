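"""Charged residues and their representative probe atoms.

Each charged side chain is represented by a single probe atom standing in for
its charge position: NZ (Lys), CD (Glu), CG (Asp), CZ (Arg), CE1 (His).
Histidine is treated as always positively charged — a deliberate
simplification; no protonation-state inference is attempted. Backbone termini
are never probes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .structure_io import Frame

#: residue → (probe atom name, charge sign)
PROBE_ATOMS: dict[str, tuple[str, int]] = {
    "LYS": ("NZ", +1),
    "ARG": ("CZ", +1),
    "HIS": ("CE1", +1),
    "GLU": ("CD", -1),
    "ASP": ("CG", -1),
}

#: force-field naming dialects normalised to the canonical residue name
RESIDUE_ALIASES: dict[str, str] = {
    "HID": "HIS", "HIE": "HIS", "HIP": "HIS", "HSD": "HIS", "HSE": "HIS",
    "HSP": "HIS",
    "LYN": "LYS", "LYSH": "LYS",
    "GLH": "GLU", "GLUH": "GLU",
    "ASH": "ASP", "ASPH": "ASP",
    "ARN": "ARG",
    "CYX": "CYS",
}

SIGN_CLASSES = ("opposite", "positive-positive", "negative-negative")


def normalize_residue_name(name: str) -> str:
    name = name.strip().upper()
    return RESIDUE_ALIASES.get(name, name)


@dataclass(frozen=True)
class ProbeAtom:
    """The representative charge-position atom of one charged residue."""

    residue_key: tuple[str, int, str]   # (chain, residue number, residue name)
    probe_atom_name: str
    sign: int
    atom_index: int                     # index into the Frame atom list

    @property
    def chain_id(self) -> str:
        return self.residue_key[0]

    @property
    def residue_number(self) -> int:
        return self.residue_key[1]

    @property
    def residue_name(self) -> str:
        return self.residue_key[2]

    @property
    def label(self) -> str:
        return f"{self.residue_name}{self.residue_number}:{self.chain_id}"


def select_probe_atoms(frame: Frame, chains: Iterable[str] | None = None
                       ) -> tuple[list[ProbeAtom], list[tuple[str, int, str]]]:
    """Select one probe atom per charged residue in the given chains.

    Returns ``(probes, missing)`` where ``missing`` lists charged residues
    whose probe atom is absent from the frame (reported, never silently
    dropped). Order follows (chain, residue number, insertion code).
    """
    chain_set = set(chains) if chains is not None else None
    charged: dict[tuple[str, int, str], str] = {}
    atom_lookup: dict[tuple[str, int, str, str], int] = {}
    for i, a in enumerate(frame.atoms):
        if chain_set is not None and a.chain_id not in chain_set:
            continue
        canon = normalize_residue_name(a.residue_name)
        key = (a.chain_id, a.residue_number, a.insertion_code)
        if canon in PROBE_ATOMS:
            charged.setdefault(key, canon)
            atom_lookup[key + (a.name,)] = i
    probes: list[ProbeAtom] = []
    missing: list[tuple[str, int, str]] = []
    for key in sorted(charged):
        canon = charged[key]
        probe_name, sign = PROBE_ATOMS[canon]
        idx = atom_lookup.get(key + (probe_name,))
        if idx is None:
            missing.append((key[0], key[1], canon))
            continue
        probes.append(ProbeAtom(
            residue_key=(key[0], key[1], canon),
            probe_atom_name=probe_name,
            sign=sign,
            atom_index=idx,
        ))
    return probes, missing


def pair_sign_class(a: ProbeAtom, b: ProbeAtom) -> str:
    """Classify a probe pair as opposite / positive-positive / negative-negative."""
    if a.sign * b.sign < 0:
        return "opposite"
    return "positive-positive" if a.sign > 0 else "negative-negative"


def probe_table(probes: list[ProbeAtom], missing: list[tuple[str, int, str]] | None = None
                ) -> str:
    """TSV report of probes (chain, residue number/name, probe atom, sign)."""
    lines = ["chain\tresidue_number\tresidue_name\tprobe_atom\tsign"]
    for p in probes:
        lines.append(f"{p.chain_id}\t{p.residue_number}\t{p.residue_name}\t"
                     f"{p.probe_atom_name}\t{p.sign:+d}")
    for chain, num, name in missing or []:
        lines.append(f"{chain}\t{num}\t{name}\t<missing>\t0")
    return "\n".join(lines) + "\n"


def write_probe_table(path: str | Path, probes: list[ProbeAtom],
                      missing: list[tuple[str, int, str]] | None = None) -> None:
    Path(path).write_text(probe_table(probes, missing))
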