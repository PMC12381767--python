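"""Shared fixtures: in-memory structure builders and synthetic DSSP files."""

from __future__ import annotations

import numpy as np
import pytest

from chargenet.charge_probes import PROBE_ATOMS
from chargenet.structure_io import Atom, Frame

ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def make_atom(name: str, pos, residue_name: str = "GLY", chain: str = "A",
              resnum: int = 1, serial: int = 1, icode: str = "",
              element: str = "") -> Atom:
    return Atom(serial=serial, name=name, residue_name=residue_name,
                chain_id=chain, residue_number=resnum, insertion_code=icode,
                position=np.asarray(pos, dtype=float),
                element=element or name[:1])


def frame_from_sequence(seq: str, chain: str = "A", numbers=None,
                        spacing: float = 0.5) -> Frame:
    """Synthetic linear-chain frame for a one-letter sequence.

    Coordinates are invented (residues 'spacing' nm apart along x); each
    residue gets a CA and, if charged, its probe atom. Sequence-level
    results (probe counts, composition, motifs) are exact; 3D geometry is
    a stand-in.
    """
    if numbers is None:
        numbers = list(range(1, len(seq) + 1))
    atoms = []
    serial = 1
    for i, (aa, num) in enumerate(zip(seq.upper(), numbers)):
        res = ONE_TO_THREE.get(aa, "UNK")
        x = i * spacing
        atoms.append(make_atom("CA", (x, 0.0, 0.0), res, chain, num, serial,
                               element="C"))
        serial += 1
        if res in PROBE_ATOMS:
            probe_name, _ = PROBE_ATOMS[res]
            atoms.append(make_atom(probe_name, (x, 0.3, 0.0), res, chain, num,
                                   serial,
                                   element="N" if probe_name == "NZ" else "C"))
            serial += 1
    return Frame(atoms=atoms)


def dssp_classic_line(idx: int, resnum: int, chain: str, aa: str, ss: str) -> str:
    """One data line of classic DSSP output (fixed columns)."""
    line = [" "] * 120
    line[0:5] = f"{idx:5d}"
    line[5:10] = f"{resnum:5d}"
    line[11] = chain
    line[13] = aa
    line[16] = ss if ss.strip() else " "
    line[34:38] = f"{0:4d}"
    # four hydrogen-bond (relidx, energy) fields at their fixed offsets
    line[38:45] = f"{0:7d}"
    for start, width in ((50, 6), (61, 6), (72, 6)):
        line[start:start + width] = f"{0:{width}d}"
    for comma in (45, 56, 67, 78):
        line[comma] = ","
    for start in (46, 57, 68, 79):
        line[start:start + 4] = f"{0.0:4.1f}"
    line[103:109] = f"{360.0:6.1f}"
    line[109:115] = f"{360.0:6.1f}"
    return "".join(line)


def dssp_classic_text(entries) -> str:
    """Synthetic classic-layout DSSP file for (chain, resnum, aa, ss) entries."""
    header = [
        "==== Secondary Structure Definition by the program DSSP ====",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
        "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA",
    ]
    lines = [dssp_classic_line(i + 1, resnum, chain, aa, ss)
             for i, (chain, resnum, aa, ss) in enumerate(entries)]
    return "\n".join(header + lines) + "\n"


def dssp_mmcif_text(entries) -> str:
    """Synthetic mmCIF-layout DSSP file for (chain, resnum, ss) entries."""
    rows = "\n".join(f"x {chain} {resnum} {ss if ss.strip() else '.'}"
                     for chain, resnum, ss in entries)
    return (
        "data_synthetic_dssp\n"
        "loop_\n"
        "_dssp_struct_summary.entry_id\n"
        "_dssp_struct_summary.label_asym_id\n"
        "_dssp_struct_summary.label_seq_id\n"
        "_dssp_struct_summary.secondary_structure\n"
        f"{rows}\n"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
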