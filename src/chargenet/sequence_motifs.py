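"""Charged-dipeptide motif scanning and charged-residue composition.

Adjacent charged residues in sequence (KE, EK, KK, EE, DR, …) place two
charge-bearing side chains next to each other and are the sequence-level
signature of the short-distance charge approaches the dynamics analysis
measures in space. Adjacency requires consecutive residue numbering — a gap
in a crystal structure must not create false sequence neighbours. Secondary
structure comes from precomputed DSSP output only (classic text layout or the
mmCIF layout); residues absent from the DSSP file are labelled "N/A".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi.cif
from Bio import SeqIO
from Bio.PDB.DSSP import make_dssp_dict

CHARGED_ONE_LETTER = {"D": -1, "E": -1, "H": +1, "K": +1, "R": +1}

NOT_ASSIGNED = "N/A"


@dataclass(frozen=True)
class MotifHit:
    """Two sequence-adjacent charged residues."""

    positions: tuple[int, int]        # residue numbers (i, i+1)
    dipeptide: str                    # e.g. "KE"
    sign_class: str                   # opposite | same-positive | same-negative
    chain_id: str = ""
    dssp_labels: tuple[str, str] | None = None


def _classify(a: str, b: str) -> str:
    sa, sb = CHARGED_ONE_LETTER[a], CHARGED_ONE_LETTER[b]
    if sa * sb < 0:
        return "opposite"
    return "same-positive" if sa > 0 else "same-negative"


def scan_charged_dipeptides(sequence: str, numbers: list[int] | None = None,
                            chain_id: str = "") -> list[MotifHit]:
    """All overlapping length-2 windows whose residues are both charged.

    ``numbers`` gives the residue number of each sequence position (defaults
    to 1..n); windows spanning a numbering gap are not adjacent and yield no
    hit. Overlapping hits are allowed ("KEK" gives KE and EK).
    """
    sequence = sequence.upper()
    if numbers is None:
        numbers = list(range(1, len(sequence) + 1))
    if len(numbers) != len(sequence):
        raise ValueError("numbers must align with the sequence")
    hits: list[MotifHit] = []
    for i in range(len(sequence) - 1):
        a, b = sequence[i], sequence[i + 1]
        if a in CHARGED_ONE_LETTER and b in CHARGED_ONE_LETTER \
                and numbers[i + 1] == numbers[i] + 1:
            hits.append(MotifHit(
                positions=(numbers[i], numbers[i + 1]),
                dipeptide=a + b,
                sign_class=_classify(a, b),
                chain_id=chain_id,
            ))
    return hits


def charged_composition(sequence: str) -> dict[str, int]:
    """Counts of D/E/H/K/R in a one-letter sequence, plus the total."""
    sequence = sequence.upper()
    counts = {aa: sequence.count(aa) for aa in sorted(CHARGED_ONE_LETTER)}
    counts["total"] = sum(counts.values())
    return counts


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by record id (FASTA alternative to structure input)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- DSSP input

def _read_dssp_mmcif(path: Path) -> dict[tuple[str, int], str]:
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    table = block.find("_dssp_struct_summary.",
                       ["label_asym_id", "label_seq_id", "secondary_structure"])
    if len(table) == 0:
        raise ValueError(f"{path}: no _dssp_struct_summary records")
    out: dict[tuple[str, int], str] = {}
    for row in table:
        chain, seq, ss = row[0], row[1], row[2]
        if seq in (".", "?"):
            continue
        ss = "" if ss in (".", "?") else ss
        out[(chain, int(seq))] = ss or " "
    return out


def read_dssp(path: str | Path) -> dict[tuple[str, int], str]:
    """Parse precomputed DSSP output into {(chain, residue number): SS code}.

    Both the classic fixed-column layout and the mmCIF layout are accepted;
    DSSP is never computed here. The code " " (loop/irregular) is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"DSSP file not found: {path}")
    head = path.read_text(errors="replace")[:4096]
    if head.lstrip().startswith("data_") or "_dssp_struct_summary" in head:
        return _read_dssp_mmcif(path)
    try:
        dssp_dict, _ = make_dssp_dict(str(path))
    except Exception as exc:
        raise ValueError(f"malformed DSSP file {path}: {exc}") from exc
    out: dict[tuple[str, int], str] = {}
    for (chain, res_id), fields in dssp_dict.items():
        hetflag, resnum, icode = res_id
        out[(chain, resnum)] = fields[1]
    if not out:
        raise ValueError(f"malformed DSSP file {path}: no residue records found")
    return out


def annotate_dssp(hits: list[MotifHit], dssp: dict[tuple[str, int], str] | str | Path
                  ) -> list[MotifHit]:
    """Attach per-residue DSSP labels to motif hits (unmatched → "N/A")."""
    if not isinstance(dssp, dict):
        dssp = read_dssp(dssp)
    out = []
    for h in hits:
        labels = tuple(
            dssp.get((h.chain_id, pos), NOT_ASSIGNED) for pos in h.positions
        )
        out.append(MotifHit(positions=h.positions, dipeptide=h.dipeptide,
                            sign_class=h.sign_class, chain_id=h.chain_id,
                            dssp_labels=labels))  # type: ignore[arg-type]
    return out


def motif_table(hits: list[MotifHit]) -> str:
    """TSV motif report."""
    lines = ["chain\tpos_i\tpos_j\tdipeptide\tsign_class\tdssp_i\tdssp_j"]
    for h in hits:
        di, dj = h.dssp_labels if h.dssp_labels else (NOT_ASSIGNED, NOT_ASSIGNED)
        lines.append(f"{h.chain_id}\t{h.positions[0]}\t{h.positions[1]}\t"
                     f"{h.dipeptide}\t{h.sign_class}\t{di}\t{dj}")
    return "\n".join(lines) + "\n"
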