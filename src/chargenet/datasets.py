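"""Small built-in reference sequences.

Only sequence-level references are bundled; structure and trajectory files
are user-supplied inputs.
"""

from __future__ import annotations

#: Canonical human ubiquitin, the 76-residue repeat unit of UniProt P0CG48.
HUMAN_UBIQUITIN = (
    "MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYN"
    "IQKESTLHLVLRLRGG"
)


def human_ubiquitin() -> tuple[str, list[int]]:
    """The human ubiquitin sequence with residue numbers 1..76."""
    seq = HUMAN_UBIQUITIN
    return seq, list(range(1, len(seq) + 1))
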