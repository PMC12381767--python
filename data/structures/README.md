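# User-supplied structure inputs

Place reference PDB coordinate files here to enable the structure-dependent
checks and examples, e.g.

    data/structures/1UBQ.pdb   # human ubiquitin crystal structure
    data/structures/3NSM.pdb   # Ostrinia furnacalis chitinolytic enzyme

This repository does not redistribute PDB entries; download them from a PDB
mirror (`https://files.rcsb.org/download/<ID>.pdb`). All sequence-level
results and the synthetic-system validation run without any files here.
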