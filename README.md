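# chargenet

Charge-proximity network analysis for protein dynamics.

Charged side chains (Asp, Glu, His, Lys, Arg) dominate a protein's surface
electrostatics, and because they reorient on picosecond–nanosecond time
scales, the charge pattern a protein presents to its neighbours is a dynamic
quantity. `chargenet` turns a structure plus trajectory into that pattern's
summary: which charges transiently pair, which never approach any other
charge, and how the pairings organise into concerted groups. It is aimed at
structural bioinformaticians analysing MD output (multi-model PDB
trajectories or per-pair distance files) and at anyone who wants the same
machinery validated end-to-end on synthetic ground truth.

## The analysis

Each charged residue is reduced to one **probe atom** standing in for its
charge position — NZ (Lys), CZ (Arg), CE1 (His), CD (Glu), CG (Asp); His is
treated as always protonated. For every probe pair the inter-probe distance
`r_id` is tracked along the trajectory (minimum-image in a cubic periodic
box). A pair is a retained **interaction** when

    occupancy = #frames(r_id < 0.6 nm) / #frames  >=  5%   (inclusive)

with `r_id < 0.4 nm` reported per edge as a hydrogen-bond proximity proxy.
The resulting **charge-interaction network** (nodes = all charged residues,
edge weight = occupancy) yields each residue's interaction **rank** (degree),
the **lone charges** (rank 0), the **patches** (connected components of
non-isolated nodes), and the opposite/same-sign edge tally. Probe burial is
annotated with an exposed-volume **depth index** `D = 2·V_exposed/V_sphere`
(probing sphere 0.9 nm by default; 2 = fully exposed, →0 = buried), and
sequences are scanned for **charged dipeptides** (adjacent charged residues,
e.g. KE/EK), optionally annotated with precomputed DSSP labels. A telegraph
(two-state Markov) generator plants interaction networks with known
occupancies so every stage is testable without running MD. Details and all
numerical conventions: [docs/methods.md](docs/methods.md).

## Worked example

Recover a planted network from a synthetic trajectory
(`python examples/01_planted_network.py`):

```
trajectory: 5000 frames, box 23.7 nm
planted pairs: [[0, 1], [2, 3], [4, 5], [6, 7], [8, 9], [10, 11]]
recovered edges (6):
  LYS1:A -- GLU2:A  occupancy 0.117  hbond 0.113  <r_id> 1.10 nm  [opposite]
  ASP3:A -- ARG4:A  occupancy 0.200  hbond 0.191  <r_id> 1.03 nm  [opposite]
  ...
lone charges: ['ASP13:A', 'ARG14:A', 'HIS15:A']
sign classes: {'opposite': 3, 'positive-positive': 2, 'negative-negative': 1}
```

All six planted pairs — and nothing else — pass the 5%/0.6 nm filter; each
edge's occupancy estimates its pair's planted bound fraction, and the three
decoy residues come out as lone charges.

Sequence-level analysis of human ubiquitin
(`python examples/02_sequence_motifs.py`):

```
human ubiquitin: 76 residues
charged composition: D: 5, E: 6, H: 1, K: 7, R: 4 (total 23)
charged dipeptides (4):
  DK at 32-33  [opposite]
  KE at 33-34  [opposite]
  ED at 51-52  [same-negative]
  KE at 63-64  [opposite]
KE/EK motifs: 2 (KE33, KE63)
```

Of ubiquitin's 76 residues, 23 carry charged side chains, and the
lysine–glutamate dipole motif occurs exactly twice (K33E34, K63E64).

Other examples: `03_depth_index.py` (burial limits: isolated atom D ≈ 2,
flat surface ≈ 1, buried ≈ 0; grid vs Monte Carlo estimators) and
`04_telegraph_series.py` (occupancy calibration against the stationary bound
fraction, with autocorrelation-corrected standard errors).

## Command line

A thin CLI wraps the library for shell use:

```sh
chargenet run --trajectory traj.pdb --out results/      # full pipeline
chargenet probes --structure protein.pdb                # probe-atom table
chargenet network --trajectory traj.pdb --fmin 0.05 --cutoff 0.6
chargenet depth --structure protein.pdb --depth-radius 0.9
chargenet motifs --fasta seqs.fasta
chargenet synth --config system.cfg --out synthetic     # planted generator
```

`run` writes probe/edge/depth/motif TSV tables, GraphML + GEXF graphs,
per-edge binned r_id profiles, a JSON summary and a manifest with input
checksums; reruns are byte-identical under the grid depth estimator.

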