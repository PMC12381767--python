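# Methods

## The model

Charged amino-acid side chains (Asp, Glu, His, Lys, Arg) dominate the
electrostatic character of a protein surface, and their fast reorientation
makes the local charge distribution a dynamic quantity that static structures
cannot capture. This package quantifies that dynamics from a trajectory by
tracking, for every pair of charged residues, the internuclear distance
`r_id` between two *probe atoms* — one representative side-chain atom that
stands in for each residue's charge position:

| residue | probe atom | sign |
|---------|-----------|------|
| Lys     | NZ        | +1   |
| Arg     | CZ        | +1   |
| His     | CE1       | +1   |
| Glu     | CD        | −1   |
| Asp     | CG        | −1   |

Histidine is treated as always positively charged. This is a deliberate
simplification — no pKa or protonation-state inference is attempted — and it
makes the sign classification of every pair (opposite, positive–positive,
negative–negative) unambiguous. Backbone termini are never probes: the
analysis concerns side chains only.

### Distance series and the interaction filter

For a trajectory of `T` frames sampled at a uniform interval (1 ps by
default), the full symmetric matrix of probe–probe distances is computed per
frame. When the system carries a cubic periodic box, the minimum-image
convention applies: each displacement component is wrapped to `[-L/2, L/2)`.
Non-cubic cells are rejected for periodic analysis rather than approximated;
structures without a meaningful cell are treated as non-periodic.

A pair becomes an *interaction* when its occupancy fraction — the fraction
of frames with `r_id` strictly below 0.6 nm — is at least 5%. Both
constants are exposed (`cutoff`, `f_min`) but the defaults are the analysis
definition, not tuning knobs. The 5% boundary is **inclusive** (occupancy
exactly 0.05 is retained); the comparison at the distance cutoff is
**strict** (`r_id < 0.6`), so boundary distances do not count. A second
fixed threshold, `r_id < 0.4 nm`, is reported per edge as a proxy for
transient hydrogen bonding between the charged moieties; it is a pure
distance criterion, with no donor–H–acceptor geometry.

The occupancy filter is applied to the raw per-frame distances. Binned
`r_id` profiles (0.02 nm bins over [0, 2.0) nm, with an overflow count so
frame totals are conserved) are produced for display and inspection, not for
selection.

### The charge-interaction network

Nodes are *all* charged residues with a resolvable probe atom — including
those that pass no filter. Edges are the retained interactions, weighted by
their 0.6 nm occupancy (this package's operationalisation of "average
proximity"; the mean distance and the 0.4 nm fraction are carried as
secondary attributes so either can drive a visualisation). Derived results:

- **rank** — a residue's degree: how many distinct charges it approaches;
- **lone charges** — rank-0 residues: charges that never come near another
  charge, which in functional proteins often flags residues whose constant
  electric environment is functionally required (active-site or
  binding-site residues);
- **patches** — connected components over the non-isolated nodes,
  interpreted as groups of charges whose short-distance approaches are
  concerted; lone charges are reported separately, never as one-node
  patches;
- **sign-class tally** — counts and fractions of opposite and same-sign
  edges.

Node and edge ordering is deterministic (residues by chain and number,
edges lexicographic), so GraphML/GEXF/TSV/JSON exports are byte-stable.

### Atom depth index

Burial of each probe atom is measured with an exposed-volume depth index:

    D_i = 2 · V_exposed / V_sphere

for a probing sphere of radius `r_p` centred on the atom, where `V_exposed`
is the part of the sphere not occupied by protein atoms modelled as hard
spheres with element van der Waals radii (C 0.170, N 0.155, O 0.152,
S 0.180 nm; hydrogens excluded, as crystal structures generally lack them).
`D = 2` is an isolated atom, `D ≈ 1` an atom flush with a flat surface,
`D → 0` a deeply buried one. The default probe radius is 0.9 nm; 1.2 nm
gives a coarser, surface-scale view.

By default the atom's **own** vdW sphere counts as occupied volume, which is
recorded in the result metadata; the alternative convention (own sphere
ignored) is available and makes the isolated-atom limit exact at any probe
radius. With the default and `r_p = 0.9` nm, the own-sphere term is below
1%, so the two conventions differ negligibly at the radii used here.

Two estimators are provided. The grid estimator counts cubic-lattice points
(0.05 nm spacing by default) inside the probe sphere and is fully
deterministic — identical inputs give bitwise-identical results. The Monte
Carlo estimator draws uniform points in the ball (10⁵ by default) and is
reproducible under a seed; its standard error on `D` is
`2·sqrt(f(1−f)/n)`. The two agree within their stated tolerances on random
clusters, which is tested. Depth is computed on a single designated frame
(the input structure by default), not averaged over the trajectory.

Because published depth values depend on the exact radius set and estimator
of the implementation that produced them, agreement with third-party depth
tables should be expected only within about ±0.1, while relative orderings
(which probe is the most buried) are robust.

### Sequence motifs

Charged dipeptides — adjacent residues both carrying charged side chains —
are scanned over every overlapping length-2 window. Adjacency requires
consecutive residue numbering, so chain breaks in a crystal structure never
create false neighbours; overlapping hits are allowed ("KEK" yields KE and
EK). The charged composition (counts of D/E/H/K/R) is reported alongside.
Secondary structure is taken from **precomputed** DSSP output only — both
the classic fixed-column layout and the mmCIF (`_dssp_struct_summary`)
layout are parsed — and residues absent from the DSSP file are labelled
"N/A". DSSP is never computed by this package; only synthetic fixtures
exercise the parsers in the test suite.

## The synthetic generator

Real charge-pair dynamics show bimodal bound/unbound behaviour: long dwells
near salt-bridge contact distances interrupted by excursions. The generator
emulates exactly this and nothing more: a two-state Markov (telegraph)
chain with per-frame switching probabilities `p_on` (unbound→bound) and
`p_off`, started from its stationary distribution, emits
`distance = state mean + Gaussian noise`, truncated at 0.05 nm. The
stationary occupancy is `p_bound = p_on/(p_on+p_off)`, so the expected
selection occupancy of a planted pair is known in closed form. Defaults:
bound state 0.35 ± 0.03 nm (salt-bridge scale, inside both the 0.6 nm and
0.4 nm thresholds), unbound 1.20 ± 0.15 nm (safely outside), 5000 frames at
1 ps — a desk-scale 5 ns window chosen so that a planted pair with
`p_bound ≥ 0.15` clears the 5% filter by many corrected standard errors
while decoys cannot pass at all.

Because consecutive frames are correlated (lag-1 autocorrelation
`ρ = 1 − p_on − p_off`), the standard error of an empirical occupancy is
inflated by `sqrt((1+ρ)/(1−ρ))`; `PairSpec.stationary_stderr` applies this
correction and all calibration tests use it.

For 3D systems, planted pairs must form a matching (each residue in at most
one pair). Each pair is embedded as an isolated dimer — first probe fixed at
an anchor, partner placed at the sampled distance along a fixed random
direction — and dimers/decoys occupy a cubic anchor grid whose spacing
guarantees at least 3 nm between units even at maximal pair extension, inside
a cubic periodic box. Each synthetic residue carries a minimal backbone stub
plus its probe atom, so probe selection, PDB round-tripping and depth
computation all run on generator output. The matching restriction is a
design choice: exact 3D embedding of arbitrary correlated distance networks
is infeasible, and a matching keeps the ground truth exact; multi-partner
hubs are exercised at the distance-series level instead.

What the generator does **not** emulate: force-field physics, solvent,
correlated multi-body motions, backbone flexibility, and realistic protein
packing. Passing the planted-recovery tests therefore demonstrates that the
filter, network assembly and bookkeeping are correct under known dynamics —
not that any particular biological protein will show a particular network.

## Numerical and design choices

- Internal length unit is nm everywhere; PDB I/O converts from/to Å.
  Multi-model PDB writing keeps coordinates to 0.001 Å, so write→read
  round trips preserve inter-atom distances to ≤ 2×10⁻⁴ nm.
- Alternate locations resolve to the highest-occupancy conformer, ties
  broken by altLoc identifier order; insertion codes are part of residue
  identity; HETATM records and waters are excluded throughout.
- Force-field residue-name dialects (HID/HIE/HIP/HSD/…) normalise to their
  canonical names before probe selection.
- Charged residues whose probe atom is missing from the coordinates are
  reported explicitly, never silently dropped.
- The minimum-image computation is validated against a 27-periodic-image
  brute-force oracle (agreement ≤ 10⁻¹² nm) and against MDAnalysis'
  periodic distance routine; patch decomposition is validated against a
  transitive-closure reachability oracle.
- The selection boundary is inclusive at `f_min` because the analysis
  definition reads "at least 5%"; a strict reading ("more than 5%") differs
  only for occupancies exactly on the boundary and is available by passing
  a marginally larger `f_min`.
- Pipeline runs are deterministic: with the grid depth estimator, identical
  config and inputs produce byte-identical reports (tested), and the run
  manifest records config, package version and input SHA-256 checksums.

## Problem sizes

The validation suite uses desk-scale problems chosen to make every
statistical assertion sharp under the corrected standard errors: planted
systems of 15 residues (6 dimers + 3 decoys) over 5000 frames, recovery
measured over 50 seeded replicates; occupancy calibration at 10⁵ frames;
oracle comparisons at ≤ 10 probes × ≤ 50 frames (exhaustive) and graphs of
≤ 12 nodes. `scripts/acceptance.py` recomputes the same quantities from
scratch at these sizes, plus the sequence-level human-ubiquitin counts.

## Limitations

- Checks that require the 1UBQ or 3NSM crystal coordinates read
  user-supplied files from `data/structures/` (PDB entries are not
  redistributed); without them those checks fail with an explicit message.
- Hydrogen-bond proximity is a pure distance criterion; orientation-aware
  geometry is out of scope.
- Depth indexes are computed on one frame, not MD-averaged.
- Binary trajectory formats (XTC/DCD) are not read; multi-model PDB and
  XVG-style two-column series are the supported inputs.
- Patches are plain connected components; no finer community structure is
  inferred.
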