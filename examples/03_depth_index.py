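"""Exposed-volume depth index: limits and burial ordering.

D = 2*V_exposed/V_sphere for a 0.9 nm probing sphere: an isolated atom
reads ~2, an atom on a flat wall of packed atoms ~1, a buried atom -> 0.
"""

import numpy as np

from chargenet import depth_index
from chargenet.structure_io import Atom, Frame


def atom(name, pos, res="GLY", num=1, serial=1, element="C"):
    return Atom(serial=serial, name=name, residue_name=res, chain_id="A",
                residue_number=num, insertion_code="",
                position=np.asarray(pos, float), element=element)


# isolated atom: fully exposed
lone = Frame(atoms=[atom("NZ", (0, 0, 0), "LYS", element="N")])
d = depth_index(lone, 0, probe_radius=0.9)
print(f"isolated atom: D = {d.depth_index:.3f} (expected ~2)")

# atom at the surface of a tightly packed half-space: half the sphere filled
s = 0.06
grid = np.arange(-1.02, 1.02 + s / 2, s)
zs = np.arange(-1.02, -0.17 + s / 2, s)
wall = [(x, y, z) for x in grid for y in grid for z in zs
        if x * x + y * y + z * z <= 1.12 ** 2]
atoms = [atom("CA", c, num=i + 1, serial=i + 1) for i, c in enumerate(wall)]
atoms.append(atom("NZ", (0, 0, 0), "LYS", num=len(wall) + 1,
                  serial=len(wall) + 1, element="N"))
d = depth_index(Frame(atoms=atoms), len(wall), probe_radius=0.9,
                resolution=0.04)
print(f"surface atom on a wall: D = {d.depth_index:.3f} (expected ~1)")

# atom in the middle of a dense cluster: buried
grid = np.arange(-1.2, 1.2 + 0.06, 0.12)
cluster = [(x, y, z) for x in grid for y in grid for z in grid]
centre = int(np.argmin(np.linalg.norm(np.array(cluster), axis=1)))
frame = Frame(atoms=[atom("CA", c, num=i + 1, serial=i + 1)
                     for i, c in enumerate(cluster)])
d = depth_index(frame, centre, probe_radius=0.9)
print(f"buried atom in a cluster: D = {d.depth_index:.3f} (expected ~0)")

# grid vs Monte Carlo estimator on the same input
g = depth_index(lone, 0, probe_radius=0.9, estimator="grid")
m = depth_index(lone, 0, probe_radius=0.9, estimator="monte-carlo",
                n_samples=50_000, seed=0)
print(f"estimators on the isolated atom: grid {g.depth_index:.3f}, "
      f"monte-carlo {m.depth_index:.3f}")
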