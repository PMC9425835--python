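"""Enumerate the cluster states a 6 x 6 torus admits.

Every pair of phase steps (psi_h, psi_v) with psi_h a multiple of
2pi/p_h (p_h dividing the number of columns, winding coprime) and
likewise vertically is a phase-locked state; it splits the lattice into
p = lcm(p_h, p_v) equal clusters of synchronously firing cells.
"""

import numpy as np

import phaselattice as pl
from phaselattice import ClusterSolution, TorusLattice

lat = TorusLattice(6, 6)
sols = pl.enumerate_solutions(6, 6)
print(f"{len(sols)} cluster solutions on the 6x6 torus "
      "(6 admissible steps per direction)\n")
print("psi_h/pi  psi_v/pi   p   type")
for s in sols:
    kind = ("synchronous" if s.p == 1
            else "horizontal stripes" if s.psi_h == 0
            else "vertical stripes" if s.psi_v == 0
            else "diagonal stripes" if s.p_h == s.p_v
            else f"({s.p_h}, {s.p_v}) mixed")
    print(f"{s.psi_h / np.pi:8.3f} {s.psi_v / np.pi:8.3f} {s.p:4d}   {kind}")

# the (2, 3) six-cluster state: 2 clusters across rows, 3 down columns
sol = ClusterSolution(2, 1, 3, 1)
field = pl.phase_field(sol, lat)
groups = pl.cluster_partition(field)
print(f"\n(2, 3) solution: {len(groups)} clusters of {len(groups[0])} cells each")
print("phase field / pi:")
print(np.round(field.phases / np.pi, 2))
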