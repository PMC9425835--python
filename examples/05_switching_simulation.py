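"""Switch a 4 x 4 inhibitory network between coexisting cluster states.

With 8-neighbor coupling the 4 x 4 network has four coexisting stable
states.  A strong transient current pulse to a subset of cells acts as
a state switch: here the 2-cluster horizontal stripe is driven into the
alternating-phase 4-cluster state, mirroring how transient input can
re-select a neural assembly.  (~30 s of compute.)
"""

import numpy as np

import phaselattice as pl
from phaselattice import ClusterSolution, CouplingWeights, TorusLattice

lc = pl.compute_adjoint(pl.find_limit_cycle())
lat = TorusLattice(4, 4)
w = CouplingWeights.symmetric(h1=1, v1=1, d=1)
conn = pl.build_connectivity(lat, w)

start = pl.phase_field(ClusterSolution(1, 0, 2, 1), lat)  # horizontal stripes
states = pl.init_from_pattern(start, lc)

rng = np.random.default_rng(0)
targets = tuple(int(i) for i in rng.choice(lat.n_sites, 8, replace=False))
pulse = pl.PerturbationProtocol(targets=targets, delta_I=0.05,
                                t_on=1500.0, t_off=1800.0)

spikes, _ = pl.simulate_biophysical(states, conn, lc.params, 4000.0, pulse)

before = pl.empirical_phases(spikes, lat, window=(600.0, 1500.0))
after = pl.empirical_phases(spikes, lat, window=(3000.0, 4000.0))
print("phases / pi before the pulse:")
print(np.round(before.phases / np.pi, 2))
print("phases / pi after the pulse:")
print(np.round(after.phases / np.pi, 2))

alt = pl.alternating_four_cluster(lat)
mirror = pl.PhaseField(lat, -alt.phases)  # same clusters, reversed firing order
tol = 2 * np.pi * 2 / lc.T
print("\nstill the horizontal stripe?",
      pl.matches_pattern(after, start, tol))
print("switched to the alternating 4-cluster state (either chirality)?",
      pl.matches_pattern(after, alt, tol) or pl.matches_pattern(after, mirror, tol))
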