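"""How much diagonal coupling destroys the anti-phase diagonal stripes?

The (pi, pi) checkerboard stripe is the most robust cluster state under
nearest-neighbor inhibition.  Diagonal connections couple cells that
are in phase, which for this inhibitory H is destabilizing; the
closed-form eigenvalues predict loss of stability at

    d / min(h1, v1) = -H'_odd(pi) / (2 H'_odd(0))  (about 7.5).

The same number comes out of root-finding the leading eigenvalue on the
full 6x6 mode grid, and (near 7.6) out of perturb-and-relax bisection
on the biophysical network (see the acceptance script).
"""

import phaselattice as pl
from phaselattice import TorusLattice

lc = pl.compute_adjoint(pl.find_limit_cycle())
H = pl.interaction_function(lc)

ratio = pl.diagonal_destabilization_ratio(H.odd_part().derivative())
d_root = pl.critical_diagonal_coupling(H.derivative(), TorusLattice(6, 6))

print(f"threshold from the H'_odd ratio formula : {ratio:.3f}")
print(f"threshold from eigen-grid root finding  : {d_root:.3f}")
print("(diagonal weight in units of the nearest-neighbor weight)")
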