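"""Reduce the Wang-Buzsaki interneuron to its phase-interaction function.

Finds the tonically firing limit cycle at I_app = 0.4 uA/cm^2, computes
the adjoint (infinitesimal phase response), and assembles the synaptic
interaction function H.  The five printed values of H'_odd are the
quantities the whole stability analysis runs on: a negative value at a
phase offset means inhibitory coupling pulls neighbors at that offset
apart (destabilizing for a pattern using it), a positive value means it
locks them (stabilizing).
"""

import numpy as np

import phaselattice as pl

lc = pl.compute_adjoint(pl.find_limit_cycle())
print(f"limit cycle period T = {lc.T:.3f} ms ({1000 / lc.T:.1f} Hz)")

H = pl.interaction_function(lc)
h_odd_prime = H.odd_part().derivative()

for label, psi in [("0", 0.0), ("pi/3", np.pi / 3), ("pi/2", np.pi / 2),
                   ("2pi/3", 2 * np.pi / 3), ("pi", np.pi)]:
    print(f"H'_odd({label:>5}) = {h_odd_prime(psi):+.3f}")

crossings = pl.zero_crossings(h_odd_prime)
print("H'_odd sign changes at", np.round(crossings, 4),
      "rad  (stabilizing band between them)")
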