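"""Analytic interaction-function fixtures.

Tabulated closed-form H's let the lattice and stability machinery be
exercised (and property-tested) without running the ODE pipeline:

* ``sine_interaction``: H = sin, the Kuramoto-type coupling for which
  synchrony is stable under any nonnegative weights.
* ``negative_sine_interaction``: H = -sin; synchrony is unstable and
  the (pi, pi) anti-phase stripe is stable under nearest-neighbor
  coupling.
* ``two_harmonic_interaction``: two odd harmonics plus an even part,
  with the sign structure of the inhibitory-network H (negative slope
  of the odd part at 0, positive at pi), so thresholds are finite.
"""

from __future__ import annotations

import numpy as np

from .reduction import InteractionFunction

__all__ = [
    "sine_interaction",
    "negative_sine_interaction",
    "two_harmonic_interaction",
]


def _grid(n: int) -> np.ndarray:
    return 2.0 * np.pi * np.arange(n) / n


def sine_interaction(n_grid: int = 1024) -> InteractionFunction:
    psi = _grid(n_grid)
    return InteractionFunction(psi, np.sin(psi), provenance="analytic sin")


def negative_sine_interaction(n_grid: int = 1024) -> InteractionFunction:
    psi = _grid(n_grid)
    return InteractionFunction(psi, -np.sin(psi), provenance="analytic -sin")


def two_harmonic_interaction(n_grid: int = 1024) -> InteractionFunction:
    """H(psi) = -sin psi + 0.25 sin 2 psi + 0.3 cos psi.

    H'_odd(0) = -0.5 < 0 and H'_odd(pi) = 1.5 > 0; the even cosine term
    makes H itself asymmetric, as for synaptic coupling.
    """
    psi = _grid(n_grid)
    values = -np.sin(psi) + 0.25 * np.sin(2.0 * psi) + 0.3 * np.cos(psi)
    return InteractionFunction(psi, values, provenance="analytic two-harmonic")
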