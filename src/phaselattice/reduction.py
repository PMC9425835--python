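"""Interaction function H of the phase-reduced network.

For weakly coupled limit-cycle oscillators the phase of cell (i, j)
obeys

    d theta_ij / dt = Omega + eps * sum_{p,q} w_pq H(theta_{i+p,j+q} - theta_ij),

with H the period average of the adjoint Z against the synaptic
coupling field evaluated at phase offset psi:

    H(psi) = (1/T) * int_0^T  Z(t) . G[X(t), X(t + psi/Omega)] dt.

Scale convention: the small parameter eps is the maximal synaptic
conductance g_syn, connection weights are dimensionless multipliers,
and the 1/C factor of the voltage equation is folded into G, so H
itself is independent of g_syn.

H is tabulated on a uniform phase grid; the odd part, finite-difference
derivative, and sign-change locations are the quantities the stability
analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .neuron import LimitCycle, NeuronParams

__all__ = [
    "InteractionFunction",
    "synaptic_coupling_G",
    "interaction_function",
    "odd_part",
    "derivative",
    "zero_crossings",
    "save_interaction_function",
    "load_interaction_function",
]


@dataclass
class InteractionFunction:
    """2pi-periodic scalar function tabulated on a uniform phase grid."""

    psi: np.ndarray
    values: np.ndarray
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.psi.shape != self.values.shape or self.psi.ndim != 1:
            raise ValueError("psi and values must be matching 1-D arrays")
        n = len(self.psi)
        expected = 2.0 * np.pi * np.arange(n) / n
        if not np.allclose(self.psi, expected, atol=1e-9):
            raise ValueError("grid must be uniform on [0, 2pi) starting at 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite interaction function values")

    @property
    def n_grid(self) -> int:
        return len(self.psi)

    def __call__(self, psi):
        """Periodic linear interpolation at arbitrary phases."""
        x = np.mod(psi, 2.0 * np.pi)
        xp = np.append(self.psi, 2.0 * np.pi)
        fp = np.append(self.values, self.values[0])
        out = np.interp(x, xp, fp)
        return out if np.ndim(psi) else float(out)

    def odd_part(self) -> "InteractionFunction":
        return odd_part(self)

    def derivative(self) -> "InteractionFunction":
        return derivative(self)


def synaptic_coupling_G(post, pre, params: NeuronParams) -> np.ndarray:
    """Per-unit-weight synaptic coupling vector field G(X_post, X_pre).

    Only the voltage component is coupled:
    -(1/C) (V_post - V_syn) * s_pre; the factor g_syn plays the role of
    the small parameter eps and is deliberately not included.
    """
    post = np.asarray(post, dtype=float)
    pre = np.asarray(pre, dtype=float)
    out = np.zeros(np.broadcast_shapes(post.shape, pre.shape))
    out[..., 0] = -(post[..., 0] - params.V_syn) * pre[..., 3] / params.C
    return out


def interaction_function(lc: LimitCycle) -> InteractionFunction:
    """H(psi) from a limit cycle with adjoint, by the periodic trapezoid rule.

    The argument convention is presynaptic phase minus postsynaptic
    phase, so H(psi_k) correlates the adjoint's voltage component at
    phase phi with the presynaptic gating variable at phase phi + psi_k.
    On the shared uniform grid the phase shift is an exact index roll
    and the trapezoid rule reduces to the sample mean.
    """
    if lc.adjoint is None:
        raise ValueError("limit cycle has no adjoint; run compute_adjoint first")
    p = lc.params
    a = lc.adjoint[:, 0] * (-(lc.orbit[:, 0] - p.V_syn) / p.C)
    s = lc.orbit[:, 3]
    n = lc.n_grid
    # H_k = mean_j a_j * s_{j+k}: circular cross-correlation via FFT
    H = np.fft.ifft(np.conj(np.fft.fft(a)) * np.fft.fft(s)).real / n
    return InteractionFunction(lc.phases.copy(), H, provenance="wang-buzsaki adjoint")


def odd_part(H: InteractionFunction) -> InteractionFunction:
    """H_odd(psi) = [H(psi) - H(2pi - psi)] / 2, grid-exact index reversal."""
    rev = np.roll(H.values[::-1], 1)  # value at 2pi - psi_k
    return InteractionFunction(H.psi.copy(), 0.5 * (H.values - rev),
                               provenance=f"odd part of {H.provenance}")


def derivative(H: InteractionFunction) -> InteractionFunction:
    """Central finite differences with periodic wraparound."""
    dpsi = 2.0 * np.pi / H.n_grid
    dv = (np.roll(H.values, -1) - np.roll(H.values, 1)) / (2.0 * dpsi)
    return InteractionFunction(H.psi.copy(), dv,
                               provenance=f"derivative of {H.provenance}")


def zero_crossings(f: InteractionFunction) -> np.ndarray:
    """Phases in [0, 2pi) where f changes sign, by linear interpolation."""
    v = f.values
    n = f.n_grid
    dpsi = 2.0 * np.pi / n
    crossings = []
    for k in range(n):
        a, b = v[k], v[(k + 1) % n]
        if a == 0.0:
            crossings.append(f.psi[k])
        elif a * b < 0.0:
            crossings.append(f.psi[k] + dpsi * a / (a - b))
    return np.sort(np.mod(np.asarray(crossings), 2.0 * np.pi))


def save_interaction_function(H: InteractionFunction, path) -> None:
    np.savetxt(path, np.column_stack([H.psi, H.values]), delimiter=",",
               header="phase,value", comments="")


def load_interaction_function(path) -> InteractionFunction:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    psi, values = data[:, 0], data[:, 1]
    if len(np.unique(psi)) != len(psi):
        raise ValueError("duplicated phase values in interaction function file")
    order = np.argsort(psi)
    try:
        return InteractionFunction(psi[order], values[order],
                                   provenance=f"file:{Path(path).name}")
    except ValueError as err:
        raise ValueError(f"invalid interaction function grid in {path}: {err}")
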