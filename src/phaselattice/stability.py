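"""Closed-form stability of cluster solutions on the torus.

Linearizing the phase model about a cluster solution with steps
(psi_h, psi_v) gives du/dt = eps (-c I + W_hat) u where W_hat is a
block circulant (of circulants) built from the effective weights
w_hat_pq = w_pq H'(p psi_h + q psi_v) and c is their sum.  The
eigenvalues therefore come in closed form indexed by lattice
wavenumbers (j, k):

    Re lambda_jk = - sum_{(p,q) in S} w_pq H'(p psi_h + q psi_v)
                       * (1 - cos(2 pi (j p / n + k q / m))).

With direction-symmetric weights the paired offsets combine through
H'(x) + H'(-x) = 2 H'_odd(x), which is the form the sign analysis uses.
The (0,0) mode is always zero (uniform phase shift); a solution is
stable when every other mode has negative real part.  eps > 0 only
scales the eigenvalues, so the analysis sets eps = 1.

:func:`jacobian_oracle` assembles the dense N x N Jacobian entry by
entry so the closed form can be checked against a direct eigensolve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .lattice import ClusterSolution, TorusLattice, enumerate_solutions

__all__ = [
    "STENCIL",
    "CouplingWeights",
    "EigenGrid",
    "StabilityVerdict",
    "eigen_real_parts",
    "jacobian_oracle",
    "classify",
    "stability_table",
    "frequency_correction",
    "diagonal_destabilization_ratio",
    "critical_diagonal_coupling",
    "horizontal_stripe_condition",
]

logger = logging.getLogger(__name__)

#: Coupling stencil: 4 nearest, 4 diagonal, 4 second-nearest offsets (p, q).
STENCIL: tuple[tuple[int, int], ...] = (
    (1, 0), (-1, 0), (0, 1), (0, -1),
    (1, 1), (1, -1), (-1, 1), (-1, -1),
    (2, 0), (-2, 0), (0, 2), (0, -2),
)


@dataclass(frozen=True)
class CouplingWeights:
    """Nonnegative coupling weights over the stencil S.

    Weights are dimensionless multipliers of the small parameter
    eps = g_syn.  Use :meth:`symmetric` for the direction-symmetric
    shorthand (h1, v1, d, h2, v2).
    """

    weights: tuple[tuple[tuple[int, int], float], ...]

    @classmethod
    def from_map(cls, mapping) -> "CouplingWeights":
        items = []
        for offset, w in dict(mapping).items():
            offset = (int(offset[0]), int(offset[1]))
            if offset not in STENCIL:
                raise ValueError(f"offset {offset} outside the coupling stencil")
            if w < 0:
                raise ValueError(f"negative weight {w} at offset {offset}")
            items.append((offset, float(w)))
        items.sort(key=lambda kv: STENCIL.index(kv[0]))
        return cls(tuple(items))

    @classmethod
    def symmetric(cls, h1=0.0, v1=0.0, d=0.0, h2=0.0, v2=0.0) -> "CouplingWeights":
        return cls.from_map({
            (1, 0): h1, (-1, 0): h1,
            (0, 1): v1, (0, -1): v1,
            (1, 1): d, (1, -1): d, (-1, 1): d, (-1, -1): d,
            (2, 0): h2, (-2, 0): h2,
            (0, 2): v2, (0, -2): v2,
        })

    def items(self):
        return self.weights

    def as_dict(self) -> dict[tuple[int, int], float]:
        return dict(self.weights)


@dataclass
class EigenGrid:
    """Re lambda_jk, j in 0..n-1 (rows), k in 0..m-1 (columns)."""

    re: np.ndarray
    c: float
    solution: ClusterSolution
    lattice: TorusLattice

    @property
    def max_nonzero_mode(self) -> float:
        masked = self.re.copy()
        masked[0, 0] = -np.inf
        return float(masked.max())


@dataclass(frozen=True)
class StabilityVerdict:
    verdict: str  # "stable" | "unstable" | "marginal"
    max_nonzero_re: float
    tol: float

    def __str__(self) -> str:
        return self.verdict


def eigen_real_parts(
    sol: ClusterSolution,
    w: CouplingWeights,
    Hp,
    lat: TorusLattice,
) -> EigenGrid:
    """Closed-form eigenvalue real parts of the linearization.

    ``Hp`` is any callable evaluating H' on [0, 2pi) (for example
    ``interaction_function(lc).derivative()``).
    """
    if not sol.admissible(lat):
        raise ValueError("solution inadmissible on this lattice")
    j = np.arange(lat.n)[:, None]
    k = np.arange(lat.m)[None, :]
    re = np.zeros((lat.n, lat.m))
    c = 0.0
    for (p, q), wpq in w.items():
        hp = float(Hp(p * sol.psi_h + q * sol.psi_v))
        c += wpq * hp
        re -= wpq * hp * (1.0 - np.cos(2.0 * np.pi * (j * p / lat.n + k * q / lat.m)))
    return EigenGrid(re=re, c=c, solution=sol, lattice=lat)


def jacobian_oracle(
    sol: ClusterSolution,
    w: CouplingWeights,
    Hp,
    lat: TorusLattice,
) -> np.ndarray:
    """Dense N x N Jacobian -c I + W_hat assembled entry by entry.

    Row-major site order (site = j * n + i).  Its full spectrum must
    match the closed form of :func:`eigen_real_parts` as a multiset.
    """
    N = lat.n_sites
    J = np.zeros((N, N))
    c = 0.0
    for (p, q), wpq in w.items():
        hp = float(Hp(p * sol.psi_h + q * sol.psi_v))
        c += wpq * hp
        for jrow in range(lat.m):
            for i in range(lat.n):
                J[lat.site_index(i, jrow), lat.site_index(i + p, jrow + q)] += wpq * hp
    J -= c * np.eye(N)
    return J


def classify(grid: EigenGrid, tol: float | None = None) -> StabilityVerdict:
    """Stable iff every non-(0,0) mode has Re lambda < -tol.

    Any non-(0,0) mode inside the +-tol band makes the verdict
    "marginal"; a mode above +tol makes it "unstable".
    """
    if tol is None:
        tol = 1e-9 * max(1.0, abs(grid.c))
    re = grid.re.copy()
    re[0, 0] = np.nan
    vals = re[~np.isnan(re)]
    if np.any(vals > tol):
        verdict = "unstable"
    elif np.any(vals >= -tol):
        verdict = "marginal"
    else:
        verdict = "stable"
    return StabilityVerdict(verdict=verdict, max_nonzero_re=float(np.max(vals)), tol=tol)


def frequency_correction(sol: ClusterSolution, w: CouplingWeights, H) -> float:
    """Frequency correction omega = sum w_pq H(p psi_h + q psi_v).

    The locked solution drifts at Omega + eps * omega.
    """
    return float(sum(wpq * H(p * sol.psi_h + q * sol.psi_v)
                     for (p, q), wpq in w.items()))


def stability_table(lat: TorusLattice, w: CouplingWeights, Hp) -> pd.DataFrame:
    """Verdicts for every cluster solution of the lattice."""
    rows = []
    for sol in enumerate_solutions(lat.m, lat.n):
        verdict = classify(eigen_real_parts(sol, w, Hp, lat))
        rows.append({
            "p_h": sol.p_h, "l_h": sol.l_h, "p_v": sol.p_v, "l_v": sol.l_v,
            "psi_h": sol.psi_h, "psi_v": sol.psi_v, "p": sol.p,
            "verdict": verdict.verdict, "max_nonzero_re": verdict.max_nonzero_re,
        })
    return pd.DataFrame(rows)


def diagonal_destabilization_ratio(Hp_odd) -> float:
    """Critical d / min(h1, v1) destabilizing the (pi, pi) diagonal stripe.

    Equals -H'_odd(pi) / (2 H'_odd(0)); requires the sign structure
    H'_odd(0) < 0 < H'_odd(pi), otherwise no finite threshold exists.
    """
    h0 = float(Hp_odd(0.0))
    hpi = float(Hp_odd(np.pi))
    if not (h0 < 0.0 < hpi):
        raise ValueError(
            f"no finite threshold: need H'_odd(0) < 0 < H'_odd(pi), "
            f"got {h0:.4g} and {hpi:.4g}"
        )
    return -hpi / (2.0 * h0)


def critical_diagonal_coupling(
    Hp,
    lat: TorusLattice | None = None,
    h1: float = 1.0,
    v1: float = 1.0,
    d_max: float = 50.0,
) -> float:
    """Root-found d at which the (pi, pi) stripe's leading mode crosses zero.

    Scans the full closed-form eigenvalue grid with h2 = v2 = 0;
    cross-validates the ratio formula, which uses only two values of
    H'_odd.  ``Hp`` is the derivative of the full H (not its odd part).
    """
    lat = lat or TorusLattice(6, 6)
    if lat.m % 2 or lat.n % 2:
        raise ValueError("(pi, pi) stripe needs even lattice dimensions")
    sol = ClusterSolution(2, 1, 2, 1)

    def leading(dval: float) -> float:
        w = CouplingWeights.symmetric(h1=h1, v1=v1, d=dval)
        return eigen_real_parts(sol, w, Hp, lat).max_nonzero_mode

    if leading(0.0) >= 0.0:
        raise ValueError("(pi, pi) stripe not stable at d = 0; no threshold")
    if leading(d_max) <= 0.0:
        raise ValueError(f"no destabilization up to d = {d_max}")
    return float(brentq(leading, 0.0, d_max, xtol=1e-10))


def horizontal_stripe_condition(Hp_odd, psi_v: float, h1: float, d: float) -> bool:
    """Necessary condition for p-cluster horizontal-stripe stability.

    The purely horizontal modes (k = 0) of a stripe with steps
    (0, psi_v) have Re lambda proportional to
    -(2 d H'_odd(psi_v) + h1 H'_odd(0)); they are damped iff
    2 d H'_odd(psi_v) + h1 H'_odd(0) > 0.  Necessary only -- the full
    verdict needs :func:`classify` over all modes.
    """
    return bool(2.0 * d * float(Hp_odd(psi_v)) + h1 * float(Hp_odd(0.0)) > 0.0)
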