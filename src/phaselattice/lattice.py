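"""Torus lattice bookkeeping and enumeration of cluster solutions.

On an m x n torus (n columns indexed by i, m rows indexed by j, all
offset arithmetic mod n horizontally and mod m vertically) a phase
pattern with constant horizontal step psi_h and vertical step psi_v is
a phase-locked solution of the reduced network whenever

    psi_h = 2 pi l_h / p_h  with p_h | n, gcd(l_h, p_h) = 1,
    psi_v = 2 pi l_v / p_v  with p_v | m, gcd(l_v, p_v) = 1.

Such a pattern splits the network into p = lcm(p_h, p_v) equal clusters
of synchronously firing cells.  The synchronous state is the special
case p_h = p_v = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TorusLattice",
    "ClusterSolution",
    "PhaseField",
    "enumerate_solutions",
    "phase_field",
    "cluster_partition",
]


@dataclass(frozen=True)
class TorusLattice:
    """m rows by n columns with periodic boundary conditions.

    Flat site order is row-major: site (i, j) -> j * n + i, with i the
    horizontal (column) index and j the vertical (row) index.
    """

    m: int
    n: int

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValueError("lattice dimensions must be >= 1")

    @property
    def n_sites(self) -> int:
        return self.m * self.n

    def site_index(self, i: int, j: int) -> int:
        return (j % self.m) * self.n + (i % self.n)


@dataclass(frozen=True)
class ClusterSolution:
    """A (p_h, p_v) cluster solution, identified by its phase steps."""

    p_h: int
    l_h: int
    p_v: int
    l_v: int

    def __post_init__(self) -> None:
        for p, l, tag in ((self.p_h, self.l_h, "horizontal"),
                          (self.p_v, self.l_v, "vertical")):
            if p < 1 or not (0 <= l < p):
                raise ValueError(f"invalid {tag} cluster indices (p={p}, l={l})")
            if p > 1 and math.gcd(l, p) != 1:
                raise ValueError(f"{tag} winding l={l} not coprime with p={p}")
            if p == 1 and l != 0:
                raise ValueError(f"{tag} winding must be 0 when p=1")

    @property
    def psi_h(self) -> float:
        return 2.0 * np.pi * self.l_h / self.p_h

    @property
    def psi_v(self) -> float:
        return 2.0 * np.pi * self.l_v / self.p_v

    @property
    def p(self) -> int:
        return math.lcm(self.p_h, self.p_v)

    def admissible(self, lat: TorusLattice) -> bool:
        return lat.n % self.p_h == 0 and lat.m % self.p_v == 0


@dataclass
class PhaseField:
    """Per-site phases (rad, mod 2pi) on a torus lattice, shape (m, n)."""

    lattice: TorusLattice
    phases: np.ndarray

    def __post_init__(self) -> None:
        self.phases = np.mod(np.asarray(self.phases, dtype=float), 2.0 * np.pi)
        if self.phases.shape != (self.lattice.m, self.lattice.n):
            raise ValueError("phase array shape must be (m, n)")

    @property
    def flat(self) -> np.ndarray:
        """Row-major flattening matching the linearization's site order."""
        return self.phases.reshape(-1)


def _windings(size: int) -> list[tuple[int, int]]:
    """All (p, l) with p | size, 0 <= l < p, gcd(l, p) = 1 (l = 0 iff p = 1)."""
    out = []
    for p in range(1, size + 1):
        if size % p:
            continue
        if p == 1:
            out.append((1, 0))
        else:
            out.extend((p, l) for l in range(1, p) if math.gcd(l, p) == 1)
    return out


def enumerate_solutions(m: int, n: int) -> list[ClusterSolution]:
    """All cluster solutions of the m x n torus, one per (psi_h, psi_v) pair.

    The count per direction is sum over divisors p of the Euler totient
    of p, i.e. exactly n horizontal steps and m vertical steps.
    """
    if m < 1 or n < 1:
        raise ValueError("lattice dimensions must be >= 1")
    sols = [
        ClusterSolution(p_h, l_h, p_v, l_v)
        for p_h, l_h in _windings(n)
        for p_v, l_v in _windings(m)
    ]
    sols.sort(key=lambda s: (s.psi_h, s.psi_v))
    return sols


def phase_field(sol: ClusterSolution, lat: TorusLattice) -> PhaseField:
    """phi_ij = i * psi_h + j * psi_v (mod 2pi)."""
    if not sol.admissible(lat):
        raise ValueError(
            f"solution (p_h={sol.p_h}, p_v={sol.p_v}) inadmissible on "
            f"{lat.m}x{lat.n} lattice: p_h must divide n and p_v divide m"
        )
    i = np.arange(lat.n)
    j = np.arange(lat.m)
    phases = np.add.outer(j * sol.psi_v, i * sol.psi_h)
    return PhaseField(lat, phases)


def _circdist(a, b):
    d = np.mod(a - b, 2.0 * np.pi)
    return np.minimum(d, 2.0 * np.pi - d)


def cluster_partition(fieldarg: PhaseField, tol: float = 1e-9) -> list[list[tuple[int, int]]]:
    """Group sites by circular phase equality within tol.

    Returns a list of site lists [(i, j), ...] sorted by representative
    phase; synchronous sites end up in a single group.
    """
    lat = fieldarg.lattice
    sites = [(i, j) for j in range(lat.m) for i in range(lat.n)]
    groups: list[tuple[float, list[tuple[int, int]]]] = []
    for (i, j) in sites:
        phi = fieldarg.phases[j, i]
        for rep, members in groups:
            if _circdist(phi, rep) <= tol:
                members.append((i, j))
                break
        else:
            groups.append((phi, [(i, j)]))
    groups.sort(key=lambda g: g[0])
    return [members for _, members in groups]
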