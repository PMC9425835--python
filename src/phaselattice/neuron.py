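"""Single Wang-Buzsaki inhibitory interneuron: dynamics, limit cycle, adjoint.

The Wang-Buzsaki model is a Hodgkin-Huxley-type conductance-based
interneuron model with a fast sodium current (instantaneous activation
``m_inf(V)``, inactivation gate ``h``), a delayed-rectifier potassium
current (gate ``n``), a leak current, and a first-order synaptic gating
variable ``s`` driven by the cell's own voltage.  State order throughout
is ``(V, h, n, s)``.

For tonic applied current the isolated cell has an exponentially
asymptotically stable periodic orbit.  :func:`find_limit_cycle` locates
it with a Poincare section (upward crossing of V = 0 mV) and
:func:`compute_adjoint` computes the infinitesimal phase-response curve
Z(t) -- the periodic solution of dZ/dt = -DF(X(t))^T Z, normalized so
that the period average of Z . F equals 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

__all__ = [
    "NeuronParams",
    "LimitCycle",
    "wb_derivatives",
    "wb_jacobian",
    "find_limit_cycle",
    "compute_adjoint",
    "save_limit_cycle",
    "load_limit_cycle",
]


@dataclass(frozen=True)
class NeuronParams:
    """Wang-Buzsaki interneuron parameters.

    Units: conductances mS/cm^2, voltages mV, capacitance uF/cm^2,
    currents uA/cm^2, rates ms^-1, times ms.  ``gamma`` is the
    dimensionless temperature-like scale of the gating kinetics.
    """

    C: float = 1.0
    I_app: float = 0.4
    g_Na: float = 35.0
    g_K: float = 9.0
    g_L: float = 0.1
    g_syn: float = 0.05
    V_Na: float = 55.0
    V_K: float = -90.0
    V_L: float = -65.0
    V_syn: float = -75.0
    gamma: float = 1.0
    alpha0: float = 4.0
    tau_inh: float = 2.0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("capacitance C must be positive")
        if self.tau_inh <= 0:
            raise ValueError("tau_inh must be positive")
        for name in ("g_Na", "g_K", "g_L", "g_syn"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")


# -- rate functions -----------------------------------------------------------
#
# alpha_m and alpha_n have removable singularities of the form
# x / (exp(x) - 1) at x = 0 (V = -35 and V = -34 mV); they are evaluated
# by a short series there.

_SERIES_CUTOFF = 1e-4


def _x_over_expm1(x):
    """x / (exp(x) - 1), with the analytic limit at x = 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < _SERIES_CUTOFF
    xs = np.where(small, 1.0, x)
    out = np.where(small, 1.0 - x / 2.0 + x * x / 12.0, xs / np.expm1(xs))
    return out if out.ndim else float(out)


def _x_over_expm1_prime(x):
    """d/dx of x / (exp(x) - 1)."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < _SERIES_CUTOFF
    xs = np.where(small, 1.0, x)
    em1 = np.expm1(xs)
    out = np.where(
        small,
        -0.5 + x / 6.0,
        (em1 - xs * (em1 + 1.0)) / (em1 * em1),
    )
    return out if out.ndim else float(out)


def alpha_m(V):
    return _x_over_expm1(-0.1 * (np.asarray(V, dtype=float) + 35.0))


def beta_m(V):
    return 4.0 * np.exp(-(np.asarray(V, dtype=float) + 60.0) / 18.0)


def m_inf(V):
    a, b = alpha_m(V), beta_m(V)
    return a / (a + b)


def alpha_h(V):
    return 0.07 * np.exp(-(np.asarray(V, dtype=float) + 58.0) / 20.0)


def beta_h(V):
    return 1.0 / (np.exp(-0.1 * (np.asarray(V, dtype=float) + 28.0)) + 1.0)


def alpha_n(V):
    return 0.1 * _x_over_expm1(-0.1 * (np.asarray(V, dtype=float) + 34.0))


def beta_n(V):
    return 0.125 * np.exp(-(np.asarray(V, dtype=float) + 44.0) / 80.0)


def alpha_inh(V, alpha0=4.0):
    return alpha0 / (1.0 + np.exp(-np.asarray(V, dtype=float) / 5.0))


def wb_derivatives(y, params: NeuronParams, drive=0.0):
    """Right-hand side of the Wang-Buzsaki cell equations.

    Parameters
    ----------
    y
        State ``(V, h, n, s)`` as the last axis of an array, so a
        single cell is shape ``(4,)`` and a population ``(N, 4)``.
    drive
        Dimensionless synaptic drive sum_j W_ij s_j of the cell
        (0 for an isolated cell); scalar or shape ``(N,)``.

    Returns
    -------
    ndarray with the same shape as ``y``.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state passed to wb_derivatives")
    V, h, n, s = y[..., 0], y[..., 1], y[..., 2], y[..., 3]
    p = params

    I_Na = p.g_Na * m_inf(V) ** 3 * h * (V - p.V_Na)
    I_K = p.g_K * n**4 * (V - p.V_K)
    I_L = p.g_L * (V - p.V_L)
    I_syn = p.g_syn * (V - p.V_syn) * drive

    dV = (p.I_app - I_Na - I_K - I_L - I_syn) / p.C
    dh = p.gamma * (alpha_h(V) * (1.0 - h) - beta_h(V) * h)
    dn = p.gamma * (alpha_n(V) * (1.0 - n) - beta_n(V) * n)
    ds = -s / p.tau_inh + alpha_inh(V, p.alpha0) * (1.0 - s)
    return np.stack([dV, dh, dn, ds], axis=-1)


def wb_jacobian(y, params: NeuronParams):
    """Analytic 4x4 Jacobian of the isolated cell (drive 0) at state y."""
    V, h, n, s = np.asarray(y, dtype=float)
    p = params

    a_m, b_m = alpha_m(V), beta_m(V)
    da_m = -0.1 * _x_over_expm1_prime(-0.1 * (V + 35.0))
    db_m = -b_m / 18.0
    minf = a_m / (a_m + b_m)
    dminf = (da_m * b_m - a_m * db_m) / (a_m + b_m) ** 2

    a_h, b_h = alpha_h(V), beta_h(V)
    da_h = -a_h / 20.0
    db_h = 0.1 * b_h * (1.0 - b_h)

    a_n, b_n = alpha_n(V), beta_n(V)
    da_n = -0.01 * _x_over_expm1_prime(-0.1 * (V + 34.0))
    db_n = -b_n / 80.0

    a_s = alpha_inh(V, p.alpha0)
    da_s = 0.2 * a_s * (1.0 - a_s / p.alpha0)

    J = np.zeros((4, 4))
    J[0, 0] = (
        -p.g_Na * h * (3.0 * minf**2 * dminf * (V - p.V_Na) + minf**3)
        - p.g_K * n**4
        - p.g_L
    ) / p.C
    J[0, 1] = -p.g_Na * minf**3 * (V - p.V_Na) / p.C
    J[0, 2] = -4.0 * p.g_K * n**3 * (V - p.V_K) / p.C

    J[1, 0] = p.gamma * (da_h * (1.0 - h) - db_h * h)
    J[1, 1] = -p.gamma * (a_h + b_h)

    J[2, 0] = p.gamma * (da_n * (1.0 - n) - db_n * n)
    J[2, 2] = -p.gamma * (a_n + b_n)

    J[3, 0] = da_s * (1.0 - s)
    J[3, 3] = -1.0 / p.tau_inh - a_s
    return J


# -- limit cycle --------------------------------------------------------------


@dataclass
class LimitCycle:
    """Phase-sampled periodic orbit and adjoint of one cell.

    ``phases`` are N uniform samples of [0, 2pi) with phase 0 at the
    upward V = 0 mV crossing; ``orbit[k]`` is the state at phase
    ``phases[k]`` and ``adjoint[k]`` (once computed) the adjoint Z
    there, normalized so that mean(Z . F) over the period equals 1.
    """

    T: float
    phases: np.ndarray
    orbit: np.ndarray
    params: NeuronParams
    adjoint: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)
    # dense time interpolant of the orbit over [0, T] from the detection
    # integration; more accurate through the spike upstroke than the
    # phase-grid spline, used by compute_adjoint when present
    dense: object | None = field(default=None, repr=False, compare=False)

    @property
    def Omega(self) -> float:
        return 2.0 * np.pi / self.T

    @property
    def n_grid(self) -> int:
        return len(self.phases)

    def orbit_spline(self) -> CubicSpline:
        """Periodic cubic interpolant of the orbit as a function of phase."""
        phi = np.append(self.phases, 2.0 * np.pi)
        vals = np.vstack([self.orbit, self.orbit[:1]])
        return CubicSpline(phi, vals, bc_type="periodic")

    def state_at_phase(self, phi) -> np.ndarray:
        return self.orbit_spline()(np.mod(phi, 2.0 * np.pi))


_DEFAULT_INIT = np.array([-64.0, 0.78, 0.09, 0.0])


def _crossing_event(t, y):
    return y[0]


_crossing_event.direction = 1.0
_crossing_event.terminal = False


def find_limit_cycle(
    params: NeuronParams | None = None,
    *,
    n_grid: int = 1024,
    tol: float = 1e-9,
    transient: float = 1500.0,
    max_time: float = 5000.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    y0=None,
) -> LimitCycle:
    """Locate the stable periodic orbit of the isolated cell.

    Integrates from a generic initial state, discards a transient, then
    detects the period from successive upward crossings of V = 0 mV
    (event-refined).  Raises ``RuntimeError("no oscillation")`` when the
    cell is quiescent within ``max_time``.
    """
    params = params or NeuronParams()
    y0 = _DEFAULT_INIT if y0 is None else np.asarray(y0, dtype=float)

    def rhs(t, y):
        return wb_derivatives(y, params)

    sol = solve_ivp(
        rhs,
        (0.0, max_time),
        y0,
        method="DOP853",
        rtol=rtol,
        atol=atol,
        events=_crossing_event,
        dense_output=False,
    )
    t_cross = sol.t_events[0]
    y_cross = sol.y_events[0]
    t_cross_late = t_cross[t_cross > transient]
    if len(t_cross_late) < 4:
        raise RuntimeError("no oscillation: too few V=0 upward crossings")
    isis = np.diff(t_cross_late)
    T = float(isis[-1])
    if abs(isis[-1] - isis[-2]) > max(tol, 1e-6) * T:
        raise RuntimeError(
            f"period not converged: last ISIs {isis[-3:]} differ by more than tol"
        )

    # one clean pass: resample the orbit over one period from the last
    # crossing state, which sits exactly on the Poincare section
    start = y_cross[np.searchsorted(t_cross, t_cross_late[-2])]
    t_eval = T * np.arange(n_grid) / n_grid
    orbit_sol = solve_ivp(
        rhs,
        (0.0, T),
        start,
        method="DOP853",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        dense_output=True,
    )
    closure = float(np.max(np.abs(orbit_sol.sol(T) - start)))
    phases = 2.0 * np.pi * np.arange(n_grid) / n_grid
    return LimitCycle(
        T=T,
        phases=phases,
        orbit=orbit_sol.y.T.copy(),
        params=params,
        dense=orbit_sol.sol,
        diagnostics={
            "closure_residual": closure,
            "isi_spread": float(np.ptp(isis[-4:])),
            "n_crossings": int(len(t_cross)),
            "rtol": rtol,
            "atol": atol,
        },
    )


def compute_adjoint(
    lc: LimitCycle,
    *,
    tol: float = 1e-10,
    max_periods: int = 60,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> LimitCycle:
    """Fill in the adjoint (phase response) samples of a limit cycle.

    Solves dZ/dt = -DF(X(t))^T Z backward in time over repeated periods
    (the orbit's stable Floquet directions decay backward), stopping when
    the period map of Z is stationary, then rescales Z so that
    (1/T) * integral of Z . F over one period equals 1.
    """
    T, Om = lc.T, lc.Omega
    if lc.dense is not None:
        def state_at_time(t):
            return lc.dense(np.mod(t, T))
    else:
        spline = lc.orbit_spline()

        def state_at_time(t):
            return spline(np.mod(t * Om, 2.0 * np.pi))

    # backward time s = -t: dZ/ds = +DF(X(-s))^T Z
    def rhs(s, Z):
        return wb_jacobian(state_at_time(-s), lc.params).T @ Z

    # rescale each period and track direction convergence only: orbit
    # discretization acts as a periodic forcing whose component along the
    # neutral Floquet direction drifts the overall scale, which the final
    # normalization removes anyway
    Z = np.array([1.0, 0.0, 0.0, 0.0])
    residual = np.inf
    for k in range(max_periods):
        sol = solve_ivp(rhs, (k * T, (k + 1) * T), Z, method="DOP853",
                        rtol=rtol, atol=atol)
        Z_new = sol.y[:, -1]
        scale = np.max(np.abs(Z_new))
        if scale == 0:
            raise RuntimeError("adjoint collapsed to zero")
        Z_new = Z_new / scale
        residual = np.max(np.abs(Z_new - Z))
        Z = Z_new
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"adjoint period map not converged after {max_periods} periods "
            f"(residual {residual:.2e})"
        )

    n = lc.n_grid
    k0 = (k + 1) * T
    s_eval = k0 + T * np.arange(n + 1) / n
    samp = solve_ivp(rhs, (k0, k0 + T), Z, method="DOP853",
                     rtol=rtol, atol=atol, t_eval=s_eval)
    # Z at backward time k0 + T*j/n is Z at phase -2pi*j/n = 2pi*(n-j)/n
    Zgrid = np.empty((n, 4))
    for j in range(n + 1):
        Zgrid[(n - j) % n] = samp.y[:, j]

    F = wb_derivatives(lc.orbit, lc.params)
    mean_ZF = float(np.mean(np.sum(Zgrid * F, axis=1)))
    if abs(mean_ZF) < 1e-14:
        raise RuntimeError("degenerate adjoint normalization integral")
    Zgrid /= mean_ZF

    diag = dict(lc.diagnostics)
    diag.update(adjoint_residual=residual, adjoint_periods=k + 1)
    return replace(lc, adjoint=Zgrid, diagnostics=diag)


# -- serialization ------------------------------------------------------------


def save_limit_cycle(lc: LimitCycle, directory) -> None:
    """Write orbit and adjoint CSV tables plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    header = "phase,V,h,n,s"
    np.savetxt(
        directory / "orbit.csv",
        np.column_stack([lc.phases, lc.orbit]),
        delimiter=",",
        header=header,
        comments="",
    )
    if lc.adjoint is not None:
        np.savetxt(
            directory / "adjoint.csv",
            np.column_stack([lc.phases, lc.adjoint]),
            delimiter=",",
            header="phase,Z_V,Z_h,Z_n,Z_s",
            comments="",
        )
    meta = {
        "T": lc.T,
        "Omega": lc.Omega,
        "n_grid": lc.n_grid,
        "params": {k: getattr(lc.params, k) for k in NeuronParams.__dataclass_fields__},
        "diagnostics": {k: v for k, v in lc.diagnostics.items()},
    }
    (directory / "limit_cycle.json").write_text(json.dumps(meta, indent=2))


def load_limit_cycle(directory) -> LimitCycle:
    directory = Path(directory)
    meta = json.loads((directory / "limit_cycle.json").read_text())
    orbit = np.loadtxt(directory / "orbit.csv", delimiter=",", skiprows=1)
    adjoint_path = directory / "adjoint.csv"
    adjoint = None
    if adjoint_path.exists():
        adjoint = np.loadtxt(adjoint_path, delimiter=",", skiprows=1)[:, 1:]
    return LimitCycle(
        T=meta["T"],
        phases=orbit[:, 0],
        orbit=orbit[:, 1:],
        params=NeuronParams(**meta["params"]),
        adjoint=adjoint,
        diagnostics=meta.get("diagnostics", {}),
    )
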