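"""Forward integrator for the extended MPDPDE model of tethered SPR reactions.

The multicenter particle density PDE (MPDPDE) coarse-grains the stochastic,
spatial kinetics of an enzyme binding to surface-immobilised phosphorylated
peptides and dephosphorylating neighbouring peptides within molecular reach.
The nondimensional state is

* ``nA``  — fraction of peptide sites that are phosphorylated and free,
* ``nB``  — fraction phosphorylated and enzyme-bound,
* ``Y(r)``  — pair correlation between a bound site and a free phospho-site
  at anchor separation ``r`` (in units of the reach L),
* ``XA(r)``, ``XB(r)`` — auto-correlations of free and bound phospho-sites,

with rates

* ``p1 = k_on * [enzyme]`` (binding), ``p2 = k_off`` (unbinding),
* ``p3 = k_cat(tethered) * [peptide]`` (trans catalysis, mean-field),
* ``p4 = k_cat(tethered) * sigma*`` (trans catalysis on the pair partner),
* ``p5 = k_cat(solution) * [enzyme]`` (catalysis from solution).

The dynamics are

    dnA/dt = -(p1+p5) nA + p2 nB
             - 4 pi c0 p3 nA nB * Int_0^inf r'^2 e^{-3r'^2/2} Y(r') dr'
    dnB/dt = p1 nA - p2 nB
    dY/dt  = p1 (nA/nB)(XA - Y) + p2 (nB/nA)(XB - Y)
             - c0 p4 e^{-3r^2/2} Y
             - 2 pi c0 p3 nB (Y/r) * D[Y, XB-1](r)
    dXA/dt = 2 p2 (nB/nA)(Y - XA) - 4 pi c0 p3 nB (XA/r) * D[Y, Y-1](r)
    dXB/dt = 2 p1 (nA/nB)(Y - XB)

with ``c0 = (3/(2 pi))^{3/2}`` and the bipolar double integral

    D[Y, G](r) = Int_0^inf dr' Int_{|r-r'|}^{r+r'} dq  q r' e^{-3r'^2/2} Y(r') G(q),

and initial conditions nA=1, nB=0, Y=XA=XB=1.  The observable sensorgram is

    Z(t) = 0                                   for t <  p_start
    Z(t) = n_ns (t - p_start) + A * nB         for p_start <= t <= p_stop
    Z(t) = A * nB                              for t >  p_stop

where the PDE clock starts at ``p_start``, the enzyme injection stops at
``p_stop`` (p1 = p5 = 0 afterwards), ``n_ns`` is a linear nonspecific-binding
drift and ``A`` is the amplitude mapping nB to instrument response units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "NondimParams",
    "RadialGrid",
    "FieldState",
    "Trajectory",
    "initial_state",
    "mpdpde_rhs",
    "integrate",
    "observable",
    "predict_signal",
]

_C0 = (3.0 / (2.0 * math.pi)) ** 1.5
_RATIO_FLOOR = 1e-12


@dataclass(frozen=True)
class NondimParams:
    """Nondimensional rate parameters plus observation nuisance terms.

    Rates ``p1..p5`` are in 1/s; ``n_ns`` in signal units per s;
    ``p_start``/``p_stop`` in s; ``amplitude`` in signal units per unit nB.
    """

    p1: float
    p2: float
    p3: float = 0.0
    p4: float = 0.0
    p5: float = 0.0
    n_ns: float = 0.0
    p_start: float = 0.0
    p_stop: float = 45.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3", "p4", "p5"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.p_start < 0:
            raise ValueError("p_start must be non-negative")
        if not self.p_stop > self.p_start:
            raise ValueError("p_stop must exceed p_start")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.p1, self.p2, self.p3, self.p4, self.p5,
             self.n_ns, self.p_start, self.p_stop, self.amplitude]
        )

    @classmethod
    def from_array(cls, vec) -> "NondimParams":
        p1, p2, p3, p4, p5, n_ns, p_start, p_stop, amplitude = map(float, vec)
        return cls(p1, p2, p3, p4, p5, n_ns, p_start, p_stop, amplitude)


class RadialGrid:
    """Uniform radial grid r_j = j*h, j = 1..n, h = r_max/n (units of L).

    Precomputes the Gaussian kernel on the nodes, trapezoid weights for
    the outer integrals, and the node indices of the bipolar limits
    |r_i - r_j| and r_i + r_j (both exact grid multiples), so each
    right-hand-side evaluation is a handful of O(n^2) array operations.
    """

    def __init__(self, r_max: float = 6.0, n_nodes: int = 96):
        if r_max < 5.0:
            raise ValueError("r_max must be >= 5 (kernel mass beyond 5 is < 1e-8)")
        if n_nodes < 64:
            raise ValueError("n_nodes must be >= 64")
        self.r_max = float(r_max)
        self.n_nodes = int(n_nodes)
        self.h = self.r_max / self.n_nodes
        j = np.arange(1, self.n_nodes + 1)
        self.r = j * self.h
        self.kernel = np.exp(-1.5 * self.r**2)
        # trapezoid weights for Int_0^{r_max} f dr' with f(0)=0 (all
        # integrands carry a factor r'), node n gets half weight
        w = np.full(self.n_nodes, self.h)
        w[-1] *= 0.5
        self.weights = w
        ii = j[:, None]
        jj = j[None, :]
        self.idx_hi = np.minimum(ii + jj, self.n_nodes)
        self.idx_lo = np.abs(ii - jj)
        # cumulative-trapezoid helper nodes q_0..q_n (q_0 = 0)
        self.q = np.concatenate(([0.0], self.r))

    def cumtrapz_q(self, g: np.ndarray) -> np.ndarray:
        """H_k = Int_0^{q_k} q g(q) dq with g given on r-nodes.

        g is flat-extrapolated to q=0 (the integrand q*g vanishes there).
        """
        qg = self.q * np.concatenate(([g[0]], g))
        out = np.empty(self.n_nodes + 1)
        out[0] = 0.0
        np.cumsum(0.5 * self.h * (qg[1:] + qg[:-1]), out=out[1:])
        return out


@dataclass
class FieldState:
    """PDE state: scalars nA, nB and radial functions Y, XA, XB."""

    nA: float
    nB: float
    Y: np.ndarray
    XA: np.ndarray
    XB: np.ndarray

    def pack(self) -> np.ndarray:
        return np.concatenate(([self.nA, self.nB], self.Y, self.XA, self.XB))

    @classmethod
    def unpack(cls, vec: np.ndarray, n: int) -> "FieldState":
        return cls(
            nA=float(vec[0]),
            nB=float(vec[1]),
            Y=vec[2 : 2 + n],
            XA=vec[2 + n : 2 + 2 * n],
            XB=vec[2 + 2 * n : 2 + 3 * n],
        )


def initial_state(grid: RadialGrid) -> FieldState:
    """nA=1, nB=0, Y=XA=XB=1."""
    ones = np.ones(grid.n_nodes)
    return FieldState(1.0, 0.0, ones.copy(), ones.copy(), ones.copy())


def _ratio(num: float, den: float) -> float:
    # ratio nX/nY regularised: whole term zeroed when the numerator state
    # is below the floor, denominator floored to avoid division by zero
    if num < _RATIO_FLOOR:
        return 0.0
    return num / max(den, _RATIO_FLOOR)


def _rhs_core(vec, p1, p2, p3, p4, p5, r, k, w, idx_hi, idx_lo, h):
    """Right-hand side on the packed state vector (hot path).

    Numerically identical to the documented equations; the bipolar double
    integrals use the exact-node cumulative-trapezoid identity described
    in :class:`RadialGrid`.
    """
    n = r.shape[0]
    nA = vec[0]
    nB = vec[1]
    Y = vec[2 : 2 + n]
    XA = vec[2 + n : 2 + 2 * n]
    XB = vec[2 + 2 * n : 2 + 3 * n]

    out = np.empty(2 + 3 * n)
    d_Y = out[2 : 2 + n]
    d_XA = out[2 + n : 2 + 2 * n]
    d_XB = out[2 + 2 * n : 2 + 3 * n]

    # single radial integral Int r'^2 e^{-3r'^2/2} Y dr'
    s1 = 0.0
    for j in range(n):
        s1 += w[j] * r[j] * r[j] * k[j] * Y[j]

    out[0] = -(p1 + p5) * nA + p2 * nB - 4.0 * math.pi * _C0 * p3 * nA * nB * s1
    out[1] = p1 * nA - p2 * nB

    rAB = 0.0 if nA < _RATIO_FLOOR else nA / max(nB, _RATIO_FLOOR)
    rBA = 0.0 if nB < _RATIO_FLOOR else nB / max(nA, _RATIO_FLOOR)

    for j in range(n):
        d_Y[j] = (p1 * rAB * (XA[j] - Y[j]) + p2 * rBA * (XB[j] - Y[j])
                  - _C0 * p4 * k[j] * Y[j])
        d_XA[j] = 2.0 * p2 * rBA * (Y[j] - XA[j])
        d_XB[j] = 2.0 * p1 * rAB * (Y[j] - XB[j])

    if p3 > 0.0 and nB > 0.0:
        hB = np.empty(n + 1)
        hY = np.empty(n + 1)
        v = np.empty(n)
        hB[0] = 0.0
        hY[0] = 0.0
        qgB = 0.0
        qgY = 0.0
        for j in range(n):
            qgB_next = r[j] * (XB[j] - 1.0)
            qgY_next = r[j] * (Y[j] - 1.0)
            hB[j + 1] = hB[j] + 0.5 * h * (qgB + qgB_next)
            hY[j + 1] = hY[j] + 0.5 * h * (qgY + qgY_next)
            qgB = qgB_next
            qgY = qgY_next
            v[j] = w[j] * r[j] * k[j] * Y[j]
        cY = 2.0 * math.pi * _C0 * p3 * nB
        cXA = 4.0 * math.pi * _C0 * p3 * nB
        for i in range(n):
            accB = 0.0
            accY = 0.0
            for j in range(n):
                hi = idx_hi[i, j]
                lo = idx_lo[i, j]
                accB += v[j] * (hB[hi] - hB[lo])
                accY += v[j] * (hY[hi] - hY[lo])
            d_Y[i] -= cY * (Y[i] / r[i]) * accB
            d_XA[i] -= cXA * (XA[i] / r[i]) * accY

    return out


try:  # optional acceleration; the pure-python path is semantically identical
    from numba import njit

    _rhs_core = njit(cache=True)(_rhs_core)
except ImportError:  # pragma: no cover - numba is a declared dependency

    def _rhs_core(vec, p1, p2, p3, p4, p5, r, k, w, idx_hi, idx_lo, h):
        n = r.shape[0]
        nA, nB = vec[0], vec[1]
        Y = vec[2 : 2 + n]
        XA = vec[2 + n : 2 + 2 * n]
        XB = vec[2 + 2 * n : 2 + 3 * n]
        s1 = float(np.dot(w, r**2 * k * Y))
        d_nA = -(p1 + p5) * nA + p2 * nB - 4.0 * math.pi * _C0 * p3 * nA * nB * s1
        d_nB = p1 * nA - p2 * nB
        rAB = _ratio(nA, nB)
        rBA = _ratio(nB, nA)
        d_Y = p1 * rAB * (XA - Y) + p2 * rBA * (XB - Y) - _C0 * p4 * k * Y
        d_XA = 2.0 * p2 * rBA * (Y - XA)
        d_XB = 2.0 * p1 * rAB * (Y - XB)
        if p3 > 0.0 and nB > 0.0:
            v = w * r * k * Y
            q = np.concatenate(([0.0], r))
            qgB = q * np.concatenate(([0.0], XB - 1.0))
            qgY = q * np.concatenate(([0.0], Y - 1.0))
            hB = np.concatenate(([0.0], np.cumsum(0.5 * h * (qgB[1:] + qgB[:-1]))))
            hY = np.concatenate(([0.0], np.cumsum(0.5 * h * (qgY[1:] + qgY[:-1]))))
            d_Y = d_Y - 2.0 * math.pi * _C0 * p3 * nB * (Y / r) * (
                (hB[idx_hi] - hB[idx_lo]) @ v
            )
            d_XA = d_XA - 4.0 * math.pi * _C0 * p3 * nB * (XA / r) * (
                (hY[idx_hi] - hY[idx_lo]) @ v
            )
        return np.concatenate(([d_nA, d_nB], d_Y, d_XA, d_XB))


def _rhs(vec: np.ndarray, p1, p2, p3, p4, p5, grid: RadialGrid) -> np.ndarray:
    vec = np.ascontiguousarray(vec, dtype=np.float64)
    return _rhs_core(
        vec, float(p1), float(p2), float(p3), float(p4), float(p5),
        grid.r, grid.kernel, grid.weights, grid.idx_hi, grid.idx_lo, grid.h,
    )


def mpdpde_rhs(state: FieldState, params: NondimParams, grid: RadialGrid,
               injection_on: bool = True) -> FieldState:
    """Time derivative of the PDE state.

    With ``injection_on=False`` the solution inputs are switched off
    (p1 = p5 = 0), as after the end of the enzyme injection.
    """
    p1, p5 = (params.p1, params.p5) if injection_on else (0.0, 0.0)
    dvec = _rhs(state.pack(), p1, params.p2, params.p3, params.p4, p5, grid)
    return FieldState.unpack(dvec, grid.n_nodes)


@dataclass
class Trajectory:
    """PDE trajectory on the internal clock tau = t - p_start."""

    tau: np.ndarray
    nA: np.ndarray
    nB: np.ndarray
    params: NondimParams
    grid: RadialGrid
    fields: list = field(default_factory=list, repr=False)

    def to_frame(self):
        import pandas as pd

        t = self.tau + self.params.p_start
        return pd.DataFrame(
            {"time": t, "nA": self.nA, "nB": self.nB,
             "Z": observable(self, self.params, times=t)}
        )


def integrate(
    params: NondimParams,
    grid: RadialGrid,
    t_end: float,
    t_eval=None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    method: str = "RK45",
    keep_fields: bool = False,
) -> Trajectory:
    """Integrate the MPDPDE on the PDE clock tau in [0, t_end].

    ``t_end`` and ``t_eval`` are on the PDE clock (tau = t - p_start).
    At tau_stop = p_stop - p_start the enzyme injection ends and
    p1 = p5 = 0 for the dissociation phase.  Deterministic given
    params, grid and tolerances.
    """
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 201)
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.size and (t_eval[0] < 0 or t_eval[-1] > t_end + 1e-12):
        raise ValueError("t_eval must lie within [0, t_end]")

    tau_stop = params.p_stop - params.p_start
    y0 = initial_state(grid).pack()
    opts = dict(method=method, rtol=rtol, atol=atol)

    def run(y_init, t0, t1, eval_pts, on):
        p1, p5 = (params.p1, params.p5) if on else (0.0, 0.0)
        sol = solve_ivp(
            lambda t, y: _rhs(y, p1, params.p2, params.p3, params.p4, p5, grid),
            (t0, t1),
            y_init,
            t_eval=eval_pts if len(eval_pts) else None,
            **opts,
        )
        if not sol.success:
            raise RuntimeError(
                f"MPDPDE integration failed at t={sol.t[-1] if sol.t.size else t0}: "
                f"{sol.message}"
            )
        return sol

    if t_end <= tau_stop:
        sol = run(y0, 0.0, t_end, t_eval, on=True)
        t, y = sol.t, sol.y
    else:
        ev1 = t_eval[t_eval <= tau_stop]
        ev2 = t_eval[t_eval > tau_stop]
        eval1 = ev1 if (len(ev1) and ev1[-1] == tau_stop) else np.append(ev1, tau_stop)
        sol1 = run(y0, 0.0, tau_stop, eval1, on=True)
        if len(ev2):
            sol2 = run(sol1.y[:, -1], tau_stop, t_end, ev2, on=False)
            t = np.concatenate([sol1.t[: len(ev1)], sol2.t])
            y = np.concatenate([sol1.y[:, : len(ev1)], sol2.y], axis=1)
        else:
            t = sol1.t[: len(ev1)]
            y = sol1.y[:, : len(ev1)]
    n = grid.n_nodes
    fields = (
        [FieldState.unpack(y[:, i].copy(), n) for i in range(y.shape[1])]
        if keep_fields
        else []
    )
    return Trajectory(tau=t, nA=y[0], nB=y[1], params=params, grid=grid, fields=fields)


def observable(traj: Trajectory, params: NondimParams, times=None) -> np.ndarray:
    """Model sensorgram Z at experiment times (seconds from trace origin).

    Piecewise: zero before p_start; amplitude*nB plus the linear
    nonspecific drift n_ns*(t - p_start) during the injection; bare
    amplitude*nB after p_stop (the drift term drops at injection end,
    so Z is discontinuous there by n_ns*(p_stop - p_start) when
    n_ns != 0).
    """
    if times is None:
        times = traj.tau + params.p_start
    t = np.asarray(times, dtype=float)
    tau = t - params.p_start
    nB = np.interp(tau, traj.tau, traj.nB, left=0.0)
    z = params.amplitude * nB
    during = (t >= params.p_start) & (t <= params.p_stop)
    z = np.where(during, z + params.n_ns * tau, z)
    z = np.where(t < params.p_start, 0.0, z)
    return z


def predict_signal(
    params: NondimParams,
    grid: RadialGrid,
    times,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    method: str = "RK45",
) -> np.ndarray:
    """Convenience: integrate the PDE and evaluate Z at the given times."""
    t = np.asarray(times, dtype=float)
    tau_end = max(float(t[-1] - params.p_start), 1e-6)
    tau_eval = np.clip(t - params.p_start, 0.0, tau_end)
    tau_eval = np.unique(np.concatenate(([0.0], tau_eval[tau_eval > 0])))
    traj = integrate(params, grid, tau_end, t_eval=tau_eval,
                     rtol=rtol, atol=atol, method=method)
    return observable(traj, params, times=t)


def switch_off_injection(params: NondimParams) -> NondimParams:
    """Params with p1 = p5 = 0 (post-injection dissociation phase)."""
    return replace(params, p1=0.0, p5=0.0)
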