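"""Brute-force stochastic simulator of the microscopic tethered reaction.

Phosphorylated peptide sites are immobilised at random positions in a
periodic box (lengths in units of the molecular reach L).  Each site is
in one of three states:

* FREE   — phosphorylated, no enzyme bound,
* BOUND  — phosphorylated with enzyme bound via its SH2 domains,
* DEPHOS — dephosphorylated (absorbing: the enzyme only binds
  phospho-sites, so these never re-enter the dynamics).

Events (exact Gillespie simulation, exponential waiting times):

* FREE -> BOUND at rate p1 (binding from solution),
* BOUND -> FREE at rate p2 (unbinding),
* FREE -> DEPHOS at rate p5 (catalysis by solution enzyme),
* FREE j -> DEPHOS by a BOUND site i at rate p4 * sigma_hat(r_ij), where
  sigma_hat(r) = (3/(2 pi))^{3/2} exp(-3 r^2 / 2) is the nondimensional
  reach kernel and r_ij the minimum-image anchor distance.

The pairwise rule uses p4 = k_cat(tethered) * sigma*; in the mean-field
PDE the same microscopic process appears both as the p3 density term and
as the p4 pair term, linked through the nondimensional site density
rho_hat = sites per L^3 by p4 = p3 / rho_hat.  Comparisons between this
simulator and :mod:`tetherkin.mpdpde` must therefore use parameter sets
satisfying that relation (see :func:`pde_params_for_system`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .mpdpde import NondimParams

__all__ = [
    "FREE",
    "BOUND",
    "DEPHOS",
    "ParticleSystem",
    "sample_sites",
    "pde_params_for_system",
    "SimResult",
    "simulate",
    "ensemble_average",
]

FREE, BOUND, DEPHOS = 0, 1, 2

_C0 = (3.0 / (2.0 * math.pi)) ** 1.5


@dataclass
class ParticleSystem:
    """Immobilised reaction sites in a periodic cubic box (units of L)."""

    positions: np.ndarray  # (n_sites, 3)
    box_side: float
    density: float  # requested sites per L^3

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    @property
    def realized_density(self) -> float:
        return self.n_sites / self.box_side**3

    def pairwise_kernel(self) -> np.ndarray:
        """sigma_hat(r_ij) with minimum-image distances; zero diagonal."""
        d = self.positions[:, None, :] - self.positions[None, :, :]
        d -= self.box_side * np.round(d / self.box_side)
        r2 = np.einsum("ijk,ijk->ij", d, d)
        k = _C0 * np.exp(-1.5 * r2)
        np.fill_diagonal(k, 0.0)
        return k


def sample_sites(density: float, box_side: float, seed: int) -> ParticleSystem:
    """Poisson number of sites placed uniformly in a periodic box.

    ``density`` is sites per L^3; ``box_side`` is in units of L and must
    be at least 4 to keep kernel truncation bias negligible.
    """
    if density < 0:
        raise ValueError("density must be non-negative")
    if box_side < 4:
        raise ValueError("box_side must be >= 4 (kernel truncation bias)")
    rng = np.random.default_rng(seed)
    n = rng.poisson(density * box_side**3)
    pos = rng.uniform(0.0, box_side, size=(n, 3))
    return ParticleSystem(positions=pos, box_side=float(box_side), density=float(density))


def pde_params_for_system(system: ParticleSystem, params: NondimParams) -> NondimParams:
    """PDE parameter set matching a particle system's realised density.

    Enforces the mean-field consistency p3 = p4 * rho_hat so the PDE's
    density term corresponds to the simulator's pairwise rule.
    """
    return replace(params, p3=params.p4 * system.realized_density)


@dataclass
class SimResult:
    """Event log and state time series from one Gillespie run."""

    times: np.ndarray  # event times, starting at 0.0
    event_types: list  # str per event ("bind", "unbind", "sol", "trans")
    site_ids: np.ndarray  # primary site of each event
    nA: np.ndarray  # fraction FREE after each event (index 0 = initial)
    nB: np.ndarray  # fraction BOUND after each event

    def at(self, t_grid: np.ndarray):
        """Piecewise-constant nA, nB sampled on a time grid."""
        idx = np.searchsorted(self.times, t_grid, side="right") - 1
        return self.nA[idx], self.nB[idx]

    def event_log(self):
        """Event log as a DataFrame (time, event, site) for text export."""
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times[1:], "event": self.event_types,
             "site": self.site_ids[1:]}
        )


def simulate(
    system: ParticleSystem,
    params: NondimParams,
    t_end: float,
    seed: int,
) -> SimResult:
    """Exact Gillespie simulation of the microscopic process.

    The injection switch is honoured: for event times past
    ``params.p_stop - params.p_start`` (PDE clock) the binding and
    solution-catalysis channels are off (p1 = p5 = 0).
    """
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    rng = np.random.default_rng(seed)
    n = system.n_sites
    tau_stop = params.p_stop - params.p_start

    state = np.full(n, FREE, dtype=np.int8)
    kmat = params.p4 * system.pairwise_kernel() if (params.p4 > 0 and n) else None
    # trans_rate[j] = sum over BOUND i of p4*sigma_hat(r_ij), for FREE j
    trans_in = np.zeros(n)

    times = [0.0]
    etypes: list = []
    ids = [-1]
    nA_list = [1.0 if n else 0.0]
    nB_list = [0.0]
    t = 0.0
    n_free = n
    n_bound = 0

    while True:
        on = t < tau_stop
        p1 = params.p1 if on else 0.0
        p5 = params.p5 if on else 0.0
        free = state == FREE
        bound = state == BOUND
        rates = np.zeros(n)
        rates[free] = p1 + p5 + trans_in[free]
        rates[bound] = params.p2
        total = rates.sum()
        if total <= 0 or n == 0:
            break
        dt = rng.exponential(1.0 / total)
        # if the injection ends before the next event, restart the clock
        # draw at tau_stop with the post-injection rates
        if on and t + dt > tau_stop:
            t = tau_stop
            continue
        t += dt
        if t > t_end:
            break
        i = int(rng.choice(n, p=rates / total))
        if state[i] == BOUND:
            state[i] = FREE
            n_bound -= 1
            n_free += 1
            if kmat is not None:
                trans_in -= kmat[i]
            etypes.append("unbind")
        else:
            # partition the site's rate among its channels
            u = rng.uniform(0.0, rates[i])
            if u < p1:
                state[i] = BOUND
                n_free -= 1
                n_bound += 1
                if kmat is not None:
                    trans_in += kmat[i]
                etypes.append("bind")
            else:
                state[i] = DEPHOS
                n_free -= 1
                etypes.append("sol" if u < p1 + p5 else "trans")
        times.append(t)
        ids.append(i)
        nA_list.append(n_free / n)
        nB_list.append(n_bound / n)

    return SimResult(
        times=np.asarray(times),
        event_types=etypes,
        site_ids=np.asarray(ids),
        nA=np.asarray(nA_list),
        nB=np.asarray(nB_list),
    )


def ensemble_average(runs, t_grid):
    """Mean and standard error of nA(t), nB(t) over replicate runs.

    Returns a dict with keys ``nA_mean``, ``nA_se``, ``nB_mean``,
    ``nB_se`` on the common time grid.  SE = sd / sqrt(n_runs).
    """
    runs = list(runs)
    if len(runs) < 2:
        raise ValueError("need at least 2 runs for an ensemble average")
    t_grid = np.asarray(t_grid, dtype=float)
    nA = np.empty((len(runs), t_grid.size))
    nB = np.empty((len(runs), t_grid.size))
    for k, run in enumerate(runs):
        nA[k], nB[k] = run.at(t_grid)
    scale = math.sqrt(len(runs))
    return {
        "t": t_grid,
        "nA_mean": nA.mean(axis=0),
        "nA_se": nA.std(axis=0, ddof=1) / scale,
        "nB_mean": nB.mean(axis=0),
        "nB_se": nB.std(axis=0, ddof=1) / scale,
    }
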