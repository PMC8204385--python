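"""Synthetic multiphasic sensorgrams with known ground truth.

No public repository of raw tethered-dephosphorylation sensorgrams
exists, so every downstream stage (fitting, MCMC, reach regression) is
exercised against traces generated by the forward model itself: fast
association, reach-limited self-dephosphorylation decay, a slow
solution-catalysis tail, a linear nonspecific drift during the
injection, and dissociation after injection end, plus additive Gaussian
instrument noise.

The default parameter sets are the published per-substrate averages
(:func:`table2_fixtures`), so synthetic experiments span the regimes the
assay actually probed: a PEG-linker series (0-28 units), the full PD-1
and SLAM cytoplasmic tails, and a low-temperature condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import ExperimentConditions, PhysicalParams, from_physical
from .io import SPRTrace
from .mpdpde import NondimParams, RadialGrid, predict_signal
from . import units

__all__ = [
    "NoiseModel",
    "generate_trace",
    "table2_fixtures",
    "generate_peg_series",
    "DEFAULT_CONDITIONS",
]

#: Default synthetic experiment: 1 uM enzyme over 10 uM immobilised
#: peptide, 45 s injection (the assay's standard protocol).  At these
#: concentrations the published PEG28 rates give the characteristic
#: multiphasic trace: association peak within a few seconds, tethered
#: self-dephosphorylation decay over ~15 s, a slow solution-catalysis
#: tail, and a sharp dissociation drop at injection end.
DEFAULT_CONDITIONS = ExperimentConditions(shp1_conc=1.0, peptide_conc=10.0)

#: Signal units per unit bound fraction.  With ~1 uM enzyme the bound
#: fraction peaks near 0.16, putting the peak at ~16 RU, in the range of
#: reference-subtracted instrument traces.
DEFAULT_AMPLITUDE = 100.0


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian instrument noise plus a linear injection drift."""

    additive_sd: float = 0.3  # ~peak/50 at the default amplitude
    drift_n_ns: float = 0.05  # signal units / s; visible baseline shift
    seed: int = 0
    sampling_rate: float = 10.0  # Hz

    def __post_init__(self) -> None:
        if self.additive_sd < 0:
            raise ValueError("additive_sd must be non-negative")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")


def generate_trace(
    phys: PhysicalParams,
    cond: ExperimentConditions = DEFAULT_CONDITIONS,
    noise: NoiseModel = NoiseModel(),
    amplitude: float = DEFAULT_AMPLITUDE,
    p_start: float = 0.1,
    dissociation_window: float = 20.0,
    grid: RadialGrid | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> SPRTrace:
    """Forward-simulate a sensorgram and add measurement noise.

    The trace covers a short pre-injection baseline, the injection
    (p_start .. p_start + injection_duration) and a dissociation window;
    ``additive_sd = 0`` reproduces the model observable exactly.  The
    ground truth (physical constants, nondimensional parameters,
    conditions, noise settings) is stored in the trace metadata.
    """
    if grid is None:
        grid = RadialGrid()
    params = from_physical(
        phys, cond, n_ns=noise.drift_n_ns, p_start=p_start, amplitude=amplitude
    )
    t_end = params.p_stop + dissociation_window
    n_samples = int(round(t_end * noise.sampling_rate)) + 1
    times = np.linspace(0.0, t_end, n_samples)
    z = predict_signal(params, grid, times, rtol=rtol, atol=atol)
    if noise.additive_sd > 0:
        rng = np.random.default_rng(noise.seed)
        z = z + rng.normal(0.0, noise.additive_sd, size=z.shape)
    truth = {
        "k_on": phys.k_on,
        "k_off": phys.k_off,
        "KD": phys.KD,
        "k_cat_tethered": phys.k_cat_tethered,
        "k_cat_solution": phys.k_cat_solution,
        "sigma_star": phys.sigma_star,
        "reach_nm": phys.reach,
        "nondim": list(params.as_array()),
    }
    meta = {
        "synthetic": True,
        "ground_truth": truth,
        "conditions": {
            "shp1_conc": cond.shp1_conc,
            "peptide_conc": cond.peptide_conc,
            "injection_duration": cond.injection_duration,
            "temperature_label": cond.temperature_label,
        },
        "noise": {
            "additive_sd": noise.additive_sd,
            "drift_n_ns": noise.drift_n_ns,
            "seed": noise.seed,
            "sampling_rate": noise.sampling_rate,
        },
        "amplitude": amplitude,
    }
    return SPRTrace(times, z, meta)


# Published per-substrate averages: N replicates, k_on (uM^-1 s^-1),
# k_off (s^-1), K_D (uM), L (nm), sigma* (uM) with its SE, k_cat(tethered)
# and k_cat(solution) (uM^-1 s^-1).
_TABLE2 = {
    "PEG0":      dict(n_peg=0,  n=3,  k_on=0.19, k_off=1.9, KD=10.4, L=10.9, sigma_star=1300.0, sigma_star_se=100.0, k_cat_tethered=0.041,  k_cat_solution=0.020),
    "PEG3":      dict(n_peg=3,  n=5,  k_on=0.22, k_off=1.6, KD=8.0,  L=13.4, sigma_star=690.0,  sigma_star_se=90.0,  k_cat_tethered=0.047,  k_cat_solution=0.040),
    "PEG6":      dict(n_peg=6,  n=6,  k_on=0.31, k_off=1.5, KD=4.9,  L=16.0, sigma_star=410.0,  sigma_star_se=77.0,  k_cat_tethered=0.033,  k_cat_solution=0.027),
    "PEG12":     dict(n_peg=12, n=5,  k_on=0.25, k_off=1.7, KD=7.2,  L=16.0, sigma_star=400.0,  sigma_star_se=100.0, k_cat_tethered=0.034,  k_cat_solution=0.030),
    "PEG28":     dict(n_peg=28, n=14, k_on=0.34, k_off=1.8, KD=6.1,  L=19.7, sigma_star=210.0,  sigma_star_se=40.0,  k_cat_tethered=0.042,  k_cat_solution=0.031),
    "PEG28_10C": dict(n_peg=28, n=8,  k_on=0.28, k_off=0.8, KD=2.9,  L=12.0, sigma_star=960.0,  sigma_star_se=260.0, k_cat_tethered=0.0036, k_cat_solution=0.0047),
    "PD1":       dict(n_peg=None, n=3, k_on=0.21, k_off=2.4, KD=11.0, L=16.0, sigma_star=400.0, sigma_star_se=100.0, k_cat_tethered=0.040,  k_cat_solution=0.023),
    "SLAM":      dict(n_peg=None, n=3, k_on=0.02, k_off=1.7, KD=130.0, L=31.2, sigma_star=55.0, sigma_star_se=6.0,   k_cat_tethered=0.036,  k_cat_solution=0.0058),
}


def table2_fixtures() -> dict:
    """Published average parameter sets, one per substrate.

    Returns ``{name: {"physical": PhysicalParams, ...row fields...}}``
    covering the PEG series (PEG0..PEG28), the low-temperature PEG28
    condition and the PD-1 and SLAM tail peptides.
    """
    out = {}
    for name, row in _TABLE2.items():
        phys = PhysicalParams(
            k_on=row["k_on"],
            k_off=row["k_off"],
            k_cat_tethered=row["k_cat_tethered"],
            k_cat_solution=row["k_cat_solution"],
            sigma_star=row["sigma_star"],
        )
        out[name] = {"physical": phys, **row}
    return out


def generate_peg_series(
    l_enzyme: float = 13.0,
    l_p: float = 0.4,
    l_unit: float = 0.4,
    peg_lengths=(3, 6, 12, 28),
    replicates: int = 5,
    noise_cv: float = 0.15,
    seed: int = 0,
) -> dict:
    """Replicate sigma* tables from the linear tether-length law.

    Per PEG length N the true squared reach is
    L^2 = 4 * N * l_unit * l_p + l_enzyme^2; the corresponding sigma* is
    scattered across replicates with multiplicative lognormal noise of
    coefficient of variation ``noise_cv`` (keeping values positive).

    Returns ``{n_peg: array of sigma* replicate values (uM)}`` suitable
    for :func:`tetherkin.reach.table_from_sigma`.
    """
    if not l_enzyme > 0:
        raise ValueError("l_enzyme must be positive")
    rng = np.random.default_rng(seed)
    out = {}
    if noise_cv > 0:
        sigma_log = np.sqrt(np.log1p(noise_cv**2))
    else:
        sigma_log = 0.0
    for n_peg in peg_lengths:
        l2 = 4.0 * n_peg * l_unit * l_p + l_enzyme**2
        sigma_true = units.sigma_star_from_reach(np.sqrt(l2))
        if sigma_log > 0:
            # mean-preserving lognormal scatter
            factors = rng.lognormal(-0.5 * sigma_log**2, sigma_log, size=replicates)
        else:
            factors = np.ones(replicates)
        out[int(n_peg)] = sigma_true * factors
    return out
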