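"""Validate the PDE against the exact stochastic particle simulator.

Places phospho-sites at random in a periodic box, runs the microscopic
Gillespie process (binding, unbinding, solution catalysis, pairwise
trans-catalysis through the Gaussian reach kernel) and compares the
ensemble-averaged bound fraction with the pair-correlation PDE.
"""

import numpy as np

from tetherkin.mpdpde import NondimParams, RadialGrid, integrate
from tetherkin.oracle import ensemble_average, sample_sites, simulate

micro = NondimParams(p1=0.5, p2=1.0, p4=0.5, p5=0.05, p_stop=1e9)
density, box = 2.0, 8.0
runs = [
    simulate(sample_sites(density, box, seed=100 + s), micro, 6.0, seed=s)
    for s in range(40)
]
t_grid = np.linspace(0.5, 6.0, 8)
ens = ensemble_average(runs, t_grid)

# mean-field consistency: p3 = p4 * (sites per reach-volume)
pde = integrate(
    NondimParams(p1=0.5, p2=1.0, p3=micro.p4 * density, p4=micro.p4,
                 p5=0.05, p_stop=1e9),
    RadialGrid(), 6.0, t_eval=t_grid,
)

print(f"{'t (s)':>6} {'nB (Gillespie)':>15} {'nB (PDE)':>10} {'dev/SE':>7}")
for i, t in enumerate(t_grid):
    z = (ens["nB_mean"][i] - pde.nB[i]) / ens["nB_se"][i]
    print(f"{t:>6.1f} {ens['nB_mean'][i]:>15.4f} {pde.nB[i]:>10.4f} {z:>7.2f}")
# Agreement within ~2 Monte-Carlo standard errors shows the
# pair-correlation closure captures the spatially correlated depletion
# that a plain mean-field model would miss.
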