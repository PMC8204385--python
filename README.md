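# tetherkin

Binding, catalysis and **molecular reach** of membrane-tethered enzyme
reactions, from surface plasmon resonance (SPR) sensorgrams.

Immune receptors signal by tethering cytoplasmic enzymes to their
phosphorylated tails. The phosphatase SHP-1, recruited by its SH2
domains to inhibitory receptors such as PD-1 or SLAM, dephosphorylates
other receptor tails *within reach*. How far the tethered catalytic
site can extend — the molecular reach `L` of the reaction — controls
both which substrates are accessible and the effective local enzyme
concentration, σ\* = 1/L³. `tetherkin` is a toolkit for measuring and
exploiting that quantity:

* **`tetherkin.mpdpde`** — a pair-correlation PDE (the MPDPDE model)
  that forward-simulates the multiphasic SPR traces produced when
  injected SHP-1 binds immobilised phospho-peptides and destroys its
  own binding sites in *trans*: fast association, reach-limited
  self-dephosphorylation decay, a solution-catalysis tail, nonspecific
  drift, and dissociation after injection end.
* **`tetherkin.oracle`** — an exact stochastic (Gillespie) particle
  simulator of the same microscopic process; the ground truth against
  which the PDE closure is validated.
* **`tetherkin.fitting`** — recovery of the eight model parameters
  (k_on, k_off, k_cat(tethered), σ\*, k_cat(solution), drift and
  injection timing) from a single trace by simulated annealing with
  quartic cooling plus least-squares polish; `screened_fit` adds a
  deterministic catalysis screen for scaled-down budgets.
* **`tetherkin.mcmc`** — Metropolis–Hastings identifiability analysis
  (adaptive step sizes, optional Fisher-preconditioned joint kernel,
  quarter-wise Kolmogorov–Smirnov stationarity rule).
* **`tetherkin.reach`** — σ\* → L conversion, the PEG-tether-series
  regression L² = 4·N·l_PEG·l_p + L_enzyme² that isolates the enzyme's
  own reach, and quadrature parsing/combining of component reaches.
* **`tetherkin.membrane`** — membrane-scale predictions: effective
  concentration C_eff = √(3/2π)·ρ₀/L and Poisson substrate coverage
  P≥1 = 1 − exp(−π·ρ₀·L²).
* **`tetherkin.synthetic`** — sensorgram generator with known ground
  truth, seeded with the published per-substrate parameter averages.

See `docs/methods.md` for the models, numerics and their assumptions,
and `examples/` for one short narrative script per capability.

## Worked example: isolating the reach of SHP-1

The reach of the *reaction* mixes tether and enzyme. Shortening the
PEG tether in steps and regressing the squared reach on tether length
leaves the enzyme's contribution as the intercept:

```python
from tetherkin.reach import peg_regression, table_from_sigma

# published per-PEG averages: (mean sigma* in uM, SE, n replicates)
sigma = {0: (1300, 100, 3), 3: (690, 90, 5), 6: (410, 77, 6),
         12: (400, 100, 5), 28: (210, 40, 14)}
table = table_from_sigma(sigma)
res = peg_regression(table, exclude={0})   # PEG0: steric artefacts
print(f"L_SHP-1 = {res['L_enzyme']:.2f} +/- {res['L_enzyme_se']:.2f} nm")
```

Output (`python examples/03_reach_regression.py`):

```
 n_peg  sigma_star_mean     L  L_squared
     0           1300.0 10.85     117.73
     3            690.0 13.40     179.58
     6            410.0 15.94     254.08
    12            400.0 16.07     258.30
    28            210.0 19.92     396.90

L^2 = 7.88 * N_PEG + 175.7  (R^2 = 0.939, p = 0.0309)
enzyme reach L_SHP-1 = 13.25 +/- 0.83 nm
```

Local concentration falls (reach grows) as the tether lengthens; the
intercept-root ≈ 13 nm is the phosphatase's own reach — more than
double the 5.3 nm crystal-structure estimate, implying the enzyme
explores extended active conformations.

Feeding that into the membrane model
(`python examples/04_membrane_coverage.py`):

```
combined receptor-enzyme reach: 14.56 nm
uniform density for 80,000 receptors on a 5-um cell: 0.000255 /nm^2
substrate coverage at that density: 15.6%
effective enzyme concentration within reach: 20.1 uM (cytosolic pool ~1 uM)
density needed for 90% coverage: 0.0035 /nm^2 (~14-fold above uniform: co-clustering required)
```

Uniformly distributed receptor–enzyme complexes reach only ~15 % of
membrane substrates; inhibiting the rest requires co-clustering.

## Command line

A thin CLI wraps the library for batch use:

```bash
tetherkin simulate --fixture PEG28 --seed 1 --out trace.csv
tetherkin fit trace.csv --shp1-conc 1.0 --peptide-conc 10.0 --amplitude 100
tetherkin reach-regression series.csv
tetherkin membrane --coverage 0.9 --reach 14.6
tetherkin oracle-check --density 2 --runs 20
```

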