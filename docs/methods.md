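# Methods

`tetherkin` quantifies membrane-tethered enzyme reactions — concretely,
the tyrosine phosphatase SHP-1 recruited by its SH2 domains to
phosphorylated receptor-tail peptides (PD-1, SLAM) immobilised on an SPR
surface, where it dephosphorylates neighbouring peptides within
molecular reach. This note documents the models, the numerics, the
synthetic-data conditions, and the choices made where the design was
genuinely open.

## The reach kernel and the σ*–L dictionary

A tethered catalytic site explores space around its anchor with a
Gaussian density

σ(r) = (3 / (2π L²))^{3/2} · exp(−3r² / (2L²)),

where `r` is the anchor–anchor separation and `L` the molecular reach of
the reaction. The kernel integrates to 1 over 3D space; its planar
integral is √(3/(2π))/L. Reaches of independent flexible components add
in quadrature: for the SPR geometry (two identical peptide tethers plus
the enzyme), L² = 2·L_tether² + L_enzyme².

The effective local concentration between two co-anchored sites is
σ* = 1/L³, converted between nm⁻³ and μM with the 2019 SI Avogadro
constant (1 μM ≡ 6.02214076×10⁻⁷ nm⁻³). All lengths in the package are
nm, times s, concentrations μM; conversion happens only in
`tetherkin.units`.

Two worm-like-chain conventions are exposed (`wlc_sqrt_lclp`,
`wlc_sqrt_2lclp`, i.e. L = √(l_c·l_p) or √(2·l_c·l_p)) because both
appear in the literature depending on whether L parameterises the
end-to-end density of a single chain or the kernel above; the
tether-length regression below uses the convention under which the
squared reaction reach is linear in the number of tether units with
slope 4·l_unit·l_p. Structure-derived reach estimates for SHP-1
(5.3 nm from the open crystal conformation, 20.4 nm fully stretched)
are stored as documented reference constants, not computed.

## The pair-correlation PDE (MPDPDE) forward model

Mean-field kinetics cannot describe tethered catalysis on an
immobilised surface: a bound enzyme preferentially destroys the
phospho-sites *near itself*, so the survivors are spatially
anti-correlated with bound enzyme. The model therefore tracks, besides
the free and bound phospho-site fractions `nA`, `nB`, three radial
correlation functions: `Y(r)` (bound–free pair correlation) and
`XA(r)`, `XB(r)` (free–free and bound–bound auto-correlations), with
nondimensional rates

p1 = k_on·[enzyme], p2 = k_off, p3 = k_cat(tethered)·[peptide],
p4 = k_cat(tethered)·σ*, p5 = k_cat(solution)·[enzyme],

and separations measured in units of L. The full system is written in
the `tetherkin.mpdpde` module docstring. Two structural points deserve
note:

* The binding/unbinding couplings of the correlation functions carry
  ratio factors (nA/nB and nB/nA). These follow uniquely from ordered
  pair-density bookkeeping: writing ρ_AB = nA·nB·Y and balancing
  AA→AB→BB conversions gives dY/dt = p1(nA/nB)(XA−Y) + p2(nB/nA)(XB−Y)
  and the analogous auto-correlation equations. The ratios are
  regularised: a term is zeroed when its numerator state is below
  10⁻¹², and denominators are floored at 10⁻¹². Early in a run this
  makes XB relax toward Y at a formally unbounded rate, which the
  explicit solver crosses as a short boundary layer. Note that the
  correlation fields are *not* confined to [0, 1]: while the bound–free
  pair correlation Y is strongly depleted near the anchor (the enzyme
  destroys its close partners), the auto-correlation of surviving free
  sites drifts slightly above 1 (≈ 1.01 over a 20 s injection at
  typical rates) because survivors cluster in enzyme-poor regions —
  genuine physics of the closure, invariant under grid refinement.
* The observable is Z(t) = 0 before the injection starts (p_start),
  A·nB(t) + n_ns·(t − p_start) during the injection, and A·nB(t) after
  it ends (p_stop), where `n_ns` is a linear nonspecific-binding drift
  and `A` maps the bound fraction to instrument response units. The
  drift ramps from zero at p_start (the baseline shift accrues during
  the injection) and drops at p_stop as the piecewise form states, so Z
  is discontinuous there by n_ns·(p_stop − p_start). At p_stop the
  solution inputs switch off (p1 = p5 = 0) for the dissociation phase.

### Discretisation

The radial functions live on a uniform grid r_j = j·h, j = 1…n,
h = r_max/n, with defaults r_max = 6 (kernel mass beyond is < 10⁻⁹) and
n = 96; a coarser preset (r_max = 5, n = 64, looser ODE tolerances) is
used inside iterative fitting. Doubling both n and r_max changes nB(t)
by < 0.5 % sup-norm (asserted in tests; measured ≈ 10⁻¹⁴ because the
integrands are smooth and compactly supported).

The equations contain "bipolar" double integrals
∫dr′∫_{|r−r′|}^{r+r′} dq [q r′ e^{−3r′²/2} Y(r′) G(q)]. On a uniform
grid from 0 the limits |r_i − r_j| and r_i + r_j are themselves grid
nodes, so the inner integral is an exact difference of a cumulative
trapezoid of q·G(q) — no interpolation — and one right-hand side costs
O(n²). The hot loop is numba-compiled with a semantically identical
NumPy fallback.

Time integration uses `scipy.solve_ivp` with RK45 (rtol 10⁻⁶,
atol 10⁻⁸ by default). The system's fastest persistent rate is
c₀·p4 ≲ 10 s⁻¹ in the regimes of interest, which an explicit method
handles efficiently; LSODA is available via `solver_opts` but is ~5×
slower here. The Langmuir limit (p3 = p4 = p5 = 0) reproduces
nB = (p1/(p1+p2))(1 − e^{−(p1+p2)t}) to < 10⁻⁵ sup-norm, and binding
conserves nA + nB to < 10⁻⁶.

## The stochastic particle oracle

`tetherkin.oracle` is an exact Gillespie simulation of the microscopic
process the PDE coarse-grains: a Poisson number of sites placed
uniformly in a periodic cubic box (side ≥ 4 L, default ≥ 6 L, minimum-
image distances), with events FREE→BOUND (p1), BOUND→FREE (p2),
FREE→DEPHOS from solution (p5), and pairwise trans-catalysis in which a
BOUND site i dephosphorylates a FREE site j at rate p4·σ̂(r̂_ij), where
σ̂ is the nondimensional kernel. Dephosphorylated sites are absorbing.

A single microscopic rule generates both catalysis terms of the PDE:
the mean-field p3 sink and the pair-level p4 sink are linked through
the nondimensional site density ρ̂ (sites per L³) by p3 = p4·ρ̂.
Comparisons between simulator and PDE must respect that relation
(`pde_params_for_system`). This resolves the question of what the p4
term means microscopically: it is the bound enzyme acting on the
specific pair partner being tracked, not a separate co-anchor process.

Equivalence testing uses box side 8: at sides 5–6 the periodic
finite-size correlations bias nB by ~2 %, which modest ensembles can
already resolve; at side 8 (~1000 sites at density 2/L³) the PDE and
100-replicate ensembles agree within ~2 Monte-Carlo standard errors
across a three-point sweep of the catalysis strength.

## Parameter estimation

The eight free quantities per trace are p1…p5, the drift n_ns and the
injection window (p_start, p_stop); the amplitude is treated as known
(from the immobilisation level) by default and can be co-fit. The
objective is the plain sum of squared errors over the whole trace,
including the dissociation phase. Optimisation operates on log-rates
(positivity) with linear n_ns, p_start, p_stop; rates are hard-bounded
to [10⁻⁷, 10³] s⁻¹ — far outside any physical value here, but keeping
the explicit solver tractable and the flat priors effectively proper.

`simulated_annealing` implements the Metropolis walk with the quartic
cooling schedule T(step) = T0·(1 − (step/n_steps)⁴), single-parameter
Gaussian proposals with acceptance-driven scale adaptation during the
first 30 % of the run, best-ever tracking, and an optional
least-squares polish. With the reference 10⁵-step schedule, T0 equal to
the initial SSE is fine; scaled-down runs (10³ steps) would then spend
most of the schedule effectively at infinite temperature, so the
default T0 is instead set from a pilot round of proposals
(3 × median |ΔSSE|), making the hot phase explore at the scale of the
local landscape. An explicit `t0` argument restores any other choice
(0 gives greedy descent).

The SSE surface has a specific trap: an *exponential-mimic* minimum in
which the pair-depletion rate p4 collapses (so the self-limiting decay
degenerates to a quasi-exponential) and p5 → 0 compensates the tail.
Its basin captures local optimisers started from the standard initial
guesses (k_on = 0.1 μM⁻¹s⁻¹, σ* = 544.6 μM, k_cat(tethered) = 0.01,
k_cat(solution) = 0.002 μM⁻¹s⁻¹, k_off from an exponential fit to the
dissociation tail). `screened_fit` therefore prepends a deterministic
screen over a coarse (k_cat, σ*) grid — adjusting only binding, tail
and drift parameters at each grid point — before annealing the five
rates on an early-weighted subset of the trace (the first seconds carry
the pair-depletion signature) and polishing all eight parameters on the
full trace with a restart (a fresh trust region rescues stalls in
curved valleys). The reference protocol — anneal three times with
different seeds, keep the lowest SSE — remains in `fit_trace`.

On synthetic traces at instrument-like noise (additive σ = 1 % of the
association peak, 10 Hz sampling), the scaled-down protocol recovers
the dissociation constant K_D with ~1 % median error and the molecular
reach L with ~5 % median error across ten seeds.

## Identifiability (Metropolis–Hastings)

`run_chain` samples the posterior under a Gaussian i.i.d. noise
likelihood (log L = −SSE/2s², s from best-fit residuals), flat priors
on the bounded rate box, p_start < 0.3 s, and per-parameter proposal
scales adapted toward the classic 0.44 acceptance target during an
adaptation window and frozen afterwards. Stationarity is declared when
the third and fourth quarters of the chain agree per parameter under a
two-sample Kolmogorov–Smirnov test (level 0.05, per parameter, no
multiplicity correction).

Two practical additions make short chains usable:

* **Fisher preconditioning.** A one-sided Gauss–Newton Jacobian at the
  start point yields per-parameter conditional posterior scales and,
  for the joint kernel, the covariance s²(JᵀJ)⁻¹ — the walk starts at
  the posterior's own scale and orientation.
* **Joint kernel** (`joint_after_adapt=True`). The (p3, p4) and
  (p1, p2) marginals are strongly correlated; axis-aligned updates
  cannot traverse those ridges in budgeted chain lengths. The joint
  kernel proposes correlated moves with a global factor tuned toward
  ~0.25 acceptance during adaptation, then frozen. With
  preconditioning, an adaptation window of 20 % of the chain suffices
  (`adapt_fraction`).

Posterior summaries report per-parameter KDE modes, central credible
intervals and the correlation matrix. Because MH samples are
autocorrelated, the KDE bandwidth is inflated (2.5× Scott) and only
peaks above 40 % of the maximum count toward the unimodality
diagnostic.

## Reach regression and parsing

Per tether length, replicate σ* values are averaged *first* and the
average transformed to L² = (σ*)^{−2/3} (in kernel units); the σ*
spread propagates to L² to first order, err(L²) = (2/3)(L²/σ*)·sd,
verified against brute-force Monte-Carlo transformation to within 10 %
for cv ≤ 0.2. (The average-then-transform rule means the package's L
values can differ from tables built by averaging per-replicate L; e.g.
σ* = 210 μM gives L = 19.9 nm where such a table prints 19.7.)

The enzyme reach comes from ordinary least squares of L² on the number
of PEG units (slope estimate 4·l_PEG·l_p, intercept L_enzyme²), with
the PEG0 point excluded by default: the directly-coupled peptide shows
steric artefacts (higher K_D, lower solution catalysis). Weighted LS by
1/err² is available but not default. The intercept-root's standard
error follows by the delta method; a negative intercept raises. On the
published per-PEG averages the intercept-root is ≈ 13.3 nm, within the
reported 13.0 ± 0.8 nm.

Receptor-tail reaches are parsed out of a combined reach via
L_tail = √((L² − L_enzyme²)/2) and recombined by root-sum-square;
parse/combine are exact inverses (10⁻¹² relative, property-tested).
Parsing 16 nm (PD-1 reaction reach) against 13.0 nm gives 6.60 nm,
within rounding of the reported 6.55 (the printed value was evidently
computed from unrounded inputs).

## Membrane model

For receptor–enzyme complexes at surface density ρ0 on a locally flat
membrane, the effective concentration seen by an in-reach substrate is
the planar kernel integral, C_eff = √(3/(2π))·ρ0/L_rxn (verified
against quadrature to 10⁻⁶), and the probability that a substrate has
at least one complex within reach is the Poisson void formula
P≥1 = 1 − exp(−π·ρ0·L_rxn²), cross-checked against a plane-dropping
Monte-Carlo oracle. With 80,000 receptors on a 5-μm-radius cell
(ρ0 ≈ 2.5×10⁻⁴ nm⁻²) and L_rxn = 14.6 nm the coverage is ≈ 15.6 %;
90 % coverage requires ρ0 ≈ 0.0034 nm⁻² (~13-fold above uniform). The
80,000-copy upper end of the physiological range is the default because
it is the stated basis of the ~15 % figure.

The closed form gives tens of μM at uniform density — a large local
enhancement over the ~1 μM cytosolic pool, but not the ~1000 μM
sometimes quoted for clustered scenarios; the package reports only the
derived closed form.

## Synthetic data: what it does and does not emulate

`generate_trace` produces the full multiphasic sensorgram (baseline,
association peak within seconds, reach-limited self-dephosphorylation
decay, slow solution-catalysis tail, linear drift during injection,
dissociation drop) plus additive Gaussian instrument noise; ground
truth always travels in the trace metadata. Default conditions: 1 μM
enzyme over 10 μM immobilised peptide, 45 s injection, 10 Hz sampling,
amplitude 100 RU per unit bound fraction (peak ≈ 15 RU), noise
σ = 0.3 RU (peak SNR ≈ 50), drift 0.05 RU/s. The per-substrate
parameter sets are the published averages (PEG0…PEG28, a 10 °C PEG28
condition, PD-1 and SLAM tails), so synthetic experiments span the
assay's real regimes. σ* replicate scatter for tether-series studies is
mean-preserving lognormal (positivity).

Not emulated: reference-cell subtraction artefacts, bulk refractive-
index jumps, mass-transport limitation, baseline wander beyond the
linear drift, or analyte depletion. Passing recovery tests therefore
demonstrates the estimator works when the model family matches the
data-generating process at instrument-like noise — not robustness to
instrument systematics outside the model.

## Problem sizes used in the test suite

The validation suite runs complete but scaled-down versions of each
study: the oracle-equivalence check uses 3 × 100 Gillespie replicates
in an 8³ box; parameter recovery uses ten seeded noisy traces with the
9-point screen, a 10³-step anneal and polish; the identifiability check
runs ten 2000-step Fisher-preconditioned chains on 4 Hz traces. The
reference-scale settings (10⁵-step annealing × 3 restarts, chains until
KS stationarity) remain the library defaults.

## Known limitations

* The MPDPDE is a pair-correlation closure, not an exact description;
  systematic deviations from the particle process grow with density and
  catalysis strength (kept < ~2 SE at the tested regimes).
* The exponential-mimic minimum means single-start local fits of real
  traces are unreliable; use `screened_fit` or multi-start annealing,
  and inspect whether fitted p4 is collapsing toward zero.
* Scaled-down chains rely on the Fisher-preconditioned joint kernel;
  the pure 0.44-target axis-aligned sampler needs far longer chains
  than any CI budget allows.
* RU→μM conversion factors for immobilised peptide are user-supplied;
  the package performs no instrument calibration.
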