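# Methods

## The core model

All ensemble members derive from one reaction scheme with two
extracellular substrates `S1`, `S2` (g/l), total biomass `B` (g/l), and
four intracellular pools referenced to biomass (mol/gDW): the
substrate-derived metabolites `X1`, `X2`, a central metabolite `M`
(standing in for flux-signalling metabolites such as PEP or
fructose-1,6-bisphosphate), and the main biomass component `B'`
(macromolecules).  Uptake enzymes `E1`, `E2` catalyse transport:

```
dS_i/dt = -r_si w_i B            r_si = k_si E_i S_i/(K_i + S_i)
dB/dt   =  mu B                  mu   = Y1 r_s1 + Y2 r_s2
dX_i/dt =  r_si - r_di           r_di = k_xi X_i
dM/dt   =  r_d1 + r_d2 - r_b     r_b  = k_m M
dB'/dt  =  r_b - mu B'           r_ei = k_i f_i
dE_i/dt =  r_ei - mu E_i
```

Growth dilution is kept for the macromolecular species (`E_i`, `B'`) and
neglected for the fast metabolites (`X_i`, `M`), whose turnover is much
faster than growth.  The regulation factors `f_i` are 1 in the base model
and are specialised by the variants.

With perfectly symmetric parameters and initial conditions the two
pathways are indistinguishable and `S1(t) = S2(t)` exactly: no diauxie.
Every ensemble variant breaks this symmetry in exactly one way.

## Rescaling

Substrates are scaled on their Michaelis constants (`s_i = S_i/K_i`),
biomass as `b = B w1/(K1 Y1)`, and all intracellular states by `Y1`
(`x = Y1 X`, etc.).  Substituting shows the scaled system has the same
structural equations with parameters

```
k~_si = k_si,  K~_i = 1,  k~_i = Y1 k_i,  k~_xi = k_xi,  k~_m = k_m,
Y~1 = 1,  Y~2 = Y2/Y1,  w~1 = 1,  w~2 = (w2/w1)(K1/K2)
```

(plus an optional time factor), i.e. only ratio parameters remain.  The
binding contract is the round-trip identity — simulating the rescaled
system and unscaling reproduces the original trajectory — which the test
suite checks numerically.  All defaults operate in this regime with every
ratio at 1, `s_i(0) = 1`, `b(0) = 0.01`, `e_i(0) = 0.01`; batch depletion
then completes within a few tens of time units.  Some variants override
single initial pools: the energy-coupled and PTS variants (A4, A5) start
with a small energy pool `m(0) = 0.1` so the transport cycle can
bootstrap, the bistable variant R5 starts on the high-M branch
(`m(0) = 1`), and the allocation variants (A1, A2, A6) start with a
protein reserve `b'(0) = 0.05`.

## Numerical integration

Kinetic variants use LSODA with `rtol = 1e-8`, `atol = 1e-10` and a dense
output grid (2001 points by default).  Pulses are applied by
stop-and-restart: the integration halts at the event time, the state is
incremented, and integration resumes, so the discontinuity never passes
through the adaptive stepper.  Substrate depletion needs no event
handling because the Michaelis–Menten form drives `r_si -> 0` smoothly;
negative excursions at the tolerance level are clipped.

Dynamic FBA uses a fixed step `dt = 0.01` with classical RK4, re-solving
the flux program at every stage evaluation.  RK4 (rather than one LP per
Euler step) is needed for the trajectory to agree with the QSS-reduced
kinetic model to ~1e-4; the flux programs of the base system and C1–C4
admit closed-form solutions (they are tiny, highly structured LPs), which
the stepping loop uses.  The general LP path
(`scipy.optimize.linprog`, HiGHS, with a secondary minimum-norm selection
among alternate optima for reproducibility) is cross-checked against the
closed forms in the tests.

## The variants

* **C1** modifies the stoichiometry: `M` is central for `S1` only; the
  biomass reaction from `M` co-produces `X2`, which is excreted through a
  reversible `S2` exchange (excretion unbounded, uptake capped at
  `h(S2)E2`) or converted to biomass by an inefficient route capped at
  `cap_frac * k_s1 * E1` (default 50% of the main route's capacity).
* **C2** (rFBA) executes one Boolean rule before each LP: `E2` is active
  iff `S1 < 0.01 K1`; at the threshold the tie goes to repression.
* **C3** adds the membrane-space inequality `a1 E1 + a2 E2 <= A_max`, and
  the enzymes become LP variables bounded above by their ODE values —
  otherwise the added inequality could render the fixed-enzyme system
  infeasible instead of reallocating capacity.
* **C4** adds `cost . r_e - benefit . r_d <= slack` with the synthesis
  rates as LP variables in `[0, k_i]`.  Because `r_e` does not influence
  the biomass objective, the LP objective carries a tiny secondary weight
  `1e-3 (r_e1 + r_e2)` to make the synthesis allocation well-posed (the
  budget then goes to the cheaper enzyme first).
* **N1–N4** add induction of enzyme synthesis by the inducers
  (`f_i = X_i/(K_a + X_i)`) and one asymmetric parameter: maximal enzyme
  synthesis (N1), initial enzyme level (N2), inducer affinity (N3), or
  maximal uptake rate (N4); the default asymmetry is a factor 2, and
  calibration searches the pair.
* **R1–R4** keep induction and add one regulatory interaction, all Hill
  forms with exponent 1: `X1` inhibits `E2` activity (R1, inducer
  exclusion), `M` inhibits `E2` synthesis (R2, the global transcription
  factor cascade reduced to its net effect), `M` activates `X2`
  consumption (R3) or inhibits `X1` consumption (R4).
* **R5** replaces induction with a reciprocal enzyme switch driven by `M`
  (Hill exponent 4) and makes `M` production autocatalytic
  (`r_di` multiplied by `eps + (1-eps) m^2/(K_A^2 + m^2)`, `eps = 0.01`
  so the system can leave `m = 0`).  Cooperativity (n = 2) folds the
  steady-state curve of the fast `M` subsystem: over an interval of
  incoming fluxes three roots coexist (outer two stable).  Stability is
  classified from the sign of `d(dm/dt)/dm`, matching the one-dimensional
  bifurcation construction.
* **A1** allocates a fraction `phi` of `B'` to the transporters at each
  instant, maximising the incoming flux; the optimum is the corner of the
  budget line (all to the pathway with the larger `k_si sigma_i / g_i`).
* **A2** solves a dynamic program: piecewise-constant allocation
  fractions `u1, u2` (10 intervals) with `r_ei = u_i u_max B'` and an
  explicit drain `u_max B'` on the `B'` balance; the objective is
  terminal biomass subject to the path constraint `M <= M_max`.  Total
  biomass still grows with the yield-weighted uptake (`mu = Y1 r_s1 +
  Y2 r_s2`): the drain moves mass from `B'` into enzymes, and both are
  part of the biomass, so subtracting it from `mu` would double-count
  and make the culture shrink while consuming substrate.  A tight
  `M_max` plus different pathway parameters (`k_s1 = 2 k_s2` by default)
  makes sequential uptake optimal.
* **A3** (cybernetic) sets `f_i = u_i = r_si/(r_s1 + r_s2)` (1/2 when both
  are zero), the matching law restricted to control of synthesis;
  asymmetric maximal uptake rates break the symmetry.
* **A4** couples transport to energy: uptake gains a factor
  `M/(K_M + M)`, one `M` is consumed per transport event, and the
  production of `M` from `X_i` carries coefficient 2.
* **A5** (PTS) splits `E1` into free and phosphorylated pools with
  mass-action phosphotransfer `k_p M E1_free`; only `E1~P` transports
  `S1` and is dephosphorylated by transport.  `X1 -> M` carries
  coefficient 2 here too — with coefficient 1 every transported molecule
  would consume exactly the `M` it later regenerates, and growth on `S1`
  alone would be impossible.  The total `E1` pool obeys ordinary
  synthesis/dilution.
* **A6** maximises a lifespan variable by free-final-time optimal
  control: the horizon is rescaled to [0, 1] with `t_end` a decision
  variable, and `B'(t) >= B'_min` is the survival constraint.  The
  unconditional drain `u_max B'` represents protein turnover; it is what
  makes the lifespan finite (with the default budget the supremum is
  close to `total substrate/(u_max B'_min)`, and the optimiser pushes
  `B'` to the floor while stretching consumption).  In this formulation
  the *ordering* of consumption is close to lifespan-neutral, so
  symmetric parameters need not produce a large diauxic index; this is a
  known difference from implementations in which enzyme investment is
  charged per pathway.

The optimal-control problems are solved by control-vector
parameterisation: SLSQP over the node values (and `t_end` for A6), path
constraints as quadratic penalties normalised by the bound and ramped
(weights 50 then 2000), finite-difference step `1e-3` (well above the ODE
solver noise), five seeded random starts by default, and a final
re-simulation of the best profile at tight tolerances.  The reported
objective is recomputed from that re-simulation, so it is self-consistent
by construction.

## Diauxic growth index

For a complete batch trajectory the index is

```
d = 1/2 * Int | rho_1(t) - rho_2(t) | dt,
rho_i = max(r_si, 0) w_i B / C_i,   C_i = max(S_i^0, gross uptake of i)
```

`rho_i` is the uptake rate as a fraction of substrate i's gross
consumption per unit time, so `Int rho_i dt = 1` for a completely
consumed substrate; strictly sequential uptake gives d = 1 and identical
profiles give d = 0.  In the rescaled unit-yield case this reduces
exactly to half the integral of `|r_1 - r_2| b`.  Flooring negative
uptake and normalising by gross consumption extends the [0, 1]
calibration to systems that transiently *produce* a substrate (C1) and to
non-unit yields/weights.  Quadrature is trapezoidal on the solver's
output grid (>= 2001 points for reported values; halving the step moves d
by < 1e-4).  If the run ends before both substrates are depleted the
result carries a warning, since d is then a lower bound.

## Calibration

Both parameter-selection problems use the same simple elitist GA:
tournament selection (size 3), blend crossover (alpha = 0.5, probability
0.9), per-gene Gaussian mutation (probability 0.25, sigma = 10% of the
box width), elitism 1.  Genomes live in [0, 1] and map log-uniformly onto
per-parameter boxes, `[1e-2, 1e2]` by default, so the search covers
essentially the whole sensible space of the rescaled models.  Populations
are evaluated in one vectorised ODE solve (RK45, `rtol 1e-5`, 501 output
points over `t_end = 50`) or one vectorised dFBA loop (Heun, `dt = 0.05`)
— accurate to ~1e-3 in d, ample for ranking — and a candidate whose
simulation fails scores 0 (d-maximisation) or +inf residual (fitting).

d-maximisation searches only the variant's free parameters (shared ratio
parameters stay at 1) and enforces the feasibility prerequisite that
growth is possible on each substrate alone: the candidate must at least
double its biomass in a single-substrate batch over the same horizon,
else fitness is 0.  Ensemble ranking takes the best of 3 seeded runs per
variant (population 40, 30 generations).  For A2 and A6 each fitness
evaluation embeds an optimal-control solve; since their free-parameter
spaces are 1–3 dimensional, the ranking uses a reduced search (population
6, 4 generations, single NLP start at coarse tolerance) for these two
variants.

Least-squares fitting minimises the sum over channels (S1, S2, B, and
the E2 activity proxy `k_s2 E2`) of squared residuals scaled by each
channel's data range, so heterogeneous observables contribute comparably.

## Synthetic observations

The generator samples simulated trajectories at given times, adds
Gaussian noise with standard deviation `noise_sd` times the channel's
dynamic range, and truncates at zero.  It emulates the observable surface
of classic diauxie experiments (substrate assays, optical density, LacZ
activity as an enzyme proxy) but none of their systematic structure:
no calibration drift, no sampling-time jitter, no correlated errors, and
the generating model is by construction inside the fitted family.
Passing recovery tests therefore demonstrates identifiability and
correctness of the pipeline under the stated noise model, not performance
on real measurements.

## Discrimination pipeline

Two simulated experiments interrogate the ensemble beyond the standard
batch: a glucose pulse during growth on lactose (pulse timed per model at
two biomass doublings on lactose-only medium, so slower models are pulsed
later; pulse size 1 in rescaled units) and a lactose-preculture batch
(initial `E2 = 1`, i.e. 100x its base value).  N2 is excluded from the
preculture design (its defining asymmetry *is* an initial-enzyme
condition) and A2 from the pulse design (its dynamic program admits no
externally timed event).  The optimal-control variants are solved on the
unperturbed medium and their allocation profile is replayed in the
scenario.

Predictions are compared at the same *phase* of the experiment rather
than the same clock time: each trajectory's axis is shifted so pulses
coincide at 0 and divided by that model's glucose-phase duration (time
to S1 depletion, marked at 1% of the initial concentration), so that
models with very different growth rates remain comparable — the natural
generalisation of rescaling the data "for the timing of the pulse".
The normalised curves are clustered per channel with Ward linkage on
Euclidean distances (4 clusters per channel by default) and each cluster
is summarised by its pointwise mean.  Feature verdicts are evaluated on
the cluster representatives, not the raw trajectories.  The committed
operationalisations of the qualitative features are: preculture —
substrate OK iff S2 drops by < 5% before S1 depletion *and* is consumed
(> 5%) afterwards, enzyme OK iff the E2 proxy decreases during the
glucose phase (by > 2%) and rises again after depletion; pulse —
substrate OK iff the specific (per-biomass) S2 consumption rate falls
below 95% of its pre-pulse median and later recovers to >= 80% of it,
enzyme OK iff the E2-proxy slope drops below 20% of its pre-pulse value
and later recovers above 50%.  Specific rather than absolute rates are
used because the culture keeps growing on the pulsed glucose, which
masks the slowdown in absolute consumption; and resumption is detected
over the whole post-pulse window because in variants whose glucose
machinery must re-induce, the pulse is consumed slowly and uptake can
only resume after re-depletion.  Verdicts within 10% of a threshold are
flagged ambiguous.  The discrimination entry point runs on each
variant's default parameters; calibrated parameter sets can be passed
in instead.

## Problem sizes

Reported quantities use: batch horizon 50 rescaled time units (the index
itself is evaluated on a 150-unit horizon so slow second phases reach
depletion; property tests use up to 120 for strongly repressed variants),
2001-point output grids, GA population 40 with 30 generations and 3
seeds, 50 observation points for fitting, 200-point common grids and
k = 4 clusters for discrimination.  These scales were chosen so each analysis completes in
minutes on a single core while leaving the reported statistics stable to
well within their assessment tolerances.

## Known limitations

* The ensemble is deterministic; no stochastic kinetics.
* The dFBA network is the three-metabolite toy system; nothing
  genome-scale.
* Quadratic-penalty optimal control yields near-feasible, locally
  optimal profiles; with few multistarts the A2/A6 objectives can land in
  local optima, and A6's lifespan objective is nearly flat in the
  consumption ordering (see above).
* The feature thresholds of the discrimination pipeline are committed
  operationalisations of qualitative statements; verdicts for borderline
  variants legitimately carry an "ambiguous" flag.
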