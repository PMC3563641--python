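# Methods

This note records the models, algorithms, default settings and design
choices behind `modeldiscrim`, and what the shipped tests do and do not
establish.

## Model representation

A `KineticModel` is an explicit ODE right-hand side with labelled species,
parameters and external inputs plus a list of linear conservation relations
used for verification.  Parameters are addressed by label everywhere;
positional order exists only as the documented label tuple of each model.
States are concentrations in model-specific arbitrary units; no unit
conversion layer is attempted.

### Simple enzyme

Mass action for S + E ⇌ ES → E + P with constants k1 (association), km1
(dissociation), k2 (catalysis).  Conserved: E + ES and S + ES + P.

### Hysteretic enzyme (slow-transition model)

The enzyme exists in an inactive (Ei) and an active (Ea) conformation.  Both
bind three substrate molecules per catalytic complex (3:1 substrate:product
stoichiometry, hence the factor 3 on substrate fluxes), and product release
regenerates the free conformation:

    Ei + 3S → EiS (k1)    EiS → Ei + 3S (k2)    EiS → Ei + P (k3)
    Ei → Ea (k4)          Ea → Ei (k5)
    EaS → Ea + P (k6)     EiS → EaS (k7)        EaS → EiS (k8)
    EaS → Ea + 3S (k9)    Ea + 3S → EaS (k10)

The generating constants (0.05, 0.001, 0.06, 0.001, 0.001, 6.0, 0.001,
0.001, 0.01, 4.0 for k1…k10) make the active conformation's catalysis (k6)
a hundredfold faster than the inactive one's (k3) while all conformational
transitions (k4, k5, k7, k8) are slow.  Starting from pure inactive enzyme,
the fast active cycle builds up gradually, producing the lag phase and
sigmoidal progress curves characteristic of hysteretic (kinetically
cooperative) monomeric enzymes.  Association rates are taken first-order in
free substrate (the complex's three substrate molecules are treated as a
lumped binding event); the 3:1 stoichiometry is carried exactly, so
S + 3·EiS + 3·EaS + 3·P and total enzyme are conserved — both are verified
numerically at random states and along trajectories.

### Chemostat benchmark

A fictitious organism in a constant-volume tank reactor with equal in/out
flow q and feed substrate concentration c_in (both external inputs).  States:
biomass B, tank substrate S, intracellular metabolites M1 and M2, inducible
enzyme E.  Rates:

    r1 = k1 · S/(Ks + S)              specific substrate uptake (Michaelis–Menten)
    r2 = k2 · E · M1 / (1 + K1·M2)    enzymatic conversion M1 → M2, with a
                                      formal non-competitive inhibition law in M2
    r3 = k3 · M1 / (1 + K2·M2)        enzyme synthesis (induced by M1,
                                      repressed by M2)
    r4 = kd · E                       enzyme degradation
    r5 = Y · r1                       specific growth rate

with dB/dt = (r5 − D)B, dS/dt = D(c_in − S) − r1·B, dM1/dt = r1 − r2 − r5·M1,
dM2/dt = r2 − r5·M2, dE/dt = r3 − r4 − r5·E, and dilution rate D = q/V.
Intracellular quantities are per-biomass concentrations diluted by growth.
Variant A replaces r3 by the constant k3 (enzyme synthesis unregulated, so
conversion is controlled only through the inhibition of enzyme activity);
variant B drops the inhibition fraction from r2 (activity unregulated, so
control happens only through M1-dependent synthesis).  The named constants
k1 = 342.3·10⁻⁶, Ks = 0.4437, k2 = 12.2, k3 = 10.0, K1 = 2.4·10⁴ and
K2 = 3.0·10⁶ follow the published benchmark values; the auxiliary constants
Y = 2000, kd = 0.008 and V = 1 are this package's reconstruction choices,
set so the chemostat sustains biomass on a 60-hour horizon (growth rate
comparable to the dilution rate) while keeping the published constants in
their stated roles.  The benchmark's standard experiment runs 60 hours with
30 measurements every 2 hours; the flow rate steps from 0.1 to 0.2 at the
10th measurement point and the feed concentration from 5.0 to 2.0 at the
15th.

## Simulation

Designs parameterize time by intervals Δtᵢ (measurement i at Σ_{j≤i} Δtⱼ;
t = 0 is not a measurement point, so 60 h sampled every 2 h gives exactly 30
points).  Integration is piecewise between measurement times with a
stiff-capable integrator (LSODA by default, BDF selectable), relative and
absolute tolerances 10⁻⁸/10⁻¹⁰.  Impulsive species perturbations and input
switches scheduled at a grid index are applied *after* the measurement at
that index — the pre-perturbation state is what the experiment records, and
the smooth perturbation weight already down-weights such points.  Single
shooting is used throughout: at the scale of these models the IVP is
integrable over the full horizon, so multiple-shooting stabilization is
unnecessary.

Sensitivities ∂η/∂v come from central finite differences of the simulator by
default, or from integrating the forward sensitivity ODEs (with rhs
Jacobians by finite differences) for smoother derivatives; the two methods
agree to ~10⁻³ relative on the shipped models, which is what the tests
enforce.

## Discrimination criterion

The directed criterion sums Gaussian KL terms over species and time points;
the homoscedastic case reduces to (η₁−η₂)²/(2σ²).  The per-point weight is
the product of a rising tanh step in the preceding interval (width 2,
center 1, i.e. intervals below ~1 time unit are disabled) and a falling tanh
step in the total scheduled perturbation magnitude (width 0.1, center 0.05).
Step steepness defaults to 10 (dimensionless); all step parameters are
per-experiment configuration.  Weights are per time point (they depend on
the grid and perturbations, not on the species).  The symmetrized criterion
sums both directions and is used where neither model is privileged.

## Estimation

Least-squares fits pool residuals (data − model) across all datasets and
species, optionally scaled per species by 1/σ, with box constraints
(default [0, ∞)) via a trust-region reflective solver; a log-parameter mode
handles rate constants spanning orders of magnitude.  Worst-case parameter
search minimizes the discrimination objective over the feasible boxes with
L-BFGS-B from multiple starts — by default the previous worst-case point
plus seeded uniform draws, five starts in total.  All random draws are
`numpy` `default_rng` streams with mandatory seeds.

## Design optimization and the robust loop

The phase-two problem — maximize the minimum of J over a finite set of
parameter pairs subject to Σ Δtᵢ = T and all box bounds — is posed in
epigraph form (maximize s with J_j(ξ) ≥ s) and solved with SLSQP.  Interval
lower bounds are 0: omission of a measurement point is expressed smoothly by
the interval weight rather than by a hard bound, and points whose weight
falls below 0.01 are reported as omitted.  A monotone safeguard returns the
initial design if a solver excursion would end below the starting value.

The outer loop alternates worst-case estimation (appending each new pair to
P_k, with de-duplication at 10⁻⁸ relative) and multi-pair design
optimization, monitoring the robustification gap Δₖ = |J_design − J_worst|;
it stops at Δₖ ≤ ε (default 10⁻³, configurable — in practice ε should be
chosen relative to the measurement variance) or after max_iter = 50
iterations.  The homotopy option ramps each newly appended pair into phase
two through a convex blend of its parameters with the previous worst-case
pair over n_steps sub-solves, triggered once the gap drops below 0.1; the
final sub-solve always uses the exact new pair, so the homotopy changes the
path, not the limit (asserted on the closed-form saddle).

## Statistics

*Noise models.*  Additive (y = η + ε) and relative (y = η(1+ε)) Gaussian
noise, independent per species/time/replicate from one seeded stream;
negative values are clipped at zero with a counter in the dataset metadata.

*Lack of fit.*  Replicated-design ANOVA per species: SS_lof = Σ r(ȳ_t − η_t)²
against SS_pure = ΣΣ(y − ȳ_t)², F compared to F(df_lof, df_pure) at 1 − α
with df_lof = n_t − p and df_pure = n_t(r − 1).  The parameter count p is an
argument: pass the number of fitted parameters when the curve was estimated
from this species' data by plain least squares, or 0 when testing a fixed
externally given curve — including curves from pooled multi-species weighted
fits, whose parameters do not consume per-species degrees of freedom in the
classical way.  The type-I error simulation in the tests is calibrated under
the n_params = 0 convention.

*Variance-ratio test.*  The larger residual variance over the smaller,
compared to the F quantile with the residual counts as degrees of freedom.
The variance ratio is the statistically proper statistic; a literal
standard-deviation-ratio mode exists as a reproduction flag.  Residuals at
perturbation positions are included.

*Robustness histogram.*  The objective at uniform draws inside the boxes,
binned into equally spaced bins over the observed range (no trimming in
computation).  For a converged robust design the minimum draw must not fall
below the final worst-case value; a single-pair design generally violates
this — both behaviors are asserted on the saddle toy.

## The recovery experiment and its identifiability limit

The headline recovery experiment simulates the hysteretic model (S₀ = 2.0,
Ei₀ = 0.1 — a clean sigmoid spanning the horizon) at 26 points spaced 10
time units, adds additive Gaussian noise with σ = 1% of each species'
signal range, replicates five times, and refits all ten constants from a
±20% start (log-parameters, 1/σ-weighted pooled least squares).

What this does and does not show: substrate and product curves at this
sampling resolution constrain the two fast constants of the active cycle
(k6 ≈ 6, k10 ≈ 4, timescales far below the 10-unit grid) almost solely
through quasi-steady-state combinations, and those combinations trade off
against the unobserved amount of activated enzyme (k4, k7).  The profile
likelihood of k6 is nearly flat across [3, 12] at this noise level, so the
data alone do not pin these two constants: the least-squares estimates stay
roughly within the band the start values span (hence the randomized rather
than fixed-sign start — a deterministic sign pattern would bias them) and
typically land within ~10% of the generating values, occasionally worse.
Tightening this would require denser early sampling, lower noise, or an
observable tied to the active conformation.  The synthetic data generator
emulates replicated
homoscedastic Gaussian measurement error on ideal trajectories; real assay
data add baseline drift, heteroscedasticity and calibration error that are
out of scope here, so passing recovery tests bound estimator behavior under
the idealized error model only.

## Degenerate inputs and tie-breaks

Zero-length intervals are legal (the measurement repeats the current state
and its weight vanishes); degenerate parameter boxes short-circuit the
worst-case search; a design space with all bounds tight returns the initial
design; duplicate worst-case pairs are not appended to P_k; coincident
measurement/perturbation times follow the measurement-first convention.
Integration failures carry the failing interval, are converted to large
penalty values inside optimization loops, and are counted and excluded (with
a warning) in histogram sampling.

## Known limitations

No SBML import (explicit rhs functions only), no delay/stochastic dynamics,
no global-optimality guarantees for either phase (multistart and the outer
approximation give local saddle points), no mixed-integer measurement
selection (smooth weights emulate omission), and the benchmark network is a
behavioral reconstruction: its published constants are used in their stated
roles, but the auxiliary constants and exact units are package choices.
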