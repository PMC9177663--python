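# Methods

## The kinetic model

`modkin` implements the general (hyperbolic, nonessential) modifier
mechanism over the enzyme states {E, ES, EX, EXS}.  Substrate binds E
with Michaelis constant Km and EX with α·Km; modifier binds E with KX
and ES with α·KX (the same α on both edges closes the thermodynamic
box); ES turns over at kcat and EXS at β·kcat.  In the
rapid-equilibrium limit the velocity is

    v/Etot = kcat · (S/Km) · (1 + β·X/(α·KX))
             ─────────────────────────────────────
             1 + S/Km + X/KX + S·X/(α·Km·KX)

Every closed form returns v/Etot in s⁻¹; absolute rates are obtained by
multiplying by the enzyme concentration at the interface layer, which
keeps fitted parameters on the same scale as published kcat values.

**Km versus KS.**  The quasi-equilibrium law is conventionally written
with the substrate dissociation constant KS = k2/k1; we parameterize it
with the Briggs–Haldane Km = (k2+k3)/k1 instead, because Km is what a
Michaelis–Menten fit measures and what efficiency tables report.  The
two differ by kcat/k1.  The mass-action ODE oracle
(`MicroscopicRates.from_kinetic_parameters` + `ode_oracle_velocity`)
quantifies the gap: with binding rates a factor *scale* above the
fastest catalytic step (kcat·max(1, β)), the closed form and the true
steady state agree to roughly 1/scale in relative terms — about 1e-4 at
scale 1e4 and better than 1e-5 at scale 1e6, which is the scale the
equivalence tests use.  Outside the rapid-equilibrium regime the Km
parameterization is an approximation, and the oracle is the tool to
measure by how much.

**Degenerate limits.**  α or KX infinite is accepted as the
"no ternary complex" limit and routed to linear competitive inhibition
(`KineticParameters.no_ternary_complex`).  β = 0 is a dead ternary
complex: complete (linear) catalytic inhibition, flagged as outside the
hyperbolic family by the classifier.

## Derived quantities

- Apparent parameters along a titration:
  kcat_app = kcat(1+βX/(αKX))/(1+X/(αKX)), Km_app = Km(1+X/KX)/(1+X/(αKX)).
  α = β makes kcat_app/Km_app independent of X — the signature of purely
  catalytic ("uncompetitive-like") modification.
- Titration midpoint: v(X) at fixed S is an exact hyperbola, so the
  half-effect point is X50 = α·KX·(Km+S)/(α·Km+S) (the AC50 of an
  activator, IC50 of an inhibitor).  At α = 1 it collapses to KX, which
  the code returns exactly.
- Substrate inhibition: v = V·S/(Km + S + S²/Ksi) peaks at
  S* = √(Km·Ksi).  A modifier that stabilizes the unproductive
  substrate–enzyme–substrate complex is modeled by scaling the S²/Ksi
  term by (1 + X/Kx_ses).  This one-parameter coupling is a modeling
  choice: it is the minimal extension that reproduces dose-dependent
  deepening of the downturn, not a mechanism established elsewhere.

## Mechanism taxonomy

`classify(alpha, beta, epsilon)` names mechanisms from the two
coefficients.  The decision order is: (1) α ≈ β (relative tolerance
ε) → purely catalytic modification, labelled "hyperbolic catalytic
activation/inhibition" (this is checked first so an exactly coupled
pair far from 1 is not called mixed); (2) α ≈ 1 → catalytic only;
(3) β ≈ 1 → specific only; (4) otherwise mixed, with dominance decided
by log-distance from neutrality (|ln α| vs |ln β|, ties within ε
"balanced").  "Predominantly" in the canonical labels is exactly this
log-distance rule — the unique simple rule consistent with calling
(30.39, 0.09) predominantly specific and (0.82, 25.4) predominantly
catalytic.  When the two components act in opposite directions the net
direction depends on substrate level; the caller must then supply a
reference S/Km and the sign of β(1+s) − (α+s) decides.

When classifying *fitted* coefficients, the global fitter widens the
α ≈ β tolerance to 2·SE(ln α − ln β) from the fit covariance (capped at
0.3): a genuinely coupled mechanism should not be split into "mixed" by
estimation noise alone.  `classify` itself stays a pure function of its
arguments.

## Signal processing

Standard curves are ordinary least-squares lines (slope, intercept, r²,
residual SD).  Signal → product inversion clips negatives within 3
blank-SDs to zero and rejects anything lower.  Initial velocities are
extracted by truncating each progress curve at the last read with
product/S0 ≤ `max_consumption` (default 0.10 — the conventional
initial-rate criterion; the cutoff is configurable because assay
protocols rarely state one) and requiring ≥ `min_points` (default 5)
reads.  Within the window the rate is the least-squares slope; when the
window holds ≥ 6 reads a quadratic least-squares fit is used and its
derivative at the window start reported, because substrate depletion
bends the window downward and the straight chord underestimates the
t = 0 rate by up to ~5% at 10% consumption.  Non-increasing product
trends raise rather than fit.  Replicate velocities are kept separate
so downstream fits can weight by replicate scatter.

## Fitting

All fits are bounded least squares (`scipy.optimize.least_squares`,
trf) on log-transformed parameters (positivity for free), multi-started
from a deterministic seed plus three jittered seeds (fixed internal RNG;
the jitter is part of the algorithm, not of the data).  The best
converged start wins on cost, ties on smaller log-norm.  Standard
errors come from the Jacobian at the optimum via the delta method.

- **Michaelis–Menten:** seeded from the Lineweaver–Burk linearization.
  Km estimates pushed ~100× outside the sampled S range are flagged
  "poorly determined".
- **Global modifier fit:** all (S, X) wells simultaneously for
  (kcat, Km, KX, α, β); seeds derived from the per-level MM family
  (kcat, Km from X = 0; α, β from top-level apparent-parameter ratios;
  KX from the half-change of Km_app).  Weights are inverse-variance
  when every condition has replicate scatter; because plate noise is
  close to constant-CV, the per-condition SD is estimated as
  pooled_CV × condition mean rather than the raw n≈6 SD (which is
  itself ~30% noisy).  Structural non-identifiability surfaces as
  `se_blowup:<param>` flags (log-scale SE > 10), never silently.
- **Dose–response:** the mechanistic hyperbola
  v = (v0 + v∞·X/X50)/(1 + X/X50), not a Hill curve — the modifier law
  is exactly hyperbolic in X, so a Hill exponent would only absorb
  noise.  Requires ≥ 5 levels spanning ≥ 2 decades; responses flat
  within the noise floor raise "no modification detected".
- **SES:** (Vmax, Km, Ksi) and, across several modifier levels, the
  shared coupling Kx_ses.  Ksi is only identifiable when the S range
  extends beyond the velocity peak; a peak at the boundary flags
  `ksi_unidentifiable`.

Convergence tolerances are 1e-14 (xtol/ftol/gtol); noise-free round
trips recover parameters to ~1e-6 relative or better.

## Synthetic assays

`reference_designs()` mirrors the assay formats the analysis targets:
three chromogenic pNA designs (substrate doubling series 0.5–8.0 mM,
substrate-specific modifier titrations, 6 replicates, 10 s reads over
30 min, Etot = 0.145 µM ≙ 10 µg/mL of a 69 kDa enzyme) and a PGP
endpoint design (S = 100–1000 µM, X = 0–0.32 µM, 20 replicates,
stopped reactions, Etot = 4.5e-4 µM).  Noise is multiplicative Gaussian
with CV 0.05 (typical of the plate format, truncated at ±4σ so signals
stay positive).  Velocity-level generation applies noise per replicate
to the exact law; progress-curve generation integrates true substrate
depletion, maps product through the standard curve (default: pNA at
405 nm, 0.0058 A/µM with a 0.05 blank) and applies read noise to the
product-proportional signal.  Concentrations are nominal — pipetting
error, plate-position effects, evaporation, and enzyme inactivation are
not modeled — so passing tests demonstrate estimator correctness under
the stated noise model, not robustness to systematic plate artifacts.

`recovery_designs()` widens the grids to the full assay coverage
(S doubling 0.5–64 mM, modifier doubling 0–2000 µM): parameter-recovery
studies need coverage around both KX and α·KX, and for a strong
specific inhibitor (α·KX in the millimolar range) the narrow
efficiency-table titration leaves β structurally invisible — the fit
correctly reports SE blow-up there, and the recovery studies use the
full-coverage grids instead.  Monte-Carlo recovery at 5% CV with 6
replicates (50 seeded repeats) gives median relative errors of ~5–11%
on α and β across the three regime exemplars with stable mechanism
labels; the problem sizes (8 × 13 × 6 wells per fit) keep one study
under ~15 s.

## ODE oracle numerics

The oracle integrates the mass-action system (LSODA, rtol 1e-11, atol
1e-13) over successively doubled horizons, starting from several
hundred relaxation times of the slowest first-order step
(min(kcat, β·kcat, k2, k5)), and declares steady state when two
successive checkpoints agree within 1e-10 in every state fraction.
Non-convergence raises — a derivative-threshold test was rejected
because solver noise on stiff binding rates (1e6–1e8 s⁻¹) keeps
absolute derivatives far above any tight threshold even at the true
steady state.

## Known limitations

- The closed-form laws assume rapid equilibrium; slow-binding modifiers
  need the ODE route.
- The SES–modifier coupling is a minimal reconstruction; other
  couplings (e.g. modifier altering Km of the second substrate site)
  would fit similar data.
- Dose–response asymptotes v0, v∞ are unbounded in sign; the fit does
  not enforce consistency with an independently fitted modifier law.
- Efficiency tables render at 2 decimals (full precision retained in
  CSV/JSON payloads); the rendered strings are a presentation contract,
  not data.
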