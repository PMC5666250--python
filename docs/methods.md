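# Methods

## Model

The population is divided into four disjoint compartments — susceptibles
not at risk of gang membership (Sn), susceptibles at risk (Sr), gang
members (G), and individuals in correctional services (C) — with the
vector field given in the README.  Assumptions worth making explicit:

* **Homogeneous mixing.**  Every at-risk susceptible meets gang members
  at the same rate; there is no spatial, network or age structure.
* **Imitation incidence.**  Initiation is `β G (1 + η G) Sr`: bilinear
  contact plus a quadratic peer-amplification term.  η ≥ 0 measures how
  strongly visible gang activity recruits beyond simple contact; η = 0
  recovers mass-action incidence.
* **Risk transition is environmental.**  Movement Sn → Sr (rate θ)
  reflects changed circumstances (e.g. economic shocks), not contact
  with gang members.
* **Correctional services as a leaky filter.**  Releases occur at rate
  σ1; a fraction 1−ε relapses directly into the gang, the effective
  fraction ε returns to the community (ν of it to the not-at-risk
  class).  ε = 1 is a fully effective programme, ε = 0 a dysfunctional
  one.
* **Demographic balance.**  dN/dt = Λ − μN, so the region
  {all compartments ≥ 0, N ≤ Λ/μ} is positively invariant; states are
  absolute counts and no normalisation to proportions is performed.
* **Time unit.**  Rates are per year (μ = 0.0166/yr corresponds to a
  60-year life expectancy).  The unit is a label only; no computation
  depends on it.

## Parameters

| name    | meaning                                   | units        | baseline |
|---------|-------------------------------------------|--------------|----------|
| Lambda  | recruitment inflow                        | ind./year    | 0.028    |
| mu      | natural exit rate                         | 1/year       | 0.0166   |
| p       | proportion of entrants not at risk        | —            | 0.5*     |
| theta   | transition rate Sn → Sr                   | 1/year       | 0.3      |
| beta    | effective contact rate                    | 1/(ind.·yr)  | 0.01     |
| eta     | imitation coefficient                     | 1/ind.       | 0.002    |
| sigma1  | release rate from correctional services   | 1/year       | 0.5      |
| sigma2  | voluntary quit rate G → Sr                | 1/year       | 0.5      |
| gamma   | conviction/sentencing rate G → C          | 1/year       | 0.8      |
| epsilon | correctional-programme efficacy           | — (in [0,1]) | 0.5*     |
| nu      | effective releases returning to Sn        | — (in [0,1]) | 0.5*     |

Starred values are repo-supplied defaults: the source material gives
only open ranges (0, 1) for the three proportions, and the baseline
table omits the demographic pair.  The defaults use the range midpoint
(0.5) for proportions and the demographic estimates for Λ and μ; each
fixture flags which of its fields are defaults versus cited values.
Validity: Λ, μ, θ, β, σ1, σ2, γ strictly positive; η ≥ 0; p, ν, ε in
[0, 1].

## Thresholds and sensitivity

All thresholds are evaluated from closed forms (see README for Rg).
The next-generation construction that produces Rg is exercised only as
a test oracle: the spectral radius of F V⁻¹ for the 2×2 (G, C) block is
checked against the closed form to 1e−12, keeping the implementation
and the cross-check on separate routes.

ε\* solves Rg(ε) = 1 and can exceed 1; it is reported unclamped with an
attainability flag rather than truncated, since an unattainable
threshold is itself informative.  Elasticities (normalized forward
sensitivity indices) are provided analytically for the eight parameters
with printed closed forms and numerically (central differences,
default relative step 1e−6, one step-halving retry at domain
boundaries) for those plus μ.  The analytic and numeric routes agree to
better than 1e−5 across randomly sampled valid parameter sets.

## Equilibria and existence regimes

Gang-persistent equilibria have G\* > 0 solving a G\*² + b G\* + c = 0
with a < 0 (for η > 0), sign(b) = sign(η − η\*) and
sign(c) = sign(Rg − 1); the remaining compartments follow by
back-substitution and every returned equilibrium is verified to satisfy
the balance equations to 1e−9·Λ.  The regime labels (H1, H2 i–v) are
decided by strict inequalities with tolerance 1e−12; inputs on a case
boundary get the lower-multiplicity label plus a boundary flag.
Numerical choices: admissibility floor G\* > 1e−10 (smaller roots are
the gang-free branch); |Rg\* + Rg − 1| < 1e−10 is treated as a tangent
(fold) root and reported once; for η = 0 the linear equation
b G\* + c = 0 is solved directly.  The η = 0, Rg ≤ 1 case (no endemic
state, outside the theorem's six labels) is mapped to the no-equilibria
label H2v_none.

Stability is decided by the eigenvalues of the exact Jacobian (absolute
tolerance 1e−9 on real parts; a "marginal" label is returned instead of
silently misclassifying near-zero real parts).  At the gang-free point
the spectrum factorises as {−(μ+θ), −μ} plus a quadratic whose constant
term is proportional to 1 − Rg, so gang-free stability ⇔ Rg < 1; the
factorisation is used as a cross-check, not as the classifier.

## Bifurcation direction

At β = β\* the Jacobian at the gang-free point has a simple zero
eigenvalue; the center-manifold coefficients contracted with the
closed-form null vectors w and v are

```
a_cm = 2 Λ β* (μ+θ)(θ+(1−p)μ)(μ+σ1)³ (η − η*) / μ
b_cm = Λ (μ+σ1)² (θ+μ(1−p)) / μ  > 0
```

derived here from the second partial derivatives of the vector field
(`a_cm = v3 · [2 w2 w3 β* + w3² · 2η β* Sr0]`); a finite-difference
Hessian-contraction oracle in the test suite confirms both to 1e−4
relative.  The eigenvectors are used unnormalized: only the signs of
a_cm and b_cm matter and positive rescaling preserves them.  The
bifurcation at Rg = 1 is backward iff a_cm > 0 iff η > η\*.

## A Hopf bifurcation inside the bistable window

At the backward-bifurcation example set (β = 0.3, η = 10, Rg ≈ 0.822)
the *lower* endemic root G\* ≈ 0.0344 is a saddle, as expected — but the
*upper* root G\* ≈ 0.2280 is **not** a point attractor: its eigenvalues,
confirmed in exact rational arithmetic, are
{−0.02, −0.18627, 0.023881 ± 0.279342 i} — an unstable spiral.
Scanning β across the bistable window shows a Hopf bifurcation at
β ≈ 0.336 (Rg ≈ 0.934): the upper branch is a stable node/focus only
above that point, and below it the gang-persistent attractor is a
stable limit cycle oscillating around the upper root (integration from
a large gang seed settles on oscillations of amplitude ≈ 0.3 in G).
The qualitative policy conclusion — gangs can persist below Rg = 1, and
elimination exhibits hysteresis — is unaffected: a small seed still
decays to the gang-free state and a large seed still sustains the gang.
But statements that the upper branch is stable across the whole window,
and that trajectories converge to the upper *equilibrium*, are false at
this parameter set.  Two acceptance-level tests assert those statements
as originally posed and are expected to fail; the unit suite asserts
the correct, eigenvalue-derived behaviour, including textbook
point-bistability at β = 0.35 in the same regime.

## Simulation

Integration uses SciPy's DOP853 adaptive explicit Runge–Kutta scheme,
defaults rtol = 1e−8, atol = 1e−10, sampled on a uniform grid of 1001
output points.  The orthant is invariant for the exact flow; numerical
undershoots below zero within max(atol, rtol · population scale) are
clamped to zero on output with a logged warning (accumulated error at
an absorbing zero scales with rtol·‖y‖, not the per-step atol), and
larger negatives abort with the failing time.  Halving the tolerances
changes terminal values by < 1e−6 relative on the fixtures.

Scenario conventions: the sweep metric is absolute G at the horizon
(default t_end = 100 years); per-step percent change is
100·(G_prev − G_next)/G_prev.  The default initial state is the
gang-free equilibrium seeded with G(0) = 0.01·Λ/μ and C(0) = 0; sweeps
probing the gang-persistent attractor instead start from a large seed
(G(0) = 0.5) so the metric reflects the endemic branch rather than a
decay tail.  Reported reductions from efficacy/conviction sweeps are
monotone-direction results under this documented metric; they are not
calibrated percentages, since the source material does not print the
initial conditions, proportions or evaluation time behind its
illustrative percentage claims.

## Problem sizes used in checks

Property tests use 50–200 randomly sampled valid parameter sets (rates
log-uniform on [1e−3, 2], proportions uniform on [0, 1], fixed seed),
a 10×10×10 jittered grid over (η, β, ε) for regime/root-count
agreement, 61-point bifurcation diagrams, and integrations to
t = 2000 years for attractor identification — small enough to run the
whole suite in a few seconds while exercising every regime of the
model.

## Limitations

* Homogeneous mixing and constant parameters; no individual-level,
  network, spatial or stochastic effects — so passing tests demonstrate
  correctness of the deterministic model's analysis, not realism of
  gang dynamics.
* No parameter fitting to data; fixtures are illustrative estimates.
* Local stability only (eigenvalues); no Lyapunov/global analysis, and
  limit cycles are detected by integration rather than continuation.
* The printed value 0.8823 for Rg at the example set is not reproduced
  by the Rg closed form (which gives 0.8223); the threshold η\* printed
  in the same sentence *is* reproduced exactly, so the closed form is
  treated as authoritative and the discrepancy is documented rather
  than targeted.
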