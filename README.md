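# gangdyn

A compartmental ODE model of gang membership dynamics under correctional
services, packaged as a reusable simulator and analysis toolkit for
quantitative criminologists and mathematical epidemiologists.

Gang recruitment behaves like a social contagion: joining is driven by
contact with, and imitation of, existing gang members.  The model splits
a community of size *N* into four compartments — susceptibles not at
risk of joining a gang (*Sₙ*), susceptibles at risk (*Sᵣ*), gang members
(*G*) and people held in correctional services (*C*) — and couples them
through an imitation-type initiation force

```
f(Sr, G) = β G (1 + η G) Sr
```

with effective contact rate *β* and imitation coefficient *η*.  Gang
members quit voluntarily at rate *σ₂* or are convicted at rate *γ*;
people leave correctional services at rate *σ₁* and, depending on the
programme efficacy *ε* ∈ [0, 1], either relapse into the gang (fraction
1 − *ε*) or rejoin the community (a fraction *ν* of effective releases
returns to the not-at-risk class).  Entrants arrive at rate *Λ* (a
proportion *p* not at risk) and everyone exits naturally at rate *μ*:

```
dSn/dt = pΛ + νεσ₁C − (μ+θ)Sn
dSr/dt = (1−p)Λ + θSn + σ₂G + (1−ν)εσ₁C − βG(1+ηG)Sr − μSr
dG/dt  = βG(1+ηG)Sr + (1−ε)σ₁C − (μ+σ₂+γ)G
dC/dt  = γG − (μ+σ₁)C
```

The package computes, in closed form, the **gang reproduction number**

```
Rg = β Λ (μ+σ₁)(θ+μ(1−p)) / [ μ(θ+μ)( μ(γ+μ+σ₂) + σ₁(γε+μ+σ₂) ) ]
```

its value R₀ at ε = 0, the critical efficacy ε\*, the contact-rate
threshold β\* (where Rg = 1), the imitation threshold η\* that switches
the bifurcation at Rg = 1 from forward to backward, and the subcritical
window parameter Rg\* (two endemic states coexist on 1 − Rg\* < Rg < 1
when η > η\*).  It also provides normalized forward sensitivity indices
(elasticities) of Rg, gang-free and gang-persistent equilibria with
eigenvalue-based stability labels, center-manifold bifurcation
diagnostics, bifurcation diagrams, time integration, hysteresis probes,
and intervention sweeps — from Python or from the `gangdyn` CLI.

## Worked example

The shipped `bifurcation_fig2` fixture is a backward-bifurcation example
set (Λ=0.047, μ=0.02, β=0.3, η=10, p=0.4, ν=0.7, θ=0.13, γ=0.5, σ₁=0.1,
σ₂=0.5, ε=0.5):

```python
from gangdyn import (load_fixture, threshold_report, classify_existence,
                     solve_endemic, assess_stability, bifurcation_direction)

p = load_fixture("bifurcation_fig2").params
print(threshold_report(p).as_dict())
```

prints (abridged)

```
Rg          0.822259     # below 1, yet gangs can persist
R0          1.106188     # without correctional efficacy, above 1
epsilon_star 0.15376     # efficacy needed to push Rg below 1 (attainable)
eta_star    2.759465     # imitation threshold; here eta=10 >> eta*
Rg_star     0.390540     # bistable window is (0.6095, 1) in Rg
beta_star   0.364849     # contact rate at which Rg = 1
```

Because η > η\* and 1 − Rg\* < Rg < 1, the model is **bistable**: a
stable gang-free state coexists with a gang-persistent attractor, and
eliminating gangs requires pushing Rg well below 1 (hysteresis):

```python
print(classify_existence(p).label)          # H2iii_two
for pt in (assess_stability(p, q) for q in solve_endemic(p)):
    print(f"G*={pt.state.G:.5f}", pt.stability,
          f"max Re = {pt.eigenvalues.real.max():+.5f}")
print(bifurcation_direction(p).direction)   # backward
```

```
H2iii_two
G*=0.03435 unstable  max Re = +0.07327    # saddle separating the basins
G*=0.22804 unstable  max Re = +0.02388    # unstable spiral: see note below
backward
```

A noteworthy finding reproduced by this package: at this parameter set
the *upper* endemic equilibrium is itself an unstable spiral — the
gang-persistent attractor is a limit cycle oscillating around
G\* ≈ 0.228, because a Hopf bifurcation sits inside the bistable window
(the upper branch is a point attractor only for Rg ≳ 0.93).  See
`docs/methods.md` for the analysis.

The same computations are available from the shell:

```bash
gangdyn thresholds --fixture bifurcation_fig2
gangdyn equilibria --fixture bifurcation_fig2 --out equilibria.json
gangdyn bifurcation-diagram --fixture bifurcation_fig2 \
    --beta-min 0.18 --beta-max 0.48 --n-points 61 --out diagram.csv
gangdyn sweep --fixture bifurcation_fig2 --name epsilon \
    --values 0.6,0.7,0.8,0.9 --t-end 100 --out sweep.csv
```

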