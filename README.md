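# actogel

Mechanochemical simulators of the excitable actomyosin cortex: RhoA
signalling coupled to active-gel mechanics, from a well-mixed patch to
two-dimensional defect turbulence.

## The problem

The actin cortex of animal cells pulses, flows, and assembles stable
contractile structures, all driven by the same molecular circuit: the GTPase
RhoA activates its own production and promotes actomyosin assembly, while
F-actin recruits GAPs that switch RhoA off — an activator–inhibitor circuit
in which the *activator diffuses faster*, so classical (Turing)
reaction–diffusion cannot pattern it.  `actogel` implements a model family
in which myosin contractility closes a second, mechanical feedback loop:
active stress drives cortical flows that advect RhoA and actomyosin up their
own concentration gradients.  This mechanochemical coupling destabilises
homogeneous states and generates, depending on just two control parameters
(basal RhoA production `S` and active contractility `σ'ₐ = σₐ/γ`), excitable
pulses, oscillations, travelling waves, stationary contractile patterns,
pulsatile flows, and topological turbulence.

## The model

Chemistry (concentrations dimensionless, rates in 1/s):

    R_r(r, m) = S + a rⁿ/(r_aⁿ + rⁿ) − g m r/(r_g + r)
    R_m(r, m) = S_m + k_a r² − k_d m

Well-mixed patch (module `local_model`): a viscoelastic element with strain
`u`, active stress saturating in m,

    η_L u̇ + E u = −σₐ m/(m₀ + m),
    ċ = R_c − c u̇/(1 + u)   for c ∈ {r, m},

so contraction concentrates and relaxation dilutes both species.

Continuum cortex (modules `gel1d`, `gel2d`): a periodic Maxwell active gel,

    γ(v + τ v̇) = η ∇²v (+ η_b ∇(∇·v) in 2D) + σₐ ∇[m/(m₀ + m)],
    ċ + ∇·(c v) = R_c + D_c ∇²c,

with hydrodynamic length λ = √(η/γ) = 14.3 μm and box L = 10λ.  Module
`linstab` builds the 3×3 plane-wave stability matrix about homogeneous fixed
points and reports the fastest-growing mode (wavelength, frequency, wave
speed).  Module `phasefield` extracts the oscillation phase
φ = atan2(r − r̄, m − m̄), detects ±1 phase singularities by plaquette
winding, and measures phase-velocity, vorticity, energy–enstrophy, and
speed-tail statistics of the turbulent states.

## Worked example

```python
import numpy as np
from actogel import (ChemistryParams, GelParams, LocalMechanicsParams,
                     classify_local, classify_spatial, simulate_local,
                     simulate_1d, local_activation_experiment)

p = ChemistryParams()                       # calibrated cortex chemistry
mp = LocalMechanicsParams(sigma_over_E=0.2)

for S in (0.0, 0.002, 0.025, 0.075):
    traj = simulate_local(None, p.with_(S=S), mp, t_end=2000)
    print(S, classify_local(traj, p.with_(S=S), mp).label)

for sig in (12.5, 25.0, 50.0):
    _, label = local_activation_experiment(GelParams(sigma_prime=sig))
    print(sig, label)
```

prints

```
0.0 quiescent
0.002 excitable
0.025 pulsatile
0.075 contractile
12.5 bistable-front
25.0 soliton
50.0 stable-localized
```

— the four dynamic regimes of the well-mixed model as the stimulus rises,
and the three memory classes of the spatial model's response to a transient
local RhoA activation: at low contractility the activation escapes as a
bistable front (no spatial memory), at moderate contractility it leaves as a
pair of annihilating solitons (transient memory), and at high contractility
it condenses into a stationary contractile peak pinned at the activation
site (persistent memory).

The same models are exposed on the command line:

```sh
actogel simulate-local --s 0.025 --out traj.tsv
actogel linstab --s 0.01 --sigma-prime 60 --out dispersion.tsv
actogel simulate-1d --sigma-prime 80 --stimulus 0.01 --out run.nc
actogel simulate-2d --sigma-prime 50 --stimulus 0.01 --out fields.nc
actogel defects --fields fields.nc --t-start 300 --out defects.tsv
```

## Layout

    src/actogel/kinetics.py     reaction terms, nullclines, fixed points
    src/actogel/local_model.py  well-mixed ODE model + regime phase diagrams
    src/actogel/gel1d.py        1D periodic active gel, kymographs, classifiers
    src/actogel/gel2d.py        2D active gel on the torus
    src/actogel/linstab.py      dispersion relations and stability maps
    src/actogel/phasefield.py   phase extraction, defects, turbulence statistics
    src/actogel/io_cli.py       configs, fixtures, output formats, CLI
    docs/methods.md             modelling and numerical methods note
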