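# gelrelease

Release kinetics of small nonionic molecules from **collapsed microgels** —
a dynamical density functional theory (DDFT) simulator with a
molecule-parameterization layer and closed-form mean-first-passage-time
predictors.

## The problem

Collapsed (dense, water-poor) microgels act as nonporous carriers: a cargo
molecule first *dissolves* in the polymer matrix and then *diffuses* down
its concentration gradient (solution–diffusion transport). Two intensive
parameters control how fast an encapsulated drug, reactant or probe leaves
a spherical particle of radius *b*:

* the in-gel diffusion coefficient **D\***, orders of magnitude below the
  bulk-water value *D*<sub>w</sub> and decaying exponentially with the
  molecule's Stokes radius *a*<sub>w</sub>, with shape-dependent constants
  (for equal size: linear > planar > spherical mobility), and
* the transfer free energy **ΔG** for moving from water into the polymer
  (negative = the gel retains the cargo), well described by a
  surface-area model ΔG = ΔG₀ + γ₀·4π(a<sub>w</sub>+0.233 nm)².

The package integrates the continuity equation for the cargo density
ρ(r,t) in spherical symmetry,

```
∂ρ/∂t = −(1/r²) ∂(r² J)/∂r,
J = −D_eff(r) [ ∂ρ/∂r + ρ ∂(βu_eff)/∂r + ρ ∂(βμ_ex)/∂r ],
```

with a smooth erf interface profile f(r) defining D_eff = D\*f + D_w(1−f)
and βu_eff = βΔG·f, a Carnahan–Starling hard-sphere excess term μ_ex, zero
flux at the center and an absorbing boundary at the cell radius R = 20b.
The released fraction f_rel(t) (cargo beyond r = b + 2δ) yields the
half-release time τ<sub>1/2</sub>.

Two headline results are reproduced computationally:

1. **Master curve** — release curves of different molecules collapse onto a
   single Weibull CDF, `f_rel = 1 − exp(−χ (t/τ½)^ν)`, once time is
   rescaled by τ<sub>1/2</sub>.
2. **Closed-form release time** — the mean escape time
   `τ̄ = b²/(15 D*) + (b²/(3 D_w)) e^(−βΔG)` (interior diffusion + barrier
   crossing) converts to τ<sub>1/2</sub> through the Weibull mean↔median
   relation and tracks the full DDFT result within ~20% across both the
   diffusion-limited and reaction-limited regimes.

## Worked example

```python
from gelrelease import analytic, ddft, fields, molecules

mol = molecules.get_molecule("Me").with_bath()      # methane at 340 K
gel = fields.MicrogelSpec(b=50.0, delta=1.0, beta_dG=mol.beta_dG)
traj = ddft.run_release(gel, mol, config=ddft.SolverConfig(scheme="implicit",
                                                           f_stop=0.995))
print(ddft.half_release_time(traj))                  # 2758 ns
print(ddft.mean_release_time(traj))                  # 5493 ns
print(analytic.analytic_half_release_time(gel.b, mol.D_star, mol.D_w,
                                          mol.beta_dG))  # 2770 ns
```

Half of the encapsulated methane leaves a 50 nm collapsed particle in about
2.8 µs; the analytic estimate (no PDE solve) lands within 1% here. The
`examples/` directory contains four short narrative scripts: molecule
parameterization from gyration-tensor eigenvalues, a full release
simulation, the two-regime analytic predictor, and the master-curve fit.

A thin CLI wraps the same library:

```bash
gelrelease molecules                 # the 15-molecule registry
gelrelease predict --b 100 --beta-dg -3 --dstar 0.01 --dw 1
gelrelease run config.yaml           # trajectory.csv + summary.json
gelrelease sweep sweep.yaml -o table.csv
```

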