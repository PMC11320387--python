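"""Simulate the release of methane from a collapsed microgel.

Solves the drift-diffusion (DDFT) equations for the cargo density in a
b = 50 nm microgel and reports the half-release and mean release times,
next to the closed-form prediction that needs no PDE solve.
"""

from gelrelease import analytic, ddft, fields, molecules

mol = molecules.get_molecule("Me").with_bath()  # resolve D_w at 340 K
gel = fields.MicrogelSpec(b=50.0, delta=1.0, beta_dG=mol.beta_dG)

config = ddft.SolverConfig(scheme="implicit", f_stop=0.995)
traj = ddft.run_release(gel, mol, config=config)

tau_half = ddft.half_release_time(traj)
tau_mean = ddft.mean_release_time(traj)
tau_half_pred = analytic.analytic_half_release_time(
    gel.b, mol.D_star, mol.D_w, mol.beta_dG
)

print(f"molecule: {mol.name} (a_w = {mol.a_w} nm, D*/D_w = {mol.Dstar_over_Dw}, "
      f"beta_dG = {mol.beta_dG})")
print(f"D_w = {mol.D_w:.2f} nm^2/ns -> tau0 = {traj.tau0 * 1e3:.1f} ps")
print(f"half-release time  tau_1/2 = {tau_half:.0f} ns "
      f"({tau_half / traj.tau0:.0f} tau0)")
print(f"mean release time  tau_bar = {tau_mean:.0f} ns")
print(f"analytic tau_1/2 (no PDE)  = {tau_half_pred:.0f} ns "
      f"({(tau_half_pred - tau_half) / tau_half:+.0%} vs DDFT)")
# half of the methane load leaves the particle within ~1 microsecond;
# the closed-form estimate tracks the full solution within ~10-20%
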