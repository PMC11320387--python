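import pytest

from gelrelease import ddft, fields, molecules


def probe_molecule(beta_dG: float, ratio: float, a_w=None) -> molecules.MoleculeSpec:
    """A reduced-unit spherical probe molecule (D_w = 1 nm^2/ns, so times
    come out in units of tau0)."""
    return molecules.MoleculeSpec(
        name="probe", symbol="probe", kappa=0.0, shape_class="spherical",
        beta_dG=beta_dG, Dstar_over_Dw=ratio, a_w=a_w, D_w=1.0,
    )


def quick_release(b, beta_dG, ratio, f_stop=0.9, **cfg_kwargs):
    """Implicit-scheme release run in reduced units."""
    mol = probe_molecule(beta_dG, ratio)
    gel = fields.MicrogelSpec(b=b, beta_dG=beta_dG)
    config = ddft.SolverConfig(scheme="implicit", f_stop=f_stop,
                               include_excess=False, **cfg_kwargs)
    return ddft.run_release(gel, mol, config=config)


@pytest.fixture(scope="session")
def master_trajectories():
    """Release curves for four registry molecules spanning fast/slow
    diffusion and attractive/neutral transfer free energies, at the
    reference conditions b = 50 nm, delta = 1 nm, rho0 = 0.01 M, R = 20b."""
    trajs = {}
    for sym in ("He", "Ne", "Me", "Et"):
        mol = molecules.get_molecule(sym)
        if mol.a_w is None:
            from dataclasses import replace

            a_w = molecules.estimate_stokes_radius(mol.kappa, mol.Dstar_over_Dw)
            mol = replace(mol, a_w=a_w)
        mol = mol.reduced()
        gel = fields.MicrogelSpec(b=50.0, delta=1.0, beta_dG=mol.beta_dG)
        config = ddft.SolverConfig(scheme="implicit", f_stop=0.995)
        trajs[sym] = ddft.run_release(gel, mol, config=config)
    return trajs
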