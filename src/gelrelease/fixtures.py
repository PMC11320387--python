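"""Self-contained fixtures: canonical shape triples and a fast reference run.

Everything here is regenerable from first principles at run time; nothing is
read from disk.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from . import analytic, ddft, fields, molecules

__all__ = ["ToyEigenvalueCase", "make_toy_eigenvalues", "make_reference_run"]


@dataclass(frozen=True)
class ToyEigenvalueCase:
    label: str
    eigenvalues: molecules.GyrationEigenvalues
    expected_kappa: float
    expected_shape: str


def make_toy_eigenvalues() -> list[ToyEigenvalueCase]:
    """Canonical gyration-eigenvalue triples with known anisotropy:
    sphere (0), regular planar (0.25), linear (1), plus perturbed variants."""
    ge = molecules.GyrationEigenvalues
    cases = [
        ToyEigenvalueCase("sphere", ge(1, 1, 1), 0.0, "spherical"),
        ToyEigenvalueCase("planar", ge(1, 1, 0), 0.25, "planar"),
        ToyEigenvalueCase("linear", ge(1, 0, 0), 1.0, "linear"),
    ]
    perturbed = [
        ("sphere-perturbed", ge(1.0, 1.01, 0.99), "spherical"),
        ("planar-perturbed", ge(1.05, 0.95, 0.02), "planar"),
        ("linear-perturbed", ge(1.0, 0.06, 0.04), "linear"),
    ]
    for label, eig, shape in perturbed:
        kappa = molecules.relative_shape_anisotropy(eig)
        cases.append(ToyEigenvalueCase(label, eig, kappa, shape))
    return cases


def make_reference_run() -> dict:
    """A fast, fully deterministic regression fixture.

    Runs a small release problem (b = 10 nm, D*/D_w = 0.1, beta dG = -1)
    with the implicit scheme and returns the trajectory, its half-release
    time, the analytic prediction, and a SHA-256 digest of the rounded
    release curve for bitwise regression checks.
    """
    mol = molecules.MoleculeSpec(
        name="reference", symbol="ref", kappa=0.0, shape_class="spherical",
        beta_dG=-1.0, Dstar_over_Dw=0.1, D_w=1.0,
    )
    gel = fields.MicrogelSpec(b=10.0, delta=1.0, beta_dG=-1.0, R_over_b=20.0)
    grid = fields.build_grid(gel, dr_fine=0.05, dr_coarse=0.5)
    config = ddft.SolverConfig(scheme="implicit", dt=1e-3, f_stop=0.99,
                               include_excess=False)
    traj = ddft.run_release(gel, mol, grid=grid, config=config)
    tau_half = ddft.half_release_time(traj)
    tau_half_analytic = analytic.analytic_half_release_time(
        gel.b, mol.D_star, mol.D_w, mol.beta_dG
    )
    payload = np.round(traj.f_rel, 12).tobytes() + np.round(traj.times, 9).tobytes()
    return {
        "trajectory": traj,
        "tau_half": tau_half,
        "tau_half_analytic": tau_half_analytic,
        "sha256": hashlib.sha256(payload).hexdigest(),
    }
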