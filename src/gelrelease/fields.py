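"""Radial profiles and the finite-volume grid for a collapsed microgel.

A collapsed microgel of radius ``b`` sits at the center of a spherical cell
of radius ``R = R_over_b * b``.  Its polymer volume fraction is roughly
uniform inside and drops to zero across a narrow interface of total width
2*delta; the same smooth switching function ``f(r)`` modulates the cargo's
effective diffusion coefficient (D* inside, D_w outside) and the effective
molecule-gel interaction (dG inside, 0 outside).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import erf

__all__ = [
    "MicrogelSpec",
    "RadialGrid",
    "interface_profile",
    "polymer_volume_fraction",
    "effective_diffusion",
    "effective_potential",
    "build_grid",
    "profiles_table",
]


@dataclass(frozen=True)
class MicrogelSpec:
    """The carrier particle and its cell.

    ``beta_dG`` is the dimensionless transfer free energy of the cargo into
    the gel; ``None`` means "take it from the molecule" in solver entry
    points.
    """

    b: float  # radius, nm
    delta: float = 1.0  # interface half-width, nm
    phi_p0: float = 0.5  # polymer volume fraction inside
    beta_dG: Optional[float] = None
    R_over_b: float = 20.0

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("microgel radius must be positive")
        if self.delta <= 0:
            raise ValueError("interface half-width must be positive")
        if not 0.0 < self.phi_p0 < 1.0:
            raise ValueError("polymer volume fraction must lie in (0, 1)")
        if self.R_over_b <= 1.0:
            raise ValueError("outer cell radius must exceed the microgel radius")
        if 2.0 * self.delta > self.b / 2.0:
            warnings.warn(
                f"interface width 2*delta={2 * self.delta} nm is not small "
                f"compared to b={self.b} nm; the sharp-interface picture "
                "underlying the model degrades",
                stacklevel=2,
            )

    @property
    def R(self) -> float:
        """Outer cell radius (nm)."""
        return self.R_over_b * self.b


def interface_profile(r, gel: MicrogelSpec):
    """Smooth switching function f(r) in [0, 1].

    f(r) = 0.5 * (1 - erf((r - b - delta)/(delta/sqrt(2)))): an erf interface
    of roughness sigma = delta/2 centered at r = b + delta, so the profile is
    ~1 (0.977) at r = b, exactly 0.5 at the midpoint b + delta, and ~0
    (0.023) at b + 2*delta — the transition is localized to [b, b + 2*delta]
    and the gel is uniform for r < b.  The convention is isolated here so a
    different width choice is a one-line change.
    """
    sigma = gel.delta / 2.0
    x = (np.asarray(r, dtype=float) - gel.b - gel.delta) / (math.sqrt(2.0) * sigma)
    return 0.5 * (1.0 - erf(x))


def polymer_volume_fraction(r, gel: MicrogelSpec):
    """phi_p(r) = phi_p0 * f(r)."""
    return gel.phi_p0 * interface_profile(r, gel)


def effective_diffusion(r, gel: MicrogelSpec, D_star: float, D_w: float):
    """Position-dependent diffusivity D_eff(r) = D* f(r) + D_w (1 - f(r))."""
    if D_star <= 0 or D_w <= 0:
        raise ValueError("diffusion coefficients must be positive")
    if D_star > D_w:
        warnings.warn(
            "D_star exceeds D_w; the collapsed-gel regime assumes D* <= D_w",
            stacklevel=2,
        )
    f = interface_profile(r, gel)
    return D_star * f + D_w * (1.0 - f)


def effective_potential(r, gel: MicrogelSpec, beta_dG: Optional[float] = None):
    """Effective molecule-gel interaction beta*u_eff(r) = beta*dG * f(r)."""
    if beta_dG is None:
        beta_dG = gel.beta_dG
    if beta_dG is None:
        raise ValueError("no beta_dG on the microgel spec and none supplied")
    return beta_dG * interface_profile(r, gel)


@dataclass(frozen=True)
class RadialGrid:
    """Nonuniform spherical finite-volume mesh.

    ``faces`` has one more entry than ``centers``; faces start at 0 and end
    at R.  ``shell_volumes`` are the exact volumes 4*pi/3*(r_{i+1}^3 - r_i^3).
    """

    faces: np.ndarray
    centers: np.ndarray = field(init=False)
    shell_volumes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        faces = np.asarray(self.faces, dtype=float)
        if faces[0] != 0.0:
            raise ValueError("grid must start at r=0")
        if np.any(np.diff(faces) <= 0):
            raise ValueError("grid faces must be strictly increasing")
        object.__setattr__(self, "faces", faces)
        object.__setattr__(self, "centers", 0.5 * (faces[:-1] + faces[1:]))
        object.__setattr__(
            self, "shell_volumes", 4.0 * np.pi / 3.0 * np.diff(faces**3)
        )

    @property
    def n_cells(self) -> int:
        return len(self.centers)

    @property
    def R(self) -> float:
        return float(self.faces[-1])

    @property
    def spacings(self) -> np.ndarray:
        return np.diff(self.faces)


def _graded_spacings(length: float, h0: float, h1: float, ratio: float) -> np.ndarray:
    """Fill an interval of ``length`` with spacings grading geometrically
    from ``h0`` to ``h1`` (then constant at ``h1``), rescaled to fit exactly.

    Uniform rescaling preserves adjacent-cell ratios, so the grading bound
    survives the fit.
    """
    if length <= 0:
        return np.empty(0)
    if length <= min(h0, h1):
        return np.array([length])
    hs = [h0]
    while sum(hs) < length:
        nxt = min(h1, hs[-1] * ratio) if h1 >= h0 else max(h1, hs[-1] / ratio)
        hs.append(nxt)
    hs = np.array(hs)
    return hs * (length / hs.sum())


def build_grid(
    gel: MicrogelSpec,
    dr_fine: float = 0.02,
    dr_coarse: float = 0.5,
    window_halfwidth: Optional[float] = None,
    grading_ratio: float = 1.3,
) -> RadialGrid:
    """Build the nonuniform mesh: fine spacing across the interface window
    [b - w, b + w] (default w = 4*delta), coarse elsewhere, geometric
    grading in between so no two adjacent cells differ by more than ~30%.
    """
    if not 0 < dr_fine <= dr_coarse:
        raise ValueError("need 0 < dr_fine <= dr_coarse")
    if window_halfwidth is None:
        window_halfwidth = 4.0 * gel.delta
    if window_halfwidth < 2.0 * gel.delta:
        raise ValueError("fine window must cover at least [b-2delta, b+2delta]")
    R = gel.R
    w0, w1 = gel.b - window_halfwidth, gel.b + window_halfwidth
    if w0 < 0 or w1 > R:
        warnings.warn("fine-grid window clipped to [0, R]", stacklevel=2)
        w0, w1 = max(w0, 0.0), min(w1, R)

    # interior: grade from coarse (at r=0) down to fine (at the window)
    inner = _graded_spacings(w0, dr_fine, dr_coarse, grading_ratio)[::-1]
    # window: uniform fine spacing
    n_win = max(1, int(np.ceil((w1 - w0) / dr_fine)))
    window = np.full(n_win, (w1 - w0) / n_win)
    # exterior: grade from fine back up to coarse
    outer = _graded_spacings(R - w1, dr_fine, dr_coarse, grading_ratio)
    faces = np.concatenate([[0.0], np.cumsum(np.concatenate([inner, window, outer]))])
    faces[-1] = R  # absorb cumulative-sum roundoff
    return RadialGrid(faces=faces)


def profiles_table(
    grid: RadialGrid,
    gel: MicrogelSpec,
    D_star: float,
    D_w: float,
    beta_dG: Optional[float] = None,
) -> pd.DataFrame:
    """All radial profiles evaluated at the cell centers, as a DataFrame
    (columns r_nm, f, phi_p, D_eff_nm2_ns, beta_u_eff) for export/plotting."""
    r = grid.centers
    return pd.DataFrame(
        {
            "r_nm": r,
            "f": interface_profile(r, gel),
            "phi_p": polymer_volume_fraction(r, gel),
            "D_eff_nm2_ns": effective_diffusion(r, gel, D_star, D_w),
            "beta_u_eff": effective_potential(r, gel, beta_dG),
        }
    )
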