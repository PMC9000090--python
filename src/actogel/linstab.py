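"""Linear stability of homogeneous steady states of the 1D gel model.

A plane-wave perturbation ~exp(ikx + lambda t) of a homogeneous fixed point
(r*, m*, v=0) of the reaction-advection-diffusion gel obeys a 3x3 complex
eigenvalue problem built from the reaction Jacobian, diffusive damping
(-D k^2), the advective couplings (-i k r*, -i k m*) and the Maxwell
velocity equation, whose active-stress term couples actomyosin perturbations
back into flow.  In gamma-scaled units the mechanics row reads

    d(dv)/dt = [ i k sigma' m0 / (m0 + m*)^2 * dm - (1 + lam^2 k^2) dv ] / tau.

The leading eigenvalue branch lambda(k) gives the growth rate; its maximum
over k selects the fastest-growing mode k*, from which wavelength 2*pi/k*,
frequency Im lambda(k*) and wave speed Im lambda(k*)/k* follow (the
`alt_convention` flag switches to an alternative normalisation
1/(2 pi k*) and Im lambda/(2 pi k*)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gel1d import GelParams
from .kinetics import ChemistryParams, FixedPoint, find_fixed_points, reaction_jacobian

__all__ = ["DispersionResult", "jacobian_k", "dispersion", "stability_map", "select_fixed_point"]


@dataclass(frozen=True)
class DispersionResult:
    """Leading eigenvalue branch of the homogeneous state vs wavenumber."""

    k_grid: np.ndarray          # 1/um
    leading: np.ndarray         # complex growth rates lambda(k), 1/s
    k_star: float               # argmax of Re lambda over the scanned k > 0
    growth_rate: float          # Re lambda(k_star)
    wavelength: float           # um (inf for k_star = 0)
    frequency: float            # |Im lambda(k_star)|, 1/s
    wave_speed: float           # um/s

    @property
    def unstable(self) -> bool:
        return self.growth_rate > 0


def select_fixed_point(p: ChemistryParams) -> FixedPoint:
    """Fixed point the homogeneous state is linearised about.

    When three coexist the low-(r, m) branch is used (the resting cortex);
    otherwise the single fixed point.
    """
    fps = find_fixed_points(p)
    if not fps:
        raise RuntimeError("no fixed point found")
    return min(fps, key=lambda f: f.m)


def jacobian_k(
    fp: FixedPoint, k: float, p: ChemistryParams, gp: GelParams
) -> np.ndarray:
    """3x3 complex stability matrix at wavenumber k about (r*, m*, 0).

    Rows/columns order (dr, dm, dv).  At k = 0 the mechanics row decouples
    to eigenvalue -1/tau and the upper-left block is the reaction Jacobian.
    """
    r, m = fp.r, fp.m
    Jr = reaction_jacobian(r, m, p)
    J = np.zeros((3, 3), dtype=complex)
    J[0, 0] = Jr[0, 0] - gp.D_r * k**2
    J[0, 1] = Jr[0, 1]
    J[0, 2] = -1j * k * r
    J[1, 0] = Jr[1, 0]
    J[1, 1] = Jr[1, 1] - gp.D_m * k**2
    J[1, 2] = -1j * k * m
    J[2, 1] = 1j * k * gp.sigma_prime * gp.m0 / (gp.tau * (gp.m0 + m) ** 2)
    J[2, 2] = -(1.0 + gp.lam**2 * k**2) / gp.tau
    return J


def dispersion(
    fp: FixedPoint | None,
    p: ChemistryParams,
    gp: GelParams,
    k_max: float | None = None,
    n_k: int = 256,
    alt_convention: bool = False,
) -> DispersionResult:
    """Scan the leading eigenvalue over k in (0, k_max].

    ``k_max`` defaults to pi/dx, the grid Nyquist wavenumber of ``gp``.
    A dispersion whose maximum growth sits at the smallest scanned k is
    reported with k_star = 0 (homogeneous instability / no finite-k mode).
    """
    if n_k < 64:
        raise ValueError("n_k must be at least 64")
    if fp is None:
        fp = select_fixed_point(p)
    if k_max is None:
        k_max = np.pi / gp.dx
    k_grid = np.linspace(k_max / n_k, k_max, n_k)
    lead = np.empty(n_k, dtype=complex)
    for i, k in enumerate(k_grid):
        ev = np.linalg.eigvals(jacobian_k(fp, k, p, gp))
        lead[i] = ev[np.argmax(ev.real)]
    i_star = int(np.argmax(lead.real))
    # interior maximum required for a finite-wavelength mode
    if i_star == 0 and lead.real[0] <= np.max(lead.real) + 1e-15:
        # maximum at the long-wavelength end: homogeneous mode dominates
        ev0 = np.linalg.eigvals(jacobian_k(fp, 0.0, p, gp))
        lam0 = ev0[np.argmax(ev0.real)]
        if lam0.real >= lead.real[0]:
            return DispersionResult(
                k_grid=k_grid, leading=lead, k_star=0.0,
                growth_rate=float(lam0.real), wavelength=np.inf,
                frequency=abs(float(lam0.imag)), wave_speed=0.0,
            )
    k_star = float(k_grid[i_star])
    lam_star = lead[i_star]
    if alt_convention:
        wavelength = 1.0 / (2.0 * np.pi * k_star)
        speed = abs(lam_star.imag) / (2.0 * np.pi * k_star)
    else:
        wavelength = 2.0 * np.pi / k_star
        speed = abs(lam_star.imag) / k_star
    return DispersionResult(
        k_grid=k_grid, leading=lead, k_star=k_star,
        growth_rate=float(lam_star.real), wavelength=float(wavelength),
        frequency=abs(float(lam_star.imag)), wave_speed=float(speed),
    )


def stability_map(
    S_values: np.ndarray,
    sigma_values: np.ndarray,
    p: ChemistryParams,
    gp: GelParams,
    **disp_kwargs,
) -> dict[str, np.ndarray]:
    """Wavelength/frequency/wave-speed/growth maps over the (S, sigma') plane."""
    S_values = np.asarray(S_values, dtype=float)
    sigma_values = np.asarray(sigma_values, dtype=float)
    shape = (S_values.size, sigma_values.size)
    out = {key: np.full(shape, np.nan) for key in
           ("wavelength", "frequency", "wave_speed", "growth_rate")}
    for i, S in enumerate(S_values):
        pc = p.with_(S=float(S))
        fp = select_fixed_point(pc)
        for j, sig in enumerate(sigma_values):
            d = dispersion(fp, pc, gp.with_(sigma_prime=float(sig)), **disp_kwargs)
            out["wavelength"][i, j] = d.wavelength
            out["frequency"][i, j] = d.frequency
            out["wave_speed"][i, j] = d.wave_speed
            out["growth_rate"][i, j] = d.growth_rate
    return out
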