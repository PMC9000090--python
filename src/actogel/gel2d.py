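"""Two-dimensional active-gel model of the cortical surface.

Same physics as the 1D strip, on a periodic square (torus).  The gel
stress tensor splits into bulk and shear parts with a common Maxwell
relaxation time, giving the velocity equation (gamma-scaled)

    tau dv/dt = -v + (eta_s/gamma) lap(v) + (eta_b/gamma) grad(div v)
                + sigma' grad[ m / (m0 + m) ],

with eta_b = (3/4) eta and eta_s = (1/4) eta by default, so a
one-dimensional (y-invariant) solution feels the full viscosity
eta_s + eta_b = eta and reduces exactly to the 1D model.  The implicit
velocity update is solved spectrally: in Fourier space the operator is
diagonal in the longitudinal/transverse decomposition of v-hat, and the
active forcing is purely longitudinal.

Transport of r and m uses dimension-split conservative van Leer fluxes
(the 1D kernel applied along x then y), spectral implicit diffusion, and
the same Heun reaction update.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import xarray as xr

from .gel1d import GelParams, StimulusProtocol, _reaction_step
from .kinetics import ChemistryParams

__all__ = [
    "Gel2DParams",
    "Field2D",
    "velocity_step_2d",
    "simulate_2d",
    "strain_rate_field",
    "initial_field_2d",
]


@dataclass(frozen=True)
class Gel2DParams(GelParams):
    """Gel parameters plus the bulk/shear split of the total viscosity."""

    eta_b_frac: float = 0.75
    eta_s_frac: float = 0.25

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.eta_b_frac <= 0 or self.eta_s_frac <= 0:
            raise ValueError("viscosity fractions must be positive")

    def with_(self, **kwargs) -> "Gel2DParams":
        return replace(self, **kwargs)


@dataclass
class Field2D:
    """Concentration and velocity fields on the periodic N x N grid."""

    x: np.ndarray           # cell-centre coordinates (shared by both axes)
    r: np.ndarray           # (N, N), first index = y row, second = x column
    m: np.ndarray
    vx: np.ndarray
    vy: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.x)
        for arr in (self.r, self.m, self.vx, self.vy):
            if arr.shape != (n, n):
                raise ValueError("2D fields must be N x N")


def initial_field_2d(
    gp: Gel2DParams,
    p: ChemistryParams,
    seed: int | None = 0,
    noise_amplitude: float = 1e-2,
    kind: str = "empty",
) -> Field2D:
    """Seedable initial condition for 2D runs.

    kind='empty'  : bare cortex (m = 0, trace RhoA noise); with a sustained
                    stimulus the first excitable pulse fires and ignites
                    patterned dynamics.
    kind='ignite' : RhoA loaded at pulse-triggering level (0.3) with
                    band-limited noise of correlation length lam/3 and 60%
                    relative amplitude, no actomyosin.  Used at S = 0 where
                    nothing fires spontaneously: the spatial structure of
                    the triggering pulse lets contractile flows amplify it
                    into clusters/networks.
    kind='rest'   : low homogeneous fixed point with small multiplicative
                    noise of ``noise_amplitude``.
    """
    from .kinetics import find_fixed_points

    rng = np.random.default_rng(seed)
    x = gp.grid()
    N = gp.N
    if kind == "empty":
        r = 1e-4 * np.abs(rng.standard_normal((N, N)))
        m = np.zeros((N, N))
    elif kind == "ignite":
        noise = rng.standard_normal((N, N))
        kx = np.fft.fftfreq(N, d=gp.dx)[None, :]
        ky = np.fft.fftfreq(N, d=gp.dx)[:, None]
        corr = gp.lam / 3.0
        filt = np.exp(-(kx**2 + ky**2) * corr**2 / 2.0)
        sm = np.fft.ifft2(np.fft.fft2(noise) * filt).real
        sm /= max(sm.std(), 1e-300)
        r = 0.3 * (1.0 + 0.6 * sm)
        m = np.zeros((N, N))
    elif kind == "rest":
        fps = find_fixed_points(p)
        low = min(fps, key=lambda f: f.m)
        r = max(low.r, 1e-3) * (1 + noise_amplitude * rng.standard_normal((N, N)))
        m = max(low.m, 1e-3) * (1 + noise_amplitude * rng.standard_normal((N, N)))
    else:
        raise ValueError(f"unknown initial-condition kind {kind!r}")
    return Field2D(x=x, r=np.clip(r, 0, None), m=np.clip(m, 0, None),
                   vx=np.zeros((N, N)), vy=np.zeros((N, N)))


def _kgrids(N: int, L: float):
    k1 = 2.0 * np.pi * np.fft.fftfreq(N, d=L / N)
    kx = k1[None, :]
    ky = k1[:, None]
    return kx, ky


def velocity_step_2d(
    vx: np.ndarray,
    vy: np.ndarray,
    m: np.ndarray,
    gp: Gel2DParams,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Backward-Euler step of the 2D Maxwell velocity equation (spectral).

    Splitting v-hat into components along and perpendicular to k decouples
    the operator: the longitudinal part relaxes with total viscosity
    (eta_s + eta_b)/gamma = lam^2 and carries all of the active forcing;
    the transverse part sees only the shear viscosity.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (np.all(np.isfinite(vx)) and np.all(np.isfinite(vy)) and np.all(np.isfinite(m))):
        raise FloatingPointError("non-finite input to velocity step")
    N, L = gp.N, gp.L
    kx, ky = _kgrids(N, L)
    k2 = kx**2 + ky**2
    a_s = gp.eta_s_frac * gp.lam**2      # eta_s / gamma
    a_l = gp.lam**2                      # (eta_s + eta_b) / gamma

    f_hat = np.fft.fft2(gp.sigma_prime * m / (gp.m0 + m))
    fx, fy = 1j * kx * f_hat, 1j * ky * f_hat   # purely longitudinal forcing

    vx_h, vy_h = np.fft.fft2(vx), np.fft.fft2(vy)
    with np.errstate(invalid="ignore", divide="ignore"):
        k2s = np.where(k2 == 0, 1.0, k2)
        # longitudinal / transverse projections of the velocity
        div_h = kx * vx_h + ky * vy_h
        lx, ly = kx * div_h / k2s, ky * div_h / k2s
    tx, ty = vx_h - lx, vy_h - ly

    c = gp.tau / dt
    denom_l = c + 1.0 + a_l * k2
    denom_t = c + 1.0 + a_s * k2
    lx_new = (c * lx + fx) / denom_l
    ly_new = (c * ly + fy) / denom_l
    tx_new = c * tx / denom_t
    ty_new = c * ty / denom_t
    vx_new = np.fft.ifft2(lx_new + tx_new).real
    vy_new = np.fft.ifft2(ly_new + ty_new).real
    return vx_new, vy_new


def _advect_axis(c: np.ndarray, v: np.ndarray, dt: float, dx: float, axis: int) -> np.ndarray:
    """Conservative van Leer update of d(c)/dt + d(c v)/daxis = 0."""
    def sh(a, n):
        return np.roll(a, n, axis=axis)

    v_face = 0.5 * (v + sh(v, 1))
    dc_m = c - sh(c, 1)
    dc_p = sh(c, -1) - c
    denom = dc_m + dc_p
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(dc_m * dc_p > 0, 2.0 * dc_m * dc_p / np.where(denom == 0, 1, denom), 0.0)
    nu = v_face * dt / dx
    up = sh(c, 1) + 0.5 * (1.0 - nu) * sh(slope, 1)
    dn = c - 0.5 * (1.0 + nu) * slope
    flux = np.where(v_face > 0, up, dn) * v_face
    return c - dt / dx * (sh(flux, -1) - flux)


def _diffuse_2d(c: np.ndarray, D: float, dt: float, gp: Gel2DParams) -> np.ndarray:
    if D <= 0:
        return c
    kx, ky = _kgrids(gp.N, gp.L)
    return np.fft.ifft2(np.fft.fft2(c) / (1.0 + dt * D * (kx**2 + ky**2))).real


def strain_rate_field(vx: np.ndarray, vy: np.ndarray, L: float) -> np.ndarray:
    """Local strain rate div(v), spectral derivatives on the torus."""
    N = vx.shape[0]
    kx, ky = _kgrids(N, L)
    return np.fft.ifft2(1j * kx * np.fft.fft2(vx) + 1j * ky * np.fft.fft2(vy)).real


def simulate_2d(
    init: Field2D | None,
    p: ChemistryParams,
    gp: Gel2DParams,
    stim: StimulusProtocol | float = 0.0,
    t_end: float = 500.0,
    dt_out: float = 1.0,
    advect: bool = True,
    include_reactions: bool = True,
    dt_max: float = 0.25,
    seed: int | None = 0,
    store: tuple[str, ...] = ("r", "m"),
    progress: Callable[[float], None] | None = None,
) -> xr.Dataset:
    """Integrate the 2D gel model; returns a (time, y, x) Dataset.

    Same operator splitting as 1D: implicit spectral velocity step,
    dimension-split van Leer transport, spectral diffusion, Heun reaction.
    ``store`` selects which fields are kept per output frame ('r', 'm',
    'v' for both components plus divergence); velocities of the final
    frame are always included.  A spatially uniform stimulus value may be
    passed directly as a float.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if isinstance(stim, (int, float)):
        uniform_S = float(stim)
        stim_fn = None
    else:
        uniform_S = None
        stim_fn = stim
    if init is None:
        init = initial_field_2d(gp, p, seed=seed)
    x, dx = init.x, gp.dx
    r, m = init.r.copy(), init.m.copy()
    vx, vy = init.vx.copy(), init.vy.copy()

    n_out = int(round(t_end / dt_out)) + 1
    times = np.arange(n_out) * dt_out
    data: dict[str, np.ndarray] = {}
    N = gp.N
    if "r" in store:
        data["r"] = np.empty((n_out, N, N))
    if "m" in store:
        data["m"] = np.empty((n_out, N, N))
    if "v" in store:
        data["vx"] = np.empty((n_out, N, N))
        data["vy"] = np.empty((n_out, N, N))

    def record(i):
        if "r" in data:
            data["r"][i] = r
        if "m" in data:
            data["m"][i] = m
        if "vx" in data:
            data["vx"][i] = vx
            data["vy"][i] = vy

    record(0)
    t = 0.0
    XX = x[None, :] * np.ones((N, 1))
    for i_out in range(1, n_out):
        t_target = times[i_out]
        while t < t_target - 1e-9:
            vmax = max(float(np.abs(vx).max()), float(np.abs(vy).max()))
            dt = min(dt_max, t_target - t)
            if vmax > 0:
                dt = min(dt, 0.5 * dx / vmax)
            vx, vy = velocity_step_2d(vx, vy, m, gp, dt)
            if advect:
                r = _advect_axis(r, vx, dt, dx, axis=1)
                r = _advect_axis(r, vy, dt, dx, axis=0)
                m = _advect_axis(m, vx, dt, dx, axis=1)
                m = _advect_axis(m, vy, dt, dx, axis=0)
            r = _diffuse_2d(r, gp.D_r, dt, gp)
            m = _diffuse_2d(m, gp.D_m, dt, gp)
            if include_reactions:
                S_loc = uniform_S if uniform_S is not None else stim_fn(XX, t)
                r, m = _reaction_step(r, m, S_loc, p, dt)
            t += dt
            if max(np.abs(r).max(), np.abs(m).max(), vmax) > 1e6:
                raise FloatingPointError(f"field blow-up at t={t:.1f}s")
        record(i_out)
        if progress is not None:
            progress(t)

    ds_vars = {key: (("time", "y", "x"), arr) for key, arr in data.items()}
    ds = xr.Dataset(
        ds_vars,
        coords={"time": times, "x": x, "y": x},
        attrs={
            "tau": gp.tau, "lam": gp.lam, "sigma_prime": gp.sigma_prime,
            "D_r": gp.D_r, "D_m": gp.D_m, "m0": gp.m0, "L": gp.L, "N": gp.N,
            "eta_b_frac": gp.eta_b_frac, "eta_s_frac": gp.eta_s_frac,
            "S_out": uniform_S if uniform_S is not None else stim_fn.S_out,
            "seed": -1 if seed is None else seed,
            "x_units": "um", "time_units": "s", "v_units": "um/s",
        },
    )
    ds["vx_final"] = (("y", "x"), vx)
    ds["vy_final"] = (("y", "x"), vy)
    return ds
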