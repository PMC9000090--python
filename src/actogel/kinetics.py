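"""Reaction kinetics of the RhoA-actomyosin circuit.

The circuit couples the small GTPase RhoA (activator, concentration ``r``)
to a single combined F-actin + myosin-II species, actomyosin (inhibitor and
force generator, concentration ``m``).  RhoA is produced at a basal rate
``S`` (GEF activity), amplifies itself autocatalytically with a saturating
(Hill) term, and is inactivated by actomyosin-recruited GAPs.  Actomyosin is
assembled downstream of RhoA and turns over by first-order disassembly:

    R_r(r, m) = S + a * r^n / (r_a^n + r^n) - g * m * r / (r_g + r)
    R_m(r, m) = S_m + k_a * r^2 - k_d * m

These two rates are the only place the chemistry enters any of the solvers
in this package; every spatial model imports them from here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Literal

import numpy as np
from scipy.optimize import brentq, fsolve

__all__ = [
    "ChemistryParams",
    "FixedPoint",
    "rr_rate",
    "rm_rate",
    "reaction_jacobian",
    "nullclines",
    "find_fixed_points",
]


@dataclass(frozen=True)
class ChemistryParams:
    """Rate constants of the RhoA-actomyosin reaction circuit.

    Defaults are the calibrated values for the *C. elegans* cortex.
    Concentrations are dimensionless; rates in 1/s.

    Attributes
    ----------
    S : basal RhoA activation rate (GEF stimulus), 1/s.
    a : autocatalytic RhoA production rate, 1/s.
    n : Hill exponent of the autocatalytic term (1 gives the Michaelis form).
    r_a : RhoA concentration at half-maximal autocatalysis.
    g : actomyosin-mediated negative-feedback (GAP) rate, 1/s.
    r_g : RhoA concentration at half-maximal inactivation.
    S_m : basal actomyosin production rate, 1/s.
    k_a : actomyosin assembly rate, 1/s.
    k_d : actomyosin disassembly rate, 1/s.
    """

    S: float = 0.0
    a: float = 0.1609
    n: float = 1.0
    r_a: float = 0.3833
    g: float = 0.1787
    r_g: float = 0.01
    S_m: float = 0.0076
    k_a: float = 0.1408
    k_d: float = 0.0828

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")
        if self.r_a <= 0 or self.r_g <= 0:
            raise ValueError("r_a and r_g must be positive")

    def with_(self, **kwargs) -> "ChemistryParams":
        """Return a copy with selected parameters replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FixedPoint:
    """A simultaneous root of (R_r, R_m) with its linear stability.

    ``stability`` is read off the eigenvalues of the 2x2 reaction Jacobian:
    'stable' (both real parts negative), 'unstable' (both positive) or
    'saddle' (real eigenvalues of opposite sign).  ``oscillatory`` flags a
    complex pair (spiral/limit-cycle-adjacent dynamics).
    """

    r: float
    m: float
    stability: Literal["stable", "unstable", "saddle"]
    oscillatory: bool = False
    eigenvalues: tuple = field(default=(), compare=False)


def _check_nonneg(r, m) -> None:
    if np.any(np.asarray(r) < 0) or np.any(np.asarray(m) < 0):
        raise ValueError("concentrations must be non-negative")


def rr_rate(r, m, p: ChemistryParams):
    """RhoA production rate R_r(r, m) in 1/s.  Accepts scalars or arrays."""
    _check_nonneg(r, m)
    r = np.asarray(r, dtype=float)
    m = np.asarray(m, dtype=float)
    rn = r**p.n
    out = p.S + p.a * rn / (p.r_a**p.n + rn) - p.g * m * r / (p.r_g + r)
    return out if out.ndim else float(out)


def rm_rate(r, m, p: ChemistryParams):
    """Actomyosin production rate R_m(r, m) in 1/s."""
    _check_nonneg(r, m)
    r = np.asarray(r, dtype=float)
    m = np.asarray(m, dtype=float)
    out = p.S_m + p.k_a * r**2 - p.k_d * m
    return out if out.ndim else float(out)


def reaction_jacobian(r: float, m: float, p: ChemistryParams) -> np.ndarray:
    """Analytic 2x2 Jacobian of (R_r, R_m) at (r, m)."""
    rn = r**p.n
    ran = p.r_a**p.n
    # d/dr of the Hill term; the r==0 limit is 0 for n > 1 and a/r_a * ... for n == 1
    if r == 0.0:
        d_auto = p.a * p.n / p.r_a if p.n == 1.0 else 0.0
    else:
        d_auto = p.a * p.n * rn / r * ran / (ran + rn) ** 2
    drr = d_auto - p.g * m * p.r_g / (p.r_g + r) ** 2
    drm = -p.g * r / (p.r_g + r)
    return np.array([[drr, drm], [2.0 * p.k_a * r, -p.k_d]])


def nullclines(p: ChemistryParams, r_grid: np.ndarray):
    """Solve each nullcline for m on a grid of r values.

    Returns ``(m_rr, m_rm)``: actomyosin concentration on the R_r = 0 and
    R_m = 0 nullclines.  The R_r nullcline is undefined at r = 0 (the
    GAP term vanishes there); such entries are returned as NaN.
    """
    r = np.asarray(r_grid, dtype=float)
    if np.any(r < 0):
        raise ValueError("r_grid must be non-negative")
    rn = r**p.n
    with np.errstate(divide="ignore", invalid="ignore"):
        m_rr = (p.S + p.a * rn / (p.r_a**p.n + rn)) * (p.r_g + r) / (p.g * r)
    m_rr = np.where(r > 0, m_rr, np.nan)
    m_rm = (p.S_m + p.k_a * r**2) / p.k_d
    return m_rr, m_rm


def _classify(jac: np.ndarray) -> tuple[str, bool]:
    ev = np.linalg.eigvals(jac)
    osc = bool(np.any(np.abs(ev.imag) > 1e-12))
    re = ev.real
    if np.all(re < 0):
        return "stable", osc
    if np.all(re > 0):
        return "unstable", osc
    return "saddle", osc


def find_fixed_points(
    p: ChemistryParams,
    r_max: float = 10.0,
    n_scan: int = 4000,
    tol: float = 1e-10,
    merge_tol: float = 1e-6,
) -> list[FixedPoint]:
    """All non-negative fixed points of the reaction system, with stability.

    Substitutes the actomyosin nullcline m(r) = (S_m + k_a r^2)/k_d into
    R_r, brackets sign changes of the resulting scalar function on a dense
    r grid, polishes each bracket with Brent's method, then verifies the
    2D residual with a Newton polish.  Stability comes from the analytic
    reaction Jacobian.  The root count is insensitive to doubling
    ``n_scan`` for the default chemistry.
    """

    def h(r: float) -> float:
        m = (p.S_m + p.k_a * r * r) / p.k_d
        return rr_rate(r, m, p)

    rg = np.linspace(0.0, r_max, n_scan)
    hv = np.array([h(x) for x in rg])
    roots: list[float] = []
    # exact zeros on grid nodes (e.g. r = 0 when S = 0)
    for i in np.flatnonzero(np.abs(hv) < tol):
        roots.append(rg[i])
    for i in np.flatnonzero(np.sign(hv[:-1]) * np.sign(hv[1:]) < 0):
        roots.append(brentq(h, rg[i], rg[i + 1], xtol=1e-14))

    out: list[FixedPoint] = []
    for r0 in sorted(roots):
        m0 = (p.S_m + p.k_a * r0 * r0) / p.k_d
        if r0 > 0:
            sol = fsolve(
                lambda z: [rr_rate(max(z[0], 0.0), max(z[1], 0.0), p),
                           rm_rate(max(z[0], 0.0), max(z[1], 0.0), p)],
                [r0, m0], full_output=False, xtol=1e-13,
            )
            r0, m0 = max(float(sol[0]), 0.0), max(float(sol[1]), 0.0)
        if abs(rr_rate(r0, m0, p)) > 1e2 * tol or abs(rm_rate(r0, m0, p)) > 1e2 * tol:
            continue
        if any(abs(r0 - q.r) < merge_tol and abs(m0 - q.m) < merge_tol for q in out):
            continue
        stab, osc = _classify(reaction_jacobian(r0, m0, p))
        out.append(FixedPoint(r=r0, m=m0, stability=stab, oscillatory=osc,
                              eigenvalues=tuple(np.linalg.eigvals(reaction_jacobian(r0, m0, p)))))
    return out
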