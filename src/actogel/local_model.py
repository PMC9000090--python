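"""Well-mixed mechanochemical model of a homogeneous cortex patch.

A locally homogeneous region of cortex is treated as an active Kelvin-Voigt
element with strain ``u``: actomyosin pulls with a saturating active stress
``sigma_a * m / (m0 + m)``, balanced by elastic restoring stress ``E u`` and
viscous drag ``eta_L du/dt``.  Contraction (du/dt < 0) concentrates the
membrane-bound species and relaxation dilutes them, so each concentration
``c`` obeys dc/dt = R_c - c * (du/dt) / (1 + u): the product c*(1+u) is
conserved when reactions are switched off.

Only two mechanical groups enter: the relative contractility sigma_a/E and
the viscoelastic time eta_L/E.  Depending on the basal RhoA stimulus S the
patch is quiescent, excitable (single pulse), pulsatile (limit cycle) or
contractile (settles at high actomyosin after damped ringing).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .kinetics import ChemistryParams, find_fixed_points, rm_rate, rr_rate

__all__ = [
    "LocalMechanicsParams",
    "LocalState",
    "LocalTrajectory",
    "LocalRegime",
    "local_rhs",
    "simulate_local",
    "classify_local",
    "phase_diagram_local",
]

RegimeLabel = Literal["quiescent", "excitable", "pulsatile", "contractile"]


@dataclass(frozen=True)
class LocalMechanicsParams:
    """Mechanical constants of the local (well-mixed) model.

    sigma_over_E : relative contractility sigma_a / E (dimensionless).
    tau_local    : viscoelastic time eta_L / E in seconds.
    m0           : actomyosin concentration at half-maximal active stress.
    """

    sigma_over_E: float = 0.2
    tau_local: float = 5.0
    m0: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_over_E < 0:
            raise ValueError("sigma_over_E must be >= 0")
        if self.tau_local <= 0 or self.m0 <= 0:
            raise ValueError("tau_local and m0 must be positive")

    def with_(self, **kwargs) -> "LocalMechanicsParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class LocalState:
    r: float
    m: float
    u: float = 0.0

    def __post_init__(self) -> None:
        if self.r < 0 or self.m < 0:
            raise ValueError("concentrations must be non-negative")
        if 1.0 + self.u <= 0:
            raise ValueError("strain must satisfy 1 + u > 0")


@dataclass(frozen=True)
class LocalTrajectory:
    times: np.ndarray
    r: np.ndarray
    m: np.ndarray
    u: np.ndarray
    success: bool = True
    message: str = ""

    def final_state(self) -> LocalState:
        return LocalState(r=float(self.r[-1]), m=float(self.m[-1]), u=float(self.u[-1]))


@dataclass(frozen=True)
class LocalRegime:
    label: RegimeLabel
    confidence: Literal["high", "low"] = "high"


def local_rhs(
    state,
    p: ChemistryParams,
    mp: LocalMechanicsParams,
    include_reactions: bool = True,
) -> np.ndarray:
    """Time derivatives (dr/dt, dm/dt, du/dt) of the local model.

    ``state`` is a LocalState or a length-3 array (r, m, u).
    ``include_reactions=False`` zeroes R_r and R_m, leaving pure
    strain-dilution dynamics (useful to verify mass conservation).
    """
    if isinstance(state, LocalState):
        r, m, u = state.r, state.m, state.u
    else:
        r, m, u = float(state[0]), float(state[1]), float(state[2])
    if 1.0 + u <= 0:
        raise FloatingPointError("model breakdown: strain reached u <= -1")
    udot = (-mp.sigma_over_E * m / (mp.m0 + m) - u) / mp.tau_local
    rr = rr_rate(max(r, 0.0), max(m, 0.0), p) if include_reactions else 0.0
    rm = rm_rate(max(r, 0.0), max(m, 0.0), p) if include_reactions else 0.0
    dil = udot / (1.0 + u)
    return np.array([rr - r * dil, rm - m * dil, udot])


def default_initial_state(p: ChemistryParams) -> LocalState:
    """Empty-cortex start: no RhoA, no actomyosin, unstrained.

    Starting below the basal actomyosin level leaves the GAP brake off, so
    switching on a stimulus fires the excitable pulse before the inhibitor
    accumulates; starting at the basal steady state would sit inside the
    excitation threshold and miss it.
    """
    return LocalState(r=0.0, m=0.0, u=0.0)


def simulate_local(
    init: LocalState | None,
    p: ChemistryParams,
    mp: LocalMechanicsParams,
    t_end: float = 2000.0,
    dt_out: float = 1.0,
    include_reactions: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> LocalTrajectory:
    """Integrate the local model with adaptive RK45, sampled every ``dt_out``."""
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if init is None:
        init = default_initial_state(p)
    t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    sol = solve_ivp(
        lambda t, y: local_rhs(y, p, mp, include_reactions),
        (0.0, t_end),
        [init.r, init.m, init.u],
        method="RK45",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    return LocalTrajectory(
        times=sol.t, r=sol.y[0], m=sol.y[1], u=sol.y[2],
        success=sol.success, message=sol.message,
    )


def classify_local(
    traj: LocalTrajectory,
    p: ChemistryParams,
    mp: LocalMechanicsParams,
    transient_frac: float = 0.25,
    peak_threshold: float = 0.10,
) -> LocalRegime:
    """Assign one of {quiescent, excitable, pulsatile, contractile}.

    Decision tree on the actomyosin time series m(t):

    * prominent maxima (prominence >= ``peak_threshold`` of the full range)
      persisting past the transient with non-decaying amplitude -> pulsatile;
    * one or more decaying excursions settling at the low-m branch (when the
      reaction system has three fixed points) -> excitable; settling at the
      high-m branch, or ringing down onto a lone fixed point -> contractile;
    * no excursion at all -> quiescent (low branch / lone point reached
      monotonically) or contractile (monotone arrival on the high branch).
    """
    t, m = traj.times, traj.m
    rng = float(m.max() - m.min())
    scale = max(float(np.abs(m).max()), 1e-12)

    fps = find_fixed_points(p)
    ms = sorted(fp.m for fp in fps)
    three = len(ms) >= 3

    # negligible excursion: never left the neighbourhood of its start/end
    if rng < 0.05 * scale or rng < 1e-6:
        label = "contractile" if (three and m[-1] > ms[1]) else "quiescent"
        return LocalRegime(label=label)

    peaks, props = find_peaks(m, prominence=peak_threshold * rng)
    t_trans = transient_frac * t[-1]
    late = peaks[t[peaks] > t_trans]

    # sustained oscillation: several late peaks whose amplitude does not decay
    if len(late) >= 3:
        heights = m[late] - m[-1]
        sustained = heights[-1] > 0.5 * np.median(heights[: max(len(heights) // 2, 1)])
        # also require genuine late-time variability (not numerical ripple)
        tail = m[t > 0.75 * t[-1]]
        if sustained and (tail.max() - tail.min()) > 0.05 * rng:
            return LocalRegime(label="pulsatile")

    had_excursion = len(peaks) >= 1 and rng > 0.1 * scale
    m_final = float(m[-1])

    if three:
        high = m_final > ms[1]  # above the middle (saddle) branch
        if had_excursion:
            return LocalRegime(label="contractile" if high else "excitable")
        return LocalRegime(label="contractile" if high else "quiescent")
    # single fixed point: damped ringing onto it = contractile,
    # monotone approach = quiescent
    if had_excursion:
        return LocalRegime(label="contractile")
    return LocalRegime(label="quiescent", confidence="low")


def phase_diagram_local(
    S_values: np.ndarray,
    sigma_values: np.ndarray | None = None,
    *,
    a_values: np.ndarray | None = None,
    g_values: np.ndarray | None = None,
    p: ChemistryParams | None = None,
    mp: LocalMechanicsParams | None = None,
    t_end: float = 2000.0,
) -> np.ndarray:
    """Regime labels on a 2D parameter grid.

    Either ``(S_values, sigma_values)`` for the stimulus-contractility plane
    or ``(a_values, g_values)`` for the feedback plane (S fixed from ``p``).
    Returns an object array of labels with shape (len(rows), len(cols))
    where rows index the first axis values.
    """
    p = p or ChemistryParams()
    mp = mp or LocalMechanicsParams()

    if a_values is not None and g_values is not None:
        rows, cols = np.asarray(a_values), np.asarray(g_values)
        def cell(av, gv):
            return p.with_(a=float(av), g=float(gv)), mp
    elif sigma_values is not None:
        rows, cols = np.asarray(S_values), np.asarray(sigma_values)
        def cell(Sv, sv):
            return p.with_(S=float(Sv)), mp.with_(sigma_over_E=float(sv))
    else:
        raise ValueError("provide sigma_values or (a_values and g_values)")
    if rows.size == 0 or cols.size == 0:
        raise ValueError("parameter ranges must be non-empty")

    out = np.empty((rows.size, cols.size), dtype=object)
    for i, rv in enumerate(rows):
        for j, cv in enumerate(cols):
            pc, mc = cell(rv, cv)
            try:
                traj = simulate_local(None, pc, mc, t_end=t_end)
                out[i, j] = classify_local(traj, pc, mc).label
            except Exception as exc:  # pragma: no cover - per-cell robustness
                out[i, j] = f"failed:{exc}"
    return out
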