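"""The reduced 6-variable ODE model of the canonical NF-κB pathway.

State variables (all non-dimensional fractions):

========  ==========================================================
IKKn      neutral IκB kinase
IKKa      active IκB kinase
NFkBn     free nuclear NF-κB (total NF-κB is conserved: bound + nuclear = 1)
A20       A20 protein (inhibitor of IKKa; second negative feedback)
IkBa      free cytoplasmic IκBα protein (primary NF-κB inhibitor)
IkBat     IκBα transcript
========  ==========================================================

TNF stimulation enters as a binary input ``T_R`` ∈ {0, 1} switching the
IKKn → IKKa activation term on and off. The two negative feedback loops are
IκBα (NF-κB-induced, re-sequesters NF-κB) and A20 (NF-κB-induced, inactivates
IKKa). With TNF off the system has the resting steady state
(IKKn, IKKa, NFkBn, A20, IkBa, IkBat) = (1, 0, 0, 0, 0, 0).

Integration is carried out in seconds (the rate constants are s⁻¹) while the
public time coordinate is minutes, matching how stimulation protocols are
specified. TNF switches make the vector field discontinuous in time, so the
integrator is restarted at every switch instead of stepping across it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .parameters import ParameterSet

__all__ = [
    "STATE_NAMES",
    "FixedPointReport",
    "IntegrationError",
    "rhs",
    "jacobian",
    "simulate",
    "resting_steady_state",
    "stimulated_fixed_point",
]

STATE_NAMES = ("IKKn", "IKKa", "NFkBn", "A20", "IkBa", "IkBat")

#: Default integrator tolerances (adaptive stiff solver).
RTOL = 1e-8
ATOL = 1e-10


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails on a protocol segment."""


def _rhs(t, y, p: ParameterSet, tnf: float, a20_on: float):
    """Unchecked right-hand side, suitable as a solver callback."""
    IKKn, IKKa, NFkBn, A20, IkBa, IkBat = y
    release = p.a3 * IKKa * (1.0 - NFkBn) * p.delta / (IkBa + p.delta)
    removal = p.i1a * IkBa * NFkBn / (NFkBn + p.epsilon)
    return np.array([
        p.k_deg - p.k_deg * IKKn - tnf * p.k1 * IKKn,
        tnf * p.k1 * IKKn - (p.k3 + p.k_deg + tnf * p.k2 * A20) * IKKa,
        release - removal,
        a20_on * p.c_deg * NFkBn - p.c_deg * A20,
        p.c4a * IkBat - p.c5a * IkBa - p.a2 * IKKa * IkBa
        - p.a3 * IKKa * (1.0 - NFkBn) * IkBa / (IkBa + p.delta)
        - removal,
        p.c3a * NFkBn - p.c3a * IkBat,
    ])


def _jac(t, y, p: ParameterSet, tnf: float, a20_on: float):
    """Analytic Jacobian of :func:`_rhs` with respect to the state."""
    IKKn, IKKa, NFkBn, A20, IkBa, IkBat = y
    J = np.zeros((6, 6))
    d, e = p.delta, p.epsilon
    fB = d / (IkBa + d)            # release fraction δ/(IκBα+δ)
    gB = IkBa / (IkBa + d)         # consumption fraction IκBα/(IκBα+δ)
    hN = NFkBn / (NFkBn + e)

    J[0, 0] = -p.k_deg - tnf * p.k1

    J[1, 0] = tnf * p.k1
    J[1, 1] = -(p.k3 + p.k_deg + tnf * p.k2 * A20)
    J[1, 3] = -tnf * p.k2 * IKKa

    J[2, 1] = p.a3 * (1.0 - NFkBn) * fB
    J[2, 2] = -p.a3 * IKKa * fB - p.i1a * IkBa * e / (NFkBn + e) ** 2
    J[2, 4] = -p.a3 * IKKa * (1.0 - NFkBn) * d / (IkBa + d) ** 2 - p.i1a * hN

    J[3, 2] = a20_on * p.c_deg
    J[3, 3] = -p.c_deg

    J[4, 1] = -p.a2 * IkBa - p.a3 * (1.0 - NFkBn) * gB
    J[4, 2] = p.a3 * IKKa * gB - p.i1a * IkBa * e / (NFkBn + e) ** 2
    J[4, 4] = (-p.c5a - p.a2 * IKKa
               - p.a3 * IKKa * (1.0 - NFkBn) * d / (IkBa + d) ** 2
               - p.i1a * hN)
    J[4, 5] = p.c4a

    J[5, 2] = p.c3a
    J[5, 5] = -p.c3a
    return J


def rhs(state, params: ParameterSet, tnf, *, a20_on: float = 1.0):
    """Time derivative (per second) of the model state.

    Parameters
    ----------
    state : array-like of 6 floats
        (IKKn, IKKa, NFkBn, A20, IkBa, IkBat); must be non-negative.
    params : ParameterSet
    tnf : {0, 1}
        TNF stimulus indicator T_R.
    a20_on : float
        1 for wild type; 0 zeroes A20 synthesis (A20 knock-out).
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (6,):
        raise ValueError("state must have 6 components")
    if np.any(y < 0):
        raise ValueError(f"state components must be non-negative, got {y}")
    if tnf not in (0, 1):
        raise ValueError(f"tnf must be 0 or 1, got {tnf!r}")
    return _rhs(0.0, y, params, float(tnf), float(a20_on))


def jacobian(state, params: ParameterSet, tnf, *, a20_on: float = 1.0):
    """Analytic Jacobian ∂(dy/dt)/∂y at a state (units s⁻¹)."""
    y = np.asarray(state, dtype=float)
    if tnf not in (0, 1):
        raise ValueError(f"tnf must be 0 or 1, got {tnf!r}")
    return _jac(0.0, y, params, float(tnf), float(a20_on))


def resting_steady_state(params: ParameterSet) -> np.ndarray:
    """The TNF-off steady state (1, 0, 0, 0, 0, 0).

    With T_R = 0 the IKKn equation balances synthesis against degradation at
    IKKn = 1 and every production term of the remaining five variables
    vanishes, so the resting state is exact for any valid parameter set.
    """
    y = np.array([1.0, 0.0, 0.0, 0.0, 0.0, 0.0])
    assert np.allclose(_rhs(0.0, y, params, 0.0, 1.0), 0.0)
    return y


def _genotype_a20(genotype: str) -> float:
    if genotype == "WT":
        return 1.0
    if genotype == "A20KO":
        return 0.0
    raise ValueError(f"unknown genotype {genotype!r}; expected 'WT' or 'A20KO'")


def simulate(
    params: ParameterSet,
    stimulus,
    genotype: str = "WT",
    t_eval_min: Sequence[float] | None = None,
    y0: Sequence[float] | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
    grid_step_min: float = 0.5,
) -> pd.DataFrame:
    """Integrate the model under a piecewise-constant TNF stimulus.

    Parameters
    ----------
    params : ParameterSet
    stimulus : StimulusProfile or sequence of (start_min, end_min, T_R)
        Contiguous TNF segments covering the simulation horizon.
    genotype : {"WT", "A20KO"}
        A20KO zeroes A20 synthesis (the knocked-out protein never appears).
    t_eval_min : sequence of floats, optional
        Output times in minutes; defaults to a dense grid of
        ``grid_step_min``. Times must lie within the stimulus span.
    y0 : 6 floats, optional
        Initial state; defaults to the resting steady state.

    Returns
    -------
    pandas.DataFrame
        Columns ``time_min``, the six state variables, and the derived
        observables ``IkBa_total`` (= IκBα + 1 − NFκBn, the total IκBα
        protein including NF-κB-bound complexes) and ``NFkB_complexed``
        (= 1 − NFκBn).
    """
    segments = getattr(stimulus, "segments", stimulus)
    segments = [(float(a), float(b), int(tr)) for a, b, tr in segments]
    if not segments:
        raise ValueError("stimulus has no segments")
    t0, t_end = segments[0][0], segments[-1][1]

    if t_eval_min is None:
        t_eval_min = np.arange(t0, t_end + 0.5 * grid_step_min, grid_step_min)
    t_eval_min = np.asarray(t_eval_min, dtype=float)
    if t_eval_min.size and (t_eval_min.min() < t0 - 1e-9 or t_eval_min.max() > t_end + 1e-9):
        raise ValueError(
            f"t_eval_min outside stimulus span [{t0}, {t_end}] min"
        )

    a20_on = _genotype_a20(genotype)
    y = (np.asarray(y0, dtype=float) if y0 is not None
         else resting_steady_state(params))
    if np.any(y < 0):
        raise ValueError("initial state must be non-negative")

    out_t: list[np.ndarray] = []
    out_y: list[np.ndarray] = []
    for i, (seg_a, seg_b, tr) in enumerate(segments):
        # record requested times in this segment; the right endpoint belongs
        # to the segment (a measurement at a switch time reads the state at
        # that instant, which is continuous across the switch)
        if i == 0:
            mask = (t_eval_min >= seg_a - 1e-9) & (t_eval_min <= seg_b + 1e-9)
        else:
            mask = (t_eval_min > seg_a + 1e-9) & (t_eval_min <= seg_b + 1e-9)
        t_req = np.clip(t_eval_min[mask], seg_a, seg_b) * 60.0

        sol = solve_ivp(
            _rhs, (seg_a * 60.0, seg_b * 60.0), y,
            method="LSODA", jac=_jac,
            t_eval=np.unique(np.concatenate([t_req, [seg_b * 60.0]])),
            args=(params, float(tr), a20_on),
            rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed on segment {i} "
                f"[{seg_a}, {seg_b}] min (T_R={tr}): {sol.message}"
            )
        y = sol.y[:, -1]
        keep = np.isin(sol.t, t_req) if t_req.size else np.zeros(sol.t.size, bool)
        out_t.append(sol.t[keep] / 60.0)
        out_y.append(sol.y[:, keep])

    t = np.concatenate(out_t)
    Y = np.concatenate(out_y, axis=1)
    # solver tolerances can leave ~1e-12 negative excursions on a
    # positivity-preserving system; clamp them, but not real violations
    tiny = Y > -1e-7
    Y = np.where((Y < 0) & tiny, 0.0, Y)

    df = pd.DataFrame({"time_min": t})
    for k, name in enumerate(STATE_NAMES):
        df[name] = Y[k]
    df["IkBa_total"] = df["IkBa"] + 1.0 - df["NFkBn"]
    df["NFkB_complexed"] = 1.0 - df["NFkBn"]
    return df


@dataclass(frozen=True)
class FixedPointReport:
    """A fixed point of the stimulated (T_R = 1) system and its stability."""

    state: np.ndarray
    stable: bool
    eigenvalue_max_real_part: float  # s⁻¹
    residual_norm: float
    converged: bool

    #: stability margin on the leading eigenvalue's real part (s⁻¹)
    MARGIN = 1e-9


def stimulated_fixed_point(
    params: ParameterSet,
    genotype: str = "WT",
    settle_hours: float = 200.0,
    residual_tol: float = 1e-12,
) -> FixedPointReport:
    """Locate the T_R = 1 fixed point and classify its stability.

    The root search is seeded with the time average of the tail of a long
    tonic-TNF simulation: if the fixed point is stable the tail sits on it,
    and if it is unstable but surrounded by a limit cycle the cycle average
    lies in the interior near the fixed point. Stability comes from the
    eigenvalues of the analytic Jacobian at the root.
    """
    a20_on = _genotype_a20(genotype)
    horizon = settle_hours * 60.0
    traj = simulate(params, [(0.0, horizon, 1)], genotype=genotype,
                    grid_step_min=1.0)
    tail = traj["time_min"] >= 0.75 * horizon
    tt = traj.loc[tail, "time_min"].to_numpy() * 60.0
    yy = traj.loc[tail, list(STATE_NAMES)].to_numpy().T
    y_seed = np.trapezoid(yy, tt, axis=1) / (tt[-1] - tt[0])

    sol = root(
        lambda y: _rhs(0.0, y, params, 1.0, a20_on),
        y_seed,
        jac=lambda y: _jac(0.0, y, params, 1.0, a20_on),
        method="hybr", tol=1e-14,
    )
    res_norm = float(np.max(np.abs(_rhs(0.0, sol.x, params, 1.0, a20_on))))
    converged = bool(sol.success) and res_norm < residual_tol
    eig = np.linalg.eigvals(_jac(0.0, sol.x, params, 1.0, a20_on))
    max_re = float(np.max(eig.real))
    return FixedPointReport(
        state=sol.x,
        stable=max_re < -FixedPointReport.MARGIN,
        eigenvalue_max_real_part=max_re,
        residual_norm=res_norm,
        converged=converged,
    )
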