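"""Windkessel calibration: the pressure/flow mismatch cost, simplex
optimisation of the six free terminal parameters, identification of the
internal lumped elements from branch traces, and the outer iteration
against a pluggable high-fidelity surrogate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .inflow import FourierWaveform, SampledWaveform
from .lumped import (
    InternalElements,
    NetworkSolution,
    WindkesselSet,
    simulate_network,
)

__all__ = [
    "CalibrationRefs",
    "CostBreakdown",
    "CalibrationResult",
    "cost_phi",
    "optimize_windkessel",
    "identify_internal_elements",
    "calibrate",
    "make_zero_d_model",
]


@dataclass(frozen=True)
class CalibrationRefs:
    """Reference targets: systolic/diastolic inlet pressure and the venous
    outflow waveform over one period."""

    P_RS: float
    P_RD: float
    Q_R: SampledWaveform

    def __post_init__(self) -> None:
        if not (self.P_RS > self.P_RD > 0):
            raise ValueError("require P_RS > P_RD > 0")


@dataclass(frozen=True)
class CostBreakdown:
    term_sys: float
    term_dia: float
    term_flow: float

    @property
    def total(self) -> float:
        return self.term_sys + self.term_dia + self.term_flow


@dataclass
class CalibrationResult:
    windkessel: WindkesselSet
    internal: InternalElements
    history: list  # (phi, free-parameter vector) per outer iteration
    converged: bool


def _resample_onto(w: SampledWaveform, times: np.ndarray, period: float) -> np.ndarray:
    """Periodic linear interpolation of ``w`` onto ``times``."""
    t = np.mod(w.times - w.times[0], period)
    order = np.argsort(t)
    tp = t[order]
    vp = w.values[order]
    tp = np.concatenate([tp, [tp[0] + period]])
    vp = np.concatenate([vp, [vp[0]]])
    tq = np.mod(times - w.times[0], period)
    return np.interp(tq, tp, vp)


def cost_phi(
    P_BAI: SampledWaveform, Q_VO: SampledWaveform, refs: CalibrationRefs
) -> CostBreakdown:
    """Squared relative mismatch of systolic pressure, diastolic pressure,
    and the venous outflow waveform (L1, trapezoidal) over one period.

    Extrema of P_BAI are taken over the discrete samples.  If Q_VO and Q_R
    are sampled on different grids, Q_VO is periodically interpolated onto
    the reference grid.
    """
    p = P_BAI.values
    term_sys = ((p.max() - refs.P_RS) / refs.P_RS) ** 2
    term_dia = ((p.min() - refs.P_RD) / refs.P_RD) ** 2

    qr = refs.Q_R
    denom = np.trapezoid(np.abs(qr.values), qr.times)
    if denom == 0:
        raise ValueError("reference flow waveform integrates to zero")
    period = qr.span
    if Q_VO.times.shape == qr.times.shape and np.allclose(Q_VO.times, qr.times):
        qv = Q_VO.values
    else:
        qv = _resample_onto(Q_VO, qr.times, period if period > 0 else Q_VO.span)
    num = np.trapezoid(np.abs(qv - qr.values), qr.times)
    return CostBreakdown(term_sys, term_dia, (num / denom) ** 2)


def make_zero_d_model(
    inflow: FourierWaveform,
    internal: InternalElements,
    dt: float = 1e-3,
    max_cycles: int = 30,
    tol: float = 5e-3,
) -> Callable[[WindkesselSet], tuple[SampledWaveform, SampledWaveform]]:
    """Build the 0D evaluator used inside the optimisation loop.

    Returns a callable mapping a WindkesselSet to the (P_BAI, Q_VO) traces
    of a periodically converged network run, warm-started at the DC
    operating point.
    """

    def model(wk: WindkesselSet) -> tuple[SampledWaveform, SampledWaveform]:
        sol = simulate_network(
            inflow, wk, internal, dt=dt, max_cycles=max_cycles, tol=tol, P_init="dc"
        )
        return sol.pressure("P_BAI"), sol.flow("Q_VO")

    model.internal = internal  # type: ignore[attr-defined]
    return model


def _phi_of(model, refs: CalibrationRefs, wk: WindkesselSet) -> float:
    try:
        p_bai, q_vo = model(wk)
        phi = cost_phi(p_bai, q_vo, refs).total
    except (ValueError, FloatingPointError) as exc:  # pragma: no cover
        raise RuntimeError(f"model evaluation failed at {wk}: {exc}") from exc
    if not math.isfinite(phi):
        return 1e12
    return phi


def optimize_windkessel(
    model: Callable[[WindkesselSet], tuple[SampledWaveform, SampledWaveform]],
    refs: CalibrationRefs,
    init: WindkesselSet,
    n_restarts: int = 2,
    jitter: float = 0.15,
    seed: int = 0,
    maxiter: int = 1200,
    phi_stop: float = 1e-16,
) -> WindkesselSet:
    """Minimise the calibration cost over the 6 free terminal parameters.

    Nelder-Mead simplex on log-transformed parameters (positivity is
    structural, no constraints needed); the RAO=UAO tie is enforced by the
    parameterisation.  ``n_restarts`` seeded multiplicative jitters of the
    initial point guard against simplex collapse; the best of all runs and
    the initial point itself is returned, so the result never degrades the
    initial cost.
    """
    x0 = np.log(init.free_parameters())
    rng = np.random.default_rng(seed)

    def objective(x: np.ndarray) -> float:
        if np.any(np.abs(x) > 50):  # guard pathological excursions
            return 1e12
        return _phi_of(model, refs, WindkesselSet.from_free_parameters(np.exp(x)))

    best_x = x0
    best_phi = objective(x0)
    starts = [x0] + [
        x0 + rng.normal(scale=jitter, size=x0.size) for _ in range(n_restarts)
    ]
    for xs in starts:
        if best_phi < phi_stop:  # cost is numerically zero; stop searching
            break
        res = minimize(
            objective,
            xs,
            method="Nelder-Mead",
            options={
                "maxiter": maxiter,
                "xatol": 1e-6,
                "fatol": 1e-12,
                "adaptive": True,
            },
        )
        if res.fun < best_phi:
            best_phi = float(res.fun)
            best_x = res.x
        if best_phi < phi_stop:
            break
        # polish: restart the simplex at the current best
        res2 = minimize(
            objective,
            best_x,
            method="Nelder-Mead",
            options={"maxiter": maxiter // 2, "xatol": 1e-8, "fatol": 1e-14,
                     "adaptive": True},
        )
        if res2.fun < best_phi:
            best_phi = float(res2.fun)
            best_x = res2.x
    return WindkesselSet.from_free_parameters(np.exp(best_x))


def identify_internal_elements(
    branches: Mapping[str, tuple[SampledWaveform, SampledWaveform]],
) -> tuple[InternalElements, dict]:
    """Least-squares (R, L) per branch from pressure-drop/flow traces.

    Fits dP(t) = R*Q|Q| + L*dQ/dt with dQ/dt by central differences,
    clipping estimates at zero.  ``branches`` maps '1A', '2A', '1V' to
    (dP, Q) waveform pairs.  Returns the elements and per-branch RMS fit
    residuals.

    Raises if a branch regressor is rank-deficient (e.g. steady flow, which
    leaves L unidentifiable).
    """
    est: dict[str, tuple[float, float]] = {}
    residuals: dict[str, float] = {}
    for name, (dp, q) in branches.items():
        if len(q) < 100:
            raise ValueError(f"branch {name}: need >= 100 samples")
        t, qv = q.times, q.values
        dqdt = np.gradient(qv, t)
        A = np.column_stack([qv * np.abs(qv), dqdt])
        # scale columns for a meaningful conditioning check
        norms = np.linalg.norm(A, axis=0)
        if np.any(norms < 1e-14 * max(norms.max(), 1.0)):
            raise ValueError(
                f"branch {name}: rank-deficient regressor (constant flow?)"
            )
        sol, _, rank, _ = np.linalg.lstsq(A, dp.values, rcond=None)
        if rank < 2:
            raise ValueError(f"branch {name}: rank-deficient regressor")
        r, L = max(float(sol[0]), 0.0), max(float(sol[1]), 0.0)
        est[name] = (r, L)
        residuals[name] = float(
            np.sqrt(np.mean((dp.values - A @ [r, L]) ** 2))
        )
    try:
        elements = InternalElements(
            L1A=est["1A"][1], L2A=est["2A"][1], L1V=est["1V"][1],
            R1A=est["1A"][0], R2A=est["2A"][0], R1V=est["1V"][0],
        )
    except KeyError as exc:
        raise ValueError(f"missing branch trace {exc}") from exc
    return elements, residuals


def branch_traces(sol: NetworkSolution) -> dict:
    """Extract the (dP, Q) pairs that identify_internal_elements consumes."""
    t = sol.times
    return {
        "1A": (
            SampledWaveform(t, sol.branch_drops["1A"]),
            SampledWaveform(t, sol.branch_flows["Q_BAI"]),
        ),
        "2A": (
            SampledWaveform(t, sol.branch_drops["2A"]),
            SampledWaveform(t, sol.branch_flows["Q_RAO"] + sol.branch_flows["Q_UAO"]),
        ),
        "1V": (
            SampledWaveform(t, sol.branch_drops["1V"]),
            SampledWaveform(t, sol.branch_flows["Q_VO"]),
        ),
    }


def calibrate(
    surrogate: Callable[[WindkesselSet], NetworkSolution],
    refs: CalibrationRefs,
    init_internal: InternalElements,
    init_wk: WindkesselSet,
    inflow: FourierWaveform,
    outer_tol: float = 1e-3,
    max_outer: int = 10,
    dt: float = 1e-3,
    seed: int = 0,
) -> CalibrationResult:
    """Alternate 0D optimisation / surrogate identification to convergence.

    Each outer iteration (i) optimises the Windkessel parameters on the 0D
    model holding the internal elements fixed, (ii) runs the surrogate with
    those parameters, and (iii) re-identifies the internal elements from
    the surrogate's branch traces.  Stops when the maximum relative change
    of the free Windkessel parameters drops below ``outer_tol``.
    """
    internal = init_internal
    wk = init_wk
    history: list[tuple[float, np.ndarray]] = []
    converged = False
    prev = wk.free_parameters()
    for _ in range(max_outer):
        model = make_zero_d_model(inflow, internal, dt=dt)
        wk = optimize_windkessel(model, refs, wk, seed=seed)
        phi = _phi_of(model, refs, wk)
        params = wk.free_parameters()
        history.append((phi, params.copy()))
        change = float(np.max(np.abs(params - prev) / np.abs(prev)))
        prev = params
        if change < outer_tol:
            converged = True
            break
        sol = surrogate(wk)
        internal, _ = identify_internal_elements(branch_traces(sol))
    return CalibrationResult(
        windkessel=wk, internal=internal, history=history, converged=converged
    )
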