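"""RCR Windkessel terminals and the three-outlet 0D network.

The network mirrors the lumped representation of an arterio-venous fistula:
an inlet (BAI) feeds a proximal arterial branch (inductance ``L1A``,
quadratic resistance ``R1A``) to the anastomotic junction, from which a
distal arterial branch (``L2A``, ``R2A``) leads to the merged RAO/UAO
Windkessel terminals (assumed identical, hence carried in parallel) and a
venous branch (``L1V``, ``R1V``) leads to the VO Windkessel terminal.

Units in this module are clinical throughout: pressures in mmHg, flows in
mL/s, resistances in mmHg mL^-1 s, compliances in mL/mmHg, inductances in
mmHg mL^-1 s^2, quadratic resistance coefficients in mmHg mL^-2 s^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numba import njit

from .inflow import FourierWaveform, SampledWaveform

__all__ = [
    "WindkesselTerminal",
    "WindkesselSet",
    "InternalElements",
    "NetworkSolution",
    "AnalysisWindow",
    "RCRResponse",
    "rcr_pressure_rate",
    "simulate_network",
    "dc_flow_split",
    "window_flow_split",
    "WINDOW_WT",
    "WINDOW_WS",
    "WINDOW_WD",
]


@dataclass(frozen=True)
class WindkesselTerminal:
    """RCR outlet: proximal resistance R1, distal resistance R2, compliance C."""

    R1: float
    R2: float
    C: float

    def __post_init__(self) -> None:
        if self.R1 <= 0 or self.R2 <= 0 or self.C < 0:
            raise ValueError("R1, R2 must be positive and C nonnegative")

    @property
    def series_resistance(self) -> float:
        return self.R1 + self.R2


@dataclass(frozen=True)
class WindkesselSet:
    """The three outlet terminals; RAO and UAO may be tied component-wise."""

    rao: WindkesselTerminal
    uao: WindkesselTerminal
    vo: WindkesselTerminal
    tie_rao_uao: bool = True

    def __post_init__(self) -> None:
        if self.tie_rao_uao and self.rao != self.uao:
            raise ValueError("tie_rao_uao set but RAO and UAO parameters differ")

    @property
    def arterial_parallel_resistance(self) -> float:
        """Parallel combination of the two arterial series resistances."""
        ra = self.rao.series_resistance
        rb = self.uao.series_resistance
        return ra * rb / (ra + rb)

    def free_parameters(self) -> np.ndarray:
        """The 6 free parameters under the RAO=UAO tie."""
        return np.array(
            [self.uao.R1, self.uao.R2, self.uao.C, self.vo.R1, self.vo.R2, self.vo.C]
        )

    @classmethod
    def from_free_parameters(cls, p) -> "WindkesselSet":
        ao = WindkesselTerminal(R1=p[0], R2=p[1], C=p[2])
        vo = WindkesselTerminal(R1=p[3], R2=p[4], C=p[5])
        return cls(rao=ao, uao=ao, vo=vo, tie_rao_uao=True)


@dataclass(frozen=True)
class InternalElements:
    """Lumped elements standing in for the 3D vascular domain."""

    L1A: float = 0.0
    L2A: float = 0.0
    L1V: float = 0.0
    R1A: float = 0.0
    R2A: float = 0.0
    R1V: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.L1A, self.L2A, self.L1V, self.R1A, self.R2A, self.R1V)
        if any(v < 0 for v in vals):
            raise ValueError("internal element values must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.L1A, self.L2A, self.L1V, self.R1A, self.R2A, self.R1V]
        )


@dataclass(frozen=True)
class AnalysisWindow:
    """Named time window for the unsteadiness / flow-split analyses."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must exceed start")

    @property
    def length(self) -> float:
        return self.end - self.start


#: Canonical windows: full pulse period, systole, part of diastole.
WINDOW_WT = AnalysisWindow("WT", 1.0, 2.0)
WINDOW_WS = AnalysisWindow("WS", 1.1, 1.4)
WINDOW_WD = AnalysisWindow("WD", 1.4, 1.7)


@dataclass(frozen=True)
class RCRResponse:
    """Tagged RCR evaluation: ``rate`` carries dP/dt; ``algebraic`` carries P
    itself (the C -> 0 limit where the terminal is purely resistive)."""

    kind: Literal["rate", "algebraic"]
    value: float


def rcr_pressure_rate(
    P: float, Q: float, dQdt: float, term: WindkesselTerminal
) -> RCRResponse:
    """Explicit pressure dynamics of an RCR terminal.

    dP/dt = (Q*(R1+R2) - P)/(R2*C) + R1*dQ/dt.  With C = 0 the terminal is
    algebraic, P = Q*(R1+R2), returned as a distinct mode.
    """
    if term.C == 0.0:
        return RCRResponse("algebraic", Q * term.series_resistance)
    rate = (Q * term.series_resistance - P) / (term.R2 * term.C) + term.R1 * dQdt
    return RCRResponse("rate", rate)


@njit(cache=True)
def _simulate_cycle(
    qb, dqb,  # inlet flow and its time derivative at half-step resolution
    dt,
    y0,  # state [Q_V, P_art, P_vo]
    r1a, r2a, ca,  # per-outlet arterial terminal (each carries Q2A/2)
    r1v, r2v, cv,
    L1A, L2A, L1V, R1A, R2A, R1V,
    out,  # (7, n+1): QV, Q2A, P_art, P_vo, P_J, P_BAI, t-index filled outside
):
    n = (qb.shape[0] - 1) // 2
    Ltot = L2A + L1V
    qv = y0[0]
    pa = y0[1]
    pv = y0[2]
    for i in range(n + 1):
        # record state and derived pressures at sample i
        QB = qb[2 * i]
        dQB = dqb[2 * i]
        q2a = QB - qv
        if Ltot > 0.0:
            dqv = (R2A * q2a * abs(q2a) - R1V * qv * abs(qv) + L2A * dQB + pa - pv) / Ltot
        else:
            dqv = 0.0
        dq2a = dQB - dqv
        pj = pa + R2A * q2a * abs(q2a) + L2A * dq2a
        pb = pj + R1A * QB * abs(QB) + L1A * dQB
        out[0, i] = qv
        out[1, i] = q2a
        out[2, i] = pa
        out[3, i] = pv
        out[4, i] = pj
        out[5, i] = pb
        if i == n:
            break
        # RK4 step from sample i to i+1
        k1 = _rhs(qb[2 * i], dqb[2 * i], qv, pa, pv,
                  r1a, r2a, ca, r1v, r2v, cv, L2A, L1V, R2A, R1V)
        k2 = _rhs(qb[2 * i + 1], dqb[2 * i + 1],
                  qv + 0.5 * dt * k1[0], pa + 0.5 * dt * k1[1], pv + 0.5 * dt * k1[2],
                  r1a, r2a, ca, r1v, r2v, cv, L2A, L1V, R2A, R1V)
        k3 = _rhs(qb[2 * i + 1], dqb[2 * i + 1],
                  qv + 0.5 * dt * k2[0], pa + 0.5 * dt * k2[1], pv + 0.5 * dt * k2[2],
                  r1a, r2a, ca, r1v, r2v, cv, L2A, L1V, R2A, R1V)
        k4 = _rhs(qb[2 * i + 2], dqb[2 * i + 2],
                  qv + dt * k3[0], pa + dt * k3[1], pv + dt * k3[2],
                  r1a, r2a, ca, r1v, r2v, cv, L2A, L1V, R2A, R1V)
        qv += dt / 6.0 * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0])
        pa += dt / 6.0 * (k1[1] + 2.0 * k2[1] + 2.0 * k3[1] + k4[1])
        pv += dt / 6.0 * (k1[2] + 2.0 * k2[2] + 2.0 * k3[2] + k4[2])
    y0[0] = qv
    y0[1] = pa
    y0[2] = pv


@njit(cache=True, inline="always")
def _rhs(QB, dQB, qv, pa, pv,
         r1a, r2a, ca, r1v, r2v, cv, L2A, L1V, R2A, R1V):
    q2a = QB - qv
    Ltot = L2A + L1V
    if Ltot > 0.0:
        dqv = (R2A * q2a * abs(q2a) - R1V * qv * abs(qv) + L2A * dQB + pa - pv) / Ltot
    else:
        dqv = 0.0
    dq2a = dQB - dqv
    # merged arterial terminal: two identical RCRs in parallel, each at Q2A/2
    if ca > 0.0:
        dpa = (0.5 * q2a * (r1a + r2a) - pa) / (r2a * ca) + 0.5 * r1a * dq2a
    else:
        dpa = 0.0
    if cv > 0.0:
        dpv = (qv * (r1v + r2v) - pv) / (r2v * cv) + r1v * dqv
    else:
        dpv = 0.0
    return dqv, dpa, dpv


@dataclass
class NetworkSolution:
    """Final-cycle traces of the 0D network.

    ``times`` are relabelled so the stored cycle spans ``[period, 2*period]``
    (the cycle exported for analysis), matching the canonical WT/WS/WD
    windows regardless of how many cycles the integrator actually ran.
    """

    times: np.ndarray
    node_pressures: dict
    branch_flows: dict
    branch_drops: dict
    cycles_run: int
    periodicity_residual: float
    converged: bool

    def pressure(self, name: str) -> SampledWaveform:
        return SampledWaveform(self.times, self.node_pressures[name], units="mmHg")

    def flow(self, name: str) -> SampledWaveform:
        return SampledWaveform(self.times, self.branch_flows[name], units="mL/s")


def _dc_state(inflow: FourierWaveform, wk: WindkesselSet) -> np.ndarray:
    """Periodic-orbit warm start: mean flows through the DC resistive split."""
    qbar = inflow.mean_flow
    frac = dc_flow_split(wk)
    qv = frac * qbar
    q2a = (1.0 - frac) * qbar
    pa = 0.5 * q2a * wk.uao.series_resistance
    pv = qv * wk.vo.series_resistance
    return np.array([qv, pa, pv])


def simulate_network(
    inflow: FourierWaveform,
    wk: WindkesselSet,
    internal: InternalElements,
    dt: float = 1e-4,
    max_cycles: int = 50,
    tol: float = 5e-3,
    P_init: float | str = 78.0,
) -> NetworkSolution:
    """Integrate the 0D network to periodic steady state with explicit RK4.

    Parameters
    ----------
    inflow:
        Inlet flow waveform in mL/s.
    dt:
        Time step, must divide the period.
    tol:
        Cycle-to-cycle RMS change of P_BAI, normalised by its peak-to-peak
        range, below which the run is declared periodic.
    P_init:
        Uniform initial pressure in mmHg, or the string ``"dc"`` to warm
        start at the DC (cycle-averaged) operating point — the analogue of
        initialising a 3D solver with its steady solution.
    """
    n = round(inflow.period / dt)
    if abs(n * dt - inflow.period) > 1e-9 * inflow.period or n < 2:
        raise ValueError("dt must divide the waveform period")
    if max_cycles < 2:
        raise ValueError("max_cycles must be >= 2")
    if internal.L2A + internal.L1V <= 0.0:
        raise ValueError(
            "simulate_network requires L2A + L1V > 0 (the junction flow "
            "split is integrated as an inductor state)"
        )
    if wk.uao.C <= 0.0 or wk.vo.C <= 0.0:
        raise ValueError("network terminals must have C > 0")

    # inlet flow at half-step resolution over one cycle (RK4 stage times)
    th = np.arange(2 * n + 1) * (dt / 2.0)
    qb = inflow.evaluate(th)
    dqb = inflow.derivative(th)

    if isinstance(P_init, str):
        if P_init != "dc":
            raise ValueError("P_init must be a number or 'dc'")
        y = _dc_state(inflow, wk)
    else:
        p0 = float(P_init)
        qv0 = dc_flow_split(wk) * inflow.evaluate(0.0)
        y = np.array([qv0, p0, p0])

    out = np.empty((6, n + 1))
    prev_pb = None
    residual = math.inf
    cycles = 0
    converged = False
    for cycle in range(max_cycles):
        _simulate_cycle(
            qb, dqb, dt, y,
            wk.uao.R1, wk.uao.R2, wk.uao.C,
            wk.vo.R1, wk.vo.R2, wk.vo.C,
            internal.L1A, internal.L2A, internal.L1V,
            internal.R1A, internal.R2A, internal.R1V,
            out,
        )
        cycles += 1
        pb = out[5].copy()
        if prev_pb is not None:
            scale = max(pb.max() - pb.min(), 1e-300)
            residual = float(np.sqrt(np.mean((pb - prev_pb) ** 2)) / scale)
            if residual < tol:
                converged = True
                break
        prev_pb = pb

    times = inflow.period + np.arange(n + 1) * dt
    qv = out[0]
    q2a = out[1]
    qbai = qb[::2]
    sol = NetworkSolution(
        times=times,
        node_pressures={
            "P_BAI": out[5].copy(),
            "P_J": out[4].copy(),
            "P_RAO": out[2].copy(),
            "P_UAO": out[2].copy(),
            "P_VO": out[3].copy(),
        },
        branch_flows={
            "Q_BAI": qbai.copy(),
            "Q_VO": qv.copy(),
            "Q_RAO": 0.5 * q2a,
            "Q_UAO": 0.5 * q2a,
        },
        branch_drops={
            "1A": out[5] - out[4],        # BAI -> junction
            "2A": out[4] - out[2],        # junction -> arterial terminals
            "1V": out[4] - out[3],        # junction -> venous terminal
        },
        cycles_run=cycles,
        periodicity_residual=residual,
        converged=converged,
    )
    return sol


def dc_flow_split(wk: WindkesselSet) -> float:
    """Venous fraction of the cycle-averaged flow.

    In periodic steady state the cycle-averaged capacitor currents vanish,
    so the mean flow divides over the terminal series resistances:
    venous fraction = R_art_par / (R_art_par + R1_VO + R2_VO).
    """
    r_art = wk.arterial_parallel_resistance
    r_ven = wk.vo.series_resistance
    return r_art / (r_art + r_ven)


def _window_integral(times: np.ndarray, values: np.ndarray, t0: float, t1: float) -> float:
    """Trapezoidal integral over [t0, t1] with linear endpoint interpolation.

    Splitting an interval at any interior point and summing the pieces
    reproduces the whole-interval integral exactly.
    """
    if t0 < times[0] - 1e-9 or t1 > times[-1] + 1e-9:
        raise ValueError("window outside the stored trace")
    t0 = max(t0, float(times[0]))
    t1 = min(t1, float(times[-1]))
    i0, i1 = np.searchsorted(times, [t0, t1])
    v0 = np.interp(t0, times, values)
    v1 = np.interp(t1, times, values)
    ts = np.concatenate([[t0], times[i0:i1], [t1]])
    vs = np.concatenate([[v0], values[i0:i1], [v1]])
    keep = np.concatenate([[True], np.diff(ts) > 0])
    return float(np.trapezoid(vs[keep], ts[keep]))


def window_flow_split(
    sol: NetworkSolution, window: AnalysisWindow
) -> tuple[float, float]:
    """Venous:arterial percentage split of outflow over a window."""
    t = sol.times
    qv = _window_integral(t, sol.branch_flows["Q_VO"], window.start, window.end)
    qa = _window_integral(
        t,
        sol.branch_flows["Q_RAO"] + sol.branch_flows["Q_UAO"],
        window.start,
        window.end,
    )
    total = qv + qa
    if total == 0:
        raise ValueError("zero net outflow in window")
    return 100.0 * qv / total, 100.0 * qa / total
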