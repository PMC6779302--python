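"""Cardiac-cycle controller: phases, pressure schedules, valves, afterload.

One cycle walks through DIASTOLE -> IVC -> EJECTION -> IVR exactly once.
Diastolic filling is driven by an atrial-side ramp to EDP plus the endocardial
suction surrogate P_endo; iso-volumetric contraction ends when the probed LV
pressure exceeds the aortic pressure (initially the diastolic cuff value,
85 mmHg) and the binary aortic valve opens; ejection feeds the flow rate into a
three-element Windkessel which returns the afterload pressure; ejection ends
when the ventricle can no longer pump forward flow, and iso-volumetric
relaxation holds both tract planes closed until the cycle ends.

All pressures in mmHg, flows in mL/s, times in s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

from heartfsi.params import PhaseBCParams, WindkesselParams


class Phase(Enum):
    DIASTOLE = "DIASTOLE"
    IVC = "IVC"
    EJECTION = "EJECTION"
    IVR = "IVR"


_ORDER = [Phase.DIASTOLE, Phase.IVC, Phase.EJECTION, Phase.IVR]


class ValveState(Enum):
    OPEN = "OPEN"
    CLOSED = "CLOSED"


class PhaseOrderError(RuntimeError):
    """An out-of-order phase transition was attempted."""


@dataclass
class WindkesselState:
    Pp: float  # stored peripheral (compliance) pressure, mmHg
    Pao: float  # aortic pressure seen by the outflow tract, mmHg


@dataclass
class CirculationState:
    phase: Phase = Phase.DIASTOLE
    aortic_valve: ValveState = ValveState.CLOSED
    mitral_inflow_allowed: bool = True
    wk: WindkesselState = field(default_factory=lambda: WindkesselState(Pp=85.0, Pao=85.0))
    P_inflow: float = 0.0
    P_endo: float = 0.0
    transition_times: dict = field(default_factory=dict)


def boundary_pressures(t: float, p: PhaseBCParams, phase: Phase) -> tuple[float, float]:
    """(P_inflow, P_endo) in mmHg at time t.

    P_inflow ramps 0 -> EDP over diastole and is held at EDP through IVC;
    P_endo ramps 0 -> P_endo_max over [0, t_endo_peak], back to 0 at
    end-diastole, and stays 0 afterwards.  Both are continuous and piecewise
    linear in t.
    """
    if t < 0.0 or t > p.t_cycle:
        raise ValueError(f"t = {t} outside the cycle [0, {p.t_cycle}]")
    if phase == Phase.DIASTOLE:
        P_in = p.EDP * min(t / p.t_diastole, 1.0)
    elif phase == Phase.IVC:
        P_in = p.EDP
    else:
        P_in = 0.0
    if t <= p.t_endo_peak:
        P_endo = p.P_endo_max * t / p.t_endo_peak
    elif t <= p.t_diastole:
        P_endo = p.P_endo_max * (p.t_diastole - t) / (p.t_diastole - p.t_endo_peak)
    else:
        P_endo = 0.0
    return P_in, P_endo


def windkessel_step(
    Q: float, state: WindkesselState, p: WindkesselParams, dt: float
) -> WindkesselState:
    """Advance Ca dPp/dt = Q - Pp/Rp and return Pao = Q Rc + Pp.

    Exact exponential update for Q held constant over the step, so the
    discrete solution matches the closed-form decay/steady state to machine
    precision for constant inputs.
    """
    tau = p.Rp * p.Ca
    decay = math.exp(-dt / tau)
    Pp = state.Pp * decay + Q * p.Rp * (1.0 - decay)
    return WindkesselState(Pp=Pp, Pao=Q * p.Rc + Pp)


def aortic_valve_update(P_LV: float, Pao: float, prev: ValveState) -> ValveState:
    """Binary aortic valve; ties keep the previous state to avoid chattering."""
    if P_LV > Pao:
        return ValveState.OPEN
    if P_LV < Pao:
        return ValveState.CLOSED
    return prev


def chordae_stiffness(phase: Phase, C_diastole: float = 540.0, C_systole: float = 9000.0) -> float:
    """Chordal modulus (kPa): stiff while the valve is closed under load."""
    if phase in (Phase.IVC, Phase.EJECTION):
        return C_systole
    return C_diastole


def phase_update(
    state: CirculationState,
    t: float,
    P_LV: float,
    Q_out: float,
    p: PhaseBCParams,
) -> CirculationState:
    """One controller update given probed LV pressure and AV-plane flow.

    Transitions: DIASTOLE->IVC at t = t_diastole; IVC->EJECTION when the
    aortic valve opens (P_LV exceeding Pao); EJECTION->IVR once forward flow
    stops (Q_out <= 0); IVR persists to the end of the cycle.
    """
    phase = state.phase
    valve = state.aortic_valve
    wk = state.wk
    times = dict(state.transition_times)

    if phase == Phase.DIASTOLE and t >= p.t_diastole:
        phase = Phase.IVC
        times["IVC"] = t
    elif phase == Phase.IVC:
        valve = aortic_valve_update(P_LV, wk.Pao, valve)
        if valve == ValveState.OPEN:
            phase = Phase.EJECTION
            times["EJECTION"] = t
            # record the opening condition for diagnostics/verification
            times["EJECTION_P_LV"] = P_LV
            times["EJECTION_Pao"] = wk.Pao
    elif phase == Phase.EJECTION and Q_out <= 0.0:
        phase = Phase.IVR
        valve = ValveState.CLOSED
        times["IVR"] = t

    if _ORDER.index(phase) < _ORDER.index(state.phase):
        raise PhaseOrderError(f"{state.phase} -> {phase} at t = {t}")

    P_in, P_endo = boundary_pressures(min(t, p.t_cycle), p, phase)
    return replace(
        state,
        phase=phase,
        aortic_valve=valve if phase == Phase.EJECTION else ValveState.CLOSED,
        mitral_inflow_allowed=phase in (Phase.DIASTOLE, Phase.IVC),
        wk=wk,
        P_inflow=P_in,
        P_endo=P_endo,
        transition_times=times,
    )
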