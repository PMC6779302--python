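"""Pump-function metrics and field diagnostics.

Flow rates across the tract planes, cavity volume by the divergence theorem on
the compartment boundary polyline, whole-cycle pump metrics (stroke and
regurgitant volumes, ejection fraction, phase durations) and per-element fibre
strain.  2-D areas and line fluxes are scaled by the configured out-of-plane
depth so volumes are reported in mL and flows in mL/s; the depth is a
documented reporting convention, not a physical claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from heartfsi.ibfe import LagrangianMesh, interpolate_velocity


class PlaneOutsideGridError(ValueError):
    pass


class IncompleteCycleError(ValueError):
    pass


def flow_rate_across_plane(
    u: np.ndarray,
    plane,
    L: float,
    depth: float,
    n_quad: int = 24,
) -> float:
    """Volumetric flow rate (mL/s) across a horizontal tract plane.

    Midpoint quadrature of the kernel-interpolated normal (vertical) velocity
    along the plane segment; positive means flow out of the LV compartment
    (upward through either tract plane).
    """
    if not (0.0 <= plane.x_left < plane.x_right <= L) or not (0.0 <= plane.y <= L):
        raise PlaneOutsideGridError("tract plane outside the fluid box")
    pts = plane.quad_points(n_quad)
    U = interpolate_velocity(u, pts, L)
    ds = plane.width / n_quad
    return float(np.sum(U[:, 1]) * ds * depth)


def polygon_area(points: np.ndarray) -> float:
    """Shoelace area of a closed polygon (positive for CCW orientation)."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def cavity_volume(mesh: LagrangianMesh, loop: np.ndarray, depth: float) -> float:
    """Enclosed compartment volume (mL) from the boundary polyline.

    ``loop`` is the ordered (counter-clockwise) node-id cycle tracing the
    endocardial surface, tract inner faces and tract planes.
    """
    area = polygon_area(mesh.chi[loop])
    if area <= 0.0:
        raise ValueError("cavity loop is not a positively oriented closed contour")
    return area * depth


@dataclass
class PumpMetrics:
    """Whole-cycle pump-function summary (volumes mL, durations ms, flows mL/s)."""

    edv: float
    esv: float
    stroke_volume: float  # net AV-plane ejection
    total_ejected: float  # incl. MV closure regurgitation
    filling_volume: float
    regurgitant_volume: float
    regurgitant_fraction: float  # % of filling volume
    ejection_fraction: float  # % of EDV, using total ejected volume
    ivc_duration: float
    ejection_duration: float
    peak_mv_flow: float  # peak diastolic inflow magnitude
    peak_av_flow: float  # peak systolic outflow

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def _phase_mask(series: pd.DataFrame, phases: list[str]) -> pd.Series:
    return series["phase"].isin(phases)


def _integrate(t: np.ndarray, q: np.ndarray) -> float:
    if len(t) < 2:
        return 0.0
    return float(np.trapezoid(q, t))


def pump_metrics(result) -> PumpMetrics:
    """Compute pump metrics from a full-cycle SimulationResult.

    Sign convention: positive plane flow leaves the LV compartment.  The
    ejection fraction uses the total ejected volume (forward aortic flow plus
    mitral closure regurgitation) over the end-diastolic volume.
    """
    s = result.series
    tt = result.transition_times
    for key in ("IVC", "EJECTION", "IVR"):
        if key not in tt:
            raise IncompleteCycleError(f"cycle never reached {key}")

    t = s["t"].to_numpy()
    q_mv = s["Q_mv"].to_numpy()
    q_av = s["Q_av"].to_numpy()

    dia = _phase_mask(s, ["DIASTOLE"]).to_numpy()
    ivc = _phase_mask(s, ["IVC"]).to_numpy()
    ej = _phase_mask(s, ["EJECTION"]).to_numpy()

    filling = -_integrate(t[dia | ivc], np.minimum(q_mv[dia | ivc], 0.0))
    regurg = _integrate(t[ivc | ej], np.maximum(q_mv[ivc | ej], 0.0))
    stroke = _integrate(t[ej], q_av[ej])
    forward = _integrate(t[ej], np.maximum(q_av[ej], 0.0))
    total_ejected = forward + regurg

    v = s["V_cav"].to_numpy()
    edv = float(v[np.searchsorted(t, tt["IVC"])])
    esv = float(v[np.searchsorted(t, tt["IVR"]) - 1])

    return PumpMetrics(
        edv=edv,
        esv=esv,
        stroke_volume=stroke,
        total_ejected=total_ejected,
        filling_volume=filling,
        regurgitant_volume=regurg,
        regurgitant_fraction=100.0 * regurg / filling if filling > 0 else 0.0,
        ejection_fraction=100.0 * total_ejected / edv if edv > 0 else 0.0,
        ivc_duration=1e3 * (tt["EJECTION"] - tt["IVC"]),
        ejection_duration=1e3 * (tt["IVR"] - tt["EJECTION"]),
        peak_mv_flow=float(np.max(-q_mv[dia], initial=0.0)),
        peak_av_flow=float(np.max(q_av[ej], initial=0.0)),
    )


def fibre_strain_field(
    mesh: LagrangianMesh,
    reference_chi: np.ndarray | None = None,
    kind: str = "stretch",
) -> np.ndarray:
    """Per-triangle fibre strain relative to a reference state.

    ``kind='stretch'`` reports lambda_rel - 1 where lambda_rel is the fibre
    stretch between the reference state (default: the mesh's reference
    configuration) and the current one; ``kind='green'`` reports the Green
    strain (lambda_rel^2 - 1)/2 along the fibre.
    """
    from heartfsi.ibfe import element_deformation_gradients

    F_now, _ = element_deformation_gradients(mesh)
    lam_now = _fibre_stretch(F_now, mesh.frame_f)
    if reference_chi is None:
        lam_ref = np.ones_like(lam_now)
    else:
        ref = mesh.with_positions(reference_chi)
        F_ref, _ = element_deformation_gradients(ref)
        lam_ref = _fibre_stretch(F_ref, mesh.frame_f)
    lam = lam_now / lam_ref
    if kind == "stretch":
        return lam - 1.0
    if kind == "green":
        return 0.5 * (lam**2 - 1.0)
    raise ValueError("kind must be 'stretch' or 'green'")


def _fibre_stretch(F2: np.ndarray, f0: np.ndarray) -> np.ndarray:
    v = np.einsum("mij,mj->mi", F2, f0)
    return np.linalg.norm(v, axis=1)
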