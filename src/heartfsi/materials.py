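"""Constitutive laws for the coupled MV-LV model.

Three passive hyperelastic laws (fibre-reinforced incompressible leaflets,
neo-Hookean chordal cables, orthotropic Holzapfel-Ogden myocardium), the
rank-one active fibre stress, and a phenomenological active-tension twitch.

Conventions
-----------
* All tensors are 3x3 with optional leading batch axes; 2-D plane-strain states
  are embedded with unit out-of-plane stretch (so I1 = 3 at identity in both
  2-D and 3-D use).
* Stresses are first Piola-Kirchhoff (PK1) and carry the units of the material
  parameters (kPa throughout this package).
* Each passive PK1 includes a pressure-like correction chosen so the stress is
  exactly zero in the reference configuration, plus the bulk penalty
  ``beta_s * log(I3) * F^{-T}`` enforcing near-incompressibility of the
  immersed solid.  The corresponding scalar energies are provided so the PK1
  is the exact gradient dW/dF (the basis of the finite-difference oracles in
  the test suite).
* Fibre-family terms engage only in extension: the invariant arguments are
  clamped at 1, so a compressed fibre family contributes no stress.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from heartfsi.params import (
    ActiveTensionParams,
    HolzapfelOgdenParams,
    MVLeafletParams,
    NumericalParams,
)

__all__ = [
    "DegenerateDeformationError",
    "DeformationState",
    "FibreFrame",
    "embed_plane_strain",
    "kinematics",
    "mv_leaflet_energy",
    "mv_leaflet_pk1",
    "ho_energy",
    "ho_passive_pk1",
    "chordae_energy",
    "chordae_tension",
    "active_pk1",
    "twitch_tension",
    "twitch_peak_time",
]


class DegenerateDeformationError(ValueError):
    """Raised when det F <= 0 (inverted or collapsed material element)."""


def _as_vec3(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape[-1] == 2:
        pad = np.zeros(v.shape[:-1] + (1,))
        v = np.concatenate([v, pad], axis=-1)
    return v


@dataclass
class FibreFrame:
    """Unit direction fields in the reference configuration.

    f0: myofibre (or collagen) direction; s0: sheet direction; f0c: leaflet
    collagen direction.  2-vectors are embedded in-plane.
    """

    f0: np.ndarray
    s0: np.ndarray | None = None
    f0c: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.f0 = _unit(_as_vec3(self.f0))
        self.s0 = None if self.s0 is None else _unit(_as_vec3(self.s0))
        self.f0c = None if self.f0c is None else _unit(_as_vec3(self.f0c))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n == 0):
        raise ValueError("zero-length direction vector")
    return v / n


def embed_plane_strain(F2: np.ndarray) -> np.ndarray:
    """Embed a (...,2,2) in-plane deformation gradient as (...,3,3), F33 = 1."""
    F2 = np.asarray(F2, dtype=float)
    F = np.zeros(F2.shape[:-2] + (3, 3))
    F[..., :2, :2] = F2
    F[..., 2, 2] = 1.0
    return F


@dataclass
class DeformationState:
    """Kinematic invariants of C = F^T F at one (or a batch of) point(s)."""

    F: np.ndarray
    J: np.ndarray
    I1: np.ndarray
    I3: np.ndarray
    I4f: np.ndarray
    I4s: np.ndarray
    I8fs: np.ndarray
    I4c: np.ndarray


def _prep_F(F: np.ndarray) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    if F.shape[-2:] == (2, 2):
        F = embed_plane_strain(F)
    if F.shape[-2:] != (3, 3):
        raise ValueError("F must be (...,2,2) or (...,3,3)")
    return F


def _check_det(J: np.ndarray) -> None:
    if np.any(J <= 0):
        raise DegenerateDeformationError("non-positive det F")


def _det3(F: np.ndarray) -> np.ndarray:
    """Batched 3x3 determinant via cofactors (faster than LAPACK dispatch)."""
    return (
        F[..., 0, 0] * (F[..., 1, 1] * F[..., 2, 2] - F[..., 1, 2] * F[..., 2, 1])
        - F[..., 0, 1] * (F[..., 1, 0] * F[..., 2, 2] - F[..., 1, 2] * F[..., 2, 0])
        + F[..., 0, 2] * (F[..., 1, 0] * F[..., 2, 1] - F[..., 1, 1] * F[..., 2, 0])
    )


def kinematics(F: np.ndarray, frame: FibreFrame) -> DeformationState:
    """All invariants of C = F^T F for the given fibre frame.

    I4f/I4s/I4c are squared stretches along f0/s0/f0c; I8fs = f0.(C s0) is the
    fibre-sheet coupling invariant.
    """
    F = _prep_F(F)
    J = _det3(F)
    _check_det(J)
    C = np.swapaxes(F, -1, -2) @ F
    I1 = np.trace(C, axis1=-2, axis2=-1)
    I3 = J**2

    def quad(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return np.einsum("...i,...ij,...j->...", a, C, b)

    f0 = frame.f0
    I4f = quad(f0, f0)
    if frame.s0 is not None:
        I4s = quad(frame.s0, frame.s0)
        I8fs = quad(f0, frame.s0)
    else:
        I4s = np.ones_like(I4f)
        I8fs = np.zeros_like(I4f)
    I4c = quad(frame.f0c, frame.f0c) if frame.f0c is not None else np.ones_like(I4f)
    return DeformationState(F=F, J=J, I1=I1, I3=I3, I4f=I4f, I4s=I4s, I8fs=I8fs, I4c=I4c)


def _inv_T(F: np.ndarray) -> np.ndarray:
    """Batched transpose-inverse via the adjugate (F is 3x3, det != 0)."""
    adjT = np.empty_like(F)
    a, b, c = F[..., 0, 0], F[..., 0, 1], F[..., 0, 2]
    d, e, f = F[..., 1, 0], F[..., 1, 1], F[..., 1, 2]
    g, h, i = F[..., 2, 0], F[..., 2, 1], F[..., 2, 2]
    det = a * (e * i - f * h) - b * (d * i - f * g) + c * (d * h - e * g)
    adjT[..., 0, 0] = e * i - f * h
    adjT[..., 1, 0] = c * h - b * i
    adjT[..., 2, 0] = b * f - c * e
    adjT[..., 0, 1] = f * g - d * i
    adjT[..., 1, 1] = a * i - c * g
    adjT[..., 2, 1] = c * d - a * f
    adjT[..., 0, 2] = d * h - e * g
    adjT[..., 1, 2] = b * g - a * h
    adjT[..., 2, 2] = a * e - b * d
    # the cofactor matrix equals det(F) * inv(F)^T
    return adjT / det[..., None, None]


def _outer(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a[..., :, None] * b[..., None, :]


def _vol_energy(I3: np.ndarray, beta_s: float) -> np.ndarray:
    # gradient of (beta/4) (log I3)^2 w.r.t. F is  beta log(I3) F^{-T}
    return 0.25 * beta_s * np.log(I3) ** 2


# ---------------------------------------------------------------------------
# MV leaflets
# ---------------------------------------------------------------------------

def mv_leaflet_energy(
    F: np.ndarray, frame: FibreFrame, p: MVLeafletParams, num: NumericalParams
) -> np.ndarray:
    """Total leaflet energy density (isochoric + collagen + penalty terms)."""
    st = kinematics(F, frame)
    I4c = np.maximum(st.I4c, 1.0)
    W = p.C1 * (st.I1 - 3.0)
    W = W + p.av / (2.0 * p.bv) * (np.exp(p.bv * (I4c - 1.0) ** 2) - 1.0)
    # -C1 log I3 generates the 2*C1 F^{-T} zero-stress-at-identity correction
    W = W - p.C1 * np.log(st.I3)
    return W + _vol_energy(st.I3, num.beta_s)


def mv_leaflet_pk1(
    F: np.ndarray, frame: FibreFrame, p: MVLeafletParams, num: NumericalParams
) -> np.ndarray:
    """Passive leaflet PK1; exactly zero at F = I, collagen only in extension."""
    st = kinematics(F, frame)
    F = st.F
    FinvT = _inv_T(F)
    P = 2.0 * p.C1 * F - 2.0 * p.C1 * FinvT
    ext = st.I4c > 1.0
    if np.any(ext):
        g = np.where(ext, st.I4c - 1.0, 0.0)
        coef = 2.0 * p.av * g * np.exp(p.bv * g**2)
        M = _outer(frame.f0c, frame.f0c)
        P = P + coef[..., None, None] * (F @ M)
    P = P + (num.beta_s * np.log(st.I3))[..., None, None] * FinvT
    return P


# ---------------------------------------------------------------------------
# Holzapfel-Ogden myocardium
# ---------------------------------------------------------------------------

def ho_energy(
    F: np.ndarray, frame: FibreFrame, p: HolzapfelOgdenParams, num: NumericalParams
) -> np.ndarray:
    st = kinematics(F, frame)
    I4f = np.maximum(st.I4f, 1.0)
    I4s = np.maximum(st.I4s, 1.0)
    W = p.a / (2.0 * p.b) * np.exp(p.b * (st.I1 - 3.0))
    W = W + p.af / (2.0 * p.bf) * (np.exp(p.bf * (I4f - 1.0) ** 2) - 1.0)
    W = W + p.as_ / (2.0 * p.bs) * (np.exp(p.bs * (I4s - 1.0) ** 2) - 1.0)
    W = W + p.afs / (2.0 * p.bfs) * (np.exp(p.bfs * st.I8fs**2) - 1.0)
    W = W - 0.5 * p.a * np.log(st.I3)  # zero-stress-at-identity correction
    return W + _vol_energy(st.I3, num.beta_s)


def ho_passive_pk1(
    F: np.ndarray, frame: FibreFrame, p: HolzapfelOgdenParams, num: NumericalParams
) -> np.ndarray:
    st = kinematics(F, frame)
    F = st.F
    FinvT = _inv_T(F)
    P = (p.a * np.exp(p.b * (st.I1 - 3.0)))[..., None, None] * F - p.a * FinvT

    for I4, mod, ex, d0 in ((st.I4f, p.af, p.bf, frame.f0), (st.I4s, p.as_, p.bs, frame.s0)):
        g = np.where(I4 > 1.0, I4 - 1.0, 0.0)
        coef = 2.0 * mod * g * np.exp(ex * g**2)
        M = _outer(d0, d0)
        P = P + coef[..., None, None] * (F @ M)

    coef8 = p.afs * st.I8fs * np.exp(p.bfs * st.I8fs**2)
    Mfs = _outer(frame.f0, frame.s0) + _outer(frame.s0, frame.f0)
    P = P + coef8[..., None, None] * (F @ Mfs)
    P = P + (num.beta_s * np.log(st.I3))[..., None, None] * FinvT
    return P


# ---------------------------------------------------------------------------
# Chordae tendineae (1-D incompressible neo-Hookean cables)
# ---------------------------------------------------------------------------

def chordae_energy(stretch: np.ndarray, C: float) -> np.ndarray:
    """Cable energy density W = C (lam^2 + 2/lam - 3), zero for slack chords."""
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0):
        raise DegenerateDeformationError("non-positive chord stretch")
    W = C * (lam**2 + 2.0 / lam - 3.0)
    return np.where(lam > 1.0, W, 0.0)


def chordae_tension(stretch: np.ndarray, C: float) -> np.ndarray:
    """Nominal chord tension t = 2C (lam - lam^-2); floored at 0 when slack."""
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0):
        raise DegenerateDeformationError("non-positive chord stretch")
    t = 2.0 * C * (lam - lam**-2)
    return np.maximum(t, 0.0)


# ---------------------------------------------------------------------------
# Active stress
# ---------------------------------------------------------------------------

def active_pk1(F: np.ndarray, f0: np.ndarray, T: float | np.ndarray) -> np.ndarray:
    """Rank-one active fibre stress  P_a = J T F (f0 x f0)."""
    F = _prep_F(F)
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError("active tension must be non-negative")
    J = np.linalg.det(F)
    _check_det(J)
    f0 = _unit(_as_vec3(np.asarray(f0, dtype=float)))
    M = _outer(f0, f0)
    return (J * T)[..., None, None] * (F @ M)


def twitch_peak_time(p: ActiveTensionParams) -> float:
    """Time after onset at which the twitch peaks (closed form)."""
    return p.tau_rise * np.log(1.0 + p.tau_decay / p.tau_rise)


def twitch_tension(t: np.ndarray | float, p: ActiveTensionParams) -> np.ndarray | float:
    """Active tension T(t) in kPa: zero before t_act, then a normalised twitch.

    Shape (1 - exp(-s/tau_rise)) exp(-s/tau_decay) with s = t - t_act, scaled
    so the peak equals T_ref exactly.
    """
    t = np.asarray(t, dtype=float)
    s = t - p.t_act
    g = (1.0 - np.exp(-np.maximum(s, 0.0) / p.tau_rise)) * np.exp(-np.maximum(s, 0.0) / p.tau_decay)
    s_star = twitch_peak_time(p)
    g_peak = (1.0 - np.exp(-s_star / p.tau_rise)) * np.exp(-s_star / p.tau_decay)
    T = np.where(s > 0.0, p.T_ref * g / g_peak, 0.0)
    return float(T) if T.ndim == 0 else T
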