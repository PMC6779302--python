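"""Eulerian-Lagrangian coupling and finite-element force assembly.

The immersed structure is a 2-D triangulated Lagrangian mesh (plus 1-D chordal
segments) living on a periodic Eulerian grid.  Coupling uses the classical
four-point regularized delta kernel: nodal forces are spread to the grid and
grid velocities interpolated back with the *same* weights, making the two
operators exact adjoints of one another.

Elastic nodal forces are assembled in weak form as the exact negative gradient
of the discrete strain energy (one-point quadrature on affine triangles, which
is exact for the elementwise-constant deformation gradients those elements
produce).  Forces carry CGS units (dyn per cm of out-of-plane depth); material
laws return kPa, converted here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from heartfsi import _kernels, materials
from heartfsi.materials import DegenerateDeformationError, FibreFrame
from heartfsi.params import (
    ChordaeParams,
    HolzapfelOgdenParams,
    MVLeafletParams,
    NumericalParams,
)
from heartfsi.units import KPA


class OutOfDomainError(RuntimeError):
    """A structure node left the fluid box."""


class InvertedElementError(DegenerateDeformationError):
    """det F <= 0 on one or more elements."""

    def __init__(self, element_ids: np.ndarray):
        self.element_ids = np.asarray(element_ids)
        super().__init__(f"inverted element(s): {self.element_ids.tolist()}")


class Region(str, Enum):
    LEAFLET_ANTERIOR = "leaflet_anterior"
    LEAFLET_POSTERIOR = "leaflet_posterior"
    CHORDA = "chorda"
    WALL_CONTRACTILE = "wall_contractile"
    WALL_PASSIVE = "wall_passive"
    TRACT_INFLOW = "tract_inflow"
    TRACT_OUTFLOW = "tract_outflow"


@dataclass
class LagrangianMesh:
    """Reference/current nodal positions plus connectivity and element fields.

    ``tris`` are linear triangles; ``chords`` are 1-D cable segments given as
    (node_a, node_b) index pairs.  Per-triangle fields: region label, fibre
    frame (f0, s0 in-plane unit vectors), transmural coordinate d in [0,1]
    where defined.  ``pinned`` nodes are kinematically fixed anchor points
    (papillary-head stand-ins) whose forces are absorbed externally, never
    spread to the fluid.
    """

    X: np.ndarray  # (n,2) reference coordinates, cm
    chi: np.ndarray  # (n,2) current coordinates, cm
    tris: np.ndarray  # (m,3) int
    tri_region: np.ndarray  # (m,) of Region values (object array of str)
    frame_f: np.ndarray  # (m,2) unit fibre direction per triangle
    frame_s: np.ndarray  # (m,2) unit sheet direction per triangle
    transmural: np.ndarray  # (m,) d in [0,1]; NaN where undefined
    chords: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=int))
    chord_region: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=object))
    pinned: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    chord_L0: np.ndarray | None = None  # rest lengths; default: reference distance
    # assembly precomputation (filled by __post_init__)
    _Dm_inv: np.ndarray | None = None
    _area_ref: np.ndarray | None = None
    _chord_L: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.chi = np.asarray(self.chi, dtype=float)
        if self.chi.shape != self.X.shape:
            raise ValueError("chi and X must be congruent")
        self.tris = np.asarray(self.tris, dtype=int)
        Dm = _edge_matrix(self.X, self.tris)
        det = np.linalg.det(Dm)
        if np.any(det <= 0):
            raise ValueError("reference mesh has non-positively oriented triangles")
        self._Dm_inv = np.linalg.inv(Dm)
        self._area_ref = 0.5 * det
        if len(self.chords):
            if self.chord_L0 is not None:
                self._chord_L = np.asarray(self.chord_L0, dtype=float)
            else:
                d = self.X[self.chords[:, 1]] - self.X[self.chords[:, 0]]
                self._chord_L = np.linalg.norm(d, axis=1)
            if np.any(self._chord_L <= 0):
                raise ValueError("degenerate chord segment")

    @property
    def n_nodes(self) -> int:
        return self.X.shape[0]

    @property
    def pinned_mask(self) -> np.ndarray:
        m = np.zeros(self.n_nodes, dtype=bool)
        m[self.pinned] = True
        return m

    def with_positions(self, chi: np.ndarray) -> "LagrangianMesh":
        out = LagrangianMesh(
            X=self.X, chi=np.asarray(chi, dtype=float), tris=self.tris,
            tri_region=self.tri_region, frame_f=self.frame_f, frame_s=self.frame_s,
            transmural=self.transmural, chords=self.chords,
            chord_region=self.chord_region, pinned=self.pinned,
            chord_L0=self.chord_L0,
        )
        return out


def _edge_matrix(pts: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """(m,2,2) matrices [p1-p0, p2-p0] as columns."""
    p = pts[tris]
    D = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]], axis=-1)
    return D


# ---------------------------------------------------------------------------
# Regularized delta kernel
# ---------------------------------------------------------------------------

def delta_kernel(r: np.ndarray | float) -> np.ndarray | float:
    """Classical four-point regularized delta (1-D factor), support |r| < 2.

    Satisfies the partition-of-unity and even-moment conditions the IB scheme
    relies on; phi(0) = 1/2.
    """
    r = np.abs(np.asarray(r, dtype=float))
    out = np.zeros_like(r)
    m1 = r < 1.0
    m2 = (r >= 1.0) & (r < 2.0)
    r1 = r[m1]
    r2 = r[m2]
    out[m1] = (3.0 - 2.0 * r1 + np.sqrt(1.0 + 4.0 * r1 - 4.0 * r1**2)) / 8.0
    out[m2] = (5.0 - 2.0 * r2 - np.sqrt(-7.0 + 12.0 * r2 - 4.0 * r2**2)) / 8.0
    return float(out) if out.ndim == 0 else out


def _stencil(points: np.ndarray, h: float, n: int):
    """4x4 tensor-product stencil (indices mod n and weights) per point."""
    g = points / h  # grid coordinates (nodes at i*h)
    i0 = np.floor(g).astype(int) - 1
    offs = np.arange(4)
    ix = (i0[:, 0, None] + offs) % n
    iy = (i0[:, 1, None] + offs) % n
    wx = delta_kernel(g[:, 0, None] - (i0[:, 0, None] + offs))
    wy = delta_kernel(g[:, 1, None] - (i0[:, 1, None] + offs))
    w = wx[:, :, None] * wy[:, None, :]  # (npts, 4, 4)
    return ix, iy, w


def _check_in_domain(points: np.ndarray, L: float) -> None:
    if not np.all(np.isfinite(points)):
        raise OutOfDomainError("non-finite structure coordinates")
    if np.any(points < -L) or np.any(points >= 2.0 * L):
        raise OutOfDomainError("structure node left the fluid box")


def spread_forces(
    nodal_forces: np.ndarray, points: np.ndarray, n: int, L: float,
    method: str = "auto",
) -> np.ndarray:
    """Spread Lagrangian point forces to an (2, n, n) Eulerian force density.

    Conserves total force exactly: sum(f) * h^2 == sum(F) up to roundoff.
    The compiled and vectorized paths agree to roundoff.
    """
    points = np.asarray(points, dtype=float)
    nodal_forces = np.asarray(nodal_forces, dtype=float)
    _check_in_domain(points, L)
    h = L / n
    if method == "auto" and _kernels.HAVE_NUMBA:
        return _kernels.spread_forces_jit(nodal_forces, points, n, h)
    ix, iy, w = _stencil(points % L, h, n)
    flat = (ix[:, :, None] * n + iy[:, None, :]).ravel()
    wf = w / h**2
    f = np.stack([
        np.bincount(flat, weights=(wf * nodal_forces[:, c, None, None]).ravel(),
                    minlength=n * n).reshape(n, n)
        for c in range(2)
    ])
    return f


def interpolate_velocity(
    u: np.ndarray, points: np.ndarray, L: float, method: str = "auto"
) -> np.ndarray:
    """Kernel-weighted velocity at structure points; exact adjoint of spreading."""
    points = np.asarray(points, dtype=float)
    _check_in_domain(points, L)
    n = u.shape[-1]
    h = L / n
    if method == "auto" and _kernels.HAVE_NUMBA:
        return _kernels.interpolate_velocity_jit(
            np.ascontiguousarray(u), points, n, h
        )
    ix, iy, w = _stencil(points % L, h, n)
    flat = (ix[:, :, None] * n + iy[:, None, :]).reshape(points.shape[0], 16)
    w16 = w.reshape(points.shape[0], 16)
    U = np.empty((points.shape[0], 2))
    for c in range(2):
        U[:, c] = np.sum(u[c].reshape(-1)[flat] * w16, axis=1)
    return U


# ---------------------------------------------------------------------------
# Deformation gradients
# ---------------------------------------------------------------------------

def element_deformation_gradients(mesh: LagrangianMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-triangle in-plane F (m,2,2) and per-chord stretch (c,).

    Affine triangles make the one-point value exact everywhere on the element.
    Raises InvertedElementError naming the offending triangles.
    """
    Ds = _edge_matrix(mesh.chi, mesh.tris)
    F = Ds @ mesh._Dm_inv
    det = np.linalg.det(F)
    if np.any(det <= 0):
        raise InvertedElementError(np.nonzero(det <= 0)[0])
    if len(mesh.chords):
        d = mesh.chi[mesh.chords[:, 1]] - mesh.chi[mesh.chords[:, 0]]
        lam = np.linalg.norm(d, axis=1) / mesh._chord_L
    else:
        lam = np.zeros(0)
    return F, lam


# ---------------------------------------------------------------------------
# Elastic energy and nodal forces
# ---------------------------------------------------------------------------

@dataclass
class MaterialSet:
    """Per-region constitutive parameters used by the assembler."""

    anterior: MVLeafletParams
    posterior: MVLeafletParams
    chordae: ChordaeParams
    myocardium: HolzapfelOgdenParams
    numerics: NumericalParams


def _tri_groups(mesh: LagrangianMesh) -> dict[str, np.ndarray]:
    cached = getattr(mesh, "_groups_cache", None)
    if cached is not None:
        return cached
    reg = np.asarray([str(r) for r in mesh.tri_region])
    groups = {}
    for law, names in {
        "leaflet_anterior": [Region.LEAFLET_ANTERIOR.value],
        "leaflet_posterior": [Region.LEAFLET_POSTERIOR.value],
        "myocardium": [
            Region.WALL_CONTRACTILE.value,
            Region.WALL_PASSIVE.value,
            Region.TRACT_INFLOW.value,
            Region.TRACT_OUTFLOW.value,
        ],
    }.items():
        idx = np.nonzero(np.isin(reg, names))[0]
        if len(idx):
            groups[law] = idx
    mesh._groups_cache = groups
    mesh._contract_cache = reg == Region.WALL_CONTRACTILE.value
    return groups


def _tri_pk1(
    mesh: LagrangianMesh,
    F2: np.ndarray,
    mats: MaterialSet,
    T_active: float,
) -> np.ndarray:
    """In-plane PK1 block per triangle, in kPa."""
    m = len(mesh.tris)
    P = np.zeros((m, 2, 2))
    num = mats.numerics
    for law, idx in _tri_groups(mesh).items():
        Fb = F2[idx]
        f0 = mesh.frame_f[idx]
        s0 = mesh.frame_s[idx]
        if law == "myocardium":
            frame = FibreFrame(f0=f0, s0=s0)
            P3 = materials.ho_passive_pk1(Fb, frame, mats.myocardium, num)
            if T_active > 0.0:
                contract = mesh._contract_cache[idx]
                if np.any(contract):
                    Pa = materials.active_pk1(
                        Fb[contract], frame.f0[contract], T_active
                    )
                    P3[contract] += Pa
        else:
            p = mats.anterior if law == "leaflet_anterior" else mats.posterior
            frame = FibreFrame(f0=f0, f0c=f0)
            P3 = materials.mv_leaflet_pk1(Fb, frame, p, num)
        P[idx] = P3[:, :2, :2]
    return P


def total_elastic_energy(
    mesh: LagrangianMesh, mats: MaterialSet, chordae_C: float | None = None
) -> float:
    """Discrete passive strain energy (erg per cm depth); gradient check oracle.

    Excludes active stress (which is not derivable from a potential here).
    ``chordae_C`` defaults to the diastolic chordal modulus.
    """
    F2, lam = element_deformation_gradients(mesh)
    num = mats.numerics
    E = 0.0
    for law, idx in _tri_groups(mesh).items():
        Fb = F2[idx]
        f0 = mesh.frame_f[idx]
        if law == "myocardium":
            frame = FibreFrame(f0=f0, s0=mesh.frame_s[idx])
            W = materials.ho_energy(Fb, frame, mats.myocardium, num)
        else:
            p = mats.anterior if law == "leaflet_anterior" else mats.posterior
            frame = FibreFrame(f0=f0, f0c=f0)
            W = materials.mv_leaflet_energy(Fb, frame, p, num)
        E += float(np.sum(W * mesh._area_ref[idx]))
    if len(mesh.chords):
        C = mats.chordae.C_diastole if chordae_C is None else chordae_C
        Wc = materials.chordae_energy(lam, C)
        E += float(np.sum(Wc * mesh._chord_L * mats.chordae.cross_section))
    return E * KPA


def _packed_laws(mesh: LagrangianMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-triangle law codes + contractile mask for the compiled assembler."""
    cached = getattr(mesh, "_law_cache", None)
    if cached is not None:
        return cached
    law = np.full(len(mesh.tris), _kernels.LAW_MYOCARDIUM, dtype=np.int8)
    reg = np.asarray([str(r) for r in mesh.tri_region])
    law[reg == Region.LEAFLET_ANTERIOR.value] = _kernels.LAW_LEAFLET_ANT
    law[reg == Region.LEAFLET_POSTERIOR.value] = _kernels.LAW_LEAFLET_POST
    contractile = reg == Region.WALL_CONTRACTILE.value
    mesh._law_cache = (law, contractile)
    return law, contractile


def assemble_elastic_forces(
    mesh: LagrangianMesh,
    mats: MaterialSet,
    T_active: float = 0.0,
    chordae_C: float | None = None,
    method: str = "auto",
) -> np.ndarray:
    """Nodal forces = -dE/dchi (dyn per cm depth) in weak form.

    Triangles: one-point quadrature of the in-plane PK1; chords: along-segment
    nominal tension with the phase-dependent modulus ``chordae_C``.  Active
    fibre stress is added on contractile elements only.  ``method`` picks the
    compiled ('jit') or vectorized-reference ('numpy') inner loop; both give
    identical forces to roundoff.
    """
    if method == "auto":
        method = "jit" if _kernels.HAVE_NUMBA else "numpy"
    if method == "jit":
        return _assemble_jit(mesh, mats, T_active, chordae_C)
    F2, lam = element_deformation_gradients(mesh)
    P = _tri_pk1(mesh, F2, mats, T_active) * KPA
    # dE/dDs = A_ref * P * Dm_inv^T ; scatter to nodes
    H = (mesh._area_ref[:, None, None] * P) @ np.swapaxes(mesh._Dm_inv, -1, -2)
    forces = np.zeros_like(mesh.chi)
    t = mesh.tris
    np.add.at(forces, t[:, 1], -H[:, :, 0])
    np.add.at(forces, t[:, 2], -H[:, :, 1])
    np.add.at(forces, t[:, 0], H[:, :, 0] + H[:, :, 1])
    if len(mesh.chords):
        C = mats.chordae.C_diastole if chordae_C is None else chordae_C
        tension = materials.chordae_tension(lam, C) * KPA  # dyn/cm^2
        d = mesh.chi[mesh.chords[:, 1]] - mesh.chi[mesh.chords[:, 0]]
        unit = d / np.linalg.norm(d, axis=1, keepdims=True)
        fmag = (tension * mats.chordae.cross_section)[:, None] * unit
        np.add.at(forces, mesh.chords[:, 0], fmag)
        np.add.at(forces, mesh.chords[:, 1], -fmag)
    return forces


def _assemble_jit(
    mesh: LagrangianMesh,
    mats: MaterialSet,
    T_active: float,
    chordae_C: float | None,
) -> np.ndarray:
    law, contractile = _packed_laws(mesh)
    p = mats.myocardium
    forces = np.zeros_like(mesh.chi)
    bad = _kernels.assemble_tri_forces_jit(
        mesh.chi, mesh.tris, mesh._Dm_inv, mesh._area_ref, law, contractile,
        mesh.frame_f, mesh.frame_s,
        np.array([mats.anterior.C1, mats.posterior.C1]),
        np.array([mats.anterior.av, mats.posterior.av]),
        np.array([mats.anterior.bv, mats.posterior.bv]),
        p.a, p.b, p.af, p.bf, p.as_, p.bs, p.afs, p.bfs,
        mats.numerics.beta_s, float(T_active), KPA, forces,
    )
    if bad >= 0:
        raise InvertedElementError(np.asarray([bad]))
    if len(mesh.chords):
        C = mats.chordae.C_diastole if chordae_C is None else chordae_C
        _kernels.chord_forces_jit(
            mesh.chi, mesh.chords, mesh._chord_L, C,
            mats.chordae.cross_section, KPA, forces,
        )
    return forces


# ---------------------------------------------------------------------------
# Tether (target-point) forces
# ---------------------------------------------------------------------------

@dataclass
class TetherSet:
    """Target-point constraints on a subset of nodes.

    mode 'full': isotropic spring; 'vertical': penalize only the vertical
    (longitudinal) displacement component, leaving radial motion free (the
    basal-ring condition).  ``cap`` enables the soft-then-stiff valvular
    tether: linear up to the cap displacement, hardened beyond it so the
    displacement saturates near the cap.
    """

    nodes: np.ndarray
    targets: np.ndarray
    k: float
    mode: str = "full"
    cap: float | None = None
    cap_hardening: float = 20.0
    damping: float = 0.0  # dyn s/cm per node: numerical stabilization dashpot

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=int)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.targets.shape != (len(self.nodes), 2):
            raise ValueError("targets must be (n_nodes, 2)")


def tether_forces(
    mesh: LagrangianMesh,
    tethers: list[TetherSet],
    stiffness_scale: float = 1.0,
    velocities: np.ndarray | None = None,
) -> np.ndarray:
    """Linear restoring forces toward target points (dyn per cm depth).

    ``stiffness_scale`` implements the systolic pull-back schedule (the
    simulator ramps it above 1 after end-diastole for capped sets).  When node
    ``velocities`` are supplied, each set's dashpot adds -damping * v, which
    suppresses the neutrally stable spring/fluid oscillation of the explicit
    coupling without changing any equilibrium.
    """
    forces = np.zeros_like(mesh.chi)
    for ts in tethers:
        d = mesh.chi[ts.nodes] - ts.targets
        k = ts.k * (stiffness_scale if ts.cap is not None else 1.0)
        if ts.mode == "vertical":
            f = np.zeros_like(d)
            f[:, 1] = -k * d[:, 1]
        elif ts.cap is None:
            f = -k * d
        else:
            r = np.linalg.norm(d, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                unit = np.where(r[:, None] > 0, d / np.where(r == 0, 1.0, r)[:, None], 0.0)
            mag = np.where(
                r <= ts.cap, k * r, k * ts.cap + ts.cap_hardening * k * (r - ts.cap)
            )
            f = -mag[:, None] * unit
        if velocities is not None and ts.damping > 0.0:
            v = velocities[ts.nodes]
            if ts.mode == "vertical":
                f[:, 1] -= ts.damping * v[:, 1]
            else:
                f -= ts.damping * v
        np.add.at(forces, ts.nodes, f)
    return forces
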