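"""Idealized 2-D MV-LV geometries standing in for an image-derived mesh.

The default chamber is a long-axis (LVOT-view) cross-section that keeps the
topology of the real system: an elliptical contractile wall open at the base,
a passive valvular/housing region, separate inflow and outflow tracts rising
from the basal opening, two unequal mitral leaflets mounted at the annulus
with chordae running to fixed papillary-head stand-in anchors, and a binary
aortic-valve plane at the top of the outflow tract.

Region labelling follows the four-part division of the ventricle model
(contractile wall below the basal plane, passive valvular region above it,
inflow tract, outflow tract) plus the valve's own regions (two leaflets,
chordae).  All lengths in cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from heartfsi.ibfe import LagrangianMesh, Region, TetherSet
from heartfsi.params import GeometryConfig, TetherParams


class InfeasibleGeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Fibre rule
# ---------------------------------------------------------------------------

def fibre_field(
    circumferential: np.ndarray,
    transmural: np.ndarray,
    theta_endo: float = -60.0,
    theta_epi: float = 60.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rule-based myofibre frame: rotate linearly from endo to epicardium.

    The fibre angle is theta(d) = theta_endo + (theta_epi - theta_endo) * d
    measured from the local circumferential direction, rotated consistently in
    the 2-D section plane.  Returns unit (f0, s0) with s0 the in-plane sheet
    direction orthogonal to f0.
    """
    circ = np.asarray(circumferential, dtype=float)
    d = np.asarray(transmural, dtype=float)
    if np.any(~np.isfinite(d)):
        raise ValueError("missing transmural coordinate")
    circ = circ / np.linalg.norm(circ, axis=-1, keepdims=True)
    theta = np.deg2rad(theta_endo + (theta_epi - theta_endo) * d)
    c, s = np.cos(theta), np.sin(theta)
    f0 = np.stack([c * circ[..., 0] - s * circ[..., 1],
                   s * circ[..., 0] + c * circ[..., 1]], axis=-1)
    s0 = np.stack([-f0[..., 1], f0[..., 0]], axis=-1)
    return f0, s0


# ---------------------------------------------------------------------------
# Mesh builder
# ---------------------------------------------------------------------------

class _Builder:
    def __init__(self) -> None:
        self.nodes: list[np.ndarray] = []
        self.tris: list[tuple[int, int, int]] = []
        self.region: list[str] = []
        self.f0: list[np.ndarray] = []
        self.s0: list[np.ndarray] = []
        self.d: list[float] = []
        self.chords: list[tuple[int, int]] = []
        self.chord_L0: list[float] = []
        self.pinned: list[int] = []

    def add_nodes(self, pts: np.ndarray) -> np.ndarray:
        base = len(self.nodes)
        self.nodes.extend(np.asarray(pts, dtype=float))
        return np.arange(base, base + len(pts))

    def add_tri(self, a: int, b: int, c: int, region: str,
                f0: np.ndarray, s0: np.ndarray, d: float) -> None:
        p = np.asarray(self.nodes)
        ab, ac = p[b] - p[a], p[c] - p[a]
        if ab[0] * ac[1] - ab[1] * ac[0] < 0:
            b, c = c, b
        self.tris.append((a, b, c))
        self.region.append(region)
        self.f0.append(np.asarray(f0, dtype=float))
        self.s0.append(np.asarray(s0, dtype=float))
        self.d.append(d)

    def build(self) -> LagrangianMesh:
        X = np.asarray(self.nodes)
        return LagrangianMesh(
            X=X,
            chi=X.copy(),
            tris=np.asarray(self.tris, dtype=int),
            tri_region=np.asarray(self.region, dtype=object),
            frame_f=np.asarray(self.f0),
            frame_s=np.asarray(self.s0),
            transmural=np.asarray(self.d),
            chords=np.asarray(self.chords, dtype=int).reshape(-1, 2),
            chord_region=np.asarray([Region.CHORDA.value] * len(self.chords), dtype=object),
            pinned=np.asarray(self.pinned, dtype=int),
            chord_L0=np.asarray(self.chord_L0) if self.chord_L0 else None,
        )


def _band(
    builder: _Builder,
    centerline: np.ndarray,
    normals: np.ndarray,
    thickness: float,
    n_layers: int,
    region_fn,
    frame_fn,
) -> np.ndarray:
    """Extrude a centerline into a triangulated band of n_layers elements.

    Layer 0 sits on the -normal side (the endocardial side for outward
    normals).  ``region_fn(centroid) -> str`` labels elements;
    ``frame_fn(tangent, d, centroid) -> (f0, s0, d)`` assigns fibre frames.
    Returns the (k, n_layers+1) node index grid.
    """
    k = len(centerline)
    offs = (np.arange(n_layers + 1) / n_layers - 0.5) * thickness
    pts = centerline[:, None, :] + offs[None, :, None] * normals[:, None, :]
    idx = builder.add_nodes(pts.reshape(-1, 2)).reshape(k, n_layers + 1)
    tang = np.diff(centerline, axis=0)
    tang = tang / np.linalg.norm(tang, axis=1, keepdims=True)
    p = pts
    for j in range(k - 1):
        for l in range(n_layers):
            dmid = (l + 0.5) / n_layers
            quad = [idx[j, l], idx[j + 1, l], idx[j + 1, l + 1], idx[j, l + 1]]
            cent = 0.25 * (p[j, l] + p[j + 1, l] + p[j + 1, l + 1] + p[j, l + 1])
            f0, s0, dval = frame_fn(tang[j], dmid, cent)
            for tri in ((quad[0], quad[1], quad[2]), (quad[0], quad[2], quad[3])):
                c3 = np.mean([builder.nodes[t] for t in tri], axis=0)
                builder.add_tri(*tri, region_fn(c3), f0, s0, dval)
    return idx


def _resample(points: np.ndarray, ds: float) -> np.ndarray:
    """Resample a polyline at about ds spacing (endpoints preserved)."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(2, int(np.ceil(s[-1] / ds)) + 1)
    si = np.linspace(0.0, s[-1], n)
    out = np.stack([np.interp(si, s, points[:, 0]), np.interp(si, s, points[:, 1])], axis=1)
    return out


# ---------------------------------------------------------------------------
# Leaflets and chordae
# ---------------------------------------------------------------------------

def _add_leaflet(
    builder: _Builder,
    root: np.ndarray,
    direction: np.ndarray,
    length: float,
    thickness: float,
    ds: float,
    region: str,
) -> np.ndarray:
    """Straight leaflet strip hanging from ``root`` along ``direction``.

    Collagen fibres run along the leaflet (the in-plane projection of the
    annulus-parallel collagen sheet).  Returns the node index grid
    (k, 3) with the middle column on the centerline; the root column is
    pinned to the (rigid) annulus.
    """
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    n_seg = max(4, int(round(length / ds)))
    cl = root[None, :] + np.linspace(0.0, length, n_seg + 1)[:, None] * direction[None, :]
    normal = np.array([-direction[1], direction[0]])
    normals = np.tile(normal, (len(cl), 1))
    idx = _band(
        builder, cl, normals, thickness, 2,
        region_fn=lambda c: region,
        frame_fn=lambda t, d, c: (direction, normal, d),
    )
    builder.pinned.extend(idx[0].tolist())
    return idx


def _attach_chordae(
    builder: _Builder,
    leaflet_idx: np.ndarray,
    anchor: np.ndarray,
    n_chords: int,
    rest_scale: float,
) -> None:
    """Evenly distribute chords from the distal (free-edge) half to an anchor.

    The chord reference length is the reference-configuration distance scaled
    by ``rest_scale`` (> 1: slack in the open position, engaging as the
    leaflet excurses toward closure/eversion).
    """
    mid = leaflet_idx[:, 1]
    k = len(mid)
    picks = np.round(np.linspace(k // 2, k - 1, n_chords)).astype(int)
    anchor_id = int(builder.add_nodes(anchor[None, :])[0])
    builder.pinned.append(anchor_id)
    pts = np.asarray(builder.nodes)
    for pick in picks:
        a = int(mid[pick])
        L0 = rest_scale * float(np.linalg.norm(pts[a] - anchor))
        builder.chords.append((a, anchor_id))
        builder.chord_L0.append(L0)


# ---------------------------------------------------------------------------
# Apparatus (planes, probes, tethers) for the chamber model
# ---------------------------------------------------------------------------

@dataclass
class PlaneDef:
    """A horizontal tract plane: measurement line + plug/pressure markers."""

    x_left: float
    x_right: float
    y: float
    markers: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))

    @property
    def width(self) -> float:
        return self.x_right - self.x_left

    def quad_points(self, n: int) -> np.ndarray:
        x = self.x_left + (np.arange(n) + 0.5) * self.width / n
        return np.stack([x, np.full(n, self.y)], axis=1)


@dataclass
class ChamberApparatus:
    """Everything the simulator needs beyond the bare mesh."""

    mv_plane: PlaneDef
    av_plane: PlaneDef
    tethers: list[TetherSet]
    capped_tether_index: int  # index of the valvular (capped) tether set
    endo_chain: np.ndarray  # ordered node ids along the contractile endocardium
    cavity_loop: np.ndarray  # ordered node ids of the closed flow compartment
    probe_center: np.ndarray
    reference_center: np.ndarray
    basal_plane_y: float


# ---------------------------------------------------------------------------
# Channel-valve model (valve-only test configuration)
# ---------------------------------------------------------------------------

def build_channel_valve(config: GeometryConfig) -> LagrangianMesh:
    """Two leaflets mounted across a rigid straight channel, chords to anchors.

    The channel runs along +x; leaflets attach at x = annulus and initially
    lie nearly parallel to the (vertical) annulus line, tips tilted slightly
    downstream.
    """
    cfg = config
    b = _Builder()
    yc = cfg.center_y
    w = 2.0 * cfg.gap_half_width  # channel height
    x0, x1 = cfg.center_x - 4.0, cfg.center_x + 4.0
    x_ann = cfg.center_x - 1.5
    if w <= cfg.anterior_length + cfg.posterior_length - 1.0:
        raise InfeasibleGeometryError("leaflets overlap across the channel")

    def wall(y: float, normal_sign: float) -> np.ndarray:
        cl = _resample(np.array([[x0, y], [x1, y]]), cfg.ds_wall)
        normals = np.tile([0.0, normal_sign], (len(cl), 1))
        return _band(
            b, cl, normals, cfg.tract_wall_thickness, cfg.n_wall_layers,
            region_fn=lambda c: Region.TRACT_INFLOW.value,
            frame_fn=lambda t, d, c: (t, np.array([-t[1], t[0]]), d),
        )

    wall(yc + w / 2.0, 1.0)
    wall(yc - w / 2.0, -1.0)

    tilt = np.deg2rad(5.0)
    d_top = np.array([np.sin(tilt), -np.cos(tilt)])  # from top wall, downward
    d_bot = np.array([np.sin(tilt), np.cos(tilt)])
    ant = _add_leaflet(
        b, np.array([x_ann, yc + w / 2.0]), d_top, cfg.anterior_length,
        cfg.leaflet_thickness, cfg.ds_leaflet, Region.LEAFLET_ANTERIOR.value,
    )
    post = _add_leaflet(
        b, np.array([x_ann, yc - w / 2.0]), d_bot, cfg.posterior_length,
        cfg.leaflet_thickness, cfg.ds_leaflet, Region.LEAFLET_POSTERIOR.value,
    )
    n_half = cfg.n_chordae // 2
    _attach_chordae(b, ant, np.array([x_ann + 2.5, yc + 0.8]), n_half, 1.35)
    _attach_chordae(b, post, np.array([x_ann + 2.5, yc - 0.8]), n_half, 1.35)
    mesh = b.build()
    return _apply_jitter(mesh, cfg)


# ---------------------------------------------------------------------------
# LV chamber model
# ---------------------------------------------------------------------------

def build_lv_chamber(
    config: GeometryConfig, tether_params: TetherParams | None = None
) -> tuple[LagrangianMesh, ChamberApparatus]:
    """The coupled valve-in-chamber model with tether targets and tract planes."""
    cfg = config
    b = _Builder()
    cx, cy = cfg.center_x, cfg.center_y
    ah, av_ = cfg.short_axis, cfg.long_axis
    if cfg.gap_half_width >= ah:
        raise InfeasibleGeometryError("basal opening exceeds the cavity width")

    # --- elliptical wall band (open at the basal gap) --------------------
    phi_gap = np.arcsin(cfg.gap_half_width / ah)
    phi = np.linspace(phi_gap, 2.0 * np.pi - phi_gap, 720)
    cl = np.stack([cx + ah * np.sin(phi), cy + av_ * np.cos(phi)], axis=1)
    cl = _resample(cl, cfg.ds_wall)
    rel = (cl - [cx, cy]) / [ah**2, av_**2]
    normals = rel / np.linalg.norm(rel, axis=1, keepdims=True)

    def wall_region(c: np.ndarray) -> str:
        return (Region.WALL_CONTRACTILE.value if c[1] < cfg.basal_plane_y
                else Region.WALL_PASSIVE.value)

    def wall_frame(t: np.ndarray, d: float, c: np.ndarray):
        f0, s0 = fibre_field(t[None, :], np.array([d]))
        return f0[0], s0[0], d

    wall_idx = _band(b, cl, normals, cfg.wall_thickness, cfg.n_wall_layers,
                     wall_region, wall_frame)

    # --- vertical tract/housing bands ------------------------------------
    pill_half = cfg.pillar_thickness / 2.0
    ch_w = cfg.gap_half_width - pill_half - cfg.tract_wall_thickness / 2.0
    mv_inner = cx - pill_half - ch_w  # left edge of the inflow channel
    av_inner = cx + pill_half + ch_w
    y_wall_end = cy + av_ * np.cos(phi_gap)

    def vband(x: float, y_from: float, region_of_y) -> np.ndarray:
        cl_v = _resample(np.array([[x, y_from], [x, cfg.tract_top_y]]), cfg.ds_wall)
        normals_v = np.tile([1.0, 0.0], (len(cl_v), 1))
        return _band(
            b, cl_v, normals_v, cfg.tract_wall_thickness, cfg.n_wall_layers,
            region_fn=lambda c: region_of_y(c[1]),
            frame_fn=lambda t, d, c: (t, np.array([-t[1], t[0]]), d),
        )

    def housing_or(tract: str):
        return lambda y: Region.WALL_PASSIVE.value if y < cfg.annulus_y else tract

    left_idx = vband(mv_inner - cfg.tract_wall_thickness / 2.0, y_wall_end - 0.35,
                     housing_or(Region.TRACT_INFLOW.value))
    right_idx = vband(av_inner + cfg.tract_wall_thickness / 2.0, y_wall_end - 0.35,
                      housing_or(Region.TRACT_OUTFLOW.value))

    # central pillar between the tracts (aorto-mitral continuity / housing)
    cl_p = _resample(np.array([[cx, cfg.annulus_y], [cx, cfg.tract_top_y]]), cfg.ds_wall)
    normals_p = np.tile([1.0, 0.0], (len(cl_p), 1))
    pillar_idx = _band(
        b, cl_p, normals_p, cfg.pillar_thickness, cfg.n_wall_layers,
        region_fn=lambda c: (Region.WALL_PASSIVE.value if c[1] < cfg.annulus_y + 0.8
                             else Region.TRACT_OUTFLOW.value),
        frame_fn=lambda t, d, c: (t, np.array([-t[1], t[0]]), d),
    )

    # --- mitral leaflets + chordae ---------------------------------------
    ant_root = np.array([cx - pill_half, cfg.annulus_y])
    post_root = np.array([mv_inner, cfg.annulus_y])
    # open (diastolic) position: leaflets hang along the flow direction at the
    # channel edges, leaving the orifice clear
    d_ant = np.array([0.02, -1.0])
    d_post = np.array([-0.02, -1.0])
    ant_idx = _add_leaflet(b, ant_root, d_ant, cfg.anterior_length,
                           cfg.leaflet_thickness, cfg.ds_leaflet,
                           Region.LEAFLET_ANTERIOR.value)
    post_idx = _add_leaflet(b, post_root, d_post, cfg.posterior_length,
                            cfg.leaflet_thickness, cfg.ds_leaflet,
                            Region.LEAFLET_POSTERIOR.value)
    n_half = cfg.n_chordae // 2
    ant_anchor = np.array([cx - 0.8, cy - 0.6])
    post_anchor = np.array([mv_inner + 0.3, cy - 0.4])
    _attach_chordae(b, ant_idx, ant_anchor, n_half, 1.35)
    _attach_chordae(b, post_idx, post_anchor, n_half, 1.35)

    mesh = _apply_jitter(b.build(), cfg)

    # --- apparatus --------------------------------------------------------
    apparatus = _make_apparatus(
        mesh, cfg, wall_idx, left_idx, right_idx, pillar_idx, tether_params
    )
    return mesh, apparatus


def _apply_jitter(mesh: LagrangianMesh, cfg: GeometryConfig) -> LagrangianMesh:
    if cfg.jitter <= 0.0:
        return mesh
    rng = np.random.default_rng(cfg.seed)
    X = mesh.X.copy()
    free = ~mesh.pinned_mask
    X[free] += rng.uniform(-cfg.jitter, cfg.jitter, size=X[free].shape)
    return LagrangianMesh(
        X=X, chi=X.copy(), tris=mesh.tris, tri_region=mesh.tri_region,
        frame_f=mesh.frame_f, frame_s=mesh.frame_s, transmural=mesh.transmural,
        chords=mesh.chords, chord_region=mesh.chord_region, pinned=mesh.pinned,
        chord_L0=mesh.chord_L0,
    )


def _make_apparatus(
    mesh: LagrangianMesh,
    cfg: GeometryConfig,
    wall_idx: np.ndarray,
    left_idx: np.ndarray,
    right_idx: np.ndarray,
    pillar_idx: np.ndarray,
    tether_params: TetherParams | None = None,
) -> ChamberApparatus:
    tp = tether_params or TetherParams()
    X = mesh.X
    cx = cfg.center_x
    pill_half = cfg.pillar_thickness / 2.0
    ch_w = cfg.gap_half_width - pill_half - cfg.tract_wall_thickness / 2.0
    mv_inner = cx - pill_half - ch_w
    av_inner = cx + pill_half + ch_w

    mv_plane = PlaneDef(x_left=mv_inner, x_right=cx - pill_half, y=cfg.plane_y)
    av_plane = PlaneDef(x_left=cx + pill_half, x_right=av_inner, y=cfg.plane_y)

    # --- tether sets ------------------------------------------------------
    band_nodes = np.unique(np.concatenate([
        left_idx.ravel(), right_idx.ravel(), pillar_idx.ravel()
    ]))
    wall_nodes = np.unique(wall_idx.ravel())
    # the wall's basal ends overlap (and are fixed to) the housing bands;
    # treating them as soft lets the free ends crumple against the rigid bands
    phi_gap = np.arcsin(cfg.gap_half_width / cfg.short_axis)
    y_rigid = cfg.center_y + cfg.long_axis * np.cos(phi_gap) - 0.35
    wall_ends = wall_nodes[X[wall_nodes, 1] >= y_rigid]
    rigid = np.unique(np.concatenate([
        band_nodes[X[band_nodes, 1] >= cfg.annulus_y], wall_ends
    ]))
    housing = band_nodes[X[band_nodes, 1] < cfg.annulus_y]
    wall_valvular = wall_nodes[
        (X[wall_nodes, 1] >= cfg.basal_plane_y) & (X[wall_nodes, 1] < y_rigid)
    ]
    valvular = np.unique(np.concatenate([housing, wall_valvular]))
    basal = wall_nodes[np.abs(X[wall_nodes, 1] - cfg.basal_plane_y) <= cfg.ds_wall]

    tethers = [
        TetherSet(nodes=rigid, targets=X[rigid], k=tp.k_tract, mode="full"),
        TetherSet(nodes=valvular, targets=X[valvular], k=tp.k_valve_soft,
                  mode="full", cap=tp.valve_cap, cap_hardening=tp.cap_hardening),
        TetherSet(nodes=basal, targets=X[basal], k=tp.k_basal, mode="vertical"),
    ]

    # --- endocardial chain (inner layer of the contractile wall) ----------
    # band layer 0 sits on the -normal side; wall normals point outward, so
    # layer 0 is the endocardial surface
    inner = wall_idx[:, 0]
    keep = X[inner, 1] < cfg.basal_plane_y
    # contiguous run around the apex
    endo_chain = inner[keep]

    # --- cavity loop ------------------------------------------------------
    def column(idx_grid: np.ndarray, layer: int, y_max: float, descending: bool):
        col = idx_grid[:, layer]
        col = col[X[col, 1] <= y_max + 1e-9]
        order = np.argsort(X[col, 1])
        if descending:
            order = order[::-1]
        return col[order]

    y_top = cfg.plane_y
    left_in = column(left_idx, left_idx.shape[1] - 1, y_top, descending=True)
    right_in = column(right_idx, 0, y_top, descending=False)
    pillar_right = column(pillar_idx, pillar_idx.shape[1] - 1, y_top, descending=True)
    pillar_left = column(pillar_idx, 0, y_top, descending=False)
    wall_inner_rev = wall_idx[::-1, 0]  # left end -> apex -> right end
    cavity_loop = np.concatenate([
        left_in,  # down the inflow-channel left face
        wall_inner_rev,  # around the cavity
        right_in,  # up the outflow-channel right face
        pillar_right,  # down the pillar right face
        pillar_left,  # up the pillar left face
    ])

    return ChamberApparatus(
        mv_plane=mv_plane,
        av_plane=av_plane,
        tethers=tethers,
        capped_tether_index=1,
        endo_chain=endo_chain,
        cavity_loop=cavity_loop,
        probe_center=np.array([cx, cfg.center_y - 0.5]),
        reference_center=np.array([2.0, 2.0]),
        basal_plane_y=cfg.basal_plane_y,
    )
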