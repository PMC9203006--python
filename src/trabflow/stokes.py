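"""Quasi-steady incompressible Stokes flow on moving 2D domains.

At the scales of the embryonic ventricle (L ~ 40 um, U ~ 1 mm/s,
T = 0.25 s) the Reynolds and Womersley numbers are well below one, so the
flow at each cardiac frame is the steady Stokes solution driven by the
instantaneous wall velocities: grad p = mu lap u, div u = 0, with
prescribed velocity on wall segments and a zero-traction ("do-nothing")
condition carrying a reference pressure on the open segments (inlet or
outlet, switched between diastole and systole; the mouth plane of an
isolated intra-trabecular space). The quasi-steady reduction makes the
viscosity scaling of wall shear stress exact: for fixed kinematics the
velocity field is viscosity-independent and WSS is proportional to mu.

Discretization: inf-sup stable Taylor-Hood elements (quadratic velocity,
linear pressure) on triangles, assembled sparsely and solved directly.
The domain is re-meshed at every frame; the persistent object is the
boundary node identity, onto which wall shear rates are mapped.

Units: lengths um, velocity um/s, viscosity Pa s, shear rate 1/s
(um/s per um is unit-exact), pressure and WSS Pa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import MovingBoundary, wall_velocities
from .meshing import Mesh, mesh_domain

__all__ = [
    "FluidProperties", "OpenSegment", "BoundarySpec", "FlowFrame",
    "CycleResult", "SolverError", "solve_frame", "solve_cycle",
    "wall_shear_rate", "mass_balance", "boundary_tangents",
]

_QP = np.array([[0.5, 0.0], [0.5, 0.5], [0.0, 0.5]])  # mid-edge rule
_QW = np.array([1.0, 1.0, 1.0]) / 6.0                  # weights x |J| = area*1/3


class SolverError(RuntimeError):
    """Singular or ill-posed Stokes problem."""


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid: density 1.025 kg/L; viscosity presets are blood
    plasma (1.5 cP) and whole embryonic blood (7.35 cP)."""

    viscosity: float = 1.5e-3   # Pa s
    density: float = 1025.0     # kg/m^3

    def __post_init__(self):
        if self.viscosity <= 0 or self.density <= 0:
            raise ValueError("viscosity and density must be > 0")

    @classmethod
    def plasma(cls) -> "FluidProperties":
        return cls(viscosity=1.5e-3)

    @classmethod
    def blood(cls) -> "FluidProperties":
        return cls(viscosity=7.35e-3)


@dataclass(frozen=True)
class OpenSegment:
    """Contiguous run of boundary nodes carrying the do-nothing condition
    with reference pressure ``pressure`` (Pa)."""

    name: str
    nodes: np.ndarray
    pressure: float = 0.0


@dataclass
class BoundarySpec:
    """Boundary conditions for one frame: per-boundary-node wall velocity
    (um/s; ignored on open nodes) plus the open segments."""

    wall_velocity: np.ndarray
    open_segments: list[OpenSegment] = field(default_factory=list)

    def open_nodes(self) -> np.ndarray:
        if not self.open_segments:
            return np.empty(0, dtype=int)
        return np.unique(np.concatenate([np.asarray(s.nodes, dtype=int)
                                         for s in self.open_segments]))


@dataclass
class FlowFrame:
    """Solved Stokes field on one frame's mesh: velocity per P2 node
    (vertices first, then edge midpoints) and pressure per vertex."""

    mesh: Mesh
    velocity: np.ndarray
    pressure: np.ndarray
    edges: np.ndarray
    frame: int = 0
    fluid: FluidProperties = FluidProperties()

    @property
    def vertex_velocity(self) -> np.ndarray:
        return self.velocity[: self.mesh.points.shape[0]]


# --------------------------------------------------------------------------
# P2/P1 assembly
# --------------------------------------------------------------------------

def _p2_grads(qp: np.ndarray) -> np.ndarray:
    """Reference gradients of the six P2 basis functions at points (k,2)."""
    xi, eta = qp[:, 0], qp[:, 1]
    l0 = 1.0 - xi - eta
    g = np.zeros((qp.shape[0], 6, 2))
    g[:, 0, 0] = -(4 * l0 - 1); g[:, 0, 1] = -(4 * l0 - 1)
    g[:, 1, 0] = 4 * xi - 1
    g[:, 2, 1] = 4 * eta - 1
    g[:, 3, 0] = 4 * (l0 - xi); g[:, 3, 1] = -4 * xi
    g[:, 4, 0] = 4 * eta;       g[:, 4, 1] = 4 * xi
    g[:, 5, 0] = -4 * eta;      g[:, 5, 1] = 4 * (l0 - eta)
    return g


_G_REF = _p2_grads(_QP)                       # (q,6,2)
_P1_AT_QP = np.stack([1 - _QP[:, 0] - _QP[:, 1], _QP[:, 0], _QP[:, 1]], axis=1)
_G_REF_VERT = _p2_grads(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]))


def _build_edges(triangles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique mesh edges and the per-element local edge->global edge map
    (local edges 01, 12, 20, matching P2 dofs 3, 4, 5)."""
    e = np.concatenate([triangles[:, [0, 1]], triangles[:, [1, 2]],
                        triangles[:, [2, 0]]])
    e_sorted = np.sort(e, axis=1)
    uniq, inv = np.unique(e_sorted, axis=0, return_inverse=True)
    elem_edges = inv.reshape(3, -1).T
    return uniq, elem_edges


def _assemble(mesh: Mesh, mu: float):
    """Sparse blocks of the Taylor-Hood saddle system."""
    tris = mesh.triangles
    pts = mesh.points
    edges, elem_edges = _build_edges(tris)
    nv, ne, nt = pts.shape[0], edges.shape[0], tris.shape[0]
    n2 = nv + ne

    v = pts[tris]                                # (nt,3,2)
    jac = np.stack([v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]], axis=1)  # rows
    det = jac[:, 0, 0] * jac[:, 1, 1] - jac[:, 0, 1] * jac[:, 1, 0]
    inv = np.empty_like(jac)                     # J^{-1}
    inv[:, 0, 0] = jac[:, 1, 1] / det
    inv[:, 0, 1] = -jac[:, 0, 1] / det
    inv[:, 1, 0] = -jac[:, 1, 0] / det
    inv[:, 1, 1] = jac[:, 0, 0] / det

    # physical gradients: d phi_i / d x_b = sum_a gref[i,a] * inv[b,a]
    grad = np.einsum("eba,qia->eqib", inv, _G_REF)
    wdet = np.abs(det)[:, None] * _QW[None, :]   # (nt,q)

    ke = np.einsum("eq,eqia,eqja->eij", wdet, grad, grad)          # (nt,6,6)
    bx = np.einsum("eq,qa,eqi->eai", wdet, _P1_AT_QP, grad[..., 0])  # (nt,3,6)
    by = np.einsum("eq,qa,eqi->eai", wdet, _P1_AT_QP, grad[..., 1])

    dofs = np.concatenate([tris, nv + elem_edges], axis=1)          # (nt,6)
    rows = np.repeat(dofs, 6, axis=1).ravel()
    cols = np.tile(dofs, (1, 6)).ravel()
    K = sp.coo_matrix((ke.ravel() * mu, (rows, cols)), shape=(n2, n2)).tocsr()

    prow = np.repeat(tris, 6, axis=1).ravel()
    pcol = np.tile(dofs, (1, 3)).ravel()
    Bx = sp.coo_matrix((bx.transpose(0, 1, 2).ravel(), (prow, pcol)),
                       shape=(nv, n2)).tocsr()
    By = sp.coo_matrix((by.transpose(0, 1, 2).ravel(), (prow, pcol)),
                       shape=(nv, n2)).tocsr()
    return K, Bx, By, edges


def _edge_midpoint_index(edges: np.ndarray, nv: int):
    """Dict (a,b)->P2 dof index of the edge midpoint."""
    return {(int(a), int(b)): nv + i for i, (a, b) in enumerate(edges)}


def solve_frame(mesh: Mesh, bc: BoundarySpec,
                fluid: FluidProperties = FluidProperties(),
                frame: int = 0) -> FlowFrame:
    """Solve steady Stokes flow on one frame.

    Wall boundary nodes (and wall-edge midpoints) carry the prescribed
    velocity; open segments carry the do-nothing condition with their
    reference pressure. Without any open segment the wall flux must be
    compatible (net zero) and the pressure is gauged at one node.
    """
    # assemble at unit viscosity and solve for the scaled pressure p/mu:
    # the reduced system is then viscosity-independent, so the velocity
    # (and the wall shear *rate*) is bit-identical across viscosities and
    # the WSS viscosity scaling of the quasi-steady model is exact
    mu = fluid.viscosity
    K, Bx, By, edges = _assemble(mesh, 1.0)
    nv = mesh.points.shape[0]
    n2 = K.shape[0]
    ndof = 2 * n2 + nv

    A = sp.bmat([[K, None, -Bx.T], [None, K, -By.T], [Bx, By, None]],
                format="csr")
    rhs = np.zeros(ndof)

    wv = np.asarray(bc.wall_velocity, dtype=float)
    if wv.shape[0] != mesh.n_boundary:
        raise SolverError("wall_velocity must cover every boundary node")
    open_set = set(int(i) for i in bc.open_nodes())
    # transition nodes (an open node flanked by a wall node) carry the wall
    # velocity: a free corner between a no-slip edge and a do-nothing edge
    # would otherwise absorb the wall traction into its weak equation
    neighbor: dict[int, list[int]] = {}
    for loop in mesh.loops:
        for k in range(loop.size):
            i = int(loop[k])
            neighbor[i] = [int(loop[k - 1]), int(loop[(k + 1) % loop.size])]
    interior_open = {i for i in open_set
                     if all(nb in open_set for nb in neighbor.get(i, []))}
    if bc.open_segments and not interior_open:
        raise SolverError("each open segment needs at least three nodes")
    mid_of = _edge_midpoint_index(edges, nv)

    fixed: dict[int, float] = {}
    b_edges = mesh.boundary_edges()
    # outward-normal line integrals for open-segment reference pressure
    for segm in bc.open_segments:
        seg_nodes = set(int(i) for i in segm.nodes)
        if segm.pressure == 0.0:
            continue
        for a, b in b_edges:
            if int(a) in seg_nodes and int(b) in seg_nodes:
                pa, pb = mesh.points[a], mesh.points[b]
                d = pb - pa
                h = float(np.hypot(*d))
                nrm = np.array([d[1], -d[0]]) / h     # outward for CCW shell
                m = mid_of[(min(int(a), int(b)), max(int(a), int(b)))]
                for dof, wgt in ((int(a), h / 6), (int(b), h / 6), (m, 2 * h / 3)):
                    rhs[dof] += -segm.pressure / mu * nrm[0] * wgt
                    rhs[n2 + dof] += -segm.pressure / mu * nrm[1] * wgt

    for i in range(mesh.n_boundary):
        if i not in interior_open:
            fixed[i] = wv[i, 0]
            fixed[n2 + i] = wv[i, 1]
    for a, b in b_edges:
        ia, ib = int(a), int(b)
        if ia in open_set and ib in open_set:
            continue  # natural (do-nothing) edge
        m = mid_of[(min(ia, ib), max(ia, ib))]
        fixed[m] = 0.5 * (wv[ia, 0] + wv[ib, 0])
        fixed[n2 + m] = 0.5 * (wv[ia, 1] + wv[ib, 1])

    if not bc.open_segments:
        # solvability: net wall flux must vanish
        flux = 0.0
        scale = 0.0
        for a, b in b_edges:
            pa, pb = mesh.points[a], mesh.points[b]
            d = pb - pa
            nrm = np.array([d[1], -d[0]])
            um = 0.5 * (wv[a] + wv[b])
            flux += float(um @ nrm)
            scale += float(np.hypot(*d)) * float(np.hypot(*um))
        if abs(flux) > 1e-8 * max(scale, 1e-12):
            raise SolverError(
                f"all-wall boundary with incompatible flux {flux:.3e} um^2/s")
        fixed[2 * n2] = 0.0  # pressure gauge

    fixed_idx = np.fromiter(fixed.keys(), dtype=int)
    fixed_val = np.fromiter(fixed.values(), dtype=float)
    free = np.ones(ndof, dtype=bool)
    free[fixed_idx] = False
    x = np.zeros(ndof)
    x[fixed_idx] = fixed_val
    rhs_f = rhs[free] - A[:, fixed_idx][free] @ fixed_val
    A_ff = A[free][:, free].tocsc()
    try:
        x[free] = spla.spsolve(A_ff, rhs_f)
    except RuntimeError as exc:  # pragma: no cover
        raise SolverError(f"sparse solve failed: {exc}") from exc
    if not np.all(np.isfinite(x)):
        raise SolverError("singular Stokes system (non-finite solution)")

    vel = np.stack([x[:n2], x[n2:2 * n2]], axis=1)
    return FlowFrame(mesh=mesh, velocity=vel, pressure=mu * x[2 * n2:],
                     edges=edges, frame=frame, fluid=fluid)


# --------------------------------------------------------------------------
# wall quantities
# --------------------------------------------------------------------------

def boundary_tangents(points: np.ndarray, loops: list[np.ndarray]
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Unit tangents (traversal direction) and outward-from-fluid normals
    at boundary nodes, from central differences along each loop."""
    n = sum(l.size for l in loops)
    tan = np.zeros((n, 2))
    for loop in loops:
        p = points[loop]
        d = np.roll(p, -1, axis=0) - np.roll(p, 1, axis=0)
        tan[loop] = d / np.linalg.norm(d, axis=1, keepdims=True)
    nrm = np.stack([tan[:, 1], -tan[:, 0]], axis=1)
    return tan, nrm


def wall_shear_rate(ff: FlowFrame, nodes: np.ndarray | None = None
                    ) -> np.ndarray:
    """Signed tangential wall shear rate (1/s) at boundary nodes.

    gamma = t . (2 eps) . n with eps the symmetric velocity gradient
    recovered at each boundary vertex by averaging the elementwise P2
    gradient over incident elements; t is the loop traversal tangent and
    n the outward-from-fluid normal, so the value is frame-indifferent
    under rigid wall translation and equals tau_w / mu.
    """
    mesh = ff.mesh
    if nodes is None:
        nodes = np.arange(mesh.n_boundary)
    nodes = np.asarray(nodes, dtype=int)
    if np.any(nodes >= mesh.n_boundary):
        raise SolverError("requested node is not a boundary node")

    nv = mesh.points.shape[0]
    _, elem_edges = _build_edges(mesh.triangles)
    dofs = np.concatenate([mesh.triangles, nv + elem_edges], axis=1)

    incident: dict[int, list[tuple[int, int]]] = {int(i): [] for i in nodes}
    want = set(int(i) for i in nodes)
    for e, tri in enumerate(mesh.triangles):
        for k in range(3):
            t = int(tri[k])
            if t in want:
                incident[t].append((e, k))

    v = mesh.points[mesh.triangles]
    jac = np.stack([v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]], axis=1)
    det = jac[:, 0, 0] * jac[:, 1, 1] - jac[:, 0, 1] * jac[:, 1, 0]
    inv = np.empty_like(jac)
    inv[:, 0, 0] = jac[:, 1, 1] / det
    inv[:, 0, 1] = -jac[:, 0, 1] / det
    inv[:, 1, 0] = -jac[:, 1, 0] / det
    inv[:, 1, 1] = jac[:, 0, 0] / det

    loops = ff.mesh.loops
    tan, nrm = boundary_tangents(mesh.points, loops)

    gamma = np.zeros(nodes.size)
    for out_i, node in enumerate(nodes):
        grads = []
        for (e, k) in incident[int(node)]:
            gref = _G_REF_VERT[k]                       # (6,2)
            gphys = gref @ inv[e].T                     # d/dx, d/dy per basis
            ue = ff.velocity[dofs[e]]                   # (6,2)
            grads.append(gphys.T @ ue)                  # (2,2): [d/dxi][comp]
        if not grads:
            continue
        gu = np.mean(grads, axis=0)                     # gu[i,j] = d u_j / d x_i
        eps2 = gu + gu.T                                # 2 * sym grad
        gamma[out_i] = float(tan[node] @ eps2 @ nrm[node])
    return gamma


def open_boundary_flux(ff: FlowFrame, bc: BoundarySpec,
                       relative_to: np.ndarray | None = None) -> float:
    """Net outward volume flux (um^2/s) through the open segments,
    integrated with the quadratic boundary trace. With ``relative_to`` set
    to the prescribed boundary velocity the flux is measured relative to
    the moving opening, which is the quantity incompressibility ties to
    the domain area rate."""
    mesh = ff.mesh
    nv = mesh.points.shape[0]
    mid_of = _edge_midpoint_index(ff.edges, nv)
    flux = 0.0
    for segm in bc.open_segments:
        seg = set(int(i) for i in segm.nodes)
        for a, b in mesh.boundary_edges():
            ia, ib = int(a), int(b)
            if ia in seg and ib in seg:
                d = mesh.points[ib] - mesh.points[ia]
                nrm = np.array([d[1], -d[0]])           # length-weighted
                m = mid_of[(min(ia, ib), max(ia, ib))]
                ua, um, ub = ff.velocity[ia], ff.velocity[m], ff.velocity[ib]
                if relative_to is not None:
                    ua = ua - relative_to[ia]
                    ub = ub - relative_to[ib]
                    um = um - 0.5 * (relative_to[ia] + relative_to[ib])
                flux += (ua @ nrm + 4 * (um @ nrm) + ub @ nrm) / 6.0
    return float(flux)


def mass_balance(ff: FlowFrame, bc: BoundarySpec, dadt: float,
                 eps: float = 1e-9) -> float:
    """Mass-conservation residual |Q_open + dA/dt| / max(|dA/dt|, eps).

    Q_open is the open-segment flux relative to the moving opening;
    expansion of the domain (dA/dt > 0) must be balanced by net relative
    inflow through the open segments.
    """
    q = open_boundary_flux(ff, bc, relative_to=bc.wall_velocity)
    return abs(q + dadt) / max(abs(dadt), eps)


# --------------------------------------------------------------------------
# full-cycle driver
# --------------------------------------------------------------------------

@dataclass
class CycleResult:
    """Wall shear rate series on the persistent boundary nodes, plus the
    per-frame flow fields and solver audit numbers."""

    boundary: MovingBoundary
    fluid: FluidProperties
    gamma: np.ndarray                 # (n_frames, n_nodes) signed, 1/s
    tangents: np.ndarray              # (n_frames, n_nodes, 2)
    mass_residuals: np.ndarray        # (n_frames,)
    reynolds: float
    womersley: float
    frames: list[FlowFrame] | None = None

    @property
    def quasi_steady_valid(self) -> bool:
        return self.reynolds < 1.0 and self.womersley < 1.0

    def times(self) -> np.ndarray:
        return self.boundary.phases() * self.boundary.cycle_duration


def default_schedule(mb: MovingBoundary, frame: int) -> list[str]:
    """Phase-switched openings: an isolated groove's mouth is always the
    zero-reference-pressure boundary; for the whole ventricle the inlet is
    open while the chamber fills (dA/dt > 0) and the outlet while it
    ejects, per the valve-less switching of the imaging study."""
    if "mouth" in mb.openings:
        return ["mouth"]
    areas = mb.areas()
    dadt = areas[(frame + 1) % mb.n_frames] - areas[(frame - 1) % mb.n_frames]
    return ["inlet"] if dadt > 0 else ["outlet"]


def solve_cycle(mb: MovingBoundary,
                fluid: FluidProperties = FluidProperties(),
                resolution: float | None = None,
                schedule=default_schedule,
                keep_frames: bool = False) -> CycleResult:
    """Quasi-steady Stokes solve of a full cardiac cycle.

    Re-meshes the fluid domain at every frame, prescribes the periodic
    central-difference wall velocities, and maps signed wall shear rates
    back onto the persistent boundary node identity.
    """
    n = mb.n_frames
    n_nodes = mb.n_nodes
    gamma = np.zeros((n, n_nodes))
    tangents = np.zeros((n, n_nodes, 2))
    residuals = np.zeros(n)
    frames: list[FlowFrame] = []
    areas = mb.areas()
    umax = 0.0

    for f in range(n):
        shell = mb.loop_coords(f, 0)
        holes = [mb.loop_coords(f, i) for i in range(1, len(mb.loops))]
        try:
            mesh = mesh_domain(shell, holes, resolution=resolution)
        except Exception as exc:
            raise SolverError(f"remeshing failed at frame {f}: {exc}") from exc
        mesh.loops = [np.asarray(l) for l in mb.loops]

        wv = wall_velocities(mb, f)
        umax = max(umax, float(np.max(np.linalg.norm(wv, axis=1))))
        open_names = schedule(mb, f)
        segs = [OpenSegment(name, mb.openings[name]) for name in open_names]
        bc = BoundarySpec(wall_velocity=wv, open_segments=segs)
        ff = solve_frame(mesh, bc, fluid, frame=f)
        gamma[f] = wall_shear_rate(ff)
        tangents[f], _ = boundary_tangents(mesh.points, mesh.loops)
        dadt = (areas[(f + 1) % n] - areas[(f - 1) % n]) / (2 * mb.dt)
        dadt_all = (np.roll(areas, -1) - np.roll(areas, 1)) / (2 * mb.dt)
        # normalize near-extremum frames (dA/dt ~ 0) by the cycle peak rate
        floor = 0.05 * float(np.max(np.abs(dadt_all)))
        residuals[f] = mass_balance(ff, bc, dadt, eps=max(floor, 1e-9)) \
            if segs else 0.0
        if keep_frames:
            frames.append(ff)

    lchar = 2.0 * math.sqrt(float(np.max(areas)) / math.pi) * 1e-6  # m
    uchar = umax * 1e-6                                             # m/s
    re = fluid.density * uchar * lchar / fluid.viscosity
    wo = (lchar / 2.0) * math.sqrt(
        2 * math.pi / mb.cycle_duration * fluid.density / fluid.viscosity)
    return CycleResult(boundary=mb, fluid=fluid, gamma=gamma,
                       tangents=tangents, mass_residuals=residuals,
                       reynolds=re, womersley=wo,
                       frames=frames if keep_frames else None)
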