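"""Axisymmetric linear magnetostatics for the permeable-core devices.

Solves for the scaled azimuthal vector potential u = r * A_phi on the (r, z)
half-plane with first-order triangular elements:

    div( (1 / (mu0 mu_r r)) grad u ) = -J_phi,     u = 0 on axis & far boundary

so that B_r = -(1/r) du/dz and B_z = (1/r) du/dr.  Working with u instead of
A_phi removes the 1/r singularity at the axis (u ~ r^2 near r = 0).  The
element coefficient 1/(mu0 mu_r r) is evaluated at triangle centroids.

Meshes are graded quadtree point clouds triangulated with Delaunay: fine near
the device (and extra-fine at rod tips), growing geometrically toward a far
Dirichlet boundary.  A structured ``rectangle_mesh`` helper exists for
verification problems.  Materials are linear; a warning is logged when the
computed core field exceeds 0.5 T, where real mu-metal and ferrite saturate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import Delaunay

from .errors import MeshError, SolverError
from .fieldmaps import LineScan
from .geometry import CircularCoilSpec, DriveCondition, PotCoreSpec, RodCoreSpec

logger = logging.getLogger(__name__)

MU0 = 4e-7 * math.pi

REGION_AIR = 0
REGION_CORE = 1
REGION_COIL = 2

#: flux density above which real mu-metal / ferrite saturates (linear model
#: keeps going; we warn)
SATURATION_WARN_T = 0.5


# ---------------------------------------------------------------------------
# mesh container
# ---------------------------------------------------------------------------

@dataclass
class AxisymMesh:
    """Triangulated (r, z) half-plane with per-triangle material labels."""

    nodes: np.ndarray        # (n, 2) r, z in metres; r >= 0
    triangles: np.ndarray    # (m, 3) node indices, CCW
    region: np.ndarray       # (m,) ints in {REGION_AIR, REGION_CORE, REGION_COIL}
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.region = np.asarray(self.region, dtype=np.int64)
        if np.any(self.nodes[:, 0] < -1e-12):
            raise MeshError("mesh nodes must have r >= 0")
        if np.any(self.areas() <= 0):
            raise MeshError("mesh contains degenerate or inverted triangles")

    def areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                      - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))

    def centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)

    def aspect_ratios(self) -> np.ndarray:
        """Longest edge squared over twice the area (2 for a right isoceles)."""
        p = self.nodes[self.triangles]
        e = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 1], p[:, 0] - p[:, 2]])
        lmax = np.sqrt((e ** 2).sum(-1)).max(axis=0)
        return lmax ** 2 / (2.0 * self.areas())

    def boundary_nodes(self) -> np.ndarray:
        """Nodes on the rectangular domain boundary (axis, far edges)."""
        r, z = self.nodes[:, 0], self.nodes[:, 1]
        span = max(r.max() - r.min(), z.max() - z.min())
        tol = 1e-9 * span
        on = ((r < r.min() + tol) | (r > r.max() - tol)
              | (z < z.min() + tol) | (z > z.max() - tol))
        return np.nonzero(on)[0]


def rectangle_mesh(rmin: float, rmax: float, zmin: float, zmax: float,
                   nr: int, nz: int) -> AxisymMesh:
    """Structured mesh of a rectangle: (nr+1)(nz+1) nodes, 2*nr*nz triangles.

    Used for manufactured-solution verification; every triangle is labelled
    air.
    """
    r = np.linspace(rmin, rmax, nr + 1)
    z = np.linspace(zmin, zmax, nz + 1)
    R, Z = np.meshgrid(r, z, indexing="ij")
    nodes = np.column_stack([R.ravel(), Z.ravel()])

    def nid(i, j):
        return i * (nz + 1) + j

    tris = []
    for i in range(nr):
        for j in range(nz):
            a, b = nid(i, j), nid(i + 1, j)
            c, d = nid(i + 1, j + 1), nid(i, j + 1)
            if (i + j) % 2 == 0:
                tris += [[a, b, c], [a, c, d]]
            else:
                tris += [[a, b, d], [b, c, d]]
    tris = np.asarray(tris)
    return AxisymMesh(nodes, tris, np.zeros(len(tris), dtype=np.int64))


# ---------------------------------------------------------------------------
# device geometry adapters
# ---------------------------------------------------------------------------

def _dist_box(r, z, r0, r1, z0, z1):
    dr = np.maximum(np.maximum(r0 - r, r - r1), 0.0)
    dz = np.maximum(np.maximum(z0 - z, z - z1), 0.0)
    return np.hypot(dr, dz)


class _AxiGeometry:
    """Labels (r, z) points with material regions and provides a mesh size
    field graded away from the device."""

    def __init__(self, device, target_edge: float):
        self.device = device
        self.h = target_edge
        if isinstance(device, RodCoreSpec):
            c = device.coil
            self.extent = max(device.core_length / 2, c.outer_radius,
                              abs(c.axial_center) + c.height / 2)
            self._box = (0.0, c.outer_radius + 2e-3,
                         -device.core_length / 2 - 2e-3,
                         device.core_length / 2 + 2e-3)
            self._tips = [(0.0, device.core_length / 2),
                          (0.0, -device.core_length / 2)]
            self._corridor = (0.0, 3e-3, self._box[2] - 45e-3,
                              self._box[3] + 45e-3)
        elif isinstance(device, PotCoreSpec):
            r_out = device.outer_diameter / 2
            self.extent = max(r_out, device.height / 2, device.coil.outer_radius)
            self._box = (0.0, self.extent + 2e-3,
                         -device.height / 2 - 2e-3, device.height / 2 + 2e-3)
            self._tips = []
            self._corridor = (0.0, 3e-3, self._box[2] - 45e-3,
                              self._box[3] + 45e-3)
        elif isinstance(device, CircularCoilSpec):
            self.extent = max(device.outer_radius,
                              abs(device.axial_center) + device.height / 2)
            self._box = (0.0, device.outer_radius + 2e-3,
                         device.axial_center - device.height / 2 - 2e-3,
                         device.axial_center + device.height / 2 + 2e-3)
            self._tips = []
            self._corridor = (0.0, 3e-3, self._box[2] - 45e-3,
                              self._box[3] + 45e-3)
        else:
            raise TypeError(f"unsupported device type {type(device).__name__}")

    # -- labelling ----------------------------------------------------------

    def label(self, r: np.ndarray, z: np.ndarray) -> np.ndarray:
        out = np.full(r.shape, REGION_AIR, dtype=np.int64)
        d = self.device
        coil = d if isinstance(d, CircularCoilSpec) else d.coil
        in_coil = ((r >= coil.inner_radius) & (r <= coil.outer_radius)
                   & (np.abs(z - coil.axial_center) <= coil.height / 2))
        if isinstance(d, RodCoreSpec):
            prof = np.array([d.core_radius_at(zz) for zz in np.atleast_1d(z)])
            in_core = (np.abs(z) <= d.core_length / 2) & (r <= prof)
        elif isinstance(d, PotCoreSpec):
            r_out = d.outer_diameter / 2
            inside = (r <= r_out) & (np.abs(z) <= d.height / 2)
            in_channel = ((r >= d.channel_inner_radius)
                          & (r <= d.channel_outer_radius)
                          & (z >= d.height / 2 - d.channel_depth)
                          & (z <= d.height / 2))
            in_core = inside & ~in_channel
        else:
            in_core = np.zeros(r.shape, dtype=bool)
        out[in_core] = REGION_CORE
        out[in_coil] = REGION_COIL
        return out

    # -- size field ---------------------------------------------------------

    def size_field(self, r: np.ndarray, z: np.ndarray, h_max: float) -> np.ndarray:
        r0, r1, z0, z1 = self._box
        h = np.minimum(h_max, self.h + 0.5 * _dist_box(r, z, r0, r1, z0, z1))
        # near-axis corridor: on-axis fields are recovered from u/r^2 close to
        # r = 0, which needs resolved elements all along the scan line
        cr0, cr1, cz0, cz1 = self._corridor
        h = np.minimum(h, self.h / 2 + 0.5 * _dist_box(r, z, cr0, cr1, cz0, cz1))
        if isinstance(self.device, PotCoreSpec):
            d = self.device
            hc = self.h / 4 + 0.4 * _dist_box(r, z, 0.0, d.outer_diameter / 2,
                                              -d.height / 2, d.height / 2)
            h = np.minimum(h, hc)
        for (tr, tz) in self._tips:
            ht = self.h / 8 + 0.3 * np.hypot(r - tr, z - tz)
            h = np.minimum(h, ht)
        return h


# ---------------------------------------------------------------------------
# quadtree meshing
# ---------------------------------------------------------------------------

def _quadtree_points(geom: _AxiGeometry, R: float, h_min_cap: float = 1e-5
                     ) -> np.ndarray:
    """Corner points of a 2:1-balanced quadtree over [0,R] x [-R,R].

    The half-plane is two root squares of size R (z >= 0 and z <= 0).  Cells
    subdivide until their size satisfies the geometry's size field.
    """
    h_max = R / 8.0
    max_level = 24
    # leaves / internal keyed by (block, level, i, j); block 0: z in [0,R]
    leaves: set = {(0, 0, 0, 0), (1, 0, 0, 0)}
    internal: set = set()

    def cell_box(key):
        b, l, i, j = key
        s = R / (1 << l)
        x0 = i * s
        y0 = j * s if b == 0 else -R + j * s
        return x0, y0, s

    def split(key):
        leaves.discard(key)
        internal.add(key)
        b, l, i, j = key
        for di in (0, 1):
            for dj in (0, 1):
                leaves.add((b, l + 1, 2 * i + di, 2 * j + dj))

    # size-driven refinement
    queue = list(leaves)
    while queue:
        key = queue.pop()
        if key not in leaves:
            continue
        b, l, i, j = key
        x0, y0, s = cell_box(key)
        if l >= max_level or s <= h_min_cap:
            continue
        cx, cy = x0 + s / 2, y0 + s / 2
        h = float(geom.size_field(np.array([cx]), np.array([cy]), h_max)[0])
        if s > h:
            split(key)
            for di in (0, 1):
                for dj in (0, 1):
                    queue.append((b, l + 1, 2 * i + di, 2 * j + dj))

    # 2:1 balance: a leaf must not touch leaves two or more levels finer
    def neighbors(key):
        b, l, i, j = key
        n = 1 << l
        out = []
        if i > 0:
            out.append((b, l, i - 1, j))
        if i < n - 1:
            out.append((b, l, i + 1, j))
        if j > 0:
            out.append((b, l, i, j - 1))
        elif b == 0:
            out.append((1, l, i, n - 1))  # cross z = 0 downward
        if j < n - 1:
            out.append((b, l, i, j + 1))
        elif b == 1:
            out.append((0, l, i, 0))      # cross z = 0 upward
        return out

    changed = True
    while changed:
        changed = False
        for key in list(leaves):
            if key not in leaves:
                continue
            b, l, i, j = key
            for nb in neighbors(key):
                # neighbour subdivided (has children); if any child adjacent
                # to us is itself subdivided, imbalance is 2+ levels
                if nb in internal:
                    nb_b, nb_l, nb_i, nb_j = nb
                    kids = [(nb_b, nb_l + 1, 2 * nb_i + di, 2 * nb_j + dj)
                            for di in (0, 1) for dj in (0, 1)]
                    if any(k in internal for k in kids):
                        split(key)
                        changed = True
                        break

    pts = []
    for key in leaves:
        x0, y0, s = cell_box(key)
        pts += [(x0, y0), (x0 + s, y0), (x0, y0 + s), (x0 + s, y0 + s)]
    pts = np.asarray(pts)
    # dedupe exactly (quadtree corners are dyadic fractions of R -> exact)
    pts = np.unique(np.round(pts / R * (1 << 26)).astype(np.int64), axis=0)
    return pts.astype(float) * R / (1 << 26)


def build_mesh(device, far_boundary_factor: float = 5.0,
               target_edge: float | None = None) -> AxisymMesh:
    """Graded triangulation of the half-plane around a device.

    The domain is [0, F*E] x [-F*E, F*E] with F the far-boundary factor and E
    the device extent; the far Dirichlet boundary sits at >= F*E in every
    direction.  Local edge lengths reach target_edge/8 at rod tips.
    """
    if far_boundary_factor < 3:
        raise ValueError("far_boundary_factor must be >= 3")
    if target_edge is None:
        target_edge = 1.2e-3 if isinstance(device, RodCoreSpec) else 0.8e-3
    if target_edge <= 0:
        raise ValueError("target_edge must be positive")

    geom = _AxiGeometry(device, target_edge)
    R = far_boundary_factor * geom.extent
    pts = _quadtree_points(geom, R)
    tri = Delaunay(pts)
    simplices = tri.simplices.copy()

    p = pts[simplices]
    areas = 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                   - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    flip = areas < 0
    simplices[flip] = simplices[flip][:, ::-1]
    keep = np.abs(areas) > 1e-14 * R * R
    simplices = simplices[keep]

    cent = pts[simplices].mean(axis=1)
    region = geom.label(cent[:, 0], cent[:, 1])
    mesh = AxisymMesh(pts, simplices, region,
                      metadata={"far_boundary_factor": far_boundary_factor,
                                "target_edge": target_edge,
                                "domain_half_width": R,
                                "device": type(device).__name__})
    if isinstance(device, PotCoreSpec):
        mesh.metadata["pot_core_inferred"] = {
            "center_post_radius_mm": device.center_post_radius / 1e-3,
            "shield_thickness_mm": device.shield_thickness / 1e-3,
            "base_thickness_mm": (device.height - device.channel_depth) / 1e-3,
        }
    return mesh


def write_gmsh(mesh: AxisymMesh, path) -> None:
    """Export in Gmsh 2.2 ASCII (z stored as the y coordinate, third = 0)."""
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write(f"$Nodes\n{len(mesh.nodes)}\n")
        for k, (r, z) in enumerate(mesh.nodes, start=1):
            fh.write(f"{k} {r:.12g} {z:.12g} 0\n")
        fh.write("$EndNodes\n")
        fh.write(f"$Elements\n{len(mesh.triangles)}\n")
        for k, (tri, reg) in enumerate(zip(mesh.triangles, mesh.region), start=1):
            a, b, c = (int(t) + 1 for t in tri)
            fh.write(f"{k} 2 2 {int(reg)} {int(reg)} {a} {b} {c}\n")
        fh.write("$EndElements\n")


# ---------------------------------------------------------------------------
# materials & solution
# ---------------------------------------------------------------------------

@dataclass
class MaterialMap:
    """Per-region relative permeability and azimuthal current density."""

    mu_r: dict
    current_density: dict  # region -> J_phi (A/m^2)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for reg, mu in self.mu_r.items():
            if mu < 1:
                raise ValueError(f"mu_r for region {reg} must be >= 1")
        for reg, J in self.current_density.items():
            if J != 0.0 and reg != REGION_COIL:
                raise ValueError("current density only allowed in coil regions")


def materials_for(device, drive: DriveCondition, mesh: AxisymMesh,
                  mu_r_override: float | None = None) -> MaterialMap:
    """Material map for a meshed device: core permeability plus a coil
    current density chosen so the meshed ampere-turns equal N*I exactly."""
    coil = device if isinstance(device, CircularCoilSpec) else device.coil
    coil_area = float(mesh.areas()[mesh.region == REGION_COIL].sum())
    if coil_area <= 0:
        raise SolverError("mesh has no driven coil region")
    I = drive.effective_current
    J = coil.turns * I / coil_area
    mu_core = 1.0
    if isinstance(device, (RodCoreSpec, PotCoreSpec)):
        mu_core = device.relative_permeability if mu_r_override is None else mu_r_override
    return MaterialMap(
        mu_r={REGION_AIR: 1.0, REGION_CORE: mu_core, REGION_COIL: 1.0},
        current_density={REGION_AIR: 0.0, REGION_CORE: 0.0, REGION_COIL: J},
        metadata={"ampere_turns": coil.turns * I, "meshed_coil_area": coil_area})


@dataclass
class AxisymSolution:
    """Nodal u = r*A_phi plus derived per-element flux density."""

    mesh: AxisymMesh
    materials: MaterialMap
    u: np.ndarray             # (n,) T*m^2 (r * A_phi)
    b_elements: np.ndarray    # (m, 2): B_r, B_z per triangle, T

    _interp: Optional[LinearNDInterpolator] = None

    def u_at(self, r, z):
        """Linear interpolation of u at arbitrary (r, z)."""
        if self._interp is None:
            self._interp = LinearNDInterpolator(self.mesh.nodes, self.u,
                                                fill_value=0.0)
        return self._interp(np.column_stack([np.atleast_1d(r), np.atleast_1d(z)]))

    def b_axis(self, z_values, r_probe: float = 0.8e-3) -> np.ndarray:
        """On-axis B_z extrapolated from the near-axis potential.

        Near the axis u = (B/2) r^2 + c r^4; B is recovered by least-squares
        over a band of probe radii around ``r_probe`` (averaging out P1
        interpolation noise rather than trusting two samples).
        """
        z = np.atleast_1d(np.asarray(z_values, dtype=float))
        radii = r_probe * np.linspace(0.7, 3.0, 8)
        U = np.array([self.u_at(np.full_like(z, r), z) for r in radii])
        A = np.column_stack([radii ** 2 / 2, radii ** 4])
        coef, *_ = np.linalg.lstsq(A, U, rcond=None)
        return coef[0]

    def stored_energy(self) -> float:
        """Total magnetic energy (J): 2*pi integral of B^2/(2 mu) r dr dz."""
        areas = self.mesh.areas()
        rc = self.mesh.centroids()[:, 0]
        mu = MU0 * np.array([self.materials.mu_r[r] for r in self.mesh.region])
        b2 = (self.b_elements ** 2).sum(axis=1)
        return float(2 * np.pi * np.sum(0.5 * b2 / mu * rc * areas))


def assemble(mesh: AxisymMesh, materials: MaterialMap):
    """Stiffness matrix and load vector of the Galerkin system (pre-BC)."""
    nodes, tris = mesh.nodes, mesh.triangles
    p = nodes[tris]
    areas = mesh.areas()
    cent = mesh.centroids()

    mu = np.array([materials.mu_r[r] for r in mesh.region])
    coeff = 1.0 / (MU0 * mu * np.maximum(cent[:, 0], 1e-300))

    # P1 gradients: grad N_i = (b_i, c_i) / (2A)
    x, y = p[..., 0], p[..., 1]
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)

    Ke = coeff[:, None, None] * (b[:, :, None] * b[:, None, :]
                                 + c[:, :, None] * c[:, None, :]) \
        / (4.0 * areas[:, None, None])

    rows = np.repeat(tris, 3, axis=1).reshape(-1)
    cols = np.tile(tris, (1, 3)).reshape(-1)
    K = sp.coo_matrix((Ke.reshape(-1), (rows, cols)),
                      shape=(len(nodes), len(nodes))).tocsr()

    J = np.array([materials.current_density[r] for r in mesh.region])
    f = np.zeros(len(nodes))
    np.add.at(f, tris.reshape(-1), np.repeat(J * areas / 3.0, 3))
    return K, f


def solve(mesh: AxisymMesh, materials: MaterialMap,
          dirichlet: Optional[tuple[np.ndarray, np.ndarray]] = None
          ) -> AxisymSolution:
    """Solve the axisymmetric magnetostatic problem.

    ``dirichlet`` is (node_indices, values); by default u = 0 on the domain
    boundary (which includes the axis and the far boundary).
    """
    K, f = assemble(mesh, materials)
    if dirichlet is None:
        bnodes = mesh.boundary_nodes()
        bvals = np.zeros(len(bnodes))
    else:
        bnodes, bvals = np.asarray(dirichlet[0]), np.asarray(dirichlet[1], float)
    if len(bnodes) == 0:
        raise SolverError("no Dirichlet constraint: the system is singular")

    n = len(mesh.nodes)
    u = np.zeros(n)
    u[bnodes] = bvals
    free = np.setdiff1d(np.arange(n), bnodes)
    rhs = f[free] - K[free][:, bnodes] @ bvals
    Kff = K[free][:, free].tocsc()
    u[free] = spla.spsolve(Kff, rhs)
    if not np.all(np.isfinite(u)):
        raise SolverError("linear solve produced non-finite values")

    cent = mesh.centroids()
    areas = mesh.areas()
    p = mesh.nodes[mesh.triangles]
    x, y = p[..., 0], p[..., 1]
    bcoef = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    ccoef = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    ue = u[mesh.triangles]
    du_dr = (bcoef * ue).sum(axis=1) / (2 * areas)
    du_dz = (ccoef * ue).sum(axis=1) / (2 * areas)
    rc = np.maximum(cent[:, 0], 1e-300)
    b_el = np.column_stack([-du_dz / rc, du_dr / rc])

    core = mesh.region == REGION_CORE
    if core.any():
        bmax = float(np.abs(b_el[core]).max())
        if bmax > SATURATION_WARN_T:
            logger.warning("computed core |B| reaches %.2f T; real core "
                           "materials saturate near %.1f T (linear model keeps "
                           "scaling)", bmax, SATURATION_WARN_T)

    return AxisymSolution(mesh=mesh, materials=materials, u=u, b_elements=b_el)


# ---------------------------------------------------------------------------
# device simulations
# ---------------------------------------------------------------------------

def _axis_line_scan(sol: AxisymSolution, face_z: float, positions: np.ndarray,
                    drive: DriveCondition, r_probe: float) -> LineScan:
    z = face_z + positions
    bz = sol.b_axis(z, r_probe=r_probe)
    return LineScan(start=np.array([0.0, 0.0, face_z]),
                    direction=np.array([0.0, 0.0, 1.0]),
                    positions=positions, magnitude=np.abs(bz),
                    excitation=drive,
                    b_vectors=np.column_stack([np.zeros_like(bz),
                                               np.zeros_like(bz), bz]))


def default_scan_positions(start_mm: float = 1.0, stop_mm: float = 40.0,
                           step_mm: float = 0.5) -> np.ndarray:
    """On-axis sample offsets (m): every 0.5 mm, starting 1 mm from the
    surface (apex values are mesh-dependent and not reported)."""
    return np.arange(start_mm, stop_mm + step_mm / 2, step_mm) * 1e-3


def simulate_rod_core(spec: RodCoreSpec, drive: DriveCondition,
                      far_boundary_factor: float = 5.0,
                      target_edge: float | None = None,
                      positions: np.ndarray | None = None,
                      mesh: AxisymMesh | None = None,
                      mu_r_override: float | None = None) -> LineScan:
    """On-axis |B| beyond the rod tip (offsets measured from the apex)."""
    if positions is None:
        positions = default_scan_positions()
    if mesh is None:
        mesh = build_mesh(spec, far_boundary_factor, target_edge)
    mats = materials_for(spec, drive, mesh, mu_r_override)
    sol = solve(mesh, mats)
    return _axis_line_scan(sol, spec.core_length / 2, positions, drive,
                           r_probe=0.8e-3)


def simulate_pot_core(spec: PotCoreSpec, drive: DriveCondition,
                      far_boundary_factor: float = 5.0,
                      target_edge: float | None = None,
                      positions: np.ndarray | None = None,
                      mesh: AxisymMesh | None = None,
                      mu_r_override: float | None = None) -> LineScan:
    """On-axis |B| beyond the open (unshielded, +z) face of the pot core."""
    if positions is None:
        positions = default_scan_positions()
    if mesh is None:
        mesh = build_mesh(spec, far_boundary_factor, target_edge)
    mats = materials_for(spec, drive, mesh, mu_r_override)
    sol = solve(mesh, mats)
    return _axis_line_scan(sol, spec.height / 2, positions, drive,
                           r_probe=0.6e-3)


def permeability_sensitivity(spec: PotCoreSpec, drive: DriveCondition,
                             tolerance_fraction: float | None = None,
                             **kwargs) -> tuple[LineScan, LineScan, LineScan]:
    """Scans at mu_r*(1-t), mu_r, mu_r*(1+t) on a shared mesh.

    The manufacturer's quoted permeability tolerance for the ferrite is wide
    (+-30%); this quantifies how much of that spread reaches the target.
    """
    t = spec.permeability_tolerance if tolerance_fraction is None else tolerance_fraction
    if not (0 <= t < 1):
        raise ValueError("tolerance_fraction must be in [0, 1)")
    mesh = kwargs.pop("mesh", None)
    if mesh is None:
        mesh = build_mesh(spec, kwargs.pop("far_boundary_factor", 5.0),
                          kwargs.pop("target_edge", None))
    mu = spec.relative_permeability
    out = []
    for factor in (1 - t, 1.0, 1 + t):
        out.append(simulate_pot_core(spec, drive, mesh=mesh,
                                     mu_r_override=mu * factor, **kwargs))
    return tuple(out)  # type: ignore[return-value]
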