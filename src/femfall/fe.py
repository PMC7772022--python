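"""2D plane-strain linear-elastic finite-element model of the sideways fall.

Linear (constant-strain) triangles on a Delaunay mesh of the femur plus
the two PMMA pads.  Bone elements get a Young's modulus from the pixel
BMD under the element centroid through an apparent-density power law;
pad elements get PMMA constants.  The distal shaft is fully fixed, the
medial face of the head pad is fixed in x, and the fall load enters as
a uniform pressure on the flat lateral face of the trochanteric pad.

Conventions: coordinates in mm, moduli and stresses in MPa, forces in N
(out-of-plane thickness carried explicitly), strains dimensionless,
strain energy density reported in J/m^3.  Plane strain: eps_zz = 0 and
sigma_zz = nu (sigma_xx + sigma_yy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve
from scipy.spatial import Delaunay, cKDTree
from shapely import contains_xy
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union
from skimage import measure as skmeasure

from .cohort import ScanRaster
from .morphometry import PadGeometry

__all__ = [
    "Mesh2D",
    "MaterialField",
    "BoundaryConditions",
    "LoadCase",
    "FESolution",
    "FEError",
    "TAG_FEMUR",
    "TAG_TROCH_PAD",
    "TAG_HEAD_PAD",
    "femur_polygon",
    "mesh_polygons",
    "mesh_domain",
    "assign_materials",
    "apply_constraints",
    "apply_load",
    "solve",
    "write_vtk",
    "PMMA_E",
    "PMMA_NU",
    "BONE_NU",
]

TAG_FEMUR, TAG_TROCH_PAD, TAG_HEAD_PAD = 0, 1, 2

PMMA_E = 1500.0     # MPa, pad Young's modulus
PMMA_NU = 0.37      # pad Poisson ratio
BONE_NU = 0.3       # bone Poisson ratio


class FEError(ValueError):
    """Raised for ill-posed meshes, materials or systems."""


@dataclass
class Mesh2D:
    nodes: np.ndarray       # (n, 2) mm
    elements: np.ndarray    # (m, 3) int, CCW
    tags: np.ndarray        # (m,) int domain tag

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=int)
        self.tags = np.asarray(self.tags, dtype=int)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def areas(self) -> np.ndarray:
        """Signed triangle areas (positive for the stored CCW orientation)."""
        p = self.nodes[self.elements]
        return 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                      - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))

    def centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def boundary_edges(self) -> np.ndarray:
        """(k, 2) node pairs belonging to exactly one element."""
        e = self.elements
        edges = np.vstack([e[:, [0, 1]], e[:, [1, 2]], e[:, [2, 0]]])
        key = np.sort(edges, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True,
                                   return_counts=True)
        return edges[idx[counts == 1]]

    def element_adjacency(self) -> list[list[int]]:
        """Edge-neighbour lists (shared-edge adjacency)."""
        e = self.elements
        owners: dict[tuple[int, int], list[int]] = {}
        for k in range(len(e)):
            for a, b in ((0, 1), (1, 2), (2, 0)):
                key = (min(e[k, a], e[k, b]), max(e[k, a], e[k, b]))
                owners.setdefault(key, []).append(k)
        adj: list[list[int]] = [[] for _ in range(len(e))]
        for pair in owners.values():
            if len(pair) == 2:
                adj[pair[0]].append(pair[1])
                adj[pair[1]].append(pair[0])
        return adj


@dataclass
class MaterialField:
    density: np.ndarray             # (m,) apparent density g/cm^3 (0 for pads)
    youngs: np.ndarray              # (m,) MPa
    poisson: np.ndarray             # (m,)
    law_a: float = 6850.0           # MPa (g/cm^3)^-p
    law_p: float = 1.49
    t_ref_cm: float = 1.0           # areal -> apparent density thickness
    e_floor: float = 10.0           # MPa


@dataclass
class BoundaryConditions:
    fixed: np.ndarray               # (n, 2) bool, True = dof constrained
    distal_nodes: np.ndarray = field(default=None)
    head_pad_nodes: np.ndarray = field(default=None)


@dataclass
class LoadCase:
    forces: np.ndarray              # (n, 2) N
    total_force: float              # N, magnitude of the resultant
    thickness: float                # mm, out-of-plane


@dataclass
class FESolution:
    mesh: Mesh2D
    displacements: np.ndarray       # (n, 2) mm
    strain: np.ndarray              # (m, 3) [exx, eyy, gamma_xy]
    stress: np.ndarray              # (m, 3) [sxx, syy, sxy] MPa
    stress_zz: np.ndarray           # (m,) MPa
    s1: np.ndarray                  # (m,) max in-plane principal stress, MPa
    s3: np.ndarray                  # (m,) min in-plane principal stress, MPa
    e1: np.ndarray                  # (m,) principal strains (dimensionless)
    e3: np.ndarray
    von_mises: np.ndarray           # (m,) MPa
    sed: np.ndarray                 # (m,) J/m^3
    equilibrium_residual: float     # |sum reactions + applied| / |applied|


# --------------------------------------------------------------------------
# meshing
# --------------------------------------------------------------------------

def femur_polygon(scan: ScanRaster) -> Polygon:
    """Largest mask contour as a shapely polygon in mm coordinates."""
    padded = np.pad(scan.mask.astype(float), 1)
    contours = skmeasure.find_contours(padded, 0.5)
    if not contours:
        raise FEError("empty mask")
    contour = max(contours, key=len)
    rows = contour[:, 0] - 1.0
    cols = contour[:, 1] - 1.0
    n_rows = scan.mask.shape[0]
    x = cols * scan.pixel_dx
    y = (n_rows - 1 - rows) * scan.pixel_dy
    poly = Polygon(np.column_stack([x, y])).buffer(0)
    if poly.geom_type != "Polygon":
        poly = max(poly.geoms, key=lambda g: g.area)
    return poly.simplify(0.2)


def _boundary_points(poly: Polygon, h: float) -> np.ndarray:
    """Ring vertices plus per-edge subdivision at spacing <= h."""
    coords = np.asarray(poly.exterior.coords)
    pts = []
    for p0, p1 in zip(coords[:-1], coords[1:]):
        seg = p1 - p0
        n = max(int(np.ceil(np.linalg.norm(seg) / h)), 1)
        for i in range(n):
            pts.append(p0 + (i / n) * seg)
    return np.asarray(pts)


def mesh_polygons(domains: list[Polygon], target_elements: int) -> Mesh2D:
    """Delaunay mesh of a list of (possibly overlapping) domain polygons.

    Element tags follow list order priority: an element centroid inside
    ``domains[0]`` is tagged 0 even where domains overlap.
    """
    if target_elements < 50:
        raise FEError("target element count too small")
    clean = []
    for dom in domains:
        if dom is None or dom.is_empty:
            continue
        d = dom.buffer(0)
        if d.geom_type != "Polygon":
            d = max(d.geoms, key=lambda g: g.area)
        if not d.is_valid or d.area <= 0:
            raise FEError("invalid (self-intersecting) domain contour")
        clean.append(d)
    union = unary_union(clean)
    if union.geom_type != "Polygon":
        union = max(union.geoms, key=lambda g: g.area)
    h = float(np.sqrt(2.0 * union.area / target_elements))

    pts = [_boundary_points(union, h)]
    for dom in clean:
        inter = dom.exterior.intersection(union.buffer(-0.3 * h))
        if not inter.is_empty:
            for g in getattr(inter, "geoms", [inter]):
                if g.length > h:
                    n = max(int(np.ceil(g.length / h)), 2)
                    pts.append(np.asarray([
                        g.interpolate(i / n, normalized=True).coords[0]
                        for i in range(n + 1)]))
    boundary = np.vstack(pts)

    minx, miny, maxx, maxy = union.bounds
    xs = np.arange(minx, maxx + h, h)
    ys = np.arange(miny, maxy + h * np.sqrt(3) / 2, h * np.sqrt(3) / 2)
    gx, gy = np.meshgrid(xs, ys)
    gx[1::2] += 0.5 * h        # hexagonal packing
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    inside = contains_xy(union, grid[:, 0], grid[:, 1])
    grid = grid[inside]
    if len(boundary) > 0 and len(grid) > 0:
        tree = cKDTree(boundary)
        dmin, _ = tree.query(grid)
        grid = grid[dmin > 0.45 * h]

    points = np.vstack([boundary, grid])
    # deduplicate (shared domain boundaries repeat points)
    _, uniq = np.unique(np.round(points, 6), axis=0, return_index=True)
    points = points[np.sort(uniq)]
    tri = Delaunay(points)
    cells = tri.simplices
    cent = points[cells].mean(axis=1)
    keep = contains_xy(union, cent[:, 0], cent[:, 1])
    cells = cells[keep]
    cent = cent[keep]
    # orient CCW and drop degenerate slivers
    p = points[cells]
    area2 = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
             - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    flip = area2 < 0
    cells[flip] = cells[flip][:, ::-1]
    ok = np.abs(area2) > 1e-9 * h * h
    cells, cent = cells[ok], cent[ok]

    tags = np.full(len(cells), -1, dtype=int)
    for i, dom in enumerate(clean):
        untagged = tags == -1
        if not np.any(untagged):
            break
        hit = contains_xy(dom, cent[untagged, 0], cent[untagged, 1])
        idx = np.flatnonzero(untagged)[hit]
        tags[idx] = i
    # centroids in the union but caught between domain boundaries get the
    # nearest domain by distance
    for k in np.flatnonzero(tags == -1):
        pt = Point(cent[k])
        tags[k] = int(np.argmin([dom.distance(pt) for dom in clean]))

    used = np.unique(cells)
    remap = -np.ones(len(points), dtype=int)
    remap[used] = np.arange(len(used))
    return Mesh2D(nodes=points[used], elements=remap[cells], tags=tags)


def mesh_domain(scan: ScanRaster, pads: PadGeometry,
                target_elements: int = 6000) -> Mesh2D:
    """Mesh femur + trochanteric pad + head pad from a scan and pad set."""
    if target_elements < 500:
        raise FEError("target_elements must be at least 500")
    femur = femur_polygon(scan)
    return mesh_polygons([femur, pads.troch_polygon, pads.head_polygon],
                         target_elements)


# --------------------------------------------------------------------------
# materials, boundary conditions, load
# --------------------------------------------------------------------------

def assign_materials(mesh: Mesh2D, scan: ScanRaster,
                     law_a: float = 6850.0, law_p: float = 1.49,
                     t_ref_cm: float = 1.0,
                     e_floor: float = 10.0) -> MaterialField:
    """Per-element material properties from the BMD map.

    Femur elements: areal BMD sampled bilinearly at the element centroid,
    converted to apparent density rho = BMD / t_ref, then E = a rho^p,
    floored at ``e_floor`` to keep the system well posed.  Pad elements
    get the PMMA constants.
    """
    cent = mesh.centroids()
    n_rows = scan.mask.shape[0]
    src_cols = cent[:, 0] / scan.pixel_dx
    src_rows = n_rows - 1 - cent[:, 1] / scan.pixel_dy
    bmd = ndimage.map_coordinates(scan.bmd_map, np.vstack([src_rows, src_cols]),
                                  order=1, mode="nearest")
    density = np.where(mesh.tags == TAG_FEMUR, bmd / t_ref_cm, 0.0)
    youngs = np.where(mesh.tags == TAG_FEMUR,
                      np.maximum(law_a * np.power(np.maximum(density, 0.0), law_p),
                                 e_floor),
                      PMMA_E)
    poisson = np.where(mesh.tags == TAG_FEMUR, BONE_NU, PMMA_NU)
    return MaterialField(density=density, youngs=youngs, poisson=poisson,
                         law_a=law_a, law_p=law_p, t_ref_cm=t_ref_cm,
                         e_floor=e_floor)


def apply_constraints(mesh: Mesh2D, pads: PadGeometry | None = None,
                      shaft_tilt_deg: float = 10.0) -> BoundaryConditions:
    """Distal shaft fully fixed; medial head-pad face fixed in x.

    The distal set is the femur boundary strip within 2.5 mm of the
    lowest station along the (pose-standardised) shaft axis.  The head
    pad's outer arc nodes are fixed in the medial (x) direction only.
    """
    d = np.array([np.sin(np.radians(shaft_tilt_deg)),
                  np.cos(np.radians(shaft_tilt_deg))])
    fixed = np.zeros((mesh.n_nodes, 2), dtype=bool)

    femur_nodes = np.unique(mesh.elements[mesh.tags == TAG_FEMUR])
    if len(femur_nodes) == 0:
        raise FEError("no femur elements in mesh")
    station = mesh.nodes[femur_nodes] @ d
    distal = femur_nodes[station <= station.min() + 2.5]
    fixed[distal, :] = True

    head_nodes = np.array([], dtype=int)
    if pads is not None:
        hp_nodes = np.unique(mesh.elements[mesh.tags == TAG_HEAD_PAD])
        if len(hp_nodes) > 0:
            r = np.linalg.norm(mesh.nodes[hp_nodes] - pads.head_centre, axis=1)
            head_nodes = hp_nodes[r >= pads.head_outer_radius - 1.5]
            fixed[head_nodes, 0] = True
    if not fixed.any():
        raise FEError("empty constraint set")
    return BoundaryConditions(fixed=fixed, distal_nodes=distal,
                              head_pad_nodes=head_nodes)


def apply_load(mesh: Mesh2D, hp: float, pads: PadGeometry) -> LoadCase:
    """Uniform inward pressure ``hp`` (MPa) on the trochanteric pad face.

    The traction is lumped to the boundary nodes on the flat lateral face
    and scaled so that the resultant equals hp * b * t exactly.
    """
    if hp < 0:
        raise FEError("pressure must be non-negative")
    p0, p1 = pads.load_p0, pads.load_p1
    seg = p1 - p0
    seg_len = float(np.linalg.norm(seg))
    u = seg / seg_len
    rel = mesh.nodes - p0
    along = rel @ u
    offset = np.abs(rel @ np.array([-u[1], u[0]]))
    on_face = (offset <= 0.6) & (along >= -0.5) & (along <= seg_len + 0.5)
    face_nodes = np.flatnonzero(on_face)
    if len(face_nodes) < 2:
        raise FEError("zero-length loaded edge")
    order = np.argsort(along[face_nodes])
    face_nodes = face_nodes[order]
    seg_lens = np.diff(along[face_nodes])
    forces = np.zeros((mesh.n_nodes, 2))
    total = hp * pads.b * pads.t
    if seg_lens.sum() <= 0:
        raise FEError("zero-length loaded edge")
    scale = total / seg_lens.sum()
    for k, ln in enumerate(seg_lens):
        f = 0.5 * scale * ln * pads.load_normal
        forces[face_nodes[k]] += f
        forces[face_nodes[k + 1]] += f
    return LoadCase(forces=forces, total_force=total, thickness=pads.t)


# --------------------------------------------------------------------------
# solver
# --------------------------------------------------------------------------

def _b_matrices(mesh: Mesh2D) -> tuple[np.ndarray, np.ndarray]:
    """Per-element strain-displacement matrices (m, 3, 6) and areas (m,)."""
    p = mesh.nodes[mesh.elements]
    x, y = p[..., 0], p[..., 1]
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    area = 0.5 * ((x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0])
                  - (x[:, 2] - x[:, 0]) * (y[:, 1] - y[:, 0]))
    if np.any(area <= 0):
        raise FEError("inverted or degenerate element in mesh")
    m = mesh.n_elements
    B = np.zeros((m, 3, 6))
    inv2a = 1.0 / (2.0 * area)
    for i in range(3):
        B[:, 0, 2 * i] = b[:, i] * inv2a
        B[:, 1, 2 * i + 1] = c[:, i] * inv2a
        B[:, 2, 2 * i] = c[:, i] * inv2a
        B[:, 2, 2 * i + 1] = b[:, i] * inv2a
    return B, area


def _d_matrices(materials: MaterialField) -> np.ndarray:
    E, nu = materials.youngs, materials.poisson
    f = E / ((1.0 + nu) * (1.0 - 2.0 * nu))
    m = len(E)
    D = np.zeros((m, 3, 3))
    D[:, 0, 0] = D[:, 1, 1] = f * (1.0 - nu)
    D[:, 0, 1] = D[:, 1, 0] = f * nu
    D[:, 2, 2] = f * (1.0 - 2.0 * nu) / 2.0
    return D


def solve(mesh: Mesh2D, materials: MaterialField,
          constraints: BoundaryConditions, load: LoadCase) -> FESolution:
    """Assemble and solve the plane-strain system; post-process tensors."""
    B, area = _b_matrices(mesh)
    D = _d_matrices(materials)
    t = load.thickness
    Ke = np.einsum("eji,ejk,ekl,e->eil", B, D, B, area * t)

    dof = np.empty((mesh.n_elements, 6), dtype=int)
    dof[:, 0::2] = 2 * mesh.elements
    dof[:, 1::2] = 2 * mesh.elements + 1
    rows = np.repeat(dof, 6, axis=1).ravel()
    cols = np.tile(dof, (1, 6)).ravel()
    K = coo_matrix((Ke.ravel(), (rows, cols)),
                   shape=(2 * mesh.n_nodes, 2 * mesh.n_nodes)).tocsr()

    f = load.forces.ravel().copy()
    free = ~constraints.fixed.ravel()
    if not free.any() or free.all():
        raise FEError("constraints must fix some but not all dofs")
    Kff = K[free][:, free]
    uf = spsolve(Kff, f[free])
    if not np.all(np.isfinite(uf)):
        raise FEError("singular system (sparse solve failed); check that "
                      "constraints remove all rigid-body modes")
    u = np.zeros(2 * mesh.n_nodes)
    u[free] = uf

    # equilibrium: reactions at constrained dofs balance the applied load
    residual_vec = K @ u - f
    reactions = residual_vec[~free]
    applied = np.linalg.norm(f)
    if applied > 0:
        total_reaction = np.array([residual_vec[0::2][constraints.fixed[:, 0]].sum(),
                                   residual_vec[1::2][constraints.fixed[:, 1]].sum()])
        total_applied = load.forces.sum(axis=0)
        eq_res = float(np.linalg.norm(total_reaction + total_applied)
                       / max(np.linalg.norm(total_applied), 1e-30))
    else:
        eq_res = 0.0
    del reactions

    ue = u[dof]                                    # (m, 6)
    strain = np.einsum("eij,ej->ei", B, ue)        # [exx, eyy, gxy]
    stress = np.einsum("eij,ej->ei", D, strain)    # [sxx, syy, sxy]
    szz = materials.poisson * (stress[:, 0] + stress[:, 1])

    def principal(xx, yy, xy):
        centre = 0.5 * (xx + yy)
        radius = np.sqrt((0.5 * (xx - yy)) ** 2 + xy ** 2)
        return centre + radius, centre - radius

    s1, s3 = principal(stress[:, 0], stress[:, 1], stress[:, 2])
    e1, e3 = principal(strain[:, 0], strain[:, 1], 0.5 * strain[:, 2])
    vm = np.sqrt(0.5 * ((stress[:, 0] - stress[:, 1]) ** 2
                        + (stress[:, 1] - szz) ** 2
                        + (szz - stress[:, 0]) ** 2)
                 + 3.0 * stress[:, 2] ** 2)
    sed_mpa = 0.5 * (stress[:, 0] * strain[:, 0] + stress[:, 1] * strain[:, 1]
                     + stress[:, 2] * strain[:, 2])
    sed = sed_mpa * 1.0e6      # MPa == MJ/m^3 -> J/m^3

    return FESolution(mesh=mesh, displacements=u.reshape(-1, 2),
                      strain=strain, stress=stress, stress_zz=szz,
                      s1=s1, s3=s3, e1=e1, e3=e3, von_mises=vm, sed=sed,
                      equilibrium_residual=eq_res)


def write_vtk(solution: FESolution, path, materials: MaterialField | None = None
              ) -> None:
    """Legacy-ASCII VTK dump of the mesh and element fields.

    Nodes carry displacements; elements carry domain tag, von Mises
    stress, principal stresses, SED and (optionally) Young's modulus.
    """
    mesh = solution.mesh
    lines = ["# vtk DataFile Version 3.0", "femfall plane-strain solution",
             "ASCII", "DATASET UNSTRUCTURED_GRID",
             f"POINTS {mesh.n_nodes} float"]
    for x, y in mesh.nodes:
        lines.append(f"{x:.6f} {y:.6f} 0.0")
    lines.append(f"CELLS {mesh.n_elements} {4 * mesh.n_elements}")
    for a, b, c in mesh.elements:
        lines.append(f"3 {a} {b} {c}")
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines.extend(["5"] * mesh.n_elements)
    lines.append(f"POINT_DATA {mesh.n_nodes}")
    lines.append("VECTORS displacement float")
    for ux, uy in solution.displacements:
        lines.append(f"{ux:.6e} {uy:.6e} 0.0")
    lines.append(f"CELL_DATA {mesh.n_elements}")
    fields = [("domain_tag", mesh.tags.astype(float)),
              ("von_mises_mpa", solution.von_mises),
              ("s1_mpa", solution.s1), ("s3_mpa", solution.s3),
              ("sed_j_per_m3", solution.sed)]
    if materials is not None:
        fields.append(("youngs_mpa", materials.youngs))
    for name, vals in fields:
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.6e}" for v in vals)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
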