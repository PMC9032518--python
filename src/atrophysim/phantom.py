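"""Parametric labeled brain phantom meshes.

Generates desk-scale analogs of a segmented brain model: a folded white
matter (WM) core, a gray matter (GM) ribbon of spatially constant thickness
obtained by offsetting the WM boundary outward, an interior ventricular
cavity meshed as a solid subdomain, a hippocampal subregion adjacent to the
ventricle, and a cerebrospinal fluid (CSF) layer bounded by a smooth outer
surface that carries the zero-displacement anchor in the mechanics solve.

The default phantom is a 2D coronal-slice analog; ``dimension=3`` extrudes
the slice into a quasi-3D tetrahedral mesh.  Geometry is deterministic for a
fixed seed (the seed only drives a small symmetric jitter of the interior
point lattice that removes co-circular Delaunay degeneracies).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import LineString, Polygon

from . import _fem

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------- regions

WM, GM, HIPPO, VENT, CSF = 1, 2, 3, 4, 5
REGION_NAMES = {WM: "WM", GM: "GM", HIPPO: "HIPPO", VENT: "VENT", CSF: "CSF"}
REGION_IDS = {v: k for k, v in REGION_NAMES.items()}
TISSUE_REGIONS = (WM, GM, HIPPO, VENT)  # "brain" = everything but CSF

#: pocket names used when n_folds == 5, mirroring five prominent sulci
SULCUS_NAMES_5 = (
    "sylvian", "superior_temporal", "central", "intra_parietal",
    "superior_frontal",
)


class PhantomGeometryError(ValueError):
    """Raised when the requested phantom geometry is infeasible."""


class PhantomMeshingError(RuntimeError):
    """Raised when meshing fails for a specific region."""


# ----------------------------------------------------------------- types

@dataclass(frozen=True)
class PhantomParams:
    """Geometry controls for the synthetic brain slice.

    Lengths in mm.  ``outer_radius`` is the fixed outer (skull-proxy) CSF
    surface; the WM base radius is derived as
    ``outer_radius - csf_thickness - cortical_thickness - fold_amplitude``
    so that gyral crests sit ``csf_thickness`` below the outer surface.
    """
    outer_radius: float = 65.0
    csf_thickness: float = 5.0
    cortical_thickness: float = 3.0
    n_folds: int = 5
    fold_amplitude: float = 12.0
    fold_gap: float = 3.0
    ventricle_semiaxes: tuple[float, float] = (12.0, 8.0)
    hippocampus_center: tuple[float, float] | None = None
    hippocampus_radius: float = 7.0
    target_edge_length: float = 2.15
    seed: int = 0
    dimension: int = 2
    extrusion_thickness: float = 6.0  # 3D only

    def __post_init__(self):
        if self.dimension not in (2, 3):
            raise PhantomGeometryError("dimension must be 2 or 3")
        if self.fold_gap <= 0:
            raise PhantomGeometryError(
                "fold_gap must be > 0: a positive inter-gyral gap prevents "
                "self-contact of the cortical (pial) surface")
        if self.n_folds == 0 and self.fold_amplitude != 0:
            raise PhantomGeometryError(
                "fold_amplitude must be 0 when n_folds == 0")
        if self.n_folds < 0 or self.fold_amplitude < 0:
            raise PhantomGeometryError("folds must be non-negative")
        for name in ("outer_radius", "csf_thickness", "cortical_thickness",
                     "hippocampus_radius", "target_edge_length"):
            if getattr(self, name) <= 0:
                raise PhantomGeometryError(f"{name} must be > 0")
        if self.wm_base_radius <= 0:
            raise PhantomGeometryError(
                "outer_radius too small for the requested layer thicknesses")

    @property
    def wm_base_radius(self) -> float:
        return (self.outer_radius - self.csf_thickness
                - self.cortical_thickness - self.fold_amplitude)

    @property
    def hippo_center(self) -> tuple[float, float]:
        if self.hippocampus_center is not None:
            return tuple(self.hippocampus_center)
        # adjacent to the ventricle boundary (temporal-horn analog): slight
        # overlap guarantees shared element facets after meshing
        a = self.ventricle_semiaxes[0]
        return (a + 0.8 * self.hippocampus_radius, 0.0)


@dataclass
class LabeledMesh:
    """Conforming simplicial mesh with per-element region labels.

    ``boundary_sets`` are named node-index sets (``csf_outer`` is always the
    entire exterior boundary); ``element_sets`` are named element-index sets
    (the per-sulcus fluid pockets live here so sulcal volumes can be summed).
    """
    nodes: np.ndarray           # (n_nodes, dim) mm
    simplices: np.ndarray       # (n_elem, dim+1) int
    element_region: np.ndarray  # (n_elem,) int codes, see REGION_NAMES
    boundary_sets: dict[str, np.ndarray] = field(default_factory=dict)
    element_sets: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def dimension(self) -> int:
        return self.nodes.shape[1]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.simplices)

    def element_volumes(self, coords: np.ndarray | None = None) -> np.ndarray:
        """Signed element measures (areas in 2D, volumes in 3D)."""
        pts = self.nodes if coords is None else coords
        return _fem.element_volumes(pts, self.simplices)

    def region_elements(self, region: int | str) -> np.ndarray:
        rid = REGION_IDS[region] if isinstance(region, str) else int(region)
        return np.flatnonzero(self.element_region == rid)

    def region_volume(self, region: int | str,
                      coords: np.ndarray | None = None) -> float:
        idx = self.region_elements(region)
        return float(np.abs(self.element_volumes(coords)[idx]).sum())

    def total_volume(self, coords: np.ndarray | None = None) -> float:
        return float(np.abs(self.element_volumes(coords)).sum())

    def boundary_facets(self, elements: np.ndarray | None = None) -> np.ndarray:
        """Facets (edges/faces) that belong to exactly one of `elements`."""
        simp = self.simplices if elements is None else self.simplices[elements]
        nv = simp.shape[1]
        facets = []
        for drop in range(nv):
            keep = [a for a in range(nv) if a != drop]
            facets.append(simp[:, keep])
        facets = np.concatenate(facets, axis=0)
        key = np.sort(facets, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                                   return_counts=True)
        return facets[counts[inv] == 1]

    def exterior_nodes(self) -> np.ndarray:
        return np.unique(self.boundary_facets())

    def validate(self) -> None:
        vols = self.element_volumes()
        if not np.all(vols > 0):
            raise PhantomMeshingError(
                f"{np.sum(vols <= 0)} elements have non-positive measure")
        present = set(np.unique(self.element_region))
        missing = [REGION_NAMES[r] for r in REGION_NAMES if r not in present]
        if missing:
            raise PhantomMeshingError(f"missing region labels: {missing}")


@dataclass
class MeshQualityReport:
    n_nodes: int
    n_elements: int
    min_edge: float
    max_edge: float
    max_aspect_ratio: float
    min_volume: float
    edge_band: tuple[float, float] | None = None
    fraction_in_band: float | None = None
    inverted_elements: int = 0

    @property
    def has_inverted_elements(self) -> bool:
        return self.inverted_elements > 0


# -------------------------------------------------------- curve sampling

def _wm_radius(params: PhantomParams, phi: np.ndarray) -> np.ndarray:
    r0 = params.wm_base_radius
    if params.n_folds == 0:
        return np.full_like(np.asarray(phi, float), r0)
    # cosine folds keep the phantom mirror-symmetric about the x-axis
    return r0 + params.fold_amplitude * np.cos(params.n_folds * np.asarray(phi))


def _dense_half_curve(params: PhantomParams, which: str, m: int = 4096):
    """Densely sampled upper half (y >= 0) of one analytic interface."""
    phi = np.linspace(0.0, np.pi, m)
    if which == "outer":
        r = np.full(m, params.outer_radius)
        return np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    if which == "vent":
        a, b = params.ventricle_semiaxes
        return np.column_stack([a * np.cos(phi), b * np.sin(phi)])
    if which == "hippo":
        cx, cy = params.hippo_center
        r = params.hippocampus_radius
        return np.column_stack([cx + r * np.cos(phi), cy + r * np.sin(phi)])
    r = _wm_radius(params, phi)
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    if which == "wm":
        return pts
    if which == "pial":
        # constant-distance normal offset; validity (no cusp) is checked by
        # the self-intersection / gap tests downstream
        n = params.n_folds
        A = params.fold_amplitude
        dr = -A * n * np.sin(n * phi) if n else np.zeros(m)
        tx = dr * np.cos(phi) - r * np.sin(phi)
        ty = dr * np.sin(phi) + r * np.cos(phi)
        norm = np.hypot(tx, ty)
        return pts + params.cortical_thickness * np.column_stack(
            [ty / norm, -tx / norm])
    raise ValueError(which)


def _resample_by_arclength(pts: np.ndarray, spacing: float,
                           rng: np.random.Generator | None = None
                           ) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    L = s[-1]
    # lower bound keeps the polygonal-inscription area deficit of small
    # closed interfaces (ventricle, hippocampus) well below 1%
    n = max(16, int(round(L / spacing)))
    t = np.linspace(0.0, L, n + 1)
    if rng is not None and n > 2:
        # tangential jitter breaks the near-cocircular quads formed by
        # parallel offset curves, making the Delaunay diagonals unique (and
        # hence mirror-symmetric for the mirrored point set)
        t[1:-1] += rng.uniform(-0.15, 0.15, n - 1) * (L / n)
    out = np.column_stack([np.interp(t, s, pts[:, 0]),
                           np.interp(t, s, pts[:, 1])])
    out[0, 1] = 0.0
    out[-1, 1] = 0.0
    return out


def _mirror_closed(upper: np.ndarray) -> np.ndarray:
    """Full closed loop from an upper-half polyline ending on the x-axis."""
    lower = upper[-2:0:-1].copy()
    lower[:, 1] *= -1.0
    return np.vstack([upper, lower])


def _min_self_gap(loop: np.ndarray, arc_cutoff: float) -> float:
    """Smallest distance between non-neighboring portions of a closed loop."""
    seg = np.linalg.norm(np.diff(np.vstack([loop, loop[:1]]), axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])[:-1]
    L = s[-1] + seg[-1]
    tree = cKDTree(loop)
    dist, idx = tree.query(loop, k=min(64, len(loop)))
    ds = np.abs(s[idx] - s[:, None])
    ds = np.minimum(ds, L - ds)
    far = ds > arc_cutoff
    d = np.where(far, dist, np.inf)
    return float(d.min())


# ------------------------------------------------------------ generation

def build_brain_phantom(params: PhantomParams) -> LabeledMesh:
    """Generate the labeled phantom mesh (2D triangles or extruded tets)."""
    mesh2d = _build_phantom_2d(params)
    if params.dimension == 2:
        return mesh2d
    n_layers = max(2, int(round(params.extrusion_thickness
                                / params.target_edge_length)))
    mesh = extrude_mesh(mesh2d, params.extrusion_thickness, n_layers)
    mesh.validate()
    return mesh


def _build_phantom_2d(params: PhantomParams) -> LabeledMesh:
    h = params.target_edge_length
    spacing = 0.85 * h

    rng = np.random.default_rng(params.seed)
    curves = {name: _mirror_closed(
        _resample_by_arclength(_dense_half_curve(params, name), spacing,
                               rng=rng))
        for name in ("wm", "pial", "outer", "vent", "hippo")}

    # --- feasibility -----------------------------------------------------
    pial_dense = _mirror_closed(_dense_half_curve(params, "pial"))
    ring = LineString(np.vstack([pial_dense, pial_dense[:1]]))
    if not ring.is_simple:
        raise PhantomGeometryError(
            "infeasible geometry: the offset pial surface self-intersects "
            "(folds too deep/sharp for the requested cortical_thickness)")
    if params.n_folds > 0:
        gap = _min_self_gap(pial_dense, arc_cutoff=4.0 * params.cortical_thickness
                            + 2.0 * params.fold_amplitude)
        if gap < params.fold_gap:
            raise PhantomGeometryError(
                f"infeasible geometry: minimum inter-gyral pial gap {gap:.2f} "
                f"mm is below fold_gap={params.fold_gap:.2f} mm")

    wm_poly = Polygon(curves["wm"])
    pial_poly = Polygon(curves["pial"])
    vent_poly = Polygon(curves["vent"])
    hippo_poly = Polygon(curves["hippo"])
    for name, poly in (("ventricle", vent_poly), ("hippocampus", hippo_poly)):
        inner = wm_poly.buffer(-0.25 * h)
        if not inner.contains(poly):
            raise PhantomGeometryError(
                f"infeasible geometry: {name} is not contained in the white "
                "matter core")

    # --- point cloud ------------------------------------------------------
    # later curves are thinned against earlier ones so intersecting
    # interfaces (hippocampus/ventricle) do not create sliver edges
    parts, sets, offset = [], {}, 0
    for name in ("wm", "pial", "outer", "vent", "hippo"):
        pts = curves[name]
        if parts:
            d, _ = cKDTree(np.vstack(parts)).query(pts)
            pts = pts[d > 0.55 * h]
        parts.append(pts)
        sets[name] = np.arange(offset, offset + len(pts))
        offset += len(pts)
    boundary_pts = np.vstack(parts)

    lattice = _interior_lattice(params, boundary_pts, h)
    points = np.vstack([boundary_pts, lattice])

    # --- triangulate + label ----------------------------------------------
    tri = Delaunay(points)
    simplices = tri.simplices.copy()
    areas = _fem.element_volumes(points, simplices)
    flip = areas < 0
    simplices[flip, 0], simplices[flip, 1] = (simplices[flip, 1],
                                              simplices[flip, 0])
    areas = np.abs(areas)
    keep = areas > 1e-12 * h * h
    simplices = simplices[keep]

    cx = points[simplices].mean(axis=1)
    labels = np.full(len(simplices), CSF, dtype=np.int32)
    for poly, code in ((pial_poly, GM), (wm_poly, WM),
                       (hippo_poly, HIPPO), (vent_poly, VENT)):
        inside = shapely.contains_xy(poly, cx[:, 0], cx[:, 1])
        labels[inside] = code

    mesh = LabeledMesh(
        nodes=points, simplices=simplices, element_region=labels,
        boundary_sets={
            "csf_outer": None,  # filled below
            "pial": sets["pial"],
            "wm_surface": sets["wm"],
            "ventricle_surface": sets["vent"],
            "hippocampus_surface": sets["hippo"],
        },
    )
    mesh.boundary_sets["csf_outer"] = mesh.exterior_nodes()
    _assign_sulcal_pockets(mesh, params)
    mesh.validate()
    logger.info("phantom: %d nodes, %d elements", mesh.n_nodes,
                mesh.n_elements)
    return mesh


def _interior_lattice(params: PhantomParams, boundary_pts: np.ndarray,
                      h: float) -> np.ndarray:
    """Jittered hexagonal lattice, mirror-symmetric about the x-axis."""
    R = params.outer_radius
    dy = h * np.sqrt(3.0) / 2.0
    rows = int(np.ceil(R / dy))
    xs = np.arange(-R - h, R + h, h)
    rng = np.random.default_rng(params.seed + 1)
    # row exactly on the mirror axis (jittered along x only) so no element
    # quad straddles y = 0 — a straddling quad has no symmetric diagonal
    axis_row = np.column_stack([
        xs + rng.uniform(-0.1 * h, 0.1 * h, len(xs)), np.zeros(len(xs))])
    upper = []
    for j in range(1, rows + 1):
        y = j * dy
        x = xs + (j % 2) * h / 2.0
        upper.append(np.column_stack([x, np.full_like(x, y)]))
    upper = np.vstack(upper)
    upper = upper + rng.uniform(-0.1 * h, 0.1 * h, size=upper.shape)
    upper[:, 1] = np.maximum(upper[:, 1], 0.3 * dy)  # stay off the axis
    lower = upper.copy()
    lower[:, 1] *= -1.0
    pts = np.vstack([axis_row, upper, lower])
    pts = pts[np.hypot(pts[:, 0], pts[:, 1]) < R - 0.55 * h]
    d, _ = cKDTree(boundary_pts).query(pts)
    return pts[d > 0.62 * h]


def _assign_sulcal_pockets(mesh: LabeledMesh, params: PhantomParams) -> None:
    """Partition the inter-gyral fluid into named per-sulcus element sets."""
    if params.n_folds < 1:
        return
    crest_pial = (params.wm_base_radius + params.fold_amplitude
                  + params.cortical_thickness)
    csf_elems = mesh.region_elements(CSF)
    c = mesh.nodes[mesh.simplices[csf_elems]].mean(axis=1)
    r = np.hypot(c[:, 0], c[:, 1])
    pocket = csf_elems[r < crest_pial - 0.5]
    if len(pocket) == 0:
        return
    c = mesh.nodes[mesh.simplices[pocket]].mean(axis=1)
    ang = np.mod(np.arctan2(c[:, 1], c[:, 0]), 2 * np.pi)
    n = params.n_folds
    valleys = (2 * np.arange(n) + 1) * np.pi / n  # cos(n*phi) == -1
    d = np.abs(ang[:, None] - valleys[None, :])
    d = np.minimum(d, 2 * np.pi - d)
    owner = np.argmin(d, axis=1)
    names = SULCUS_NAMES_5 if n == 5 else tuple(
        f"sulcus_{k}" for k in range(n))
    for k, name in enumerate(names):
        idx = pocket[owner == k]
        if len(idx):
            mesh.element_sets[name] = idx


# ------------------------------------------------------------- extrusion

def extrude_mesh(mesh2d: LabeledMesh, thickness: float,
                 n_layers: int) -> LabeledMesh:
    """Extrude a triangle mesh into a conforming tetrahedral mesh.

    Each prism is split into three tets with the minimum-vertex-index rule,
    which guarantees matching diagonals on shared quad faces.
    """
    n = mesh2d.n_nodes
    z = np.linspace(0.0, thickness, n_layers + 1)
    nodes = np.vstack([
        np.column_stack([mesh2d.nodes, np.full(n, zk)]) for zk in z])

    tets, labels = [], []
    for k in range(n_layers):
        lo, hi = k * n, (k + 1) * n
        for t, lab in zip(mesh2d.simplices, mesh2d.element_region):
            w = [lo + t[0], lo + t[1], lo + t[2],
                 hi + t[0], hi + t[1], hi + t[2]]
            tets.extend(_split_prism(w))
            labels.extend([lab] * 3)
    simplices = np.asarray(tets, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int32)

    vols = _fem.element_volumes(nodes, simplices)
    flip = vols < 0
    simplices[flip, 0], simplices[flip, 1] = (simplices[flip, 1].copy(),
                                              simplices[flip, 0].copy())

    elem_sets = {}
    base = np.arange(len(mesh2d.simplices))
    for name, idx in mesh2d.element_sets.items():
        mask = np.isin(base, idx)
        tet_mask = np.repeat(np.tile(mask, n_layers), 3)
        elem_sets[name] = np.flatnonzero(tet_mask)

    bnd = {}
    for name, idx in mesh2d.boundary_sets.items():
        bnd[name] = np.concatenate([idx + k * n for k in range(n_layers + 1)])

    mesh = LabeledMesh(nodes=nodes, simplices=simplices,
                       element_region=labels, boundary_sets=bnd,
                       element_sets=elem_sets)
    mesh.boundary_sets["csf_outer"] = mesh.exterior_nodes()
    return mesh


def _split_prism(w):
    """Dompierre et al. prism-to-3-tets split keyed on global indices."""
    rot = {0: (0, 1, 2, 3, 4, 5), 1: (1, 2, 0, 4, 5, 3),
           2: (2, 0, 1, 5, 3, 4), 3: (3, 5, 4, 0, 2, 1),
           4: (4, 3, 5, 1, 0, 2), 5: (5, 4, 3, 2, 1, 0)}
    i = int(np.argmin(w))
    v = [w[j] for j in rot[i]]
    if min(v[1], v[5]) < min(v[2], v[4]):
        return [(v[0], v[1], v[2], v[5]),
                (v[0], v[1], v[5], v[4]),
                (v[0], v[4], v[5], v[3])]
    return [(v[0], v[1], v[2], v[4]),
            (v[0], v[4], v[2], v[5]),
            (v[0], v[4], v[5], v[3])]


# ------------------------------------------------------- other operations

def extract_region_boundary(mesh: LabeledMesh, region: int | str):
    """Closed boundary of one labeled region.

    2D: list of node-index loops, largest loop first and counter-clockwise
    (outward normal), interior loops clockwise.  3D: (m, 3) array of
    outward-oriented boundary triangles.
    """
    elems = mesh.region_elements(region)
    if len(elems) == 0:
        name = region if isinstance(region, str) else REGION_NAMES.get(region)
        raise ValueError(f"region {name!r} has no elements in this mesh")
    facets = mesh.boundary_facets(elems)
    if mesh.dimension == 3:
        return _orient_surface(mesh, elems, facets)

    nxt: dict[int, list[int]] = {}
    for a, b in facets:
        nxt.setdefault(int(a), []).append(int(b))
        nxt.setdefault(int(b), []).append(int(a))
    unused = {tuple(sorted(e)) for e in facets.tolist()}
    loops = []
    while unused:
        a, b = unused.pop()
        loop = [a, b]
        while True:
            cands = [c for c in nxt[loop[-1]]
                     if tuple(sorted((loop[-1], c))) in unused]
            if not cands:
                break
            c = cands[0]
            unused.discard(tuple(sorted((loop[-1], c))))
            if c == loop[0]:
                break
            loop.append(c)
        loops.append(np.asarray(loop))

    def signed_area(loop):
        p = mesh.nodes[loop]
        x, y = p[:, 0], p[:, 1]
        return 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)

    loops.sort(key=lambda lp: -abs(signed_area(lp)))
    out = []
    for i, lp in enumerate(loops):
        want_ccw = i == 0
        if (signed_area(lp) > 0) != want_ccw:
            lp = lp[::-1]
        out.append(lp)
    return out


def _orient_surface(mesh, elems, facets):
    """Orient boundary triangles so normals point away from the region."""
    simp = mesh.simplices[elems]
    facet_map = {}
    for e, tet in enumerate(simp):
        for drop in range(4):
            face = tuple(sorted(np.delete(tet, drop)))
            facet_map[face] = e
    out = []
    for f in facets:
        e = facet_map[tuple(sorted(f))]
        centroid = mesh.nodes[simp[e]].mean(axis=0)
        p = mesh.nodes[f]
        nrm = np.cross(p[1] - p[0], p[2] - p[0])
        if np.dot(nrm, p.mean(axis=0) - centroid) < 0:
            f = f[[0, 2, 1]]
        out.append(f)
    return np.asarray(out)


def boundary_length(mesh: LabeledMesh, loop: np.ndarray) -> float:
    p = mesh.nodes[loop]
    return float(np.linalg.norm(np.diff(np.vstack([p, p[:1]]), axis=0),
                                axis=1).sum())


def mesh_quality_report(mesh: LabeledMesh,
                        edge_band: tuple[float, float] | None = None
                        ) -> MeshQualityReport:
    """Edge-length / aspect-ratio / volume diagnostics."""
    simp = mesh.simplices
    nv = simp.shape[1]
    pairs = [(a, b) for a in range(nv) for b in range(a + 1, nv)]
    edges = np.unique(np.sort(np.concatenate(
        [simp[:, [a, b]] for a, b in pairs]), axis=1), axis=0)
    elen = np.linalg.norm(mesh.nodes[edges[:, 0]] - mesh.nodes[edges[:, 1]],
                          axis=1)

    vols = mesh.element_volumes()
    # aspect ratio: longest edge over inradius-equivalent scale
    el = np.stack([np.linalg.norm(
        mesh.nodes[simp[:, a]] - mesh.nodes[simp[:, b]], axis=1)
        for a, b in pairs], axis=1)
    longest = el.max(axis=1)
    dim = mesh.dimension
    with np.errstate(divide="ignore"):
        if dim == 2:
            inr = 2.0 * np.abs(vols) / el.sum(axis=1)
        else:
            # rough 3D surrogate: volume / longest-face scale
            inr = np.abs(vols) / (longest ** 2)
        aspect = longest / np.where(inr > 0, inr, np.inf)

    frac = None
    if edge_band is not None:
        lo, hi = edge_band
        frac = float(np.mean((elen >= lo) & (elen <= hi)))
    return MeshQualityReport(
        n_nodes=mesh.n_nodes, n_elements=mesh.n_elements,
        min_edge=float(elen.min()), max_edge=float(elen.max()),
        max_aspect_ratio=float(aspect.max()),
        min_volume=float(vols.min()),
        edge_band=edge_band, fraction_in_band=frac,
        inverted_elements=int(np.sum(vols <= 0)))


# ---------------------------------------------------- simple test meshes

def build_strip_mesh(length: float, width: float, h: float,
                     region: int = WM) -> LabeledMesh:
    """Structured triangulated strip, useful for 1D travelling-wave checks."""
    nx = max(2, int(round(length / h)))
    ny = max(1, int(round(width / h)))
    xs = np.linspace(0.0, length, nx + 1)
    ys = np.linspace(0.0, width, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):
        return i * (ny + 1) + j

    tris = []
    for i in range(nx):
        for j in range(ny):
            a, b = nid(i, j), nid(i + 1, j)
            c, d = nid(i + 1, j + 1), nid(i, j + 1)
            tris.append((a, b, c))
            tris.append((a, c, d))
    simplices = np.asarray(tris, dtype=np.int64)
    mesh = LabeledMesh(nodes=nodes, simplices=simplices,
                       element_region=np.full(len(simplices), region,
                                              dtype=np.int32))
    mesh.boundary_sets["csf_outer"] = mesh.exterior_nodes()
    return mesh


def default_phantom(seed: int = 0, **overrides) -> LabeledMesh:
    """Convenience wrapper: the default study phantom with a given seed."""
    return build_brain_phantom(replace(PhantomParams(), seed=seed,
                                       **overrides))
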