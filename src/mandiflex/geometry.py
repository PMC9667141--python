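"""Parametric mandible-surrogate meshes.

The surrogate is a swept, thickened U-arch (horseshoe) with posterior
vertical rami -- not an anatomical mandible.  It reproduces the topology and
load paths needed for comparative chewing simulations: a cortical shell
around a trabecular core, tooth blocks along the superior corpus border,
condylar and bite-point node sets, bilateral attachment patches for the five
jaw-closing muscles, an oblique fracture through the left angle, and
miniplate/screw fixation constructs (one superior plate, or superior plus
inferior lateral plate).

Global frame: origin at the inter-condylar midpoint, x superior-inferior
(positive up), y anterior-posterior (positive anterior), z mediolateral
(positive toward the anatomical left).  Units are mm throughout.

Meshing strategy: structured hexahedral lattices (a swept corpus/arch block,
ramus boxes, tooth layers, plate and screw boxes) merged on coincident
nodes, then each hexahedron is split into 12 tetrahedra about its centroid
with face diagonals chosen through the lowest global node index.  The face
rule depends only on the shared face's node ids, so adjoining blocks always
triangulate shared faces identically and the mesh is conforming by
construction.  The construction is fully deterministic: identical parameters
give byte-identical meshes.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.spatial import cKDTree

REGION_NAMES = ("cortical", "trabecular", "tooth", "plate", "screw")
REGION_CODES = {name: i for i, name in enumerate(REGION_NAMES)}
BIOLOGICAL_CODES = (0, 1, 2)

_MERGE_DECIMALS = 6


class ParameterError(ValueError):
    """A geometry parameter violates its stated invariant."""


class GeometryError(RuntimeError):
    """A geometric operation produced an invalid configuration."""


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class PlateSpec:
    """A fixation miniplate lying flat on the lateral (buccal) surface.

    ``x_range``/``y_range`` give the footprint on the bone surface,
    ``thickness`` the outward (z) extent, ``hole_ys`` the screw positions
    along the plate and ``screw_depth`` how far screws reach into bone.
    """

    name: str
    x_range: tuple[float, float]
    y_range: tuple[float, float]
    thickness: float = 1.0
    hole_ys: tuple[float, ...] = ()
    screw_depth: float = 6.0
    screw_halfwidth: float = 1.0

    def scaled(self, s: float) -> "PlateSpec":
        return PlateSpec(
            self.name,
            (self.x_range[0] * s, self.x_range[1] * s),
            (self.y_range[0] * s, self.y_range[1] * s),
            self.thickness * s,
            tuple(y * s for y in self.hole_ys),
            self.screw_depth * s,
            self.screw_halfwidth * s,
        )


@dataclass(frozen=True)
class GeometryParams:
    """Lengths (mm) defining the surrogate.  All lengths must be positive.

    Defaults approximate an adult human mandible: 113.5 mm long
    (anterior-most point to the condylar plane) with a ~96 mm inter-condylar
    span.  ``target_edge_length`` defaults to a desk-scale 3 mm; the 1 mm
    resolution used for the reference anatomical models is reachable by
    configuration.
    """

    arch_radius: float = 48.0
    corpus_height: float = 24.0
    corpus_width: float = 11.0
    ramus_height: float = 40.0
    ramus_ap_width: float = 33.0
    condyle_height: float = 8.0
    cortical_thickness: float = 2.5
    tooth_height: float = 8.0
    target_edge_length: float = 3.0
    mandible_length: float = 113.5
    toothrow_posterior_y: float = 22.0
    tooth_landmarks: tuple[tuple[str, float], ...] = (
        ("P3", 55.0), ("P4", 49.0), ("M1", 41.0), ("M2", 33.0), ("M3", 25.0),
    )
    fracture_point: tuple[float, float, float] | None = None
    fracture_normal: tuple[float, float, float] | None = None
    plates: tuple[PlateSpec, ...] | None = None
    rng_seed: int = 7

    # -- derived layout -----------------------------------------------------

    @property
    def x_corpus_top(self) -> float:
        return -self.ramus_height

    @property
    def x_corpus_bottom(self) -> float:
        return -self.ramus_height - self.corpus_height

    @property
    def y_arch_center(self) -> float:
        return self.mandible_length - self.arch_radius - self.corpus_width / 2.0

    @property
    def z_lateral(self) -> float:
        """Outer (buccal) surface |z| along the straight corpus segments."""
        return self.arch_radius + self.corpus_width / 2.0

    @property
    def z_lingual(self) -> float:
        return self.arch_radius - self.corpus_width / 2.0

    def default_fracture_plane(self) -> tuple[np.ndarray, np.ndarray]:
        """Oblique left-angle cut, if not explicitly configured: from the
        inferior border of the posterior corpus antero-superiorly to the
        retromolar region at the superior corpus border (the classic angle
        fracture path through the third-molar region)."""
        if self.fracture_point is not None and self.fracture_normal is not None:
            n = np.asarray(self.fracture_normal, float)
            return np.asarray(self.fracture_point, float), n / np.linalg.norm(n)
        y_sup = 0.5 * (self.ramus_ap_width / 2.0 + self.toothrow_posterior_y)
        p_inf = np.array([self.x_corpus_bottom, -0.4 * self.ramus_ap_width, 0.0])
        p_sup = np.array([self.x_corpus_top, y_sup, 0.0])
        slope = (p_sup[1] - p_inf[1]) / (p_sup[0] - p_inf[0])
        point = 0.5 * (p_inf + p_sup)
        point[2] = self.arch_radius
        normal = np.array([-slope, 1.0, 0.0])
        return point, normal / np.linalg.norm(normal)

    def fracture_trace_y(self, x: float) -> float:
        """y-position of the default fracture plane's trace at height x."""
        point, normal = self.default_fracture_plane()
        return point[1] - normal[0] / normal[1] * (x - point[0])

    def default_plates(self) -> tuple[PlateSpec, PlateSpec]:
        """Superior (Champy-style, 24 x 4 x 1 mm) and inferior lateral
        (26.1 x 2.5 x 1 mm) miniplates, each centred on the fracture trace
        at its own height so two screws sit in each fragment."""
        if self.plates is not None:
            return self.plates
        s = self.mandible_length / 113.5
        xt, xb = self.x_corpus_top, self.x_corpus_bottom
        t_sup = self.fracture_trace_y(xt - 3.0 * s)
        champy = PlateSpec(
            name="champy",
            x_range=(xt - 5.0 * s, xt - 1.0 * s),
            y_range=(t_sup - 12.0 * s, t_sup + 12.0 * s),
            thickness=1.0 * s,
            hole_ys=(t_sup - 9.0 * s, t_sup - 5.0 * s,
                     t_sup + 5.0 * s, t_sup + 9.0 * s),
            screw_depth=6.0 * s,
            screw_halfwidth=1.0 * s,
        )
        t_inf = self.fracture_trace_y(xb + 1.25 * s)
        inferior = PlateSpec(
            name="inferior",
            x_range=(xb, xb + 2.5 * s),
            y_range=(t_inf - 4.9 * s, t_inf + 21.2 * s),
            thickness=1.0 * s,
            hole_ys=(t_inf - 3.6 * s, t_inf - 1.4 * s,
                     t_inf + 5.0 * s, t_inf + 9.0 * s),
            screw_depth=6.0 * s,
            screw_halfwidth=1.0 * s,
        )
        return champy, inferior

    def scaled(self, s: float) -> "GeometryParams":
        """Uniformly scale every length parameter by ``s`` (isometry)."""
        if s <= 0:
            raise ParameterError(f"scale factor must be positive, got {s}")
        kw = {}
        for f in (
            "arch_radius", "corpus_height", "corpus_width", "ramus_height",
            "ramus_ap_width", "condyle_height", "cortical_thickness",
            "tooth_height", "target_edge_length", "mandible_length",
            "toothrow_posterior_y",
        ):
            kw[f] = getattr(self, f) * s
        kw["tooth_landmarks"] = tuple((n, y * s) for n, y in self.tooth_landmarks)
        if self.fracture_point is not None:
            kw["fracture_point"] = tuple(c * s for c in self.fracture_point)
            kw["fracture_normal"] = self.fracture_normal
        if self.plates is not None:
            kw["plates"] = tuple(p.scaled(s) for p in self.plates)
        return replace(self, **kw)

    def validate(self) -> None:
        for f in (
            "arch_radius", "corpus_height", "corpus_width", "ramus_height",
            "ramus_ap_width", "condyle_height", "cortical_thickness",
            "tooth_height", "target_edge_length", "mandible_length",
        ):
            if getattr(self, f) <= 0:
                raise ParameterError(f"{f} must be positive, got {getattr(self, f)}")
        if self.condyle_height >= self.ramus_height:
            raise ParameterError(
                "condyle_height must be smaller than ramus_height")
        if self.cortical_thickness >= self.corpus_width / 2.0:
            raise ParameterError(
                "cortical_thickness must be smaller than corpus_width/2 "
                f"({self.cortical_thickness} >= {self.corpus_width / 2.0})"
            )
        smallest = min(self.corpus_width, self.corpus_height,
                       self.ramus_ap_width, self.tooth_height)
        if self.target_edge_length > smallest:
            raise ParameterError(
                "target_edge_length larger than smallest feature "
                f"({self.target_edge_length} > {smallest})"
            )
        if self.y_arch_center <= self.ramus_ap_width / 2.0:
            raise ParameterError(
                "mandible_length too short for the given arch_radius / "
                "ramus_ap_width (corpus straight segment has negative length)"
            )
        for name, y in self.tooth_landmarks:
            if not (self.toothrow_posterior_y <= y <= self.y_arch_center):
                raise ParameterError(
                    f"tooth_landmarks[{name}]={y} outside the straight toothrow "
                    f"segment [{self.toothrow_posterior_y}, {self.y_arch_center}]"
                )


# ---------------------------------------------------------------------------
# mesh container


@dataclass
class FractureInterface:
    """Paired, initially-coincident triangulated fracture surfaces."""

    pairs: np.ndarray          # (k, 2) node ids: column 0 fragment A, 1 fragment B
    tris_a: np.ndarray         # (t, 3) triangles on the fragment-A side
    tris_b: np.ndarray
    normal: np.ndarray         # unit, pointing from fragment B toward fragment A


@dataclass
class ContactSurface:
    """A registered plate-bone contact interface (node-to-node pairs)."""

    name: str
    pairs: np.ndarray          # (k, 2): column 0 plate node, 1 bone node
    normal: np.ndarray         # unit, from bone toward plate
    gap0: np.ndarray           # initial gaps along the normal


@dataclass
class LabeledMesh:
    nodes: np.ndarray                       # (n, 3) float64, mm
    elements: np.ndarray                    # (m, 4) int, tetrahedra
    regions: np.ndarray                     # (m,) int codes into REGION_NAMES
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    element_sets: dict[str, np.ndarray] = field(default_factory=dict)
    ties: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), int))
    fracture: FractureInterface | None = None
    contact_surfaces: list[ContactSurface] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    params: GeometryParams | None = None

    # -- basic queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def biological_mask(self) -> np.ndarray:
        return np.isin(self.regions, BIOLOGICAL_CODES)

    def element_volumes(self) -> np.ndarray:
        x = self.nodes[self.elements]
        return np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0

    def total_volume(self, mask: np.ndarray | None = None) -> float:
        v = self.element_volumes()
        return float(v.sum() if mask is None else v[mask].sum())

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def connected_components(self, mask: np.ndarray | None = None):
        """Edge-connected components (via shared nodes) of a subset of
        elements.  Returns (count, labels-over-subset)."""
        els = self.elements if mask is None else self.elements[mask]
        m = len(els)
        if m == 0:
            return 0, np.zeros(0, int)
        rows = np.repeat(np.arange(m), 4)
        inc = sparse.coo_matrix(
            (np.ones(4 * m, bool), (rows, els.ravel())),
            shape=(m, self.n_nodes),
        ).tocsr()
        adj = inc @ inc.T
        return csgraph.connected_components(adj, directed=False)[0:2]

    def boundary_faces(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Triangular faces used by exactly one element of the subset."""
        els = self.elements if mask is None else self.elements[mask]
        faces = np.concatenate([
            els[:, [1, 2, 3]], els[:, [0, 3, 2]],
            els[:, [0, 1, 3]], els[:, [0, 2, 1]],
        ])
        key = np.sort(faces, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
        return faces[idx[counts == 1]]

    def surface_nodes(self, mask: np.ndarray | None = None) -> np.ndarray:
        return np.unique(self.boundary_faces(mask))

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.nodes).tobytes())
        h.update(np.ascontiguousarray(self.elements).tobytes())
        h.update(np.ascontiguousarray(self.regions).tobytes())
        for name in sorted(self.node_sets):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.node_sets[name]).tobytes())
        return h.hexdigest()

    def copy(self) -> "LabeledMesh":
        return LabeledMesh(
            nodes=self.nodes.copy(),
            elements=self.elements.copy(),
            regions=self.regions.copy(),
            node_sets={k: v.copy() for k, v in self.node_sets.items()},
            element_sets={k: v.copy() for k, v in self.element_sets.items()},
            ties=self.ties.copy(),
            fracture=self.fracture,
            contact_surfaces=list(self.contact_surfaces),
            metadata=dict(self.metadata),
            params=self.params,
        )


# ---------------------------------------------------------------------------
# lattice machinery


class _NodeBank:
    """Coordinate-keyed node registry; merges coincident nodes exactly."""

    def __init__(self):
        self._coords: list[tuple[float, float, float]] = []
        self._index: dict[tuple[float, float, float], int] = {}

    def add(self, x: float, y: float, z: float) -> int:
        key = (round(x, _MERGE_DECIMALS), round(y, _MERGE_DECIMALS),
               round(z, _MERGE_DECIMALS))
        i = self._index.get(key)
        if i is None:
            i = len(self._coords)
            self._index[key] = i
            self._coords.append(key)
        return i

    def array(self) -> np.ndarray:
        return np.array(self._coords, float).reshape(-1, 3)


_HEX_FACES = ((0, 1, 2, 3), (4, 5, 6, 7), (0, 1, 5, 4),
              (1, 2, 6, 5), (2, 3, 7, 6), (3, 0, 4, 7))


def _split_hexes(hexes: list[tuple[int, ...]], bank: _NodeBank,
                 coords_of) -> tuple[list[tuple[int, int, int, int]], list[int]]:
    """Split hexes into 12 tets each about the hex centroid, using the
    lowest-global-id face diagonal rule (conforming across any block
    adjacency).  Returns (tets, hex index per tet)."""
    tets: list[tuple[int, int, int, int]] = []
    owner: list[int] = []
    for ih, h in enumerate(hexes):
        pts = [coords_of(i) for i in h]
        cx = sum(p[0] for p in pts) / 8.0
        cy = sum(p[1] for p in pts) / 8.0
        cz = sum(p[2] for p in pts) / 8.0
        c = bank.add(cx, cy, cz)
        for fa in _HEX_FACES:
            q = [h[i] for i in fa]
            m = q.index(min(q))
            tris = ((q[m], q[(m + 1) % 4], q[(m + 2) % 4]),
                    (q[m], q[(m + 2) % 4], q[(m + 3) % 4]))
            for tri in tris:
                tets.append((tri[0], tri[1], tri[2], c))
                owner.append(ih)
    return tets, owner


def _orient_tets(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    x = nodes[tets]
    vol = np.linalg.det(x[:, 1:] - x[:, :1])
    flip = vol < 0
    tets[flip] = tets[flip][:, [1, 0, 2, 3]]
    return tets


def _grid(lo: float, hi: float, h: float) -> np.ndarray:
    n = max(1, int(round((hi - lo) / h)))
    return np.linspace(lo, hi, n + 1)


# ---------------------------------------------------------------------------
# builder


def _stations(p: GeometryParams):
    """Centerline stations (y, z) and outward in-plane normals (ny, nz) of
    the swept arch, ordered right-posterior -> anterior -> left-posterior.
    Built from a mirrored right half so the layout is exactly symmetric."""
    h = p.target_edge_length
    R = p.arch_radius
    yc = p.y_arch_center
    ap2 = p.ramus_ap_width / 2.0

    y_post = _grid(-ap2, ap2, h)            # under the ramus footprint
    y_ant = _grid(ap2, yc, h)[1:]           # up to the arch junction
    n_arc = max(2, int(round(np.pi * R / h)))
    if n_arc % 2:
        n_arc += 1
    phi_half = np.linspace(0.0, np.pi / 2.0, n_arc // 2 + 1)[1:]  # (0, pi/2]

    ys, zs, nys, nzs = [], [], [], []
    # right straight: z = -R, outward normal (0, -1)
    for y in np.concatenate([y_post, y_ant]):
        ys.append(y); zs.append(-R); nys.append(0.0); nzs.append(-1.0)
    # arc interior (the phi = +-pi/2 junction stations already belong to the
    # straight segments); the left half mirrors the right half exactly
    half = [(yc + R * np.cos(ph), R * np.sin(ph), np.cos(ph), np.sin(ph))
            for ph in phi_half[:-1]]
    for y, z, ny, nz in reversed(half):
        ys.append(y); zs.append(-z); nys.append(ny); nzs.append(-nz)
    ys.append(yc + R); zs.append(0.0); nys.append(1.0); nzs.append(0.0)
    for y, z, ny, nz in half:
        ys.append(y); zs.append(z); nys.append(ny); nzs.append(nz)
    # left straight
    for y in np.concatenate([y_ant[::-1], y_post[::-1]]):
        ys.append(y); zs.append(R); nys.append(0.0); nzs.append(1.0)
    return (np.array(ys), np.array(zs), np.array(nys), np.array(nzs),
            len(y_post) - 1)


def build_surrogate_mandible(params: GeometryParams | None = None) -> LabeledMesh:
    """Build the healthy (one-component) surrogate with every node set the
    downstream loading/analysis stages need."""
    p = params or GeometryParams()
    p.validate()
    h = p.target_edge_length
    R, w = p.arch_radius, p.corpus_width
    xt, xb = p.x_corpus_top, p.x_corpus_bottom
    ap2 = p.ramus_ap_width / 2.0

    sy, sz, sny, snz, n_post = _stations(p)
    n_stat = len(sy)
    U = _grid(-w / 2.0, w / 2.0, h)
    X = _grid(xb, xt, h)
    XT = _grid(xt, xt + p.tooth_height, h)
    nu, nk, nkt = len(U) - 1, len(X) - 1, len(XT) - 1

    bank = _NodeBank()
    coords: dict[int, tuple[float, float, float]] = {}

    def put(x, y, z):
        i = bank.add(x, y, z)
        coords[i] = (round(x, _MERGE_DECIMALS), round(y, _MERGE_DECIMALS),
                     round(z, _MERGE_DECIMALS))
        return i

    # corpus sweep lattice
    corp = np.empty((n_stat, nu + 1, nk + 1), int)
    for i in range(n_stat):
        for j, u in enumerate(U):
            y = sy[i] + u * sny[i]
            z = sz[i] + u * snz[i]
            for k, x in enumerate(X):
                corp[i, j, k] = put(x, y, z)

    hexes: list[tuple[int, ...]] = []
    hex_region: list[int] = []
    tc = p.cortical_thickness
    for i in range(n_stat - 1):
        for j in range(nu):
            uc = 0.5 * (U[j] + U[j + 1])
            du = w / 2.0 - abs(uc)
            for k in range(nk):
                xc = 0.5 * (X[k] + X[k + 1])
                dist = min(du, xc - xb, xt - xc)
                hexes.append((corp[i, j, k], corp[i + 1, j, k],
                              corp[i + 1, j + 1, k], corp[i, j + 1, k],
                              corp[i, j, k + 1], corp[i + 1, j, k + 1],
                              corp[i + 1, j + 1, k + 1], corp[i, j + 1, k + 1]))
                hex_region.append(0 if dist < tc else 1)

    # tooth layer over stations anterior to the toothrow limit
    tooth = {}
    for i in range(n_stat):
        if sy[i] >= p.toothrow_posterior_y - 1e-9:
            col = np.empty((nu + 1, nkt + 1), int)
            for j, u in enumerate(U):
                y = sy[i] + u * sny[i]
                z = sz[i] + u * snz[i]
                for k, x in enumerate(XT):
                    col[j, k] = put(x, y, z)
            tooth[i] = col
    for i in range(n_stat - 1):
        if i in tooth and (i + 1) in tooth:
            a, b = tooth[i], tooth[i + 1]
            for j in range(nu):
                for k in range(nkt):
                    hexes.append((a[j, k], b[j, k], b[j + 1, k], a[j + 1, k],
                                  a[j, k + 1], b[j, k + 1], b[j + 1, k + 1],
                                  a[j + 1, k + 1]))
                    hex_region.append(2)

    # rami: boxes over the posterior straight segments, topped by condylar
    # knobs whose superior faces define the x = 0 condylar plane
    ch = p.condyle_height
    XR = _grid(xt, -ch, h)
    XC = _grid(-ch, 0.0, h)
    nkr, nkc = len(XR) - 1, len(XC) - 1
    YR = sy[: n_post + 1]                       # station y-values under ramus
    knob_sel = np.abs(YR) <= condyle_halfwidth(p) + 1e-9
    if knob_sel.sum() < 2:
        mid = np.argsort(np.abs(YR))[:2]
        knob_sel = np.zeros(len(YR), bool)
        knob_sel[mid] = True
    YK = YR[knob_sel]
    for sgn in (-1.0, 1.0):
        # cross-section z-values coincide with the corpus lattice there
        # (U is symmetric about zero)
        ZR = np.sort(sgn * R + U)
        ram = np.empty((len(YR), nu + 1, nkr + 1), int)
        for i, y in enumerate(YR):
            for j, z in enumerate(ZR):
                for k, x in enumerate(XR):
                    ram[i, j, k] = put(x, y, z)
        for i in range(len(YR) - 1):
            yc_ = 0.5 * (YR[i] + YR[i + 1])
            for j in range(nu):
                zc = 0.5 * (ZR[j] + ZR[j + 1])
                dz = w / 2.0 - abs(abs(zc) - R)
                for k in range(nkr):
                    xc = 0.5 * (XR[k] + XR[k + 1])
                    dist = min(dz, ap2 - abs(yc_), -ch - xc)
                    hexes.append((ram[i, j, k], ram[i + 1, j, k],
                                  ram[i + 1, j + 1, k], ram[i, j + 1, k],
                                  ram[i, j, k + 1], ram[i + 1, j, k + 1],
                                  ram[i + 1, j + 1, k + 1], ram[i, j + 1, k + 1]))
                    hex_region.append(0 if dist < tc else 1)
        knob = np.empty((len(YK), nu + 1, nkc + 1), int)
        for i, y in enumerate(YK):
            for j, z in enumerate(ZR):
                for k, x in enumerate(XC):
                    knob[i, j, k] = put(x, y, z)
        for i in range(len(YK) - 1):
            for j in range(nu):
                for k in range(nkc):
                    hexes.append((knob[i, j, k], knob[i + 1, j, k],
                                  knob[i + 1, j + 1, k], knob[i, j + 1, k],
                                  knob[i, j, k + 1], knob[i + 1, j, k + 1],
                                  knob[i + 1, j + 1, k + 1],
                                  knob[i, j + 1, k + 1]))
                    hex_region.append(0)        # condylar knob: cortical

    tets, owner = _split_hexes(hexes, bank, lambda i: coords[i])
    nodes = bank.array()
    elements = _orient_tets(nodes, np.array(tets, int))
    regions = np.array(hex_region, int)[np.array(owner, int)]

    mesh = LabeledMesh(nodes=nodes, elements=elements, regions=regions,
                       params=p)
    vols = mesh.element_volumes()
    if (vols <= 0).any():
        bad = int(np.argmin(vols))
        raise GeometryError(f"element {bad} has non-positive volume {vols[bad]:g}")

    _add_node_sets(mesh, p)

    point, normal = p.default_fracture_plane()
    mesh.metadata.update(
        mandible_length=p.mandible_length,
        target_edge_length=h,
        mean_edge_length=float(np.mean(np.cbrt(vols)) * 6 ** (1 / 3)),
        z_lateral=p.z_lateral,
        z_lingual=p.z_lingual,
        fracture_point=tuple(point),
        fracture_normal=tuple(normal),
        fracture_z_guard=R / 3.0,
        landmarks={**dict(p.tooth_landmarks),
                   "coronoid_tip": ap2, "angle": -ap2 / 2.0, "condyle": 0.0},
        state="healthy",
    )
    return mesh


def condyle_halfwidth(p: GeometryParams) -> float:
    """AP half-extent of the condylar knob footprint."""
    return 0.16 * p.ramus_ap_width


def _add_node_sets(mesh: LabeledMesh, p: GeometryParams) -> None:
    nd = mesh.nodes
    tol = 1e-6
    R, w = p.arch_radius, p.corpus_width
    xt = p.x_corpus_top
    ap = p.ramus_ap_width

    x_tooth_top = xt + p.tooth_height
    on_condyle_top = np.abs(nd[:, 0]) < tol
    on_ramus_top = np.abs(nd[:, 0] + p.condyle_height) < tol
    for sgn, suf in ((1.0, "L"), (-1.0, "R")):
        side = sgn * nd[:, 2] > 0
        lat = np.abs(sgn * nd[:, 2] - p.z_lateral) < tol
        med = np.abs(sgn * nd[:, 2] - p.z_lingual) < tol
        in_ramus_y = np.abs(nd[:, 1]) <= ap / 2.0 + tol
        x = nd[:, 0]

        mesh.node_sets[f"condyle_{suf}"] = np.flatnonzero(
            on_condyle_top & side)
        mesh.node_sets[f"anterior_temporalis_{suf}"] = np.flatnonzero(
            on_ramus_top & side & (nd[:, 1] >= 0.2 * ap))
        mesh.node_sets[f"posterior_temporalis_{suf}"] = np.flatnonzero(
            on_ramus_top & side & (nd[:, 1] <= -0.2 * ap))
        mesh.node_sets[f"superficial_masseter_{suf}"] = np.flatnonzero(
            lat & in_ramus_y & (x >= xt - tol) & (x <= xt + 0.6 * p.ramus_height))
        mesh.node_sets[f"deep_masseter_{suf}"] = np.flatnonzero(
            lat & in_ramus_y & (x > xt + 0.6 * p.ramus_height) & (x <= -0.05 * p.ramus_height))
        mesh.node_sets[f"medial_pterygoid_{suf}"] = np.flatnonzero(
            med & in_ramus_y & (x >= xt - tol) & (x <= xt + 0.5 * p.ramus_height))

        tooth_top = np.abs(nd[:, 0] - x_tooth_top) < tol
        land = dict(p.tooth_landmarks)
        for lm in ("P3", "P4", "M1"):
            yl = land[lm]
            cand = np.flatnonzero(tooth_top & side)
            if len(cand) == 0:
                raise GeometryError(f"no tooth-top nodes for bite_{lm}_{suf}")
            ys = np.unique(np.round(nd[cand, 1], 6))
            ynear = ys[np.argmin(np.abs(ys - yl))]
            mesh.node_sets[f"bite_{lm}_{suf}"] = cand[
                np.abs(nd[cand, 1] - ynear) < 1e-6]

    for name, ids in mesh.node_sets.items():
        if len(ids) == 0:
            raise GeometryError(f"node set {name!r} is empty")


def analytic_volume(p: GeometryParams) -> float:
    """Closed-form volume of the parametric solid (corpus sweep + tooth
    layer + rami + condylar knobs) before meshing."""
    L_straight = p.y_arch_center - (-p.ramus_ap_width / 2.0)
    path = 2.0 * L_straight + np.pi * p.arch_radius
    corpus = p.corpus_width * p.corpus_height * path
    tooth_straight = max(0.0, p.y_arch_center - p.toothrow_posterior_y)
    tooth_path = 2.0 * tooth_straight + np.pi * p.arch_radius
    teeth = p.corpus_width * p.tooth_height * tooth_path
    rami = 2.0 * p.ramus_ap_width * p.corpus_width * (
        p.ramus_height - p.condyle_height)
    # the knob footprint snaps to the ramus station lattice
    ys = _grid(-p.ramus_ap_width / 2.0, p.ramus_ap_width / 2.0,
               p.target_edge_length)
    sel = ys[np.abs(ys) <= condyle_halfwidth(p) + 1e-9]
    if len(sel) < 2:
        sel = ys[np.argsort(np.abs(ys))[:2]]
    knobs = 2.0 * (sel.max() - sel.min()) * p.corpus_width * p.condyle_height
    return corpus + teeth + rami + knobs


# ---------------------------------------------------------------------------
# fracture


def cut_angle_fracture(mesh: LabeledMesh,
                       plane: tuple | None = None) -> LabeledMesh:
    """Split the biological elements into two fragments along an element-face
    surface approximating the given plane (point, unit normal; defaults to
    the parametric left-angle plane).

    Nodes on the interface are duplicated in place, giving two coincident
    paired surfaces with exactly zero initial gap.
    """
    if plane is None:
        point = np.asarray(mesh.metadata["fracture_point"], float)
        normal = np.asarray(mesh.metadata["fracture_normal"], float)
    else:
        point = np.asarray(plane[0], float)
        normal = np.asarray(plane[1], float)
    normal = normal / np.linalg.norm(normal)
    z_guard = mesh.metadata.get("fracture_z_guard", 0.0)

    bio = mesh.biological_mask()
    cent = mesh.element_centroids()
    d = (cent - point) @ normal
    # the cut runs through bone; tooth elements follow the fragment that
    # holds their socket (anterior fragment for the default angle plane)
    side_b = (bio & (d < 0.0) & (cent[:, 2] > z_guard)
              & (mesh.regions != REGION_CODES["tooth"]))
    side_a = bio & ~side_b
    if not side_b.any() or not side_a.any():
        raise GeometryError("fracture plane does not intersect the mesh")

    out = mesh.copy()
    nc_a = out.connected_components(side_a)[0]
    nc_b = out.connected_components(side_b)[0]
    if nc_a != 1 or nc_b != 1:
        raise GeometryError(
            f"planar cut produced {nc_a + nc_b} biological components (expected 2)")

    nodes_a = np.unique(out.elements[side_a])
    nodes_b = np.unique(out.elements[side_b])
    shared = np.intersect1d(nodes_a, nodes_b, assume_unique=True)
    if len(shared) == 0:
        raise GeometryError("fracture plane does not intersect the mesh")
    h = out.metadata.get("mean_edge_length", out.metadata.get(
        "target_edge_length", 1.0))
    d_iface = np.abs((out.nodes[shared] - point) @ normal)
    if d_iface.max() > 3.0 * h:
        raise GeometryError(
            "fracture plane does not intersect the mesh (interface would lie "
            f"{d_iface.max():.1f} mm off the plane)")

    # interface faces: element faces shared between an A and a B element
    def faces_of(els):
        return np.concatenate([
            els[:, [1, 2, 3]], els[:, [0, 3, 2]],
            els[:, [0, 1, 3]], els[:, [0, 2, 1]]])

    fa = faces_of(out.elements[side_a])
    fb = faces_of(out.elements[side_b])
    ka = np.sort(fa, axis=1)
    kb = np.sort(fb, axis=1)
    kb_view = {tuple(r) for r in kb.tolist()}
    sel = np.array([tuple(r) in kb_view for r in ka.tolist()], bool)
    tris_a = fa[sel]

    n0 = out.n_nodes
    dup_of = {int(n): n0 + i for i, n in enumerate(shared)}
    out.nodes = np.vstack([out.nodes, out.nodes[shared]])
    remap = np.arange(out.n_nodes)
    for orig, dup in dup_of.items():
        remap[orig] = dup
    els_b = out.elements[side_b]
    out.elements = out.elements.copy()
    out.elements[side_b] = remap[els_b]
    tris_b = remap[tris_a]

    pairs = np.array([[int(n), dup_of[int(n)]] for n in shared], int)
    # orient the stored normal from fragment B toward fragment A (i.e. the
    # direction in which the gap opens): fragment A lies at d > 0
    out.fracture = FractureInterface(pairs=pairs, tris_a=tris_a, tris_b=tris_b,
                                     normal=normal.copy())
    out.metadata["state"] = "fractured"
    out.metadata["fracture_point"] = tuple(point)
    out.metadata["fracture_normal"] = tuple(normal)
    return out


# ---------------------------------------------------------------------------
# fixation


def _build_box_block(bank_nodes: list, x_range, y_range, z_range, h):
    xs = _grid(*x_range, h)
    ys = _grid(*y_range, h)
    zs = _grid(*z_range, h)
    return xs, ys, zs


def attach_fixation(mesh: LabeledMesh, scheme: str) -> LabeledMesh:
    """Add miniplate + screw constructs to a fractured mesh.

    ``champy`` adds the single superior plate; ``biplanar`` adds the
    superior plate plus the inferior lateral plate.  Screws are tied
    (master-slave) to plate and bone; the plate-bone facing surfaces are
    registered as contact interfaces.
    """
    if scheme not in ("champy", "biplanar"):
        raise ParameterError(f"unknown fixation scheme {scheme!r}")
    if mesh.fracture is None:
        raise GeometryError("attach_fixation requires a fractured mesh")
    p = mesh.params
    out = mesh.copy()
    champy, inferior = p.default_plates()
    plates = (champy,) if scheme == "champy" else (champy, inferior)

    point = np.asarray(out.metadata["fracture_point"], float)
    normal = np.asarray(out.metadata["fracture_normal"], float)
    bio = out.biological_mask()
    frag_b_nodes = np.unique(out.elements[_side_b_mask(out)])
    frag_a_nodes = np.setdiff1d(np.unique(out.elements[bio]), frag_b_nodes)

    surf_nodes = out.surface_nodes(bio)
    z_surf = p.z_lateral
    on_plane = surf_nodes[np.abs(out.nodes[surf_nodes, 2] - z_surf) < 1e-6]
    plane_a = np.intersect1d(on_plane, frag_a_nodes)
    plane_b = np.intersect1d(on_plane, frag_b_nodes)
    tree_a = cKDTree(out.nodes[plane_a])
    tree_b = cKDTree(out.nodes[plane_b])
    bone_all = np.unique(out.elements[bio])
    bone_a = np.intersect1d(bone_all, frag_a_nodes)
    bone_b = frag_b_nodes
    btree_a = cKDTree(out.nodes[bone_a])
    btree_b = cKDTree(out.nodes[bone_b])

    h_plate = min(2.0, p.target_edge_length)
    new_ties = [out.ties]
    implant_bone_nodes = [np.zeros(0, int)]

    for spec in plates:
        bank = _NodeBank()
        coords: dict[int, tuple] = {}

        def put(x, y, z):
            i = bank.add(x, y, z)
            coords[i] = (round(x, _MERGE_DECIMALS), round(y, _MERGE_DECIMALS),
                         round(z, _MERGE_DECIMALS))
            return i

        hexes, hreg = [], []
        xs = _grid(*spec.x_range, h_plate)
        ys = _grid(*spec.y_range, h_plate)
        zs = _grid(z_surf, z_surf + spec.thickness, spec.thickness)
        lat = np.empty((len(xs), len(ys), len(zs)), int)
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                for k, z in enumerate(zs):
                    lat[i, j, k] = put(x, y, z)
        for i in range(len(xs) - 1):
            for j in range(len(ys) - 1):
                for k in range(len(zs) - 1):
                    hexes.append((lat[i, j, k], lat[i + 1, j, k],
                                  lat[i + 1, j + 1, k], lat[i, j + 1, k],
                                  lat[i, j, k + 1], lat[i + 1, j, k + 1],
                                  lat[i + 1, j + 1, k + 1], lat[i, j + 1, k + 1]))
                    hreg.append(3)
        xc_mid = 0.5 * (spec.x_range[0] + spec.x_range[1])
        sw = spec.screw_halfwidth
        node_hole: dict[int, int] = {}
        hole_centers = []
        for ih, yh in enumerate(spec.hole_ys):
            hole_centers.append(
                np.array([xc_mid, yh, z_surf - 0.5 * spec.screw_depth]))
            sxs = _grid(xc_mid - sw, xc_mid + sw, 2 * sw)
            sys_ = _grid(yh - sw, yh + sw, 2 * sw)
            szs = _grid(z_surf - spec.screw_depth, z_surf + spec.thickness,
                        min(2.0, spec.screw_depth / 3.0))
            slat = np.empty((len(sxs), len(sys_), len(szs)), int)
            for i, x in enumerate(sxs):
                for j, y in enumerate(sys_):
                    for k, z in enumerate(szs):
                        slat[i, j, k] = put(x, y, z)
                        node_hole[slat[i, j, k]] = ih
            for i in range(len(sxs) - 1):
                for j in range(len(sys_) - 1):
                    for k in range(len(szs) - 1):
                        hexes.append((slat[i, j, k], slat[i + 1, j, k],
                                      slat[i + 1, j + 1, k], slat[i, j + 1, k],
                                      slat[i, j, k + 1], slat[i + 1, j, k + 1],
                                      slat[i + 1, j + 1, k + 1],
                                      slat[i, j + 1, k + 1]))
                        hreg.append(4)

        tets, owner = _split_hexes(hexes, bank, lambda i: coords[i])
        cnodes = bank.array()
        offset = out.n_nodes
        ctets = np.array(tets, int) + offset
        ctets = _orient_tets(np.vstack([out.nodes, cnodes]), ctets)
        cregs = np.array(hreg, int)[np.array(owner, int)]

        e0 = out.n_elements
        out.nodes = np.vstack([out.nodes, cnodes])
        out.elements = np.vstack([out.elements, ctets])
        out.regions = np.concatenate([out.regions, cregs])
        out.element_sets[f"plate_{spec.name}"] = e0 + np.flatnonzero(cregs == 3)
        out.element_sets[f"screws_{spec.name}"] = e0 + np.flatnonzero(cregs == 4)

        # ties: screw nodes -> plate (inside the plate layer) or bone
        construct_ids = np.unique(ctets)
        screw_node_ids = np.unique(ctets[cregs == 4])
        plate_node_ids = np.unique(ctets[cregs == 3])
        screw_only = np.setdiff1d(screw_node_ids, plate_node_ids)
        plate_set = set(plate_node_ids.tolist())
        # a screw belongs to exactly one fragment, decided by its hole
        # centre, so no screw bridges the fracture
        hole_side = [float((c - point) @ normal) >= 0 for c in hole_centers]
        ties, tie_plate, tie_bone = [], 0, 0
        for nid in screw_only:
            x, y, z = out.nodes[nid]
            if z > z_surf + 0.25 * spec.thickness:
                # inside the plate layer but not a shared lattice node: tie to plate
                tgt = plate_node_ids[
                    cKDTree(out.nodes[plate_node_ids]).query([x, y, z])[1]]
                ties.append((nid, int(tgt)))
                tie_plate += 1
            else:
                ih = node_hole.get(int(nid) - offset)
                if ih is None:      # hex-centre node: nearest hole by y
                    ih = int(np.argmin([abs(y - c[1]) for c in hole_centers]))
                pool, tree = ((bone_a, btree_a) if hole_side[ih]
                              else (bone_b, btree_b))
                tgt = int(pool[tree.query([x, y, z])[1]])
                ties.append((nid, tgt))
                tie_bone += 1
                implant_bone_nodes.append(np.array([tgt]))
        if tie_bone == 0:
            raise GeometryError(f"plate {spec.name}: screws found no bone to tie to")
        new_ties.append(np.array(ties, int))

        # plate-bone contact pairs on the facing surface
        bottom = plate_node_ids[np.abs(out.nodes[plate_node_ids, 2] - z_surf) < 1e-6]
        pr, sides = [], set()
        for nid in bottom:
            dplane = float((out.nodes[nid] - point) @ normal)
            pool, tree = ((plane_a, tree_a) if dplane >= 0 else (plane_b, tree_b))
            tgt = int(pool[tree.query(out.nodes[nid])[1]])
            pr.append((nid, tgt))
            sides.add("A" if dplane >= 0 else "B")
        if sides != {"A", "B"}:
            raise GeometryError(
                f"plate {spec.name} footprint does not span the fracture")
        pr = np.array(pr, int)
        gaps = (out.nodes[pr[:, 0]] - out.nodes[pr[:, 1]]) @ np.array([0, 0, 1.0])
        out.contact_surfaces.append(ContactSurface(
            name=f"plate_{spec.name}_bone", pairs=pr,
            normal=np.array([0.0, 0.0, 1.0]), gap0=np.abs(gaps)))
        implant_bone_nodes.append(pr[:, 1])

    out.ties = np.vstack(new_ties)
    out.node_sets["implant_contact_bone"] = np.unique(
        np.concatenate(implant_bone_nodes))
    out.metadata["state"] = scheme
    out.metadata["champy_plate_top_x"] = champy.x_range[1]
    out.metadata["plate_names"] = [s.name for s in plates]
    return out


def _side_b_mask(mesh: LabeledMesh) -> np.ndarray:
    """Elements belonging to fragment B (referencing duplicated nodes or
    connected to them): recovered from the stored fracture pair ids."""
    if mesh.fracture is None:
        raise GeometryError("mesh has no fracture")
    dup_min = int(mesh.fracture.pairs[:, 1].min())
    bio = mesh.biological_mask()
    point = np.asarray(mesh.metadata["fracture_point"], float)
    normal = np.asarray(mesh.metadata["fracture_normal"], float)
    z_guard = mesh.metadata.get("fracture_z_guard", 0.0)
    cent = mesh.element_centroids()
    d = (cent - point) @ normal
    return (bio & (d < 0.0) & (cent[:, 2] > z_guard)
            & (mesh.regions != REGION_CODES["tooth"]))


# ---------------------------------------------------------------------------
# simple box meshes (verification fixtures)


def box_mesh(lx: float, ly: float, lz: float, h: float,
             region: str = "cortical", origin=(0.0, 0.0, 0.0)) -> LabeledMesh:
    """A rectangular tet-meshed bar with face node sets (xmin, xmax, ymin,
    ymax, zmin, zmax); used by the solver verification problems."""
    ox, oy, oz = origin
    bank = _NodeBank()
    coords: dict[int, tuple] = {}

    def put(x, y, z):
        i = bank.add(x, y, z)
        coords[i] = (round(x, _MERGE_DECIMALS), round(y, _MERGE_DECIMALS),
                     round(z, _MERGE_DECIMALS))
        return i

    xs = _grid(ox, ox + lx, h)
    ys = _grid(oy, oy + ly, h)
    zs = _grid(oz, oz + lz, h)
    lat = np.empty((len(xs), len(ys), len(zs)), int)
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            for k, z in enumerate(zs):
                lat[i, j, k] = put(x, y, z)
    hexes = []
    for i in range(len(xs) - 1):
        for j in range(len(ys) - 1):
            for k in range(len(zs) - 1):
                hexes.append((lat[i, j, k], lat[i + 1, j, k],
                              lat[i + 1, j + 1, k], lat[i, j + 1, k],
                              lat[i, j, k + 1], lat[i + 1, j, k + 1],
                              lat[i + 1, j + 1, k + 1], lat[i, j + 1, k + 1]))
    tets, _ = _split_hexes(hexes, bank, lambda i: coords[i])
    nodes = bank.array()
    elements = _orient_tets(nodes, np.array(tets, int))
    mesh = LabeledMesh(nodes=nodes, elements=elements,
                       regions=np.full(len(elements), REGION_CODES[region], int))
    tol = 1e-9
    nd = mesh.nodes
    mesh.node_sets = {
        "xmin": np.flatnonzero(np.abs(nd[:, 0] - xs[0]) < tol),
        "xmax": np.flatnonzero(np.abs(nd[:, 0] - xs[-1]) < tol),
        "ymin": np.flatnonzero(np.abs(nd[:, 1] - ys[0]) < tol),
        "ymax": np.flatnonzero(np.abs(nd[:, 1] - ys[-1]) < tol),
        "zmin": np.flatnonzero(np.abs(nd[:, 2] - zs[0]) < tol),
        "zmax": np.flatnonzero(np.abs(nd[:, 2] - zs[-1]) < tol),
    }
    mesh.metadata["mean_edge_length"] = h
    return mesh
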