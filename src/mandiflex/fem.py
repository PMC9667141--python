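"""Linear-elastic static finite elements on labeled tetrahedral meshes.

Four-node (constant-strain) tetrahedra, small-strain isotropic elasticity.
Tie constraints are enforced by merging the slave node's degrees of freedom
into the master's (exact for the conforming interfaces the mesh generator
produces).  Dirichlet constraints are eliminated; reactions are recovered
as the residual K u - f at constrained DOFs.

Units: mm / N / MPa; strains are dimensionless and usually quoted in
microstrain (1 ue = 1e-6).  Voigt strain order is
(xx, yy, zz, xy, yz, xz) with engineering shears.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as spla

from .geometry import REGION_NAMES, LabeledMesh
from .loads import LoadCase, distribute_over_patch, patch_set_name

VOIGT = ("xx", "yy", "zz", "xy", "yz", "xz")


class AssemblyError(RuntimeError):
    pass


class ConfigurationError(ValueError):
    pass


class SolveError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# materials


@dataclass(frozen=True)
class MaterialMap:
    """Isotropic homogeneous material per mesh region (E in MPa).

    Defaults: cortical bone E = 17 GPa, teeth 24.5 GPa, trabecular tissue
    10 GPa (all nu = 0.3); titanium implant (plates and screws) 105 GPa,
    nu = 0.36.
    """

    cortical: tuple[float, float] = (17000.0, 0.3)
    teeth: tuple[float, float] = (24500.0, 0.3)
    trabecular: tuple[float, float] = (10000.0, 0.3)
    implant: tuple[float, float] = (105000.0, 0.36)

    def __post_init__(self):
        for name in ("cortical", "teeth", "trabecular", "implant"):
            E, nu = getattr(self, name)
            if E <= 0:
                raise ConfigurationError(f"{name}: E must be positive")
            if not 0.0 <= nu < 0.5:
                raise ConfigurationError(f"{name}: nu must be in [0, 0.5)")

    def for_region(self, region_name: str) -> tuple[float, float]:
        return {
            "cortical": self.cortical,
            "trabecular": self.trabecular,
            "tooth": self.teeth,
            "plate": self.implant,
            "screw": self.implant,
        }[region_name]

    def stiffness_matrix(self, region_name: str) -> np.ndarray:
        E, nu = self.for_region(region_name)
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        G = E / (2 * (1 + nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] += 2 * G
        D[np.arange(3, 6), np.arange(3, 6)] = G
        return D


# ---------------------------------------------------------------------------
# assembly


def _union_find(n: int, pairs: np.ndarray) -> np.ndarray:
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[ra] = rb
    for i in range(n):
        parent[i] = find(i)
    return parent


@dataclass
class FESystem:
    K: sparse.csr_matrix
    eq_node: np.ndarray            # node id -> equation-node id (ties merged)
    n_eq_nodes: int
    mesh: LabeledMesh
    materials: MaterialMap
    grads: np.ndarray              # (m, 4, 3) shape-function gradients
    volumes: np.ndarray

    @property
    def ndof(self) -> int:
        return 3 * self.n_eq_nodes

    def dofs_of(self, node_ids) -> np.ndarray:
        en = self.eq_node[np.asarray(node_ids)]
        return (3 * en[:, None] + np.arange(3)).astype(int)


def assemble_system(mesh: LabeledMesh, materials: MaterialMap | None = None,
                    extra_ties: np.ndarray | None = None) -> FESystem:
    """Assemble the global stiffness with tie pairs merged.

    The unconstrained stiffness is symmetric positive-semidefinite with the
    six rigid-body modes in its null space.  Inverted elements abort
    assembly naming the offending element.
    """
    materials = materials or MaterialMap()
    ties = mesh.ties
    if extra_ties is not None and len(extra_ties):
        ties = np.vstack([ties, np.asarray(extra_ties, int)])

    parent = _union_find(mesh.n_nodes, ties)
    reps, eq_node = np.unique(parent, return_inverse=True)
    n_eq = len(reps)

    x = mesh.nodes[mesh.elements]                       # (m, 4, 3)
    A = x[:, 1:] - x[:, :1]                             # (m, 3, 3)
    detA = np.linalg.det(A)
    if (detA <= 0).any():
        bad = int(np.argmax(detA <= 0))
        raise AssemblyError(
            f"element {bad} is inverted or degenerate (det = {detA[bad]:g})")
    vol = detA / 6.0
    Ainv = np.linalg.inv(A)                             # (m, 3, 3)
    grads = np.empty((len(x), 4, 3))
    # lambda = A^{-T} (x - x0) with edge rows in A, so grad lambda_k is the
    # k-th column of A^{-1}
    grads[:, 1:, :] = np.transpose(Ainv, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)

    # B matrices (m, 6, 12)
    m = len(x)
    B = np.zeros((m, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx

    D_by_region = {i: materials.stiffness_matrix(name)
                   for i, name in enumerate(REGION_NAMES)}
    Ke = np.empty((m, 12, 12))
    for code, D in D_by_region.items():
        sel = mesh.regions == code
        if sel.any():
            Bs = B[sel]
            Ke[sel] = np.einsum("eji,jk,ekl->eil", Bs, D, Bs,
                                optimize=True) * vol[sel, None, None]

    edofs = (3 * eq_node[mesh.elements][:, :, None]
             + np.arange(3)[None, None, :]).reshape(m, 12)
    rows = np.repeat(edofs, 12, axis=1).ravel()
    cols = np.tile(edofs, (1, 12)).ravel()
    K = sparse.coo_matrix((Ke.ravel(), (rows, cols)),
                          shape=(3 * n_eq, 3 * n_eq)).tocsr()
    return FESystem(K=K, eq_node=eq_node, n_eq_nodes=n_eq, mesh=mesh,
                    materials=materials, grads=grads, volumes=vol)


# ---------------------------------------------------------------------------
# constraints and loads


@dataclass
class ConstrainedSystem:
    system: FESystem
    fixed: np.ndarray               # bool over system DOFs
    prescribed: np.ndarray          # values at fixed DOFs (0 elsewhere)
    load_case: LoadCase | None = None


def apply_constraints(system: FESystem, load_case: LoadCase) -> ConstrainedSystem:
    """Fix the DOFs named by the load case's constraint scheme to zero."""
    fixed = np.zeros(system.ndof, bool)
    for set_name, dofs in load_case.constraints():
        ids = system.mesh.node_sets.get(set_name)
        if ids is None or len(ids) == 0:
            raise ConfigurationError(f"constraint node set {set_name!r} is "
                                     "missing or empty")
        nd = system.dofs_of(ids)
        for d in dofs:
            fixed[nd[:, d]] = True
    return ConstrainedSystem(system=system, fixed=fixed,
                             prescribed=np.zeros(system.ndof),
                             load_case=load_case)


def fix_nodes(system: FESystem, node_ids, dofs=(0, 1, 2),
              values=None) -> ConstrainedSystem:
    """Directly constrain nodes (optionally to prescribed displacements)."""
    node_ids = np.asarray(node_ids)
    if node_ids.size == 0:
        raise ConfigurationError("empty constraint node set")
    fixed = np.zeros(system.ndof, bool)
    presc = np.zeros(system.ndof)
    nd = system.dofs_of(node_ids)
    for j, d in enumerate(dofs):
        fixed[nd[:, d]] = True
        if values is not None:
            presc[nd[:, d]] = np.asarray(values)[:, j] if np.ndim(values) == 2 \
                else values
    return ConstrainedSystem(system=system, fixed=fixed, prescribed=presc)


def build_load_vector(system: FESystem, load_case: LoadCase) -> np.ndarray:
    """Nodal force vector from the muscle forces distributed uniformly over
    their attachment patches."""
    f = np.zeros(system.ndof)
    for (muscle, side), F in load_case.force_dict().items():
        ids = system.mesh.node_sets.get(patch_set_name(muscle, side))
        if ids is None or len(ids) == 0:
            raise ConfigurationError(
                f"attachment patch for {muscle} {side} is missing or empty")
        per_node = distribute_over_patch(F, ids)
        nd = system.dofs_of(ids)
        np.add.at(f, nd.ravel(), per_node.ravel())
    return f


# ---------------------------------------------------------------------------
# solution


@dataclass
class SolutionField:
    """Displacements, reactions, element strain tensors and principal
    strains for one solved load case."""

    mesh: LabeledMesh
    system: FESystem
    u: np.ndarray                   # (n_nodes, 3) mm
    reactions: np.ndarray           # (n_nodes, 3) N, nonzero at constrained eq-DOFs
    strain: np.ndarray              # (m, 6) Voigt, engineering shears
    principal: np.ndarray           # (m, 3) e1 >= e2 >= e3
    fixed: np.ndarray               # bool over system DOFs
    applied: np.ndarray             # (ndof,) external load vector used

    def nodal_strain(self, region_codes=None) -> np.ndarray:
        """Volume-weighted average of adjacent element strain tensors per
        node; elements may be restricted by region code."""
        mesh, sys_ = self.mesh, self.system
        sel = np.ones(mesh.n_elements, bool) if region_codes is None else \
            np.isin(mesh.regions, region_codes)
        out = np.zeros((mesh.n_nodes, 6))
        wsum = np.zeros(mesh.n_nodes)
        els = mesh.elements[sel]
        w = sys_.volumes[sel]
        st = self.strain[sel]
        for a in range(4):
            np.add.at(out, els[:, a], st * w[:, None])
            np.add.at(wsum, els[:, a], w)
        nz = wsum > 0
        out[nz] /= wsum[nz, None]
        return out

    def nodal_principal(self, region_codes=None) -> np.ndarray:
        return principal_strains(self.nodal_strain(region_codes))


def _partition_solve(K: sparse.spmatrix, f: np.ndarray, fixed: np.ndarray,
                     prescribed: np.ndarray) -> np.ndarray:
    free = ~fixed
    Kff = K[free][:, free].tocsc()
    rhs = f[free] - K[free][:, fixed] @ prescribed[fixed]
    try:
        uf = spla.spsolve(Kff, rhs)
    except Exception as exc:   # pragma: no cover - solver backend failure
        raise SolveError(f"sparse solve failed: {exc}") from exc
    if not np.all(np.isfinite(uf)):
        raise SolveError("singular constrained system (non-finite solution); "
                         "check that constraints remove all rigid-body modes")
    u = prescribed.copy()
    u[free] = uf
    return u


def solve_static(csys: ConstrainedSystem, f: np.ndarray | None = None,
                 K_extra: sparse.spmatrix | None = None,
                 f_extra: np.ndarray | None = None) -> SolutionField:
    """Direct static solve.  ``K_extra``/``f_extra`` let the contact solver
    augment the system with penalty springs and friction forces."""
    sys_ = csys.system
    if f is None:
        if csys.load_case is None:
            raise ConfigurationError("no load vector and no load case")
        f = build_load_vector(sys_, csys.load_case)
    K = sys_.K if K_extra is None else (sys_.K + K_extra).tocsr()
    ftot = f if f_extra is None else f + f_extra
    u = _partition_solve(K, ftot, csys.fixed, csys.prescribed)
    return finalize_solution(csys, K, ftot, u)


def finalize_solution(csys: ConstrainedSystem, K: sparse.spmatrix,
                      ftot: np.ndarray, u: np.ndarray) -> SolutionField:
    """Recover reactions and strains from a solved DOF vector."""
    sys_ = csys.system
    resid = K @ u - ftot
    reactions_dof = np.where(csys.fixed, resid, 0.0)

    u_node = u.reshape(-1, 3)[sys_.eq_node]
    # attribute each constrained eq-DOF's reaction to its representative node
    r_node = np.zeros((sys_.mesh.n_nodes, 3))
    first = np.full(sys_.n_eq_nodes, -1, int)
    order = np.arange(sys_.mesh.n_nodes)[::-1]
    first[sys_.eq_node[order]] = order
    r_node[first] = reactions_dof.reshape(-1, 3)

    strain = element_strains(sys_, u_node)
    return SolutionField(mesh=sys_.mesh, system=sys_, u=u_node,
                         reactions=r_node, strain=strain,
                         principal=principal_strains(strain),
                         fixed=csys.fixed, applied=ftot)


# ---------------------------------------------------------------------------
# strain post-processing


def element_strains(system: FESystem, u_node: np.ndarray) -> np.ndarray:
    """Constant strain per linear tet, Voigt (xx, yy, zz, xy, yz, xz) with
    engineering shears."""
    ue = u_node[system.mesh.elements]            # (m, 4, 3)
    g = system.grads                             # (m, 4, 3)
    dudx = np.einsum("maj,mai->mij", ue, g)      # (m, 3, 3), du_i/dx_j
    eps = np.empty((len(ue), 6))
    eps[:, 0] = dudx[:, 0, 0]
    eps[:, 1] = dudx[:, 1, 1]
    eps[:, 2] = dudx[:, 2, 2]
    eps[:, 3] = dudx[:, 0, 1] + dudx[:, 1, 0]
    eps[:, 4] = dudx[:, 1, 2] + dudx[:, 2, 1]
    eps[:, 5] = dudx[:, 0, 2] + dudx[:, 2, 0]
    return eps


def strain_tensor(voigt: np.ndarray) -> np.ndarray:
    """(..., 6) Voigt -> (..., 3, 3) symmetric tensor (tensor shears)."""
    v = np.asarray(voigt, float)
    t = np.zeros(v.shape[:-1] + (3, 3))
    t[..., 0, 0] = v[..., 0]
    t[..., 1, 1] = v[..., 1]
    t[..., 2, 2] = v[..., 2]
    t[..., 0, 1] = t[..., 1, 0] = v[..., 3] / 2.0
    t[..., 1, 2] = t[..., 2, 1] = v[..., 4] / 2.0
    t[..., 0, 2] = t[..., 2, 0] = v[..., 5] / 2.0
    return t


def principal_strains(voigt: np.ndarray, directions: bool = False):
    """Principal strains sorted descending (e1 >= e2 >= e3); optionally the
    corresponding unit directions."""
    t = strain_tensor(np.atleast_2d(voigt))
    if directions:
        vals, vecs = np.linalg.eigh(t)
        order = np.argsort(vals, axis=-1)[..., ::-1]
        vals = np.take_along_axis(vals, order, axis=-1)
        vecs = np.take_along_axis(vecs, order[..., None, :], axis=-1)
        return vals.squeeze(), vecs.squeeze()
    vals = np.linalg.eigvalsh(t)[..., ::-1]
    out = vals if np.ndim(voigt) > 1 else vals[0]
    return out


def bite_reaction(solution: SolutionField, bite_nodes) -> np.ndarray:
    """Resultant constraint reaction (N) over the bite-point nodes.  The
    force the mandible exerts on the food item is the negative of this
    vector; its x (superior-inferior) component is then positive (up on the
    food)."""
    return solution.reactions[np.asarray(bite_nodes)].sum(axis=0)
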