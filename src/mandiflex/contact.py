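"""Frictional small-sliding contact at fracture and plate-bone interfaces.

Node-to-node penalty contact on conforming paired surfaces (the fracture
cut duplicates nodes in place, so pairing is exact), with Coulomb friction
and an active-set fixed-point iteration: solve, classify every pair as
open / stick / slip from its gap and tractions, re-solve until the active
set is unchanged and the displacement increment is below tolerance.

"Hard" contact is approximated by a large penalty stiffness; the default
scales with the softest adjacent material modulus and the local element
size so penetrations stay negligible against the element scale.  Tractions
are reported as per-pair forces (N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from scipy.sparse import linalg as spla

from .fem import ConstrainedSystem, SolutionField, finalize_solution
from .geometry import LabeledMesh

OPEN, STICK, SLIP = 0, 1, 2
STATUS_NAMES = {OPEN: "open", STICK: "stick", SLIP: "slip"}


class ContactConfigurationError(ValueError):
    pass


class ContactConvergenceError(RuntimeError):
    def __init__(self, msg, history):
        super().__init__(msg + f" (residual history: {history})")
        self.history = history


@dataclass(frozen=True)
class ContactSpec:
    """Penalty / friction parameters.

    ``friction`` defaults to the 0.3 static coefficient used at both the
    fracture plane and the plate-bone interfaces.  ``k_normal`` is the
    per-pair normal penalty stiffness (N/mm); when None it defaults to
    10 x (softest adjacent E) x (local element size) -- stiff enough that
    residual penetration stays well below the element scale (hard contact)
    while keeping the active-set iteration contractive.  ``g_tol`` is the admissible residual penetration.
    """

    friction: float = 0.3
    k_normal: float | None = None
    k_tangent: float | None = None
    max_iter: int = 250
    tol: float = 1e-6
    g_tol: float = 1e-3
    relaxation: float = 0.7

    def __post_init__(self):
        if self.friction < 0:
            raise ContactConfigurationError("friction must be >= 0")
        if self.k_normal is not None and self.k_normal <= 0:
            raise ContactConfigurationError("k_normal must be positive")
        if self.k_tangent is not None and self.k_tangent <= 0:
            raise ContactConfigurationError("k_tangent must be positive")

    def resolved_stiffness(self, mesh: LabeledMesh,
                           soft_modulus: float = 10000.0) -> tuple[float, float]:
        # normal: stiff enough for ~1e-4 mm penetrations at chewing loads;
        # tangential: of the order of the material stiffness, so the slip
        # return mapping contracts quickly while stick compliance stays at
        # the element scale
        h = mesh.metadata.get("mean_edge_length", 1.0)
        kn = self.k_normal if self.k_normal is not None else 10.0 * soft_modulus * h
        kt = self.k_tangent if self.k_tangent is not None else kn / 100.0
        return kn, kt


@dataclass
class ContactGroup:
    """One paired interface: node pairs, a shared unit normal (from side B
    toward side A, the gap-opening direction) and initial gaps."""

    name: str
    pairs: np.ndarray            # (k, 2): column 0 side A, column 1 side B
    normal: np.ndarray           # (3,)
    gap0: np.ndarray             # (k,)


def detect_pairs(coords_a: np.ndarray, coords_b: np.ndarray,
                 search_radius: float):
    """Pair each A node with its nearest B counterpart within the radius.

    Returns (index pairs into the input arrays, initial gaps).  Ties in
    distance resolve to the lowest B index (KD-tree convention); pairing is
    computed once on the undeformed coordinates and frozen.
    """
    coords_a = np.atleast_2d(coords_a)
    coords_b = np.atleast_2d(coords_b)
    if len(coords_a) == 0 or len(coords_b) == 0:
        raise ContactConfigurationError("contact surface is empty")
    d, j = cKDTree(coords_b).query(coords_a,
                                   distance_upper_bound=search_radius * (1 + 1e-12))
    ok = np.isfinite(d)
    if not ok.any():
        raise ContactConfigurationError(
            f"no contact pairs within search radius {search_radius}")
    pairs = np.column_stack([np.flatnonzero(ok), j[ok]]).astype(int)
    return pairs, d[ok]


def mesh_contact_groups(mesh: LabeledMesh) -> list[ContactGroup]:
    """The fracture interface plus any registered plate-bone surfaces."""
    groups = []
    if mesh.fracture is not None:
        fr = mesh.fracture
        groups.append(ContactGroup(
            name="fracture",
            pairs=fr.pairs, normal=fr.normal,
            gap0=np.zeros(len(fr.pairs))))
    for cs in mesh.contact_surfaces:
        # stored pairs are (plate, bone); the normal points bone -> plate,
        # so the plate node is side A (gap opens along +normal)
        groups.append(ContactGroup(name=cs.name, pairs=cs.pairs[:, [0, 1]],
                                   normal=cs.normal, gap0=cs.gap0))
    return groups


@dataclass
class ContactState:
    groups: list[ContactGroup]
    status: np.ndarray           # (k_total,) OPEN/STICK/SLIP
    normal_force: np.ndarray     # (k_total,) N, >= 0 (compression)
    tangent_force: np.ndarray    # (k_total, 3) N
    gap: np.ndarray              # (k_total,) mm
    iterations: int
    group_slices: list[tuple[str, slice]] = field(default_factory=list)

    def of_group(self, name: str) -> slice:
        for n, s in self.group_slices:
            if n == name:
                return s
        raise KeyError(name)


def solve_with_contact(csys: ConstrainedSystem, f: np.ndarray,
                       groups: list[ContactGroup] | None = None,
                       spec: ContactSpec | None = None
                       ) -> tuple[SolutionField, ContactState]:
    """Active-set penalty iteration.

    Converged pairs satisfy complementarity within tolerance: open pairs
    carry no traction, closed pairs penetrate at most ``g_tol``, sticking
    pairs lie inside the Coulomb cone and slipping pairs on it.
    """
    spec = spec or ContactSpec()
    sys_ = csys.system
    mesh = sys_.mesh
    if groups is None:
        groups = mesh_contact_groups(mesh)
    if not groups:
        raise ContactConfigurationError("no contact groups supplied")
    kn, kt = spec.resolved_stiffness(mesh)

    a_ids = np.concatenate([g.pairs[:, 0] for g in groups])
    b_ids = np.concatenate([g.pairs[:, 1] for g in groups])
    normals = np.concatenate([np.tile(g.normal, (len(g.pairs), 1))
                              for g in groups])
    gap0 = np.concatenate([g.gap0 for g in groups])
    k = len(a_ids)
    slices, off = [], 0
    for g in groups:
        slices.append((g.name, slice(off, off + len(g.pairs))))
        off += len(g.pairs)

    da = sys_.dofs_of(a_ids)      # (k, 3)
    db = sys_.dofs_of(b_ids)

    status = np.full(k, STICK)
    status[gap0 > spec.g_tol] = OPEN
    # friction by return mapping: tangential traction k_t (delta_t - p) with
    # plastic slip offset p pulled back onto the Coulomb cone each iteration
    p_slip = np.zeros((k, 3))
    u_prev = None
    r_prev = None
    omega = spec.relaxation
    history = []

    Pn = normals[:, :, None] * normals[:, None, :]          # (k, 3, 3)
    Pt = np.eye(3)[None] - Pn

    # the factorization depends only on the open set; cache it across
    # iterations that merely update the friction anchors
    free = ~csys.fixed
    presc_fix = csys.prescribed[csys.fixed]
    lu = None
    K_c = None
    Kfc = None
    cached_open = None

    for it in range(spec.max_iter):
        closed = status != OPEN
        if cached_open is None or (closed != cached_open).any():
            blocks = np.zeros((k, 3, 3))
            blocks[closed] += kn * Pn[closed] + kt * Pt[closed]
            K_pen = _penalty_matrix(sys_.ndof, da, db, blocks)
            K_c = (sys_.K + K_pen).tocsr()
            lu = spla.splu(K_c[free][:, free].tocsc())
            Kfc = K_c[free][:, csys.fixed]
            cached_open = closed.copy()
        f_corr = np.zeros(sys_.ndof)
        if closed.any():
            corr = kt * np.einsum("kij,kj->ki", Pt[closed], p_slip[closed])
            np.add.at(f_corr, da[closed].ravel(), corr.ravel())
            np.add.at(f_corr, db[closed].ravel(), (-corr).ravel())

        ftot = f + f_corr
        uf = lu.solve(ftot[free] - Kfc @ presc_fix)
        if not np.all(np.isfinite(uf)):
            raise ContactConvergenceError(
                "singular contact system (a fragment may be unconstrained "
                "with all its pairs open)", history[-10:])
        u_dof = csys.prescribed.copy()
        u_dof[free] = uf
        u = u_dof.reshape(-1, 3)[sys_.eq_node]

        delta = u[a_ids] - u[b_ids]                         # opening > 0
        gn = gap0 + np.einsum("kj,kj->k", delta, normals)
        tn = np.where(gn < 0, -kn * gn, 0.0)                # compressive force
        dt = delta - np.einsum("kj,kj->k", delta, normals)[:, None] * normals
        t_trial = kt * (dt - p_slip)
        tt_mag = np.linalg.norm(t_trial, axis=1)

        new_status = np.where(gn >= 0, OPEN,
                              np.where(tt_mag <= spec.friction * tn + 1e-12,
                                       STICK, SLIP))
        slip = new_status == SLIP
        opened = new_status == OPEN
        t_force = t_trial.copy()
        p_new = p_slip.copy()
        if slip.any():
            dirs = np.zeros((k, 3))
            nzt = slip & (tt_mag > 0)
            dirs[nzt] = t_trial[nzt] / tt_mag[nzt, None]
            t_lim = spec.friction * tn[slip, None] * dirs[slip]
            t_force[slip] = t_lim
            p_new[slip] = dt[slip] - t_lim / kt
        t_force[opened] = 0.0
        p_new[opened] = dt[opened]

        du = 1.0 if u_prev is None else (
            np.linalg.norm(u - u_prev) / max(np.linalg.norm(u), 1e-30))
        history.append(float(du))
        # physical convergence: stable open set, small displacement change,
        # admissible penetration and Coulomb-cone residual.  Pairs toggling
        # between stick and slip exactly on the cone are converged either way.
        was_open = status == OPEN
        is_open = new_status == OPEN
        tn_scale = max(float(tn.max()), 1e-12)
        cone_excess = float(np.max(
            (tt_mag - spec.friction * tn)[~is_open], initial=0.0))
        if ((is_open == was_open).all() and du < max(spec.tol, 1e-12)
                and gn.min() >= -spec.g_tol
                and cone_excess <= 1e-4 * tn_scale):
            # reported stick/slip split: slipping pairs sit on the Coulomb
            # cone within tolerance (for mu = 0 the cone is degenerate, so
            # every closed pair slides traction-free)
            on_cone = tt_mag >= spec.friction * tn - 1e-6 * (tn + 1.0)
            report_status = np.where(is_open, OPEN,
                                     np.where(on_cone, SLIP, STICK))
            state = ContactState(groups=groups, status=report_status,
                                 normal_force=tn, tangent_force=t_force,
                                 gap=gn, iterations=it + 1,
                                 group_slices=slices)
            _check_converged(state, spec)
            sol = finalize_solution(csys, K_c, ftot, u_dof)
            return sol, state
        u_prev = u
        # Aitken-accelerated relaxation of the slip-anchor update (the plain
        # fixed point contracts slowly when the tangential penalty dominates
        # the structural stiffness).  Open pairs carry no springs, so their
        # anchors are set directly and excluded from the acceleration; only a
        # change of the open set resets the acceleration.
        r = np.where(is_open[:, None], 0.0, p_new - p_slip)
        if (is_open != was_open).any() or r_prev is None:
            omega = spec.relaxation
        else:
            dr = r - r_prev
            den = float(np.sum(dr * dr))
            if den > 0:
                omega = -omega * float(np.sum(r_prev * dr)) / den
                omega = spec.relaxation if omega <= 0 else min(omega, 25.0)
        status = new_status
        r_prev = r
        p_slip = p_slip + omega * r
        p_slip[is_open] = dt[is_open]

    raise ContactConvergenceError(
        f"contact did not converge in {spec.max_iter} iterations; consider a "
        "larger penalty stiffness or a tied interface", history[-10:])


def _penalty_matrix(ndof: int, da: np.ndarray, db: np.ndarray,
                    blocks: np.ndarray) -> sparse.csr_matrix:
    """Assemble sum over pairs of the 6x6 coupling [B, -B; -B, B]."""
    k = len(da)
    dofs = np.concatenate([da, db], axis=1)                  # (k, 6)
    big = np.zeros((k, 6, 6))
    big[:, :3, :3] = blocks
    big[:, 3:, 3:] = blocks
    big[:, :3, 3:] = -blocks
    big[:, 3:, :3] = -blocks
    rows = np.repeat(dofs, 6, axis=1).ravel()
    cols = np.tile(dofs, (1, 6)).ravel()
    return sparse.coo_matrix((big.ravel(), (rows, cols)),
                             shape=(ndof, ndof)).tocsr()


def _check_converged(state: ContactState, spec: ContactSpec) -> None:
    gn, tn = state.gap, state.normal_force
    if (gn < -spec.g_tol).any():
        raise ContactConvergenceError(
            f"residual penetration {-gn.min():g} exceeds g_tol {spec.g_tol}; "
            "increase the penalty stiffness", [])
    opened = state.status == OPEN
    if opened.any() and (tn[opened] != 0).any():
        raise ContactConvergenceError("open pair carries normal traction", [])
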