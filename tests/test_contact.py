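"""Penalty contact with Coulomb friction: pairing, complementarity,
frictionless slip, tied-limit equivalence."""

import numpy as np
import pytest

from mandiflex import contact, fem
from mandiflex import geometry as geo

from conftest import face_pressure_vector, two_block_stack


class TestDetectPairs:
    def test_coincident_surfaces_pair_at_zero_gap(self, fractured_mesh):
        fr = fractured_mesh.fracture
        a, b = fr.pairs[:, 0], fr.pairs[:, 1]
        idx, gaps = contact.detect_pairs(fractured_mesh.nodes[a],
                                         fractured_mesh.nodes[b], 0.5)
        assert len(idx) == len(a)
        assert gaps.max() == 0.0

    def test_translated_copy_all_gaps_equal_offset(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(30, 3)) * 5.0     # spacing >> offset
        d = 0.25
        b = a + np.array([0, 0, d])
        idx, gaps = contact.detect_pairs(a, b, 1.0)
        assert np.allclose(gaps, d)

    def test_out_of_radius_raises(self):
        a = np.zeros((3, 3))
        b = np.ones((3, 3)) * 10
        with pytest.raises(contact.ContactConfigurationError):
            contact.detect_pairs(a, b, 0.5)

    def test_empty_surface_raises(self):
        with pytest.raises(contact.ContactConfigurationError):
            contact.detect_pairs(np.zeros((0, 3)), np.zeros((4, 3)), 1.0)


class TestStackedBlocks:
    def test_uniform_pressure_gives_uniform_traction(self):
        """Two stacked blocks under uniform pressure p: interior pair
        tractions equal p x tributary area within 5%."""
        mesh, grp = two_block_stack()
        s = fem.assemble_system(mesh)
        csys = fem.fix_nodes(s, mesh.node_sets["base"])
        p = 2.0
        f = face_pressure_vector(mesh, s, "top", p)
        sol, st = contact.solve_with_contact(csys, f, [grp])
        coords = mesh.nodes[grp.pairs[:, 0]]
        interior = ((coords[:, 1] > 0.5) & (coords[:, 1] < 3.5)
                    & (coords[:, 2] > 0.5) & (coords[:, 2] < 3.5))
        tn = st.normal_force[interior]           # tributary area = 1 mm^2
        assert np.all(np.abs(tn - p) / p < 0.05)
        assert (st.status[interior] != contact.OPEN).all()
        # complementarity everywhere
        assert st.gap.min() >= -contact.ContactSpec().g_tol
        assert np.abs(st.normal_force * np.clip(st.gap, 0, None)).max() < 1e-9

    def test_tension_opens_all_pairs(self):
        """Pulling the blocks apart (prescribed displacement of the upper
        block) opens every pair with zero traction."""
        mesh, grp = two_block_stack()
        s = fem.assemble_system(mesh)
        fixed = np.zeros(s.ndof, bool)
        presc = np.zeros(s.ndof)
        fixed[s.dofs_of(mesh.node_sets["base"]).ravel()] = True
        nd = s.dofs_of(mesh.node_sets["top"])
        fixed[nd.ravel()] = True
        presc[nd[:, 0]] = 0.05
        csys = fem.ConstrainedSystem(system=s, fixed=fixed, prescribed=presc)
        sol, st = contact.solve_with_contact(csys, np.zeros(s.ndof), [grp])
        assert (st.status == contact.OPEN).all()
        assert np.abs(st.normal_force).max() == 0.0
        assert np.abs(st.tangent_force).max() == 0.0

    def test_frictionless_slide_has_zero_tangential_traction(self):
        """mu = 0 with a prescribed rigid tangential slide of the upper
        block: every closed pair slips with zero tangential traction."""
        mesh, grp = two_block_stack()
        s = fem.assemble_system(mesh)
        top_block = np.flatnonzero(mesh.nodes[:, 0] >= 4.0 - 1e-9)
        fixed = np.zeros(s.ndof, bool)
        presc = np.zeros(s.ndof)
        fixed[s.dofs_of(mesh.node_sets["base"]).ravel()] = True
        nd = s.dofs_of(top_block)
        fixed[nd[:, 1]] = True
        presc[nd[:, 1]] = 0.1
        fixed[nd[:, 2]] = True
        csys = fem.ConstrainedSystem(system=s, fixed=fixed, prescribed=presc)
        f = face_pressure_vector(mesh, s, "top", 2.0)
        sol, st = contact.solve_with_contact(
            csys, f, [grp], contact.ContactSpec(friction=0.0))
        closed = st.status != contact.OPEN
        assert closed.any()
        assert (st.status[closed] == contact.SLIP).all()
        assert np.abs(st.tangent_force).max() < 1e-9

    def test_coulomb_cone_respected_under_frictional_slide(self):
        """mu = 0.3 rigid slide: slipping pairs sit on the cone
        (|t_t| = mu t_n), none outside it."""
        mesh, grp = two_block_stack()
        s = fem.assemble_system(mesh)
        top_block = np.flatnonzero(mesh.nodes[:, 0] >= 4.0 - 1e-9)
        fixed = np.zeros(s.ndof, bool)
        presc = np.zeros(s.ndof)
        fixed[s.dofs_of(mesh.node_sets["base"]).ravel()] = True
        nd = s.dofs_of(top_block)
        fixed[nd[:, 1]] = True
        presc[nd[:, 1]] = 0.1
        fixed[nd[:, 2]] = True
        csys = fem.ConstrainedSystem(system=s, fixed=fixed, prescribed=presc)
        f = face_pressure_vector(mesh, s, "top", 2.0)
        mu = 0.3
        sol, st = contact.solve_with_contact(
            csys, f, [grp], contact.ContactSpec(friction=mu))
        closed = st.status != contact.OPEN
        tt = np.linalg.norm(st.tangent_force, axis=1)
        assert closed.any()
        excess = tt[closed] - mu * st.normal_force[closed]
        assert excess.max() <= 1e-6 * max(st.normal_force.max(), 1.0)
        slip = st.status == contact.SLIP
        if slip.any():
            assert np.allclose(tt[slip], mu * st.normal_force[slip],
                               rtol=1e-6, atol=1e-9)

    def test_tied_limit_equivalence_under_penalty_sweep(self):
        """With an all-stick interface, raising the penalty drives the
        contact solution monotonically toward the tied (merged-DOF) solve."""
        mesh, grp = two_block_stack()
        # strong pressure + light shear keeps every pair closed and sticking,
        # the regime in which the penalty limit equals the tied solve
        sys_tied = fem.assemble_system(mesh, extra_ties=grp.pairs)
        csys_t = fem.fix_nodes(sys_tied, mesh.node_sets["base"])
        f_t = np.zeros(sys_tied.ndof)
        nd = sys_tied.dofs_of(mesh.node_sets["top"])
        f_t[nd[:, 0]] = -40.0 / len(nd)
        f_t[nd[:, 1]] = 2.0 / len(nd)
        ref = fem.solve_static(csys_t, f=f_t)

        sys_c = fem.assemble_system(mesh)
        csys_c = fem.fix_nodes(sys_c, mesh.node_sets["base"])
        f_c = np.zeros(sys_c.ndof)
        nd = sys_c.dofs_of(mesh.node_sets["top"])
        f_c[nd[:, 0]] = -40.0 / len(nd)
        f_c[nd[:, 1]] = 2.0 / len(nd)
        diffs = []
        for kn in (1e4, 1e5, 1e6, 1e7):
            sol, st = contact.solve_with_contact(
                csys_c, f_c, [grp],
                contact.ContactSpec(friction=10.0, k_normal=kn, k_tangent=kn))
            diffs.append(np.abs(sol.u - ref.u).max() / np.abs(ref.u).max())
        assert all(a > b for a, b in zip(diffs, diffs[1:]))
        assert diffs[-1] < 1e-3

    def test_determinism(self):
        mesh, grp = two_block_stack()
        s = fem.assemble_system(mesh)
        csys = fem.fix_nodes(s, mesh.node_sets["base"])
        f = face_pressure_vector(mesh, s, "top", 1.5)
        sol1, st1 = contact.solve_with_contact(csys, f, [grp])
        sol2, st2 = contact.solve_with_contact(csys, f, [grp])
        assert np.array_equal(sol1.u, sol2.u)
        assert np.array_equal(st1.status, st2.status)


def test_spec_validation():
    with pytest.raises(contact.ContactConfigurationError):
        contact.ContactSpec(friction=-0.1)
    with pytest.raises(contact.ContactConfigurationError):
        contact.ContactSpec(k_normal=0.0)


def test_mesh_contact_groups_fracture_and_plates(biplanar_mesh):
    groups = contact.mesh_contact_groups(biplanar_mesh)
    names = [g.name for g in groups]
    assert names[0] == "fracture"
    assert "plate_champy_bone" in names and "plate_inferior_bone" in names
    assert all(len(g.pairs) > 0 for g in groups)
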