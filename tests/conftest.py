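import numpy as np
import pytest

from mandiflex import geometry as geo
from mandiflex import fem


@pytest.fixture(scope="session")
def default_params():
    return geo.GeometryParams()


@pytest.fixture(scope="session")
def healthy_mesh(default_params):
    return geo.build_surrogate_mandible(default_params)


@pytest.fixture(scope="session")
def fractured_mesh(healthy_mesh):
    return geo.cut_angle_fracture(healthy_mesh)


@pytest.fixture(scope="session")
def champy_mesh(fractured_mesh):
    return geo.attach_fixation(fractured_mesh, "champy")


@pytest.fixture(scope="session")
def biplanar_mesh(fractured_mesh):
    return geo.attach_fixation(fractured_mesh, "biplanar")


def two_block_stack(h=1.0, size=4.0):
    """Two stacked cubes with a conforming contact interface at x = size;
    x is the stacking (normal) direction."""
    from mandiflex import contact

    bot = geo.box_mesh(size, size, size, h, origin=(0, 0, 0))
    top = geo.box_mesh(size, size, size, h, origin=(size, 0, 0))
    n0 = bot.n_nodes
    mesh = geo.LabeledMesh(
        nodes=np.vstack([bot.nodes, top.nodes]),
        elements=np.vstack([bot.elements, top.elements + n0]),
        regions=np.concatenate([bot.regions, top.regions]))
    mesh.metadata["mean_edge_length"] = h
    mesh.node_sets["base"] = bot.node_sets["xmin"]
    mesh.node_sets["top"] = top.node_sets["xmax"] + n0
    ia = top.node_sets["xmin"] + n0
    ib = bot.node_sets["xmax"]
    idx, gaps = contact.detect_pairs(mesh.nodes[ia], mesh.nodes[ib], 0.1)
    grp = contact.ContactGroup(
        "interface",
        np.column_stack([ia[idx[:, 0]], ib[idx[:, 1]]]),
        np.array([1.0, 0.0, 0.0]), gaps)
    return mesh, grp


def face_pressure_vector(mesh, system, set_name, pressure):
    """Consistent (tributary-area) nodal loads for a uniform pressure acting
    along -x on a boundary face node set."""
    ids = mesh.node_sets[set_name]
    tris = mesh.boundary_faces()
    sel = np.isin(tris, ids).all(axis=1)
    tt = tris[sel]
    x = mesh.nodes[tt]
    areas = 0.5 * np.linalg.norm(
        np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]), axis=1)
    w = np.zeros(mesh.n_nodes)
    for i in range(3):
        np.add.at(w, tt[:, i], areas / 3.0)
    f = np.zeros(system.ndof)
    nd = system.dofs_of(ids)
    f[nd[:, 0]] = -pressure * w[ids]
    return f
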