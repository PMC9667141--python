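"""Mesh and field IO: ASCII VTU (unstructured grid) and a plain Abaqus-INP
text dialect (nodes, C3D4 element blocks per region, element sets, node
sets).  Both formats round-trip the labeled mesh losslessly for nodes,
elements, region labels and node sets."""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .geometry import REGION_CODES, REGION_NAMES, LabeledMesh

VTK_TET = 10


# ---------------------------------------------------------------------------
# VTU


def write_vtu(mesh: LabeledMesh, path, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """ASCII VTU with the region label as cell data, one 0/1 point array per
    node set, and any extra point/cell arrays supplied."""
    n, m = mesh.n_nodes, mesh.n_elements
    pd = {}
    for name, ids in mesh.node_sets.items():
        arr = np.zeros(n, int)
        arr[ids] = 1
        pd[f"nset:{name}"] = arr
    if point_data:
        pd.update(point_data)
    cd = {"region": mesh.regions}
    if cell_data:
        cd.update(cell_data)

    def fmt(a):
        a = np.asarray(a)
        if a.ndim == 1:
            a = a[:, None]
        if np.issubdtype(a.dtype, np.integer):
            return "\n".join(" ".join(str(int(x)) for x in row) for row in a)
        return "\n".join(" ".join(repr(float(x)) for x in row) for row in a)

    def da(parent, name, a, ncomp):
        a = np.asarray(a)
        typ = "Int64" if np.issubdtype(a.dtype, np.integer) else "Float64"
        e = ET.SubElement(parent, "DataArray",
                          type=typ, Name=name, format="ascii",
                          NumberOfComponents=str(ncomp))
        e.text = "\n" + fmt(a) + "\n"

    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1",
                      byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(grid, "Piece", NumberOfPoints=str(n),
                          NumberOfCells=str(m))
    pts = ET.SubElement(piece, "Points")
    da(pts, "Points", mesh.nodes, 3)
    cells = ET.SubElement(piece, "Cells")
    da(cells, "connectivity", mesh.elements.ravel(), 1)
    da(cells, "offsets", 4 * np.arange(1, m + 1), 1)
    da(cells, "types", np.full(m, VTK_TET), 1)
    pde = ET.SubElement(piece, "PointData")
    for name, a in pd.items():
        da(pde, name, a, 1 if np.ndim(a) == 1 else np.shape(a)[1])
    cde = ET.SubElement(piece, "CellData")
    for name, a in cd.items():
        da(cde, name, a, 1 if np.ndim(a) == 1 else np.shape(a)[1])
    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="UTF-8")


def read_vtu(path) -> LabeledMesh:
    root = ET.parse(path).getroot()
    piece = root.find("./UnstructuredGrid/Piece")

    def parse(e):
        vals = e.text.split()
        if e.get("type").startswith("Int"):
            a = np.array([int(v) for v in vals], int)
        else:
            a = np.array([float(v) for v in vals], float)
        nc = int(e.get("NumberOfComponents", "1"))
        return a.reshape(-1, nc) if nc > 1 else a

    nodes = parse(piece.find("./Points/DataArray"))
    cells = {e.get("Name"): parse(e) for e in piece.findall("./Cells/DataArray")}
    if not (cells["types"] == VTK_TET).all():
        raise ValueError("VTU contains non-tetrahedral cells")
    elements = cells["connectivity"].reshape(-1, 4)
    pd = {e.get("Name"): parse(e) for e in piece.findall("./PointData/DataArray")}
    cd = {e.get("Name"): parse(e) for e in piece.findall("./CellData/DataArray")}
    mesh = LabeledMesh(nodes=nodes, elements=elements,
                       regions=cd.get("region", np.zeros(len(elements), int)))
    for name, arr in pd.items():
        if name.startswith("nset:"):
            mesh.node_sets[name[5:]] = np.flatnonzero(arr)
    return mesh


# ---------------------------------------------------------------------------
# Abaqus-INP dialect


def write_inp(mesh: LabeledMesh, path) -> None:
    """Nodes (1-based), one C3D4 element block + element set per region,
    plus the named node sets."""
    lines = ["*HEADING", "mandiflex surrogate mesh", "*NODE"]
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i}, {x:.17g}, {y:.17g}, {z:.17g}")
    eid = 1
    for code, rname in enumerate(REGION_NAMES):
        sel = np.flatnonzero(mesh.regions == code)
        if len(sel) == 0:
            continue
        lines.append(f"*ELEMENT, TYPE=C3D4, ELSET={rname.upper()}")
        for e in sel:
            a, b, c, d = mesh.elements[e] + 1
            lines.append(f"{eid}, {a}, {b}, {c}, {d}")
            eid += 1
    for name, ids in mesh.node_sets.items():
        lines.append(f"*NSET, NSET={name}")
        ids1 = (np.asarray(ids) + 1).tolist()
        for i in range(0, len(ids1), 12):
            lines.append(", ".join(str(v) for v in ids1[i:i + 12]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_inp(path) -> LabeledMesh:
    nodes, elements, regions = [], [], []
    node_sets: dict[str, list[int]] = {}
    mode, current = None, None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("**"):
            continue
        if line.startswith("*"):
            kw = line.split(",")[0].upper()
            opts = dict(
                kv.strip().split("=") for kv in line.split(",")[1:] if "=" in kv)
            opts = {k.strip().upper(): v.strip() for k, v in opts.items()}
            if kw == "*NODE":
                mode = "node"
            elif kw == "*ELEMENT":
                mode = "element"
                current = opts.get("ELSET", "CORTICAL").lower()
            elif kw == "*NSET":
                mode = "nset"
                current = opts.get("NSET", "set")
                node_sets.setdefault(current, [])
            else:
                mode = None
            continue
        if mode == "node":
            parts = line.split(",")
            nodes.append([float(v) for v in parts[1:4]])
        elif mode == "element":
            parts = [int(v) for v in line.split(",")]
            elements.append([v - 1 for v in parts[1:5]])
            regions.append(REGION_CODES.get(current, 0))
        elif mode == "nset":
            node_sets[current].extend(
                int(v) - 1 for v in line.split(",") if v.strip())
    mesh = LabeledMesh(nodes=np.array(nodes, float),
                       elements=np.array(elements, int),
                       regions=np.array(regions, int))
    for name, ids in node_sets.items():
        mesh.node_sets[name] = np.array(sorted(ids), int)
    return mesh


# ---------------------------------------------------------------------------
# solution export


def write_solution_vtu(solution, path) -> None:
    """VTU with displacement, averaged nodal strain, nodal e1/e3 point data
    and the element strain tensor + principal strains as cell data."""
    mesh = solution.mesh
    navg = solution.nodal_strain()
    nprinc = solution.nodal_principal()
    write_vtu(
        mesh, path,
        point_data={
            "displacement": solution.u,
            "reaction": solution.reactions,
            "strain_avg": navg,
            "e1": nprinc[:, 0], "e3": nprinc[:, 2],
        },
        cell_data={
            "strain": solution.strain,
            "principal": solution.principal,
        },
    )
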