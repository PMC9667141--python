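"""Free-body cross-section moment analysis.

Moments acting anterior to coronal sections through each hemimandible, and
to the left of sagittal sections through the symphysis, taken about the
area centroid of each cut cross-section.  Moments are computed from the
external loads (muscle patch resultants and constraint reactions) acting
on the free body rather than by integrating element internal forces; the
two are statically equivalent, and the equivalence (anterior moments equal
minus posterior moments) is enforced as a test invariant.

The decomposition columns follow the twisting-moment bookkeeping used for
sections through the toothrow: for a load F at arm (dx, dy, dz) from the
section centroid the moment about the anterior-posterior axis is
My = Fx*dz - Fz*dx (N m; forces in N, arms in mm, divided by 1000).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fem import SolutionField
from .geometry import LabeledMesh
from .loads import LoadCase, patch_set_name

REGIONS = ("left_hemimandible", "right_hemimandible", "symphysis")


class SectionError(ValueError):
    pass


@dataclass(frozen=True)
class SectionSpec:
    region: str
    index: int
    origin: tuple[float, float, float]
    normal: tuple[float, float, float]
    centroid: tuple[float, float, float]


@dataclass
class LoadGroup:
    """One external load for free-body bookkeeping: per-point forces with a
    common name (a muscle patch, or one constrained node set's reactions)."""

    name: str
    points: np.ndarray       # (k, 3)
    forces: np.ndarray       # (k, 3)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @property
    def resultant(self) -> np.ndarray:
        return self.forces.sum(axis=0)


# ---------------------------------------------------------------------------
# sections


def _region_mask(mesh: LabeledMesh, region: str) -> np.ndarray:
    if region not in REGIONS:
        raise SectionError(f"unknown region {region!r}")
    p = mesh.params
    z_split = p.arch_radius / 3.0 if p is not None else \
        mesh.nodes[:, 2].max() / 3.0
    cz = mesh.element_centroids()[:, 2]
    bio = mesh.biological_mask()
    if region == "left_hemimandible":
        return bio & (cz > z_split)
    if region == "right_hemimandible":
        return bio & (cz < -z_split)
    return bio & (np.abs(cz) <= z_split)


def make_sections(mesh: LabeledMesh, region: str, n: int = 30) -> list[SectionSpec]:
    """``n`` equidistant cutting planes spanning the region: coronal planes
    (normal +y) for the hemimandibles, sagittal planes (normal +z) for the
    symphysis, ordered by position.  Centroids are volume-weighted centroids
    of the elements in a one-slab neighbourhood of each plane, projected
    onto it."""
    if n < 1:
        raise SectionError(f"section count must be >= 1, got {n}")
    mask = _region_mask(mesh, region)
    if not mask.any():
        raise SectionError(f"region {region!r} contains no elements")
    axis = 1 if region != "symphysis" else 2
    normal = np.zeros(3)
    normal[axis] = 1.0
    cent = mesh.element_centroids()[mask]
    vol = mesh.element_volumes()[mask]
    lo, hi = cent[:, axis].min(), cent[:, axis].max()
    positions = np.linspace(lo, hi, n + 2)[1:-1]
    slab = max((hi - lo) / (n + 1),
               mesh.metadata.get("mean_edge_length", 1.0)) * 0.75
    out = []
    for i, pos in enumerate(positions):
        near = np.abs(cent[:, axis] - pos) <= slab
        if not near.any():
            near = np.abs(cent[:, axis] - pos) <= 2 * slab
        w = vol[near]
        c = (cent[near] * w[:, None]).sum(axis=0) / w.sum()
        c[axis] = pos
        origin = np.zeros(3)
        origin[axis] = pos
        out.append(SectionSpec(region=region, index=i + 1,
                               origin=tuple(origin), normal=tuple(normal),
                               centroid=tuple(c)))
    return out


# ---------------------------------------------------------------------------
# moments


def moment_contribution(F, point, centroid):
    """Moment (N m) of force F (N) applied at ``point`` about ``centroid``
    (both mm), plus the (Fx*dz, Fz*dx, My) decomposition.

    M = r x F with r = point - centroid; My = Fx*dz - Fz*dx.
    """
    F = np.asarray(F, float)
    r = np.asarray(point, float) - np.asarray(centroid, float)
    M = np.cross(r, F) / 1000.0
    fx_dz = F[0] * r[2] / 1000.0
    fz_dx = F[2] * r[0] / 1000.0
    return M, (fx_dz, fz_dx, fx_dz - fz_dx)


def gather_load_groups(mesh: LabeledMesh, load_case: LoadCase,
                       solution: SolutionField) -> list[LoadGroup]:
    """All external loads on the mandible: one group per muscle patch
    (uniform nodal shares) and one per constrained node set (per-node
    reactions).  Bite-point sets are merged into a single bite group."""
    groups = []
    for (muscle, side), F in load_case.force_dict().items():
        ids = mesh.node_sets[patch_set_name(muscle, side)]
        forces = np.tile(np.asarray(F, float) / len(ids), (len(ids), 1))
        groups.append(LoadGroup(name=f"{muscle} {side}",
                                points=mesh.nodes[ids], forces=forces))
    w = load_case.working_side
    bite_ids = np.concatenate([mesh.node_sets[f"bite_{t}_{w}"]
                               for t in ("P3", "P4", "M1")])
    groups.append(LoadGroup(name=f"bite {w}",
                            points=mesh.nodes[bite_ids],
                            forces=solution.reactions[bite_ids]))
    for side in ("L", "R"):
        ids = mesh.node_sets[f"condyle_{side}"]
        groups.append(LoadGroup(name=f"condyle {side}",
                                points=mesh.nodes[ids],
                                forces=solution.reactions[ids]))
    return groups


@dataclass
class SectionMomentTable:
    """Long-form table: one row per (section, load group) plus a summed row
    per section.  Moment columns in N m."""

    df: pd.DataFrame
    sections: list[SectionSpec]

    def summed(self) -> pd.DataFrame:
        return self.df[self.df["load"] == "summed"].set_index("section")

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def moments_by_section(self, component: str) -> np.ndarray:
        return self.summed()[component].to_numpy()


def _include_group(group_centroid, region: str, plane_pos: float,
                   z_split: float) -> bool:
    """Free-body membership: for hemimandible sections the free body is
    everything except that hemimandible's loads posterior to the plane (the
    contralateral side stays attached through the symphysis); for sagittal
    symphysis sections it is everything to the anatomical left.  Loads
    exactly on the plane count as anterior/left."""
    gc = group_centroid
    if region == "left_hemimandible":
        return not (gc[2] > 0 and gc[1] < plane_pos)
    if region == "right_hemimandible":
        return not (gc[2] < 0 and gc[1] < plane_pos)
    return gc[2] >= plane_pos


def section_moments(solution: SolutionField, load_case: LoadCase,
                    sections: list[SectionSpec],
                    groups: list[LoadGroup] | None = None,
                    side: str = "anterior") -> SectionMomentTable:
    """Per-section free-body moments of all external loads on the anterior
    (or, with ``side='posterior'``, the complementary) free body.

    Group membership is decided by the group's centroid; moments are then
    accumulated exactly per load point, so the summed row equals the column
    sums and My = Fx*dz - Fz*dx holds row-wise by construction.
    """
    if side not in ("anterior", "posterior"):
        raise SectionError(f"unknown side {side!r}")
    mesh = solution.mesh
    if groups is None:
        groups = gather_load_groups(mesh, load_case, solution)
    p = mesh.params
    z_split = p.arch_radius / 3.0 if p is not None else 0.0
    axis = 1 if sections[0].region != "symphysis" else 2
    bio_max = mesh.element_centroids()[mesh.biological_mask(), axis].max()
    rows = []
    for sec in sections:
        c = np.asarray(sec.centroid)
        pos = sec.origin[axis]
        tot_M = np.zeros(3)
        tot_fx_dz = tot_fz_dx = 0.0
        for grp in groups:
            # a plane beyond the mesh leaves an empty anterior free body
            inc = (pos <= bio_max) and _include_group(
                grp.centroid, sec.region, pos, z_split)
            if side == "posterior":
                inc = not inc
            if not inc:
                continue
            r = grp.points - c
            M = np.cross(r, grp.forces).sum(axis=0) / 1000.0
            fx_dz = float(np.sum(grp.forces[:, 0] * r[:, 2])) / 1000.0
            fz_dx = float(np.sum(grp.forces[:, 2] * r[:, 0])) / 1000.0
            arm = grp.centroid - c
            F = grp.resultant
            rows.append(dict(section=sec.index, load=grp.name,
                             Fx=F[0], Fy=F[1], Fz=F[2],
                             dx=arm[0], dy=arm[1], dz=arm[2],
                             fx_dz=fx_dz, fz_dx=fz_dx,
                             Mx=M[0], My=M[1], Mz=M[2]))
            tot_M += M
            tot_fx_dz += fx_dz
            tot_fz_dx += fz_dx
        rows.append(dict(section=sec.index, load="summed",
                         Fx=np.nan, Fy=np.nan, Fz=np.nan,
                         dx=np.nan, dy=np.nan, dz=np.nan,
                         fx_dz=tot_fx_dz, fz_dx=tot_fz_dx,
                         Mx=tot_M[0], My=tot_M[1], Mz=tot_M[2]))
    return SectionMomentTable(df=pd.DataFrame(rows), sections=sections)


def scale_moments(table: SectionMomentTable, linear_ratio: float) -> SectionMomentTable:
    """Isometric scaling of all moment columns by linear_ratio**3."""
    if linear_ratio <= 0:
        raise SectionError("linear ratio must be positive")
    df = table.df.copy()
    for col in ("fx_dz", "fz_dx", "Mx", "My", "Mz"):
        df[col] = df[col] * linear_ratio ** 3
    return SectionMomentTable(df=df, sections=table.sections)


def compare_tables(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Element-wise ratio B/A over the shared numeric cells; cells with a
    zero denominator come back NaN (printed as n/a)."""
    a = table_a.select_dtypes("number")
    b = table_b.select_dtypes("number")
    if a.shape != b.shape:
        raise SectionError("tables have different shapes")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = b.to_numpy() / a.to_numpy()
    ratio[np.asarray(a == 0)] = np.nan
    return pd.DataFrame(ratio, index=a.index, columns=a.columns)


def landmark_sections(mesh: LabeledMesh, sections: list[SectionSpec]) -> dict[str, int]:
    """Map landmark names (tooth positions, coronoid tip, angle, condyle) to
    the nearest section index along the region axis."""
    lms = mesh.metadata.get("landmarks", {})
    axis = 1 if sections[0].region != "symphysis" else 2
    pos = np.array([s.origin[axis] for s in sections])
    return {name: int(sections[np.argmin(np.abs(pos - y))].index)
            for name, y in lms.items()}


def plot_moments(tables: dict[str, SectionMomentTable], path,
                 component: str = "My", landmarks: dict[str, int] | None = None):
    """Moment-vs-section line plot, one line per scenario, with optional
    landmark ticks (the layout of the classic moment-profile figures)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for name, tab in tables.items():
        s = tab.summed()
        ax.plot(s.index, s[component], marker="o", ms=3, label=name)
    ax.axhline(0, color="k", lw=0.5)
    if landmarks:
        for name, idx in landmarks.items():
            ax.axvline(idx, color="grey", lw=0.4, ls=":")
            ax.annotate(name, (idx, ax.get_ylim()[1]), fontsize=7,
                        ha="center", va="bottom")
    ax.set_xlabel("section (posterior → anterior)")
    ax.set_ylabel(f"{component} (N m)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
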