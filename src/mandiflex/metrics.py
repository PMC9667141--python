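"""Fracture-fixation strain post-processing.

Three analyses specific to comparing fixation constructs against the
healthy mandible:

* bone-implant interface region selection (coordinate bounds anchored on
  named landmarks, excluding nodes on bone-screw / bone-plate interfaces)
  and principal-strain statistics with the 200-300 / 300-1000 / 1000-5000
  microstrain occupancy bins;
* interfragmentary strain (IFS) across the fracture plane,
  IFS = (deformed distance - undeformed distance) / undeformed distance,
  classified compressive (< 0) / tensile (> 0) with medians per class;
* healthy-vs-fixed principal-strain difference fields on the cortical
  surface (for the minimum principal strain the difference of absolute
  values).

The surrogate's fracture cut duplicates nodes in place, so undeformed pair
distances are exactly zero there; those pairs use the signed normal opening
divided by a configurable reference gap (default: the local mean edge
length) -- the raw formula's denominator vanishes on a zero-gap cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .fem import SolutionField
from .geometry import REGION_CODES, LabeledMesh

MICRO = 1e6
STRAIN_BINS = ((200.0, 300.0), (300.0, 1000.0), (1000.0, 5000.0))  # microstrain


class SelectionError(ValueError):
    pass


class IFSError(ValueError):
    pass


class CorrespondenceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# bone-implant interface region


@dataclass(frozen=True)
class InterfaceRegionRule:
    """Coordinate bounds for the bone-implant interface region.

    max_x: superior edge of the oblique (Champy) fixation plate;
    max_y: the M2 landmark (midpoint of the second molar);
    min_z: the lingual inferior border, so the region covers the buccal
    cortical surface around the implant.  Nodes on bone-screw and
    bone-plate contact surfaces are excluded.
    """

    max_x: float
    max_y: float
    min_z: float
    exclude_nodes: tuple[int, ...] = ()

    @classmethod
    def from_landmarks(cls, mesh: LabeledMesh) -> "InterfaceRegionRule":
        md = mesh.metadata
        if "champy_plate_top_x" not in md:
            raise SelectionError("mesh has no fixation plate metadata")
        landmarks = md.get("landmarks", {})
        if "M2" not in landmarks:
            raise SelectionError("mesh has no M2 landmark")
        excl = mesh.node_sets.get("implant_contact_bone", np.zeros(0, int))
        return cls(max_x=float(md["champy_plate_top_x"]),
                   max_y=float(landmarks["M2"]),
                   min_z=float(md["z_lingual"]),
                   exclude_nodes=tuple(int(i) for i in excl))


def select_interface_nodes(mesh: LabeledMesh,
                           rule: InterfaceRegionRule) -> np.ndarray:
    """Cortical surface nodes within the rule's bounds, minus exclusions.

    An empty selection raises, naming the bound that removed the last
    candidate nodes.
    """
    for name in ("max_x", "max_y", "min_z"):
        if not np.isfinite(getattr(rule, name)):
            raise SelectionError(f"bound {name} is not finite")
    bio = mesh.biological_mask()
    surf = mesh.surface_nodes(bio)
    cortical_nodes = np.unique(mesh.elements[mesh.regions == REGION_CODES["cortical"]])
    cand = np.intersect1d(surf, cortical_nodes, assume_unique=False)
    nd = mesh.nodes
    checks = (("max_x", nd[cand, 0] <= rule.max_x),
              ("max_y", nd[cand, 1] <= rule.max_y),
              ("min_z", nd[cand, 2] >= rule.min_z))
    sel = np.ones(len(cand), bool)
    for name, ok in checks:
        if sel.any() and not (sel & ok).any():
            raise SelectionError(f"interface region empty: bound {name} "
                                 "excludes every remaining node")
        sel &= ok
    out = cand[sel]
    out = np.setdiff1d(out, np.asarray(rule.exclude_nodes, int))
    if len(out) == 0:
        raise SelectionError("interface region empty after removing "
                             "bone-implant contact nodes")
    return out


@dataclass
class InterfaceStrainReport:
    """Medians (microstrain) and bin occupancy of nodal principal strains
    over the selected interface region."""

    n_nodes: int
    median_e1: float
    median_e3: float
    bins_e1: tuple[int, ...]
    bins_abs_e3: tuple[int, ...]

    def as_dict(self) -> dict:
        return dict(n_nodes=self.n_nodes, median_e1=self.median_e1,
                    median_e3=self.median_e3, bins_e1=list(self.bins_e1),
                    bins_abs_e3=list(self.bins_abs_e3))


def _bin_counts(values_micro: np.ndarray) -> tuple[int, ...]:
    return tuple(int(np.count_nonzero((values_micro >= lo) & (values_micro < hi)))
                 for lo, hi in STRAIN_BINS)


def strain_summary(e1: np.ndarray, e3: np.ndarray,
                   in_microstrain: bool = False) -> InterfaceStrainReport:
    """Median principal strains and half-open bin counts [200, 300),
    [300, 1000), [1000, 5000) microstrain on e1 and |e3|."""
    e1 = np.asarray(e1, float) * (1.0 if in_microstrain else MICRO)
    e3 = np.asarray(e3, float) * (1.0 if in_microstrain else MICRO)
    if e1.size == 0:
        raise SelectionError("empty strain selection")
    return InterfaceStrainReport(
        n_nodes=int(e1.size),
        median_e1=float(np.median(e1)),
        median_e3=float(np.median(e3)),
        bins_e1=_bin_counts(e1),
        bins_abs_e3=_bin_counts(np.abs(e3)),
    )


def bin_fold_changes(a: InterfaceStrainReport,
                     b: InterfaceStrainReport) -> tuple[float, ...]:
    """Per-bin occupancy ratio b/a (NaN where a has an empty bin)."""
    return tuple(nb / na if na else float("nan")
                 for na, nb in zip(a.bins_e1, b.bins_e1))


def interface_strain_report(mesh: LabeledMesh, solution: SolutionField,
                            rule: InterfaceRegionRule | None = None
                            ) -> InterfaceStrainReport:
    rule = rule or InterfaceRegionRule.from_landmarks(mesh)
    ids = select_interface_nodes(mesh, rule)
    princ = solution.nodal_principal(
        region_codes=[REGION_CODES["cortical"]])[ids]
    return strain_summary(princ[:, 0], princ[:, 2])


# ---------------------------------------------------------------------------
# interfragmentary strain


@dataclass
class IFSReport:
    """Per-pair interfragmentary strain with compressive/tensile medians.

    ``median_abs`` is the median of |IFS| over all pairs;
    ``median_compressive`` / ``median_tensile`` are signed medians within
    each class.  Means are reported alongside the medians.
    """

    ifs: np.ndarray
    undeformed: np.ndarray
    deformed: np.ndarray
    n_pairs: int
    median_abs: float
    median_compressive: float
    median_tensile: float
    mean_abs: float
    mean_compressive: float
    mean_tensile: float

    def as_dict(self) -> dict:
        return dict(n_pairs=self.n_pairs, median_abs=self.median_abs,
                    median_compressive=self.median_compressive,
                    median_tensile=self.median_tensile,
                    mean_abs=self.mean_abs,
                    mean_compressive=self.mean_compressive,
                    mean_tensile=self.mean_tensile)


def interfragmentary_strain(undeformed_a: np.ndarray, undeformed_b: np.ndarray,
                            deformed_a: np.ndarray, deformed_b: np.ndarray,
                            normal: np.ndarray | None = None,
                            ref_gap: float | None = None,
                            min_gap: float = 1e-9) -> IFSReport:
    """IFS per node pair: (deformed - undeformed distance)/undeformed.

    Pairs whose undeformed distance is below ``min_gap`` (the coincident
    duplicated-node cut) use the signed opening along ``normal`` divided by
    ``ref_gap``; widening is positive, closing negative in either branch.
    """
    ua = np.atleast_2d(np.asarray(undeformed_a, float))
    ub = np.atleast_2d(np.asarray(undeformed_b, float))
    da = np.atleast_2d(np.asarray(deformed_a, float))
    db = np.atleast_2d(np.asarray(deformed_b, float))
    d0 = np.linalg.norm(ua - ub, axis=1)
    d1 = np.linalg.norm(da - db, axis=1)
    finite = d0 >= min_gap
    ifs = np.empty(len(d0))
    ifs[finite] = (d1[finite] - d0[finite]) / d0[finite]
    if (~finite).any():
        if ref_gap is None or ref_gap <= 0:
            raise IFSError(
                f"{int((~finite).sum())} pairs have undeformed distance below "
                f"min_gap={min_gap}; a positive ref_gap is required for the "
                "zero-gap (coincident cut) convention")
        if normal is None:
            raise IFSError("zero-gap pairs need the interface normal")
        n = np.asarray(normal, float)
        n = n / np.linalg.norm(n)
        opening = ((da - ua) - (db - ub)) @ n       # signed: widening > 0
        ifs[~finite] = opening[~finite] / ref_gap
    if len(ifs) == 0:
        raise IFSError("no pairs")
    comp = ifs[ifs < 0]
    tens = ifs[ifs > 0]
    med = lambda v: float(np.median(v)) if v.size else 0.0
    mean = lambda v: float(np.mean(v)) if v.size else 0.0
    return IFSReport(
        ifs=ifs, undeformed=d0, deformed=d1, n_pairs=len(ifs),
        median_abs=float(np.median(np.abs(ifs))),
        median_compressive=med(comp), median_tensile=med(tens),
        mean_abs=float(np.mean(np.abs(ifs))),
        mean_compressive=mean(comp), mean_tensile=mean(tens),
    )


def fracture_ifs_report(mesh: LabeledMesh, solution: SolutionField,
                        ref_gap: float | None = None) -> IFSReport:
    """IFS over the mesh's fracture pairs for a solved fixation model."""
    if mesh.fracture is None:
        raise IFSError("mesh has no fracture interface")
    fr = mesh.fracture
    a, b = fr.pairs[:, 0], fr.pairs[:, 1]
    if ref_gap is None:
        ref_gap = float(mesh.metadata.get("mean_edge_length", 1.0))
    return interfragmentary_strain(
        mesh.nodes[a], mesh.nodes[b],
        mesh.nodes[a] + solution.u[a], mesh.nodes[b] + solution.u[b],
        normal=fr.normal, ref_gap=ref_gap)


# ---------------------------------------------------------------------------
# healthy-vs-fixed strain difference


def strain_difference_field(fixed_solution: SolutionField,
                            healthy_solution: SolutionField,
                            match_tol: float = 1e-6):
    """Per-node principal-strain differences on the shared cortical surface.

    Returns (fixed-mesh surface node ids, delta_e1, delta_abs_e3) with
    delta_e1 = e1_fixed - e1_healthy and
    delta_abs_e3 = |e3_fixed| - |e3_healthy|.

    Correspondence is geometric: every biological surface node of the fixed
    mesh (including fracture duplicates, which coincide with their
    originals) must match a healthy surface node within ``match_tol``.
    """
    fm, hm = fixed_solution.mesh, healthy_solution.mesh
    f_surf = fm.surface_nodes(fm.biological_mask())
    # the cut exposes interface faces that are interior in the healthy mesh,
    # so candidates are all biological nodes, not only surface nodes
    h_surf = np.unique(hm.elements[hm.biological_mask()])
    d, j = cKDTree(hm.nodes[h_surf]).query(fm.nodes[f_surf])
    if d.max() > match_tol:
        raise CorrespondenceError(
            f"{int((d > match_tol).sum())} fixed-surface nodes have no "
            f"healthy counterpart within {match_tol} (max distance {d.max():g})")
    cort = [REGION_CODES["cortical"]]
    pf = fixed_solution.nodal_principal(region_codes=cort)[f_surf]
    ph = healthy_solution.nodal_principal(region_codes=cort)[h_surf[j]]
    d_e1 = pf[:, 0] - ph[:, 0]
    d_abs_e3 = np.abs(pf[:, 2]) - np.abs(ph[:, 2])
    return f_surf, d_e1, d_abs_e3
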