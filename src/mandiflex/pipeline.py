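"""Scenario-matrix orchestration.

Runs the (healthy | champy | biplanar) x (ipsilateral/left | contralateral/
right chew) matrix on one surrogate geometry, with per-scenario solution
exports, section-moment tables, interfragmentary-strain and bone-implant
strain reports, cross-scenario comparisons and a reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contact import ContactSpec, mesh_contact_groups, solve_with_contact
from .fem import (MaterialMap, apply_constraints, assemble_system, bite_reaction,
                  build_load_vector, solve_static)
from .geometry import (GeometryParams, LabeledMesh, attach_fixation,
                       build_surrogate_mandible, cut_angle_fracture)
from .io import write_solution_vtu, write_vtu
from .loads import (build_load_case, isometric_scale_factors,
                    load_muscle_force_table, load_section_moment_table,
                    load_unit_vector_table)
from .metrics import (InterfaceRegionRule, fracture_ifs_report,
                      interface_strain_report, strain_difference_field)
from .sections import (landmark_sections, make_sections, plot_moments,
                       section_moments)

log = logging.getLogger("mandiflex")

STATES = ("healthy", "champy", "biplanar")
DEFAULT_SCENARIOS = tuple((s, c) for s in STATES for c in ("left", "right"))


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    geometry: GeometryParams = field(default_factory=GeometryParams)
    materials: MaterialMap = field(default_factory=MaterialMap)
    contact: ContactSpec = field(default_factory=ContactSpec)
    load_table: str | None = None        # CSV path; None = packaged table
    constraint_variant: str = "full"     # or "vertical_bite"
    scenarios: tuple = DEFAULT_SCENARIOS
    n_sections: int = 30
    outdir: str = "mandiflex_out"
    seed: int = 0
    write_vtu: bool = False
    make_plots: bool = False

    def __post_init__(self):
        if not self.scenarios:
            raise PipelineError("scenario list is empty")

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        def listify(o):
            if isinstance(o, dict):
                return {k: listify(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [listify(v) for v in o]
            return o

        d = dataclasses.asdict(self)
        d["geometry"] = dataclasses.asdict(self.geometry)
        d["materials"] = dataclasses.asdict(self.materials)
        d["contact"] = dataclasses.asdict(self.contact)
        return listify(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "geometry" in d:
            geo = dict(d["geometry"])
            if geo.get("tooth_landmarks") is not None:
                geo["tooth_landmarks"] = tuple(
                    (n, float(y)) for n, y in geo["tooth_landmarks"])
            if geo.get("plates") is not None:
                from .geometry import PlateSpec
                geo["plates"] = tuple(PlateSpec(**p) if isinstance(p, dict)
                                      else p for p in geo["plates"])
            d["geometry"] = GeometryParams(**{
                k: (tuple(v) if isinstance(v, list) else v)
                for k, v in geo.items()})
        if "materials" in d:
            d["materials"] = MaterialMap(**{k: tuple(v)
                                            for k, v in d["materials"].items()})
        if "contact" in d:
            d["contact"] = ContactSpec(**d["contact"])
        if "scenarios" in d:
            d["scenarios"] = tuple(tuple(s) for s in d["scenarios"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


# ---------------------------------------------------------------------------
# scenario results


@dataclass
class ScenarioResult:
    state: str
    chew_side: str
    solution: object
    contact_state: object | None
    moments: object                 # SectionMomentTable (left hemimandible)
    bite_force: np.ndarray
    ifs: object | None              # IFSReport
    interface_strain: object | None
    wall_time: float

    @property
    def name(self) -> str:
        return f"{self.state}_{self.chew_side}"


@dataclass
class RunReport:
    config: RunConfig
    results: dict[str, ScenarioResult]
    comparisons: dict
    failures: dict[str, str]
    manifest: dict

    @property
    def ok(self) -> bool:
        return not self.failures


# ---------------------------------------------------------------------------
# the pipeline


def build_state_meshes(params: GeometryParams, states) -> dict[str, LabeledMesh]:
    meshes: dict[str, LabeledMesh] = {}
    healthy = build_surrogate_mandible(params)
    meshes["healthy"] = healthy
    if any(s != "healthy" for s in states):
        fractured = cut_angle_fracture(healthy)
        for s in states:
            if s in ("champy", "biplanar"):
                meshes[s] = attach_fixation(fractured, s)
    return meshes


def solve_scenario(mesh: LabeledMesh, materials: MaterialMap,
                   load_case, contact_spec: ContactSpec,
                   n_sections: int = 30):
    """Assemble, solve (with contact when the mesh is fractured) and
    post-process one scenario."""
    t0 = time.time()
    system = assemble_system(mesh, materials)
    csys = apply_constraints(system, load_case)
    f = build_load_vector(system, load_case)
    contact_state = None
    if mesh.fracture is not None:
        solution, contact_state = solve_with_contact(
            csys, f, mesh_contact_groups(mesh), contact_spec)
    else:
        solution = solve_static(csys, f=f)
    secs = make_sections(mesh, "left_hemimandible", n_sections)
    moments = section_moments(solution, load_case, secs)
    w = load_case.working_side
    bite_ids = np.concatenate([mesh.node_sets[f"bite_{t}_{w}"]
                               for t in ("P3", "P4", "M1")])
    bite = bite_reaction(solution, bite_ids)
    ifs = None
    iface = None
    if mesh.fracture is not None:
        ifs = fracture_ifs_report(mesh, solution)
        iface = interface_strain_report(mesh, solution)
    return solution, contact_state, moments, bite, ifs, iface, time.time() - t0


def run_scenarios(config: RunConfig) -> RunReport:
    """Run the configured scenario matrix; failures abort that scenario but
    the rest continue.  Outputs land under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed)
    np.random.seed(rng_seed % 2 ** 31)    # no stochastic stages; recorded anyway

    load_df = (pd.read_csv(config.load_table)
               if config.load_table else load_muscle_force_table())
    states = sorted({s for s, _ in config.scenarios},
                    key=lambda s: STATES.index(s))
    meshes = build_state_meshes(config.geometry, states)

    results: dict[str, ScenarioResult] = {}
    failures: dict[str, str] = {}
    for state, chew in config.scenarios:
        name = f"{state}_{chew}"
        log.info("scenario %s: starting", name)
        try:
            lc = build_load_case(load_df, chew_side=chew,
                                 constraint_variant=config.constraint_variant)
            (sol, cst, moments, bite, ifs, iface, dt) = solve_scenario(
                meshes[state], config.materials, lc, config.contact,
                config.n_sections)
            res = ScenarioResult(state=state, chew_side=chew, solution=sol,
                                 contact_state=cst, moments=moments,
                                 bite_force=bite, ifs=ifs,
                                 interface_strain=iface, wall_time=dt)
            results[name] = res
            _write_scenario(outdir / name, res, config)
            log.info("scenario %s: done in %.1f s (contact iters: %s)",
                     name, dt, cst.iterations if cst else "-")
        except Exception as exc:
            log.error("scenario %s failed: %s", name, exc)
            failures[name] = f"{exc}\n{traceback.format_exc()}"

    comparisons = compare_scenarios(results, meshes)
    (outdir / "comparisons.json").write_text(
        json.dumps(comparisons, indent=2, default=_jsonable))

    manifest = dict(
        package_version=__version__,
        config_digest=config.digest(),
        seed=rng_seed,
        numpy_version=np.__version__,
        scenarios_completed=sorted(results),
        scenarios_failed=sorted(failures),
        mesh_checksums={s: m.checksum() for s, m in meshes.items()},
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    config.to_yaml(outdir / "config.yaml")
    if config.make_plots and results:
        plot_moments({n: r.moments for n, r in results.items()},
                     outdir / "moments_My.png", component="My",
                     landmarks=landmark_sections(
                         meshes["healthy"],
                         results[next(iter(results))].moments.sections))
    return RunReport(config=config, results=results, comparisons=comparisons,
                     failures=failures, manifest=manifest)


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(type(o))


def _write_scenario(d: Path, res: ScenarioResult, config: RunConfig) -> None:
    d.mkdir(parents=True, exist_ok=True)
    res.moments.to_csv(d / "section_moments.csv")
    summary = dict(
        state=res.state, chew_side=res.chew_side,
        bite_reaction_N=res.bite_force.tolist(),
        bite_force_on_food_N=(-res.bite_force).tolist(),
        wall_time_s=res.wall_time,
    )
    if res.ifs is not None:
        summary["ifs"] = res.ifs.as_dict()
        pd.DataFrame(dict(undeformed=res.ifs.undeformed,
                          deformed=res.ifs.deformed,
                          ifs=res.ifs.ifs)).to_csv(d / "ifs_pairs.csv",
                                                   index=False)
    if res.interface_strain is not None:
        summary["interface_strain"] = res.interface_strain.as_dict()
    if res.contact_state is not None:
        cs = res.contact_state
        pd.DataFrame(dict(status=cs.status, normal_force=cs.normal_force,
                          gap=cs.gap,
                          tangent_force=np.linalg.norm(cs.tangent_force,
                                                       axis=1))
                     ).to_csv(d / "contact_pairs.csv", index=False)
    (d / "summary.json").write_text(json.dumps(summary, indent=2))
    if config.write_vtu:
        write_solution_vtu(res.solution, d / "solution.vtu")


# ---------------------------------------------------------------------------
# cross-scenario comparisons


def compare_scenarios(results: dict[str, ScenarioResult],
                      meshes: dict[str, LabeledMesh]) -> dict:
    """The fixation-vs-healthy orderings the study design asks about:
    median |IFS| per fixation and chew side, sign agreement of the
    sagittal-bending (Mz) moment profile anterior to the fracture, and the
    right-side (non-fractured) strain-difference medians."""
    out: dict = {}

    ifs = {}
    for name, r in results.items():
        if r.ifs is not None:
            ifs[name] = dict(median_abs=r.ifs.median_abs,
                             median_compressive=r.ifs.median_compressive,
                             median_tensile=r.ifs.median_tensile,
                             n_pairs=r.ifs.n_pairs)
    out["ifs"] = ifs
    ords = {}
    for chew in ("left", "right"):
        a, b = f"champy_{chew}", f"biplanar_{chew}"
        if a in ifs and b in ifs:
            ords[f"champy_gt_biplanar_{chew}"] = bool(
                ifs[a]["median_abs"] > ifs[b]["median_abs"])
    for state in ("champy", "biplanar"):
        a, b = f"{state}_right", f"{state}_left"
        if a in ifs and b in ifs:
            ords[f"contralateral_ge_ipsilateral_{state}"] = bool(
                ifs[a]["median_abs"] >= ifs[b]["median_abs"])
    out["ifs_orderings"] = ords
    # diagnostic: the same orderings on the tensile (opening) medians, which
    # are insensitive to the closed-pair fraction of the zero-gap cut
    tens = {}
    for chew in ("left", "right"):
        a, b = f"champy_{chew}", f"biplanar_{chew}"
        if a in ifs and b in ifs:
            tens[f"champy_gt_biplanar_{chew}"] = bool(
                ifs[a]["median_tensile"] > ifs[b]["median_tensile"])
    for state in ("champy", "biplanar"):
        a, b = f"{state}_right", f"{state}_left"
        if a in ifs and b in ifs:
            tens[f"contralateral_ge_ipsilateral_{state}"] = bool(
                ifs[a]["median_tensile"] >= ifs[b]["median_tensile"])
    out["ifs_tensile_orderings"] = tens

    # sagittal-bending (Mz) sign agreement anterior to the fracture,
    # contralateral chew
    if all(f"{s}_right" in results for s in STATES):
        mz = {s: results[f"{s}_right"].moments.summed()["Mz"].to_numpy()
              for s in STATES}
        secs = results["healthy_right"].moments.sections
        mesh = meshes["healthy"]
        y_frac = float(mesh.metadata["fracture_point"][1])
        anterior = np.array([s.origin[1] > y_frac for s in secs])
        hs = np.sign(mz["healthy"][anterior])
        out["mz_sign_flips_anterior_contralateral"] = {
            s: int(np.sum(np.sign(mz[s][anterior]) != hs))
            for s in ("champy", "biplanar")}
        out["mz_reversal_where_biplanar_matches"] = bool(np.any(
            (np.sign(mz["champy"][anterior]) != hs)
            & (np.sign(mz["biplanar"][anterior]) == hs)))

    # non-fractured (right, z < 0) side strain-difference medians,
    # contralateral chew
    if all(f"{s}_right" in results for s in STATES):
        healthy = results["healthy_right"].solution
        med = {}
        for s in ("champy", "biplanar"):
            ids, d1, d3 = strain_difference_field(
                results[f"{s}_right"].solution, healthy)
            fmesh = results[f"{s}_right"].solution.mesh
            right = fmesh.nodes[ids, 2] < 0
            med[s] = dict(
                median_abs_de1=float(np.median(np.abs(d1[right])) * 1e6),
                median_abs_de3=float(np.median(np.abs(d3[right])) * 1e6))
        out["strain_difference_nonfractured_contralateral"] = med
        out["strain_difference_champy_gt_biplanar"] = bool(
            med["champy"]["median_abs_de1"] > med["biplanar"]["median_abs_de1"])
    return out


# ---------------------------------------------------------------------------
# printed-table validation


@dataclass
class TableValidationReport:
    failures: list[tuple]           # (table, row, column, expected, got)
    n_checks: int

    @property
    def ok(self) -> bool:
        return not self.failures


def _round_half_away(x, nd=2):
    factor = 10.0 ** nd
    return np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor


def validate_tables(force_table: pd.DataFrame | None = None,
                    unit_table: pd.DataFrame | None = None,
                    moment_table: pd.DataFrame | None = None
                    ) -> TableValidationReport:
    """Exact-arithmetic cross-checks of the packaged load/moment tables.

    Checks: every muscle force vector normalises to the printed human unit
    vector (0.01 per component); the printed human-minus-macaque block
    equals the difference of the printed unit vectors at 2 dp; the
    twisting-moment decomposition satisfies My = Fx*dz - Fz*dx within
    printed rounding; summed rows match column sums within rounding
    propagation; ratio columns match the printed cross-species ratios
    within quotient rounding propagation.
    """
    t1 = force_table if force_table is not None else load_muscle_force_table()
    t2 = unit_table if unit_table is not None else load_unit_vector_table()
    t3 = moment_table if moment_table is not None else load_section_moment_table()
    if len(t1) == 0 or len(t2) == 0 or len(t3) == 0:
        raise PipelineError("empty table fixture")
    failures, n = [], 0

    t2i = t2.set_index(["muscle", "side"])
    for _, row in t1.iterrows():
        v = np.array([row.Fx, row.Fy, row.Fz])
        u = v / np.linalg.norm(v)
        ref = t2i.loc[(row.muscle, row.side)]
        for comp, val in zip(("x", "y", "z"), u):
            n += 1
            exp = float(ref[f"homo_{comp}"])
            if abs(val - exp) > 0.01 + 1e-12:
                failures.append(("table1~table2", f"{row.muscle} {row.side} "
                                 f"{row.chew_side}", comp, exp, float(val)))
    for _, row in t2.iterrows():
        for comp in ("x", "y", "z"):
            n += 1
            got = _round_half_away(row[f"homo_{comp}"] - row[f"macaca_{comp}"])
            exp = float(row[f"diff_{comp}"])
            if abs(got - exp) > 1e-9:
                failures.append(("table2 diff", f"{row.muscle} {row.side}",
                                 comp, exp, float(got)))

    body = t3[t3["load"] != "summed torques"]
    summed = t3[t3["load"] == "summed torques"].iloc[0]
    for sp in ("macaque", "human"):
        for _, row in body.iterrows():
            n += 1
            got = row[f"{sp}_fx_dz"] - row[f"{sp}_fz_dx"]
            exp = row[f"{sp}_my"]
            if abs(got - exp) > 0.02 + 1e-12:
                failures.append(("table3 My", row["load"], sp, float(exp),
                                 float(got)))
        for col in ("fx_dz", "fz_dx", "my"):
            n += 1
            got = body[f"{sp}_{col}"].sum()
            exp = summed[f"{sp}_{col}"]
            # the printed summed row was computed before rounding the
            # per-load cells: allow the propagated rounding bound
            if abs(got - exp) > 0.005 * len(body) + 1e-12:
                failures.append(("table3 summed", col, sp, float(exp),
                                 float(got)))
    for _, row in t3.iterrows():
        for col in ("fx_dz", "fz_dx", "my"):
            exp = row[f"ratio_{col}"]
            if pd.isna(exp):
                continue
            n += 1
            mac, hum = row[f"macaque_{col}"], row[f"human_{col}"]
            if mac == 0:
                failures.append(("table3 ratio", row["load"], col,
                                 float(exp), float("nan")))
                continue
            got = hum / mac
            tol = 0.005 / abs(mac) * (1.0 + abs(got)) + 0.005
            if abs(got - exp) > tol + 1e-12:
                failures.append(("table3 ratio", row["load"], col,
                                 float(exp), float(got)))
    return TableValidationReport(failures=failures, n_checks=n)


def isometry_note() -> dict:
    """The macaque-to-human isometric scaling constants (76 -> 113.5 mm)."""
    f = isometric_scale_factors(76.0, 113.5, rounding=1)
    return dict(linear=f.linear, force=f.force, moment=round(f.moment, 2))
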