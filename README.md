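# mandiflex

Comparative mandibular biomechanics at desk scale: how does fixation of a
mandibular angle fracture — a single superior miniplate (Champy
technique) versus superior plus inferior plates (biplanar) — change the
mechanical environment of the jaw during unilateral chewing, relative to
the healthy bone?

The package is aimed at biomechanics researchers and method developers
who want a fully scripted, reproducible stand-in for the anatomical
finite-element pipelines used in mandible fixation research: a parametric
mandible surrogate with named anatomical node sets, physiologic muscle
loading, a verified linear-tetrahedral elastic solver with tie constraints
and frictional contact, and the fracture-specific post-processing that
the field reports.

## The model

* **Geometry** — a swept U-arch surrogate mandible (cortical shell,
  trabecular core, tooth blocks, rami with condylar knobs), an oblique
  element-face fracture cut through the left angle with exactly
  coincident paired surfaces, and miniplate + screw constructs that span
  the fracture.
* **Loading** — the ten jaw-closing muscle force vectors per chew side
  (anterior/posterior temporalis, deep/superficial masseter, medial
  pterygoid, both sides), built from PCSA × specific tension (30 N/cm²)
  × activation or taken from the packaged table, distributed uniformly
  over attachment patches.  Working-side condyle and bite points fixed;
  balancing condyle free mediolaterally.  Bite force is the constraint
  reaction at the bite points.
* **Solution** — small-strain isotropic elasticity (cortical 17 GPa,
  teeth 24.5 GPa, trabecular 10 GPa, titanium 105 GPa), sparse direct
  solves; penalty contact with Coulomb friction μ = 0.3 at the fracture
  and plate–bone interfaces.
* **Analysis** — free-body moments about 30 equidistant cross-sections
  (M = r × F of all external loads anterior to each plane, with the
  My = Fx·dz − Fz·dx decomposition), interfragmentary strain
  IFS = (deformed − undeformed distance)/undeformed distance across the
  fracture with compressive/tensile classification, bone–implant
  interface strain statistics (medians of principal strains ε1/ε3 and
  200–300/300–1000/1000–5000 µε occupancy bins), and fixed-vs-healthy
  strain-difference fields.

See `docs/methods.md` for assumptions, defaults, numerical choices and
what the surrogate does and does not establish.

## Worked example

```python
import numpy as np
from mandiflex import (GeometryParams, build_surrogate_mandible,
                       cut_angle_fracture, attach_fixation,
                       build_load_case, MaterialMap, assemble_system,
                       apply_constraints, build_load_vector,
                       solve_with_contact, mesh_contact_groups,
                       bite_reaction)
from mandiflex.metrics import fracture_ifs_report

mesh = attach_fixation(cut_angle_fracture(
    build_surrogate_mandible(GeometryParams())), "champy")
case = build_load_case(chew_side="right")          # contralateral chew
system = assemble_system(mesh, MaterialMap())
csys = apply_constraints(system, case)
f = build_load_vector(system, case)
sol, contact_state = solve_with_contact(csys, f, mesh_contact_groups(mesh))

bite = np.concatenate([mesh.node_sets[f"bite_{t}_R"] for t in ("P3", "P4", "M1")])
print("bite force on food (N):", np.round(-bite_reaction(sol, bite), 1))
print("median tensile IFS:", round(fracture_ifs_report(mesh, sol).median_tensile, 6))
```

prints (default 3 mm surrogate, single-plate fixation, right-side chew):

```
bite force on food (N): [31.6 28.3 28.1]
median tensile IFS: 0.000632
```

The first line is the reaction the food item sees — about 32 N
superiorly directed plus antero-lateral shear, an output of the model,
not an input.  The second is the median opening strain across the
fracture pairs; on the zero-gap surrogate the IFS denominator is the
local element size, so magnitudes are mesh-referenced (orderings across
fixations and chew sides are the meaningful comparison; single-plate
fixation under contralateral chewing is the least stable configuration).

The full scenario matrix, with comparison report and manifest:

```bash
mandiflex run --outdir out --seed 1          # 3 states x 2 chew sides
mandiflex validate-tables                    # printed-table arithmetic
mandiflex generate --outdir meshes           # VTU + INP surrogate meshes
```

`out/comparisons.json` then holds the cross-scenario orderings (IFS by
fixation and chew side, sagittal-moment sign agreement with the healthy
state, strain-difference medians), one directory per scenario holds the
section-moment table, IFS pairs, contact state and summary, and
`manifest.json` records config digest, seed and mesh checksums.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computation from scratch: the packaged-table
cross-checks (muscle force vectors against unit vectors, the section
moment decomposition and its cross-species ratios, the isometric scaling
constants) and the full six-scenario fixation matrix on the default
surrogate, printing a summary and writing the target JSON to `--out`.
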