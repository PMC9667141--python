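"""Physiologic masticatory loading.

Muscle force magnitudes follow the standard PCSA model: maximum force =
physiological cross-sectional area (cm^2) x specific tension (default
30 N/cm^2), scaled by the activation fraction recorded during unilateral
chewing.  Directions run from the mandibular insertion centroid to the
cranial origin centroid.  The canonical human load set (ten jaw-closing
muscle force vectors per chew side, in the global SI/AP/ML frame) ships as
a packaged table and is applied by distributing each vector uniformly over
its attachment patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

MUSCLES = (
    "anterior temporalis",
    "posterior temporalis",
    "deep masseter",
    "superficial masseter",
    "medial pterygoid",
)
SIDES = ("L", "R")
CHEW_SIDES = ("left", "right")
DEFAULT_SPECIFIC_TENSION = 30.0  # N/cm^2


class LoadConfigurationError(ValueError):
    """A load case is incomplete or inconsistent."""


def _data(name: str) -> pd.DataFrame:
    with resources.files("mandiflex.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_muscle_force_table() -> pd.DataFrame:
    """Packaged human muscle force vectors (N) per chew side."""
    return _data("table1_muscle_forces.csv")


def load_unit_vector_table() -> pd.DataFrame:
    """Packaged human and macaque muscle unit vectors and their difference."""
    return _data("table2_unit_vectors.csv")


def load_section_moment_table() -> pd.DataFrame:
    """Packaged section-moment decomposition (N m) anterior to the working
    side M2 section, for both species, with cross-species ratios."""
    return _data("table3_section_moments.csv")


def patch_set_name(muscle: str, side: str) -> str:
    return muscle.replace(" ", "_") + f"_{side}"


# ---------------------------------------------------------------------------
# muscle mechanics


def max_muscle_force(pcsa: float, specific_tension: float = DEFAULT_SPECIFIC_TENSION) -> float:
    """Maximum tetanic force (N) = PCSA (cm^2) x specific tension (N/cm^2)."""
    if pcsa <= 0:
        raise LoadConfigurationError(f"pcsa must be positive, got {pcsa}")
    if specific_tension <= 0:
        raise LoadConfigurationError(
            f"specific_tension must be positive, got {specific_tension}")
    return pcsa * specific_tension


def muscle_unit_vector(insertion_centroid, origin_centroid) -> np.ndarray:
    """Unit line of action from the mandibular insertion centroid toward the
    cranial origin centroid."""
    v = np.asarray(origin_centroid, float) - np.asarray(insertion_centroid, float)
    n = np.linalg.norm(v)
    if n == 0:
        raise LoadConfigurationError("insertion and origin centroids coincide")
    return v / n


@dataclass(frozen=True)
class MuscleSpec:
    name: str
    side: str
    pcsa: float                              # cm^2
    activation: float                        # fraction of maximum, per chew
    origin_centroid: tuple[float, float, float]
    insertion_centroid: tuple[float, float, float]
    specific_tension: float = DEFAULT_SPECIFIC_TENSION

    def __post_init__(self):
        if not 0.0 <= self.activation <= 1.0:
            raise LoadConfigurationError(
                f"activation must be in [0, 1], got {self.activation}")

    def force_vector(self) -> np.ndarray:
        u = muscle_unit_vector(self.insertion_centroid, self.origin_centroid)
        return max_muscle_force(self.pcsa, self.specific_tension) * self.activation * u


# ---------------------------------------------------------------------------
# load cases


@dataclass(frozen=True)
class LoadCase:
    """Per-muscle force vectors plus the chew-side constraint scheme.

    Constraints: working-side condyle and bite points (P3, P4, M1) fixed
    against translation in all directions; balancing-side condyle fixed in
    the superior-inferior (x) and anterior-posterior (y) directions only.
    The ``vertical_bite`` variant fixes bite points in x only.
    """

    chew_side: str
    forces: tuple[tuple[tuple[str, str], tuple[float, float, float]], ...]
    constraint_variant: str = "full"

    def __post_init__(self):
        if self.chew_side not in CHEW_SIDES:
            raise LoadConfigurationError(f"unknown chew side {self.chew_side!r}")
        if self.constraint_variant not in ("full", "vertical_bite"):
            raise LoadConfigurationError(
                f"unknown constraint variant {self.constraint_variant!r}")

    @property
    def working_side(self) -> str:
        return "L" if self.chew_side == "left" else "R"

    @property
    def balancing_side(self) -> str:
        return "R" if self.chew_side == "left" else "L"

    def force_dict(self) -> dict[tuple[str, str], np.ndarray]:
        return {k: np.asarray(v, float) for k, v in self.forces}

    def total_force(self) -> np.ndarray:
        return np.sum([np.asarray(v, float) for _, v in self.forces], axis=0)

    def constraints(self) -> list[tuple[str, tuple[int, ...]]]:
        w, b = self.working_side, self.balancing_side
        bite_dofs = (0, 1, 2) if self.constraint_variant == "full" else (0,)
        out = [(f"condyle_{w}", (0, 1, 2))]
        out += [(f"bite_{t}_{w}", bite_dofs) for t in ("P3", "P4", "M1")]
        out.append((f"condyle_{b}", (0, 1)))   # ML (z) left free
        return out

    def mirrored(self) -> "LoadCase":
        """The reflected load case (z -> -z, sides swapped)."""
        flip = {"L": "R", "R": "L"}
        forces = tuple(
            ((m, flip[s]), (fx, fy, -fz))
            for (m, s), (fx, fy, fz) in self.forces
        )
        chew = "right" if self.chew_side == "left" else "left"
        return replace(self, chew_side=chew, forces=forces)


def build_load_case(source=None, chew_side: str = "left",
                    constraint_variant: str = "full") -> LoadCase:
    """Assemble a LoadCase from muscle specs or a tabulated force table.

    ``source`` may be a list of :class:`MuscleSpec`, a DataFrame with columns
    (muscle, side, chew_side, Fx, Fy, Fz), or None for the packaged human
    table.  All ten bilateral jaw-closer vectors must be present.
    """
    if chew_side not in CHEW_SIDES:
        raise LoadConfigurationError(f"unknown chew side {chew_side!r}")
    forces: dict[tuple[str, str], np.ndarray] = {}
    if source is None:
        source = load_muscle_force_table()
    if isinstance(source, pd.DataFrame):
        sub = source[source["chew_side"] == chew_side]
        for _, row in sub.iterrows():
            forces[(row["muscle"], row["side"])] = np.array(
                [row["Fx"], row["Fy"], row["Fz"]], float)
    else:
        for spec in source:
            forces[(spec.name, spec.side)] = spec.force_vector()
    missing = [(m, s) for m in MUSCLES for s in SIDES if (m, s) not in forces]
    if missing:
        raise LoadConfigurationError(f"missing muscles: {missing}")
    extra = [k for k in forces if k[0] not in MUSCLES or k[1] not in SIDES]
    if extra:
        raise LoadConfigurationError(f"unknown muscles: {extra}")
    ordered = tuple(
        ((m, s), tuple(float(c) for c in forces[(m, s)]))
        for m in MUSCLES for s in SIDES
    )
    return LoadCase(chew_side=chew_side, forces=ordered,
                    constraint_variant=constraint_variant)


def distribute_over_patch(force, node_ids) -> np.ndarray:
    """Uniform per-node loads over an attachment patch; the nodal loads sum
    to the input vector exactly."""
    node_ids = np.asarray(node_ids)
    if node_ids.size == 0:
        raise LoadConfigurationError("attachment node set is empty")
    f = np.asarray(force, float)
    return np.tile(f / node_ids.size, (node_ids.size, 1))


# ---------------------------------------------------------------------------
# isometric scaling


@dataclass(frozen=True)
class ScaleFactors:
    linear: float
    force: float      # linear^2  (areas, hence PCSA-driven forces)
    moment: float     # linear^3  (force x length)


def isometric_scale_factors(length_ref: float, length_target: float,
                            rounding: int | None = None) -> ScaleFactors:
    """Geometric-similarity factors between two mandible lengths.

    When ``rounding`` is given, the linear ratio is rounded to that many
    decimals first and the force/moment factors derive from the rounded
    value (the convention used when quoting 76 mm -> 113.5 mm as 1.5x,
    2.25x, 3.38x).
    """
    if length_ref <= 0 or length_target <= 0:
        raise LoadConfigurationError("lengths must be positive")
    lin = length_target / length_ref
    if rounding is not None:
        lin = round(lin, rounding)
    return ScaleFactors(linear=lin, force=lin ** 2, moment=lin ** 3)
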