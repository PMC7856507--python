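"""Per-fraction dose accumulation and electrode-positioning scenarios.

A treatment course accumulates the per-fraction dose grids voxelwise.
Because image guidance does not cover every fraction, the accumulated
distribution is renormalized by

    N = prescription / (number of imaged fractions x dose per fraction)

so that the course sums to the prescribed dose.

Five electrode-positioning conditions are compared:

1. no electrodes on the scalp;
2. electrodes at the positions actually observed, varying from
   fixation period to fixation period;
3. electrodes virtually fixed at the sampled placement nearest the
   average position;
4. 2/5 of fractions without electrodes + 3/5 with fixed electrodes
   (array-change days are irradiated without arrays);
5. 2/5 of fractions without electrodes + 3/5 with varying positions.

The fractional mixes are implemented as deterministic convex
combinations of the accumulated component courses, which equals the
fraction-by-fraction construction when per-fraction plans are identical
and is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import DoseGrid

__all__ = [
    "FractionDose",
    "CourseDose",
    "ScenarioSpec",
    "SCENARIOS",
    "accumulate",
    "renormalization_factor",
    "build_scenario",
]

#: Scenario component sources.
NO_ELECTRODES = "no_electrodes"
VARYING_POSITIONS = "varying_positions"
FIXED_AVERAGE_POSITION = "fixed_average_position"


@dataclass(frozen=True)
class FractionDose:
    """Dose grid of a single fraction."""

    grid: DoseGrid
    electrodes_present: bool = False
    array_placement: str | None = None


@dataclass(frozen=True)
class CourseDose:
    """Accumulated (and renormalized) dose of a treatment course."""

    grid: DoseGrid
    prescription_gy: float
    fractions_accumulated: int


@dataclass(frozen=True)
class ScenarioSpec:
    """One electrode-positioning scenario as weighted component courses."""

    id: int
    components: tuple[tuple[str, float], ...]
    description: str = ""

    def __post_init__(self):
        total = sum(w for _, w in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"scenario {self.id}: component weights sum to {total}, expected 1"
            )
        if any(w < 0 for _, w in self.components):
            raise ValueError(f"scenario {self.id}: negative component weight")


SCENARIOS: dict[int, ScenarioSpec] = {
    1: ScenarioSpec(1, ((NO_ELECTRODES, 1.0),), "no electrodes"),
    2: ScenarioSpec(2, ((VARYING_POSITIONS, 1.0),), "observed varying positions"),
    3: ScenarioSpec(3, ((FIXED_AVERAGE_POSITION, 1.0),),
                    "fixed at placement nearest the average position"),
    4: ScenarioSpec(4, ((NO_ELECTRODES, 0.4), (FIXED_AVERAGE_POSITION, 0.6)),
                    "2/5 without electrodes + 3/5 fixed"),
    5: ScenarioSpec(5, ((NO_ELECTRODES, 0.4), (VARYING_POSITIONS, 0.6)),
                    "2/5 without electrodes + 3/5 varying"),
}


def accumulate(
    fractions: list[FractionDose],
    weights=None,
    prescription_gy: float | None = None,
) -> CourseDose:
    """Voxelwise weighted sum of per-fraction dose grids.

    All grids must be congruent (an error names the first mismatching
    metadata field). With ``weights=None`` each fraction contributes
    with weight 1. Linear: accumulating a concatenation of two fraction
    lists equals the sum of the separate accumulations.
    """
    if not fractions:
        raise ValueError("no fractions to accumulate")
    if weights is None:
        weights = np.ones(len(fractions))
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (len(fractions),):
        raise ValueError("one weight per fraction required")
    if np.any(weights < 0):
        raise ValueError("fraction weights must be non-negative")
    first = fractions[0].grid
    total = np.zeros(first.shape)
    for frac, w in zip(fractions, weights):
        first.congruent_with(frac.grid)
        total += w * frac.grid.values
    if prescription_gy is None:
        prescription_gy = float(total.max())
    return CourseDose(
        grid=first.with_values(total),
        prescription_gy=prescription_gy,
        fractions_accumulated=len(fractions),
    )


def renormalization_factor(
    prescription_gy: float,
    n_fractions_with_imaging: int,
    dose_per_fraction_gy: float,
) -> float:
    """Factor restoring the prescription over the imaged fractions.

    N = prescription / (imaged fractions x dose per fraction): 1 when
    every fraction was imaged, > 1 when the accumulation covers only a
    subset. The course's own prescription (e.g. 60 Gy at 2 Gy/F or
    40.05 Gy at 2.67 Gy/F) is used.
    """
    if prescription_gy <= 0 or dose_per_fraction_gy <= 0:
        raise ValueError("prescription and dose per fraction must be positive")
    if n_fractions_with_imaging <= 0:
        raise ValueError("at least one imaged fraction is required")
    return prescription_gy / (n_fractions_with_imaging * dose_per_fraction_gy)


def build_scenario(
    spec: ScenarioSpec,
    courses: dict[str, CourseDose],
) -> CourseDose:
    """Convex combination of accumulated component courses.

    Scenarios with a single component are pass-throughs; mixes are
    computed voxelwise, so integral dose mixes linearly as well.
    """
    missing = [src for src, _ in spec.components if src not in courses]
    if missing:
        raise ValueError(f"scenario {spec.id}: missing component course(s) {missing}")
    parts = []
    ref = courses[spec.components[0][0]]
    for src, w in spec.components:
        course = courses[src]
        ref.grid.congruent_with(course.grid)
        parts.append(w * course.grid.values)
    mixed = ref.grid.with_values(np.sum(parts, axis=0))
    return CourseDose(
        grid=mixed,
        prescription_gy=ref.prescription_gy,
        fractions_accumulated=max(c.fractions_accumulated for c in courses.values()),
    )
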