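"""Scale per-capita land use to national totals.

Per-capita figures (m² per person-year) are multiplied by a population
count and converted to hectares (1 ha = 10,000 m²).  Savings are also
expressed relative to named reference areas — county-level utilized
agricultural areas (UAA) — as an intuitive yardstick.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

from .errors import DietShiftError, ValidationError
from .food_model import ReferenceArea
from .scenario_engine import ScenarioResult

__all__ = [
    "NationalResult",
    "extrapolate_national",
    "national_result",
    "scenario_difference",
    "express_in_reference_areas",
]

M2_PER_HA = 10_000.0


@dataclass(frozen=True)
class NationalResult:
    """National land-use outcome of one scenario, all areas in hectares."""

    rate: float
    population: int
    national_initial: float
    national_final: float
    national_saving: float


def extrapolate_national(per_capita_m2: float, population: int) -> float:
    """Convert a per-capita figure (m²) to a national total (ha)."""
    if population <= 0:
        raise DietShiftError(f"population must be > 0, got {population}")
    if per_capita_m2 < 0:
        raise DietShiftError(f"per-capita land use must be >= 0, got {per_capita_m2}")
    return per_capita_m2 * population / M2_PER_HA


def national_result(result: ScenarioResult, population: int) -> NationalResult:
    """Extrapolate one scenario's per-capita totals to a population."""
    initial = extrapolate_national(result.total_initial, population)
    final = extrapolate_national(result.total_final, population)
    return NationalResult(
        rate=result.rate,
        population=population,
        national_initial=initial,
        national_final=final,
        national_saving=initial - final,
    )


def scenario_difference(a: NationalResult, b: NationalResult) -> float:
    """Hectares freed when moving from scenario ``a`` to scenario ``b``.

    Signed: positive when ``b`` uses less national land than ``a``.  The
    difference depends only on the replaced-land totals, so it is unaffected
    by any baseline convention.  Both results must refer to the same
    population.
    """
    if a.population != b.population:
        raise ValidationError(
            f"population mismatch: {a.population} vs {b.population}"
        )
    return a.national_final - b.national_final


def express_in_reference_areas(
    saving_ha: float, references: Sequence[ReferenceArea]
) -> list[tuple[ReferenceArea, float]]:
    """Rank reference areas by how closely they match a saving.

    Returns ``(reference, ratio)`` pairs with ``ratio = saving / hectares``
    rounded to 3 decimals, sorted so the reference whose ratio is nearest 1
    comes first.
    """
    if saving_ha < 0:
        raise DietShiftError(f"saving must be >= 0 ha, got {saving_ha}")
    if not references:
        raise ValidationError("reference area list must be nonempty")
    ranked = sorted(references, key=lambda ref: abs(saving_ha / ref.hectares - 1.0))
    return [(ref, round(saving_ha / ref.hectares, 3)) for ref in ranked]
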