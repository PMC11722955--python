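"""Per-food and total land-use accounting for protein-substitution scenarios.

For each food the model computes, per person-year:

* protein units  ``U = C · P / 10``  (number of 100-g blocks of protein),
* initial land use  ``LU_initial = U · LU_animal``,
* land claimed by the replacing plant mix at rate ``R``:
  ``LU_replaced = U · R · Σ w_i · LU_vegetal,i``,
* remaining land use  ``LU_final = LU_initial − LU_replaced``.

All computation is carried out at full floating precision; any rounding to
two decimals is a rendering concern (see :mod:`dietshift.io_cli`).  When a
food's animal intensity is *below* the mix's weighted intensity the
substitution costs land rather than saving it; such rows are reported with
a warning record, never clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections.abc import Sequence

from .errors import DietShiftError, ValidationError
from .food_model import DietBasket, FoodItem, ReplacementMix

__all__ = [
    "ScenarioSpec",
    "ScenarioRow",
    "ScenarioResult",
    "protein_units",
    "land_use_initial",
    "weighted_plant_intensity",
    "land_use_replaced",
    "land_use_final",
    "run_scenario",
    "scenario_sweep",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioSpec:
    """A replacement rate (fraction of animal protein replaced) plus the mix."""

    rate: float
    mix: ReplacementMix

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise DietShiftError(f"replacement rate must be in [0, 1], got {self.rate}")


@dataclass(frozen=True)
class ScenarioRow:
    """Per-food outcome of one scenario, all land figures in m² per capita-year."""

    food: str
    protein_units: float  # 100-g protein blocks per person-year
    lu_initial: float
    replaced_protein_units: float
    lu_replaced: float
    lu_final: float


@dataclass(frozen=True)
class ScenarioResult:
    """All rows of one scenario plus column totals (m² per capita-year)."""

    rate: float
    rows: tuple[ScenarioRow, ...]
    total_initial: float
    total_replaced: float
    total_final: float
    per_capita_saving: float
    warnings: tuple[str, ...] = ()


def protein_units(consumption: float, protein_percent: float) -> float:
    """Protein consumed, counted in 100-g blocks: ``C · P / 10``.

    ``consumption`` is kg per person-year, ``protein_percent`` g/100 g.
    One unit is 100 g of protein, so kg of protein = units / 10.
    """
    if consumption < 0:
        raise DietShiftError(f"consumption must be >= 0, got {consumption}")
    if protein_percent < 0:
        raise DietShiftError(f"protein_percent must be >= 0, got {protein_percent}")
    return consumption * protein_percent / 10.0


def land_use_initial(item: FoodItem) -> float:
    """Land claimed by the animal-source protein: ``U · LU_animal`` (m²)."""
    return protein_units(item.consumption, item.protein_percent) * item.animal_intensity


def weighted_plant_intensity(mix: ReplacementMix) -> float:
    """Weighted land intensity of the mix: ``Σ w_i · LU_vegetal,i`` (m²/100 g)."""
    return sum(w * src.intensity for src, w in mix.components)


def land_use_replaced(item: FoodItem, spec: ScenarioSpec) -> float:
    """Land claimed by the plant mix replacing a fraction of the protein.

    ``U · R · Σ w_i · LU_vegetal,i`` — linear in the rate ``R``.
    """
    units = protein_units(item.consumption, item.protein_percent)
    return units * spec.rate * weighted_plant_intensity(spec.mix)


def land_use_final(item: FoodItem, spec: ScenarioSpec) -> float:
    """Remaining land use after substitution: initial minus replaced (m²)."""
    return land_use_initial(item) - land_use_replaced(item, spec)


def _scenario_row(item: FoodItem, spec: ScenarioSpec, mix_intensity: float) -> ScenarioRow:
    units = protein_units(item.consumption, item.protein_percent)
    lu_init = units * item.animal_intensity
    replaced_units = units * spec.rate
    lu_repl = replaced_units * mix_intensity
    return ScenarioRow(
        food=item.name,
        protein_units=units,
        lu_initial=lu_init,
        replaced_protein_units=replaced_units,
        lu_replaced=lu_repl,
        lu_final=lu_init - lu_repl,
    )


def run_scenario(basket: DietBasket, spec: ScenarioSpec) -> ScenarioResult:
    """Apply one replacement scenario to every food in the basket.

    Rows preserve basket order; totals are the column sums in that order.
    The per-capita saving equals the total replaced land only because
    ``final = initial − replaced`` holds row by row — both identities are
    maintained exactly, not merely to table rounding.
    """
    mix_intensity = weighted_plant_intensity(spec.mix)
    rows = tuple(_scenario_row(item, spec, mix_intensity) for item in basket)

    warnings: list[str] = []
    for item in basket:
        if mix_intensity > item.animal_intensity:
            warnings.append(
                f"{item.name}: plant mix intensity {mix_intensity:.4g} exceeds "
                f"animal intensity {item.animal_intensity:.4g}; substitution "
                f"increases land use for this food"
            )
    for msg in warnings:
        logger.warning(msg)

    total_initial = sum(r.lu_initial for r in rows)
    total_replaced = sum(r.lu_replaced for r in rows)
    total_final = total_initial - total_replaced
    result = ScenarioResult(
        rate=spec.rate,
        rows=rows,
        total_initial=total_initial,
        total_replaced=total_replaced,
        total_final=total_final,
        per_capita_saving=total_replaced,
        warnings=tuple(warnings),
    )
    logger.info(
        "scenario rate=%.4g total_initial=%.2f total_replaced=%.2f total_final=%.2f",
        spec.rate, total_initial, total_replaced, total_final,
    )
    return result


def scenario_sweep(
    basket: DietBasket, rates: Sequence[float], mix: ReplacementMix
) -> list[ScenarioResult]:
    """Run one scenario per rate, in the order given.

    All results share the same ``total_initial``; replaced land (and hence
    the saving) is linear in the rate.
    """
    if not rates:
        raise ValidationError("rate list must be nonempty")
    return [run_scenario(basket, ScenarioSpec(rate=r, mix=mix)) for r in rates]
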