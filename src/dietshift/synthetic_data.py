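"""Random baskets and mixes with the structural properties the model assumes.

The default parameter ranges span the envelope of the bundled Romanian
fixture: consumption 0.19–599.32 kg/yr (three orders of magnitude, so it is
drawn log-uniformly), protein 3.3–18.5 g/100 g, animal intensities
3.69–184.81 m²/100 g protein, and plant intensities 2.2–5.18 so that mixes
are cheaper in land than most animal sources.  A single seeded
:class:`numpy.random.Generator` is threaded through all draws; there is no
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .food_model import DietBasket, FoodItem, PlantSource, ReplacementMix

__all__ = ["SynthSpec", "generate_basket", "generate_mix", "known_answer_case"]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic basket/mix generator."""

    n_foods: int = 8
    consumption_range: tuple[float, float] = (0.19, 599.32)  # kg/yr, log-uniform
    protein_range: tuple[float, float] = (3.3, 18.5)  # g/100 g
    animal_intensity_range: tuple[float, float] = (3.69, 184.81)  # m²/100 g
    n_plant_sources: int = 3
    plant_intensity_range: tuple[float, float] = (2.2, 5.18)  # m²/100 g
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_foods < 1 or self.n_plant_sources < 1:
            raise ValidationError("counts must be >= 1")
        for label, (lo, hi) in (
            ("consumption_range", self.consumption_range),
            ("protein_range", self.protein_range),
            ("animal_intensity_range", self.animal_intensity_range),
            ("plant_intensity_range", self.plant_intensity_range),
        ):
            if not (0 < lo <= hi):
                raise ValidationError(f"{label} must be positive and ordered, got ({lo}, {hi})")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _draw_uniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    if lo == hi:  # degenerate range: all values identical
        return np.full(n, lo)
    return rng.uniform(lo, hi, n)


def generate_basket(spec: SynthSpec, rng: np.random.Generator | None = None) -> DietBasket:
    """Draw a random basket; deterministic for a fixed spec/seed.

    Consumption is log-uniform over its range so totals are not dominated
    by a uniform tail; protein content and animal intensity are uniform.
    """
    rng = spec.rng() if rng is None else rng
    lo, hi = spec.consumption_range
    if lo == hi:
        consumption = np.full(spec.n_foods, lo)
    else:
        consumption = np.exp(rng.uniform(np.log(lo), np.log(hi), spec.n_foods))
    protein = _draw_uniform(rng, *spec.protein_range, spec.n_foods)
    intensity = _draw_uniform(rng, *spec.animal_intensity_range, spec.n_foods)
    return DietBasket(
        tuple(
            FoodItem(
                name=f"food_{i:02d}",
                consumption=float(consumption[i]),
                protein_percent=float(protein[i]),
                animal_intensity=float(intensity[i]),
            )
            for i in range(spec.n_foods)
        )
    )


def generate_mix(spec: SynthSpec, rng: np.random.Generator | None = None) -> ReplacementMix:
    """Draw a random mix with weights from a symmetric Dirichlet simplex.

    The last weight is set to ``1 − Σ`` of the others so the sum is exact
    to the validator's 1e-9 tolerance (and in practice to 1e-12).
    """
    rng = spec.rng() if rng is None else rng
    k = spec.n_plant_sources
    weights = rng.dirichlet(np.ones(k))
    weights[-1] = 1.0 - float(weights[:-1].sum())
    intensities = _draw_uniform(rng, *spec.plant_intensity_range, k)
    return ReplacementMix(
        tuple(
            (PlantSource(f"plant_{i:02d}", float(intensities[i])), float(weights[i]))
            for i in range(k)
        )
    )


def known_answer_case():
    """A one-item micro-case whose scenario outcome is hand-computable.

    Basket: one food with consumption 10 kg/yr, 10 g protein/100 g and
    animal intensity 5 — hence 10 protein units and 50 m² initial land.
    Mix: a single plant source of intensity 2.  Expected per-rate outcomes
    (initial, replaced, final) in m²:

    * rate 0.0 → (50, 0, 50)
    * rate 0.5 → (50, 10, 40)
    * rate 1.0 → (50, 20, 30)

    Returns ``(basket, mix, expected)`` with ``expected`` mapping rate to
    the triple above.
    """
    basket = DietBasket((FoodItem("micro_food", 10.0, 10.0, 5.0),))
    mix = ReplacementMix(((PlantSource("micro_plant", 2.0), 1.0),))
    expected = {
        0.0: (50.0, 0.0, 50.0),
        0.5: (50.0, 10.0, 40.0),
        1.0: (50.0, 20.0, 30.0),
    }
    return basket, mix, expected
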