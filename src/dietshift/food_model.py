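"""Domain types for food-basket land-use accounting.

The model works in three quantities per animal-source food:

* ``consumption`` — annual per-capita consumption of the product, kg;
* ``protein_percent`` — grams of protein per 100 g of product;
* ``animal_intensity`` — agricultural land needed to produce 100 g of
  protein from that food, m².

A :class:`ReplacementMix` is a convex combination of plant protein sources,
each with its own land intensity per 100 g protein.  The bundled fixture is
the Romanian 2021 consumption basket (eight aggregate categories, with
processed derivatives folded into their parent category) together with the
50/30/20 soy–pea–potato replacement mix and the adult resident population.
"""

from __future__ import annotations

import csv
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from importlib import resources

from .errors import (
    DegenerateCalibrationError,
    InfeasibleCalibrationError,
    ValidationError,
)

__all__ = [
    "FoodItem",
    "PlantSource",
    "ReplacementMix",
    "DietBasket",
    "PopulationProfile",
    "ReferenceArea",
    "load_romania_fixture",
    "calibrate_source_intensity",
    "WEIGHT_SUM_TOL",
]

#: Tolerance on Σw_i = 1 for a validated mix.
WEIGHT_SUM_TOL = 1e-9


@dataclass(frozen=True)
class FoodItem:
    """One animal-source food category of the per-capita basket."""

    name: str
    consumption: float  # kg per person per year
    protein_percent: float  # g protein per 100 g product
    animal_intensity: float  # m² per 100 g protein

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("food item name must be nonempty")
        if self.consumption < 0:
            raise ValidationError(
                f"{self.name}: consumption must be >= 0, got {self.consumption}"
            )
        if not 0 < self.protein_percent <= 100:
            raise ValidationError(
                f"{self.name}: protein_percent must be in (0, 100], "
                f"got {self.protein_percent}"
            )
        if self.animal_intensity < 0:
            raise ValidationError(
                f"{self.name}: animal_intensity must be >= 0, "
                f"got {self.animal_intensity}"
            )


@dataclass(frozen=True)
class PlantSource:
    """A plant protein source with its land intensity (m² per 100 g protein)."""

    name: str
    intensity: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("plant source name must be nonempty")
        if self.intensity <= 0:
            raise ValidationError(
                f"{self.name}: plant intensity must be > 0, got {self.intensity}"
            )


@dataclass(frozen=True)
class ReplacementMix:
    """An ordered, weighted set of plant sources; weights sum to 1."""

    components: tuple[tuple[PlantSource, float], ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValidationError("replacement mix must have at least one component")
        names = [src.name for src, _ in self.components]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate plant source names in mix: {names}")
        for src, w in self.components:
            if w <= 0:
                raise ValidationError(f"{src.name}: mix weight must be > 0, got {w}")
        total = sum(w for _, w in self.components)
        if abs(total - 1.0) > WEIGHT_SUM_TOL:
            raise ValidationError(
                f"mix weights must sum to 1 within {WEIGHT_SUM_TOL}, got {total!r}"
            )

    @classmethod
    def from_triples(
        cls, triples: Sequence[tuple[str, float, float]]
    ) -> "ReplacementMix":
        """Build a mix from ``(name, weight, intensity)`` triples."""
        return cls(
            tuple((PlantSource(name, inten), w) for name, w, inten in triples)
        )

    @property
    def weights(self) -> tuple[float, ...]:
        return tuple(w for _, w in self.components)

    @property
    def intensities(self) -> tuple[float, ...]:
        return tuple(src.intensity for src, _ in self.components)


@dataclass(frozen=True)
class DietBasket:
    """An ordered collection of uniquely named food items."""

    items: tuple[FoodItem, ...]

    def __post_init__(self) -> None:
        if not self.items:
            raise ValidationError("diet basket must be nonempty")
        names = [item.name for item in self.items]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate food names in basket: {names}")

    def __iter__(self):
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, name: str) -> FoodItem:
        for item in self.items:
            if item.name == name:
                return item
        raise KeyError(name)


@dataclass(frozen=True)
class PopulationProfile:
    """Resident population counts used for national extrapolation."""

    total: int
    adult: int  # 18 to >85 years old

    def __post_init__(self) -> None:
        if not 0 < self.adult <= self.total:
            raise ValidationError(
                f"adult population must satisfy 0 < adult <= total, "
                f"got adult={self.adult}, total={self.total}"
            )


@dataclass(frozen=True)
class ReferenceArea:
    """A named hectare benchmark (e.g. a county's utilized agricultural area)."""

    name: str
    hectares: float

    def __post_init__(self) -> None:
        if self.hectares <= 0:
            raise ValidationError(
                f"{self.name}: reference area must be > 0 ha, got {self.hectares}"
            )


# --------------------------------------------------------------------------
# Bundled Romania-2021 fixture
# --------------------------------------------------------------------------

_ROMANIA_POPULATION = PopulationProfile(total=19_053_815, adult=14_940_830)

_ROMANIA_REFERENCE_AREAS = (
    ReferenceArea("Ilfov County UAA", 61_987.41),
    ReferenceArea("Galati County UAA", 332_030.23),
    ReferenceArea("Arad + Timis Counties UAA", 1_113_352.75),
)


def _read_fixture_csv(filename: str) -> list[dict[str, str]]:
    text = resources.files("dietshift.data").joinpath(filename).read_text("utf-8")
    return list(csv.DictReader(text.splitlines()))


def load_romania_fixture() -> tuple[
    DietBasket, ReplacementMix, PopulationProfile, list[ReferenceArea]
]:
    """Return the bundled Romanian 2021 study inputs.

    The basket holds the eight aggregate animal-source categories with 2021
    per-capita consumption, protein content and land intensity.  The mix is
    50% soy, 30% peas, 20% potatoes with intensities 2.2 / 3.36 / 5.18 m²
    per 100 g protein (weighted intensity 3.144).  The population profile is
    the 2021 resident population; national scaling conventionally uses the
    adult count (14,940,830).
    """
    basket_rows = _read_fixture_csv("romania_2021_basket.csv")
    basket = DietBasket(
        tuple(
            FoodItem(
                name=row["name"],
                consumption=float(row["consumption_kg_per_capita_year"]),
                protein_percent=float(row["protein_g_per_100g"]),
                animal_intensity=float(row["land_m2_per_100g_protein"]),
            )
            for row in basket_rows
        )
    )
    mix_rows = _read_fixture_csv("romania_2021_mix.csv")
    mix = ReplacementMix.from_triples(
        [
            (row["name"], float(row["weight"]), float(row["land_m2_per_100g_protein"]))
            for row in mix_rows
        ]
    )
    return basket, mix, _ROMANIA_POPULATION, list(_ROMANIA_REFERENCE_AREAS)


# --------------------------------------------------------------------------
# Mix calibration
# --------------------------------------------------------------------------


def calibrate_source_intensity(
    mix_weights: Sequence[float],
    known_intensities: Sequence[float | None] | Mapping[int, float],
    target_weighted: float,
) -> float:
    """Back-solve the land intensity of one unknown plant source.

    Given mix weights ``w_i`` (summing to 1), the intensities of all sources
    but one, and a target weighted intensity ``T``, return the unique ``x``
    with ``Σ w_i·LU_i = T``.  Useful when a mix's aggregate intensity is
    known (e.g. recoverable from published scenario tables) but one
    component's value is not.

    ``known_intensities`` is either a sequence aligned with ``mix_weights``
    in which exactly one entry is ``None``, or a mapping from index to
    intensity covering all but one index.
    """
    weights = list(mix_weights)
    if isinstance(known_intensities, Mapping):
        known: list[float | None] = [
            known_intensities.get(i) for i in range(len(weights))
        ]
    else:
        known = list(known_intensities)
    if len(known) != len(weights):
        raise ValidationError(
            f"known_intensities length {len(known)} does not match "
            f"{len(weights)} weights"
        )
    unknown = [i for i, v in enumerate(known) if v is None]
    if len(unknown) != 1:
        raise ValidationError(
            f"exactly one unknown intensity required, got {len(unknown)}"
        )
    idx = unknown[0]
    if weights[idx] == 0:
        raise DegenerateCalibrationError(
            "unknown source has zero weight; its intensity is unidentifiable"
        )
    partial = sum(w * v for w, v in zip(weights, known) if v is not None)
    solution = (target_weighted - partial) / weights[idx]
    if solution < 0:
        raise InfeasibleCalibrationError(
            f"calibrated intensity is negative ({solution:.6g}); the target "
            f"weighted intensity {target_weighted} is unreachable with the "
            f"given known intensities"
        )
    return solution
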