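"""Food-type taxonomy, scat correction factors, and per-macronutrient energy values.

Food items are grouped into nine types: above-ground vegetation (AGVEG:
foliage, stems, flowers), below-ground vegetation (BGVEG: roots, tubers,
corms), cambium, fruit, nut, fungi, insect, and vertebrates split into small
and large. Small and large vertebrates carry different digestibility
corrections but are reported jointly as "vertebrate" in summaries and
clustering. Fungi contribute to daily energy totals but are excluded from
the clustering variables because their energy share is negligible.

Digestible energy is accounted per macronutrient with Atwater specific
factors, i.e. food-type-specific kcal/g values for protein, carbohydrate and
lipid, rather than the general 4/4/9 factors.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

MACRONUTRIENTS = ("protein", "carbohydrate", "lipid")

#: Columns used as active variables in diet typing: fungi excluded,
#: vertebrates merged.
CLUSTER_VARIABLES = (
    "agveg",
    "bgveg",
    "cambium",
    "fruit",
    "nut",
    "insect",
    "vertebrate",
)


class FoodType(str, enum.Enum):
    """The nine food types used for digestion correction and energy accounting."""

    AGVEG = "agveg"
    BGVEG = "bgveg"
    CAMBIUM = "cambium"
    FRUIT = "fruit"
    NUT = "nut"
    FUNGI = "fungi"
    INSECT = "insect"
    VERT_SMALL = "vert_small"
    VERT_LARGE = "vert_large"

    @property
    def in_clustering(self) -> bool:
        """Whether this type feeds the diet-typing variables (fungi do not)."""
        return self is not FoodType.FUNGI

    @property
    def merged_name(self) -> str:
        """Reporting name; small and large vertebrates merge to ``vertebrate``."""
        if self in (FoodType.VERT_SMALL, FoodType.VERT_LARGE):
            return "vertebrate"
        return self.value

    @classmethod
    def parse(cls, value: str) -> "FoodType":
        key = str(value).strip().lower().replace(" ", "_").replace("(", "").replace(")", "")
        aliases = {
            "vertebrate_small": "vert_small",
            "vertebrate_large": "vert_large",
            "above_ground_vegetation": "agveg",
            "below_ground_vegetation": "bgveg",
        }
        key = aliases.get(key, key)
        try:
            return cls(key)
        except ValueError:
            raise ValueError(f"unknown food type: {value!r}") from None


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("beardiet").joinpath("fixtures", name)))


def load_food_type_factors() -> pd.DataFrame:
    """Packaged scat correction factors and energy values, indexed by food type."""
    df = pd.read_csv(_fixture_path("food_type_factors.csv"))
    df["food_type"] = df["food_type"].map(FoodType.parse)
    return df.set_index("food_type")


@dataclass(frozen=True)
class EnergyFactors:
    """Per-food-type Atwater specific factors (kcal per gram of macronutrient)."""

    values: Mapping[FoodType, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ft, triple in self.values.items():
            if len(triple) != 3:
                raise ValueError(f"{ft}: expected (protein, carbohydrate, lipid)")
            if any(v <= 0 for v in triple):
                raise ValueError(f"{ft}: energy factors must be strictly positive")

    def factor(self, food_type: FoodType, nutrient: str) -> float:
        return self.values[food_type][MACRONUTRIENTS.index(nutrient)]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EnergyFactors":
        vals = {
            ft: (
                float(row["protein_kcal_per_g"]),
                float(row["carbohydrate_kcal_per_g"]),
                float(row["lipid_kcal_per_g"]),
            )
            for ft, row in df.iterrows()
        }
        return cls(vals)

    @classmethod
    def default(cls) -> "EnergyFactors":
        return cls.from_frame(load_food_type_factors())

    @classmethod
    def from_csv(cls, path) -> "EnergyFactors":
        df = pd.read_csv(path)
        df["food_type"] = df["food_type"].map(FoodType.parse)
        return cls.from_frame(df.set_index("food_type"))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "food_type": ft.value,
                "protein_kcal_per_g": p,
                "carbohydrate_kcal_per_g": c,
                "lipid_kcal_per_g": l,
            }
            for ft, (p, c, l) in self.values.items()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_correction_factors() -> dict[FoodType, float]:
    """Scat correction factors: multipliers converting fecal to dietary volume."""
    t1 = load_food_type_factors()
    return {ft: float(row["scat_correction_factor"]) for ft, row in t1.iterrows()}
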