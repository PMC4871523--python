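import numpy as np
import pandas as pd
import pytest

from beardiet.composition import CompositionDB, FoodComposition
from beardiet.foods import EnergyFactors, FoodType, default_correction_factors

MEASURED = {c: "measured" for c in ("protein", "carbohydrate", "lipid", "nondigestible")}


def make_comp(taxon, food_type, protein=0.0, carbohydrate=0.0, lipid=0.0,
              nondigestible=0.0, moisture=0.0):
    return FoodComposition(
        taxon=taxon,
        food_type=food_type,
        fresh_protein=protein,
        fresh_carbohydrate=carbohydrate,
        fresh_lipid=lipid,
        fresh_nondigestible=nondigestible,
        moisture=moisture,
        provenance=dict(MEASURED),
    )


@pytest.fixture(scope="session")
def energy_factors():
    return EnergyFactors.default()


@pytest.fixture(scope="session")
def correction():
    return default_correction_factors()


@pytest.fixture()
def simple_db():
    """A tiny hand-built database: one food per a few types."""
    return CompositionDB(
        [
            make_comp("pure_insect", FoodType.INSECT, protein=1.0),
            make_comp("elk", FoodType.VERT_LARGE, protein=0.20, lipid=0.05,
                      nondigestible=0.05, moisture=0.70),
            make_comp("berry", FoodType.FRUIT, carbohydrate=0.30, protein=0.02,
                      nondigestible=0.18, moisture=0.50),
            make_comp("grass", FoodType.AGVEG, protein=0.06, carbohydrate=0.16,
                      lipid=0.01, nondigestible=0.17, moisture=0.60),
            make_comp("mushroom", FoodType.FUNGI, protein=0.02, carbohydrate=0.05,
                      nondigestible=0.03, moisture=0.90),
        ]
    )
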