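"""Food-composition database: loading, imputation, basis conversion, energy."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beardiet.composition import (
    CompositionDB,
    PartialComposition,
    dry_to_fresh,
    energy_density,
    fresh_to_dry,
    impute_composition,
    load_composition_db,
)
from beardiet.foods import EnergyFactors, FoodType, load_food_type_factors

from conftest import make_comp

CSV_HEADER = "taxon,food_type,basis,protein,carbohydrate,lipid,nondigestible,moisture,source\n"


def _db(rows: str) -> CompositionDB:
    return load_composition_db(io.StringIO(CSV_HEADER + rows))


class TestFoodType:
    def test_nine_members_vertebrates_split(self):
        assert len(FoodType) == 9
        assert FoodType.VERT_SMALL.merged_name == FoodType.VERT_LARGE.merged_name == "vertebrate"

    def test_fungi_excluded_from_clustering_only(self):
        assert not FoodType.FUNGI.in_clustering
        assert sum(ft.in_clustering for ft in FoodType) == 8


class TestLoad:
    def test_single_fully_specified_taxon(self):
        db = _db("ant,insect,dry,0.5,0.2,0.2,0.1,0.4,x\n")
        assert len(db) == 1
        rec = db["ant"]
        assert set(rec.provenance.values()) == {"measured"}
        assert rec.fresh_protein == pytest.approx(0.5 * 0.6)

    def test_duplicate_taxon_rejected(self):
        with pytest.raises(ValueError, match="duplicate taxon: ant"):
            _db("ant,insect,dry,0.5,0.2,0.2,0.1,0.4,x\nant,insect,dry,0.5,0.2,0.2,0.1,0.4,y\n")

    def test_unknown_food_type_rejected(self):
        with pytest.raises(ValueError, match="unknown food type"):
            _db("ant,bugs,dry,0.5,0.2,0.2,0.1,0.4,x\n")

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="protein"):
            _db("ant,insect,dry,1.5,0.2,0.2,0.1,0.4,x\n")

    def test_load_is_order_independent(self):
        rows = [
            "full1,fruit,dry,0.10,0.20,0.05,0.30,0.5,a\n",
            "full2,fruit,dry,0.20,0.40,0.15,0.20,0.5,b\n",
            "partial,fruit,dry,0.12,,,,0.5,c\n",
        ]
        a = _db("".join(rows))
        b = _db("".join(reversed(rows)))
        for taxon in a.taxa():
            assert a[taxon].fresh_fractions == b[taxon].fresh_fractions

    def test_type_mean_fresh_energy_matches_published_table(self, energy_factors):
        """The packaged synthetic type means reproduce the published per-type
        mean total energy on both bases, at the table's printed precision."""
        from beardiet.foods import _fixture_path

        db = load_composition_db(_fixture_path("type_means_synthetic.csv"))
        t1 = load_food_type_factors()
        for ft in FoodType:
            rec = db[f"unidentified_{ft.value}"]
            assert energy_density(rec, energy_factors, "fresh") == pytest.approx(
                t1.loc[ft, "fresh_energy_kcal_per_g"], abs=5e-3
            )
            assert energy_density(rec, energy_factors, "dry") == pytest.approx(
                t1.loc[ft, "dry_energy_kcal_per_g"], abs=5e-3
            )


class TestImputation:
    REFS = [
        PartialComposition(
            "full1", FoodType.FRUIT,
            {"protein": 0.10, "carbohydrate": 0.20, "lipid": 0.05, "nondigestible": 0.30},
            0.5,
        ),
        PartialComposition(
            "full2", FoodType.FRUIT,
            {"protein": 0.20, "carbohydrate": 0.40, "lipid": 0.15, "nondigestible": 0.20},
            0.5,
        ),
    ]

    def test_complete_record_unchanged(self):
        rec = impute_composition(self.REFS[0], self.REFS)
        assert rec.dry_fractions["protein"] == pytest.approx(0.10)
        assert set(rec.provenance.values()) == {"measured"}

    def test_ratio_rule_fills_from_reference_means(self):
        # reference mean carbohydrate:protein is (0.3):(0.15) = 2:1
        partial = PartialComposition(
            "p", FoodType.FRUIT,
            {"protein": 0.12, "carbohydrate": None, "lipid": None, "nondigestible": None},
            0.5,
        )
        rec = impute_composition(partial, self.REFS)
        dry = rec.dry_fractions
        assert dry["carbohydrate"] == pytest.approx(0.24)
        assert dry["lipid"] == pytest.approx(0.10 * 0.12 / 0.15)
        assert rec.provenance["protein"] == "measured"
        assert rec.provenance["carbohydrate"] == "imputed_from_similar"

    def test_empty_record_takes_type_means(self):
        partial = PartialComposition(
            "p", FoodType.FRUIT,
            {"protein": None, "carbohydrate": None, "lipid": None, "nondigestible": None},
            None,
        )
        rec = impute_composition(partial, self.REFS)
        dry = rec.dry_fractions
        assert dry["protein"] == pytest.approx(0.15)
        assert dry["carbohydrate"] == pytest.approx(0.30)
        assert rec.moisture == pytest.approx(0.5)
        assert set(rec.provenance.values()) == {"type_mean"}

    def test_imputation_is_idempotent(self):
        partial = PartialComposition(
            "p", FoodType.FRUIT,
            {"protein": 0.12, "carbohydrate": None, "lipid": None, "nondigestible": None},
            0.5,
        )
        once = impute_composition(partial, self.REFS)
        again = impute_composition(
            PartialComposition("p", FoodType.FRUIT, once.dry_fractions, once.moisture),
            self.REFS,
        )
        assert once.fresh_fractions == pytest.approx(again.fresh_fractions)

    def test_overflow_shrinks_imputed_not_measured(self):
        refs = [
            PartialComposition(
                "r", FoodType.NUT,
                {"protein": 0.05, "carbohydrate": 0.15, "lipid": 0.60, "nondigestible": 0.20},
                0.1,
            )
        ] * 2
        partial = PartialComposition(
            "p", FoodType.NUT,
            {"protein": 0.80, "carbohydrate": None, "lipid": None, "nondigestible": None},
            0.1,
        )
        rec = impute_composition(partial, refs)
        dry = rec.dry_fractions
        assert dry["protein"] == pytest.approx(0.80)  # measured untouched
        assert sum(dry.values()) == pytest.approx(1.0)

    def test_no_references_raises(self):
        partial = PartialComposition(
            "p", FoodType.CAMBIUM,
            {"protein": None, "carbohydrate": None, "lipid": None, "nondigestible": None},
            None,
        )
        with pytest.raises(ValueError, match="cannot impute"):
            impute_composition(partial, [])


class TestBasisConversion:
    def test_zero_moisture_is_identity(self):
        dry = {"protein": 0.4, "carbohydrate": 0.3, "lipid": 0.1, "nondigestible": 0.2}
        assert dry_to_fresh(dry, 0.0) == dry

    def test_hand_value(self):
        assert dry_to_fresh({"protein": 0.4}, 0.5)["protein"] == pytest.approx(0.2)

    def test_moisture_one_rejected(self):
        with pytest.raises(ValueError):
            dry_to_fresh({"protein": 0.4}, 1.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        p=st.floats(0, 0.5), c=st.floats(0, 0.3), m=st.floats(0, 0.99),
    )
    def test_round_trip(self, p, c, m):
        dry = {"protein": p, "carbohydrate": c}
        back = fresh_to_dry(dry_to_fresh(dry, m), m)
        assert back["protein"] == pytest.approx(p, abs=1e-9)
        assert back["carbohydrate"] == pytest.approx(c, abs=1e-9)


class TestEnergyDensity:
    def test_zero_composition(self, energy_factors):
        comp = make_comp("nothing", FoodType.FRUIT)
        assert energy_density(comp, energy_factors) == 0.0

    def test_hand_value_large_vertebrate(self, energy_factors):
        comp = make_comp("elk", FoodType.VERT_LARGE, protein=0.20, lipid=0.05,
                         nondigestible=0.05, moisture=0.70)
        assert energy_density(comp, energy_factors) == pytest.approx(1.3055)

    def test_pure_protein_insect_matches_specific_factor(self, energy_factors):
        comp = make_comp("ant", FoodType.INSECT, protein=1.0)
        assert energy_density(comp, energy_factors) == pytest.approx(4.27)

    @settings(derandomize=True, max_examples=30)
    @given(a=st.floats(0, 1))
    def test_linearity_in_composition(self, a, energy_factors):
        c1 = dict(protein=0.3, carbohydrate=0.1, lipid=0.05, nondigestible=0.2, moisture=0.3)
        c2 = dict(protein=0.1, carbohydrate=0.4, lipid=0.02, nondigestible=0.1, moisture=0.3)
        mix = {k: a * c1[k] + (1 - a) * c2[k] for k in c1}
        d = energy_density(make_comp("m", FoodType.FRUIT, **mix), energy_factors)
        d1 = energy_density(make_comp("a", FoodType.FRUIT, **c1), energy_factors)
        d2 = energy_density(make_comp("b", FoodType.FRUIT, **c2), energy_factors)
        assert d == pytest.approx(a * d1 + (1 - a) * d2, abs=1e-12)


def test_energy_factors_round_trip_bit_exact(tmp_path, energy_factors):
    path = tmp_path / "factors.csv"
    energy_factors.to_csv(path)
    back = EnergyFactors.from_csv(path)
    assert back.values == energy_factors.values
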