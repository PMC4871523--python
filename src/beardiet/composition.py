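"""Food-composition database: nutrient fractions per taxon, imputation, energy density.

Each taxon (genus or higher group) carries digestible protein, carbohydrate
and lipid fractions, a non-digestible fraction (ash, fiber), and moisture,
all stored on a fresh-matter basis. The dry basis is a derived view:
``dry = fresh / (1 - moisture)``. Published composition data are frequently
incomplete, so records loaded with missing constituents are imputed from
fully specified records of the same food type:

* missing constituents are scaled from the type's mean constituent profile
  so that their ratio to the constituents actually measured matches the
  reference mean ratios (provenance ``imputed_from_similar``);
* records with no measured constituents take the type means outright
  (provenance ``type_mean``);
* missing moisture takes the mean moisture of same-type records.

Ratios are formed on the dry basis, before moisture dilution, so that water
content does not leak into relative macronutrient structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .foods import MACRONUTRIENTS, EnergyFactors, FoodType

CONSTITUENTS = ("protein", "carbohydrate", "lipid", "nondigestible")
PROVENANCE_LEVELS = ("measured", "imputed_from_similar", "type_mean")
_SUM_TOL = 1e-6

#: Taxon-key prefix reserved for items identified only to food type.
UNIDENTIFIED_PREFIX = "unidentified_"


@dataclass(frozen=True)
class FoodComposition:
    """Fresh-basis composition of one taxon, with per-constituent provenance."""

    taxon: str
    food_type: FoodType
    fresh_protein: float
    fresh_carbohydrate: float
    fresh_lipid: float
    fresh_nondigestible: float
    moisture: float
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        fracs = dict(self.fresh_fractions)
        fracs["moisture"] = self.moisture
        for name, v in fracs.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.taxon}: {name} fraction {v} outside [0, 1]")
        if self.moisture >= 1.0:
            raise ValueError(f"{self.taxon}: moisture must be < 1")
        total = sum(fracs.values())
        if total > 1.0 + _SUM_TOL:
            raise ValueError(
                f"{self.taxon}: constituent fractions + moisture sum to {total:.6f} > 1"
            )
        prov = dict(self.provenance)
        for c in CONSTITUENTS:
            flag = prov.get(c)
            if flag not in PROVENANCE_LEVELS:
                raise ValueError(f"{self.taxon}: constituent {c} needs one provenance flag")
        object.__setattr__(self, "provenance", prov)

    @property
    def fresh_fractions(self) -> dict[str, float]:
        return {
            "protein": self.fresh_protein,
            "carbohydrate": self.fresh_carbohydrate,
            "lipid": self.fresh_lipid,
            "nondigestible": self.fresh_nondigestible,
        }

    @property
    def dry_fractions(self) -> dict[str, float]:
        return fresh_to_dry(self.fresh_fractions, self.moisture)


def dry_to_fresh(dry: Mapping[str, float], moisture: float) -> dict[str, float]:
    """Dilute dry-matter fractions by moisture: ``fresh = dry * (1 - moisture)``."""
    if not (0.0 <= moisture < 1.0):
        raise ValueError(f"moisture {moisture} outside [0, 1)")
    total = sum(dry.values())
    if total > 1.0 + _SUM_TOL:
        raise ValueError(f"dry fractions sum to {total:.6f} > 1")
    return {k: v * (1.0 - moisture) for k, v in dry.items()}

def fresh_to_dry(fresh: Mapping[str, float], moisture: float) -> dict[str, float]:
    """Inverse of :func:`dry_to_fresh`; exact to floating-point division."""
    if not (0.0 <= moisture < 1.0):
        raise ValueError(f"moisture {moisture} outside [0, 1)")
    return {k: v / (1.0 - moisture) for k, v in fresh.items()}


def energy_density(
    comp: FoodComposition, factors: EnergyFactors, basis: str = "fresh"
) -> float:
    """Digestible energy (kcal/g) of a food on the fresh or dry basis.

    The non-digestible fraction and moisture contribute nothing; the three
    macronutrient fractions are weighted by the food type's Atwater specific
    factors, so the result is linear in composition.
    """
    if basis == "fresh":
        fracs = comp.fresh_fractions
    elif basis == "dry":
        fracs = comp.dry_fractions
    else:
        raise ValueError(f"basis must be 'fresh' or 'dry', got {basis!r}")
    return sum(fracs[n] * factors.factor(comp.food_type, n) for n in MACRONUTRIENTS)


@dataclass
class PartialComposition:
    """A possibly incomplete record as read from a composition CSV (dry basis)."""

    taxon: str
    food_type: FoodType
    constituents: dict[str, Optional[float]]
    moisture: Optional[float]

    def present(self) -> list[str]:
        return [c for c in CONSTITUENTS if self.constituents.get(c) is not None]


class CompositionDB:
    """Mapping taxon -> :class:`FoodComposition` with type-level fallbacks.

    Items identified only to food type resolve through reserved keys
    ``unidentified_<type>`` which carry the type-mean composition.
    """

    def __init__(self, records: Iterable[FoodComposition]):
        self._records: dict[str, FoodComposition] = {}
        for rec in records:
            if rec.taxon in self._records:
                raise ValueError(f"duplicate taxon: {rec.taxon}")
            self._records[rec.taxon] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._records

    def __getitem__(self, taxon: str) -> FoodComposition:
        try:
            return self._records[taxon]
        except KeyError:
            raise KeyError(f"taxon not in composition database: {taxon!r}") from None

    def taxa(self) -> list[str]:
        return list(self._records)

    def food_type_of(self, taxon: str) -> FoodType:
        return self[taxon].food_type

    def records(self) -> list[FoodComposition]:
        return list(self._records.values())


def _type_reference(
    partials: list[PartialComposition], food_type: FoodType
) -> tuple[Optional[dict[str, float]], Optional[float]]:
    """Mean dry constituent vector over fully specified same-type records,
    and mean moisture over same-type records that report moisture."""
    full = [
        p.constituents
        for p in partials
        if p.food_type is food_type and len(p.present()) == len(CONSTITUENTS)
    ]
    mean_vec = None
    if full:
        mean_vec = {c: sum(f[c] for f in full) / len(full) for c in CONSTITUENTS}
    moists = [
        p.moisture for p in partials if p.food_type is food_type and p.moisture is not None
    ]
    mean_moist = sum(moists) / len(moists) if moists else None
    return mean_vec, mean_moist


def impute_composition(
    partial: PartialComposition, context: list[PartialComposition]
) -> FoodComposition:
    """Fill the missing constituents of one record from same-type references.

    Returns a fresh-basis :class:`FoodComposition`. If imputation pushes the
    dry constituent sum above 1, the imputed values (never the measured ones)
    are scaled down proportionally.
    """
    mean_vec, mean_moist = _type_reference(context, partial.food_type)
    present = partial.present()
    missing = [c for c in CONSTITUENTS if c not in present]

    values: dict[str, float] = {c: float(partial.constituents[c]) for c in present}
    provenance: dict[str, str] = {c: "measured" for c in present}

    if missing:
        if mean_vec is None:
            if not present:
                raise ValueError(
                    f"cannot impute {partial.taxon}: no reference records for "
                    f"food type {partial.food_type.value} and no measured constituents"
                )
            raise ValueError(
                f"cannot impute {partial.taxon}: no fully specified reference "
                f"records for food type {partial.food_type.value}"
            )
        if present:
            ref_present = sum(mean_vec[c] for c in present)
            if ref_present <= 0:
                raise ValueError(
                    f"cannot impute {partial.taxon}: reference mean for measured "
                    "constituents is zero"
                )
            scale = sum(values[c] for c in present) / ref_present
            for c in missing:
                values[c] = mean_vec[c] * scale
                provenance[c] = "imputed_from_similar"
        else:
            for c in missing:
                values[c] = mean_vec[c]
                provenance[c] = "type_mean"

    # Measured values are never altered: excess mass is removed from the
    # imputed constituents only.
    total = sum(values.values())
    if total > 1.0 + _SUM_TOL:
        measured_sum = sum(values[c] for c in present)
        imputed_sum = total - measured_sum
        if measured_sum > 1.0 + _SUM_TOL:
            raise ValueError(
                f"{partial.taxon}: measured dry fractions alone sum to {measured_sum:.6f} > 1"
            )
        if imputed_sum > 0:
            shrink = (1.0 - measured_sum) / imputed_sum
            for c in missing:
                values[c] *= shrink

    moisture = partial.moisture
    if moisture is None:
        if mean_moist is None:
            raise ValueError(
                f"cannot impute {partial.taxon}: no same-type moisture values"
            )
        moisture = mean_moist

    fresh = dry_to_fresh(values, moisture)
    return FoodComposition(
        taxon=partial.taxon,
        food_type=partial.food_type,
        fresh_protein=fresh["protein"],
        fresh_carbohydrate=fresh["carbohydrate"],
        fresh_lipid=fresh["lipid"],
        fresh_nondigestible=fresh["nondigestible"],
        moisture=moisture,
        provenance=provenance,
    )


_REQUIRED_COLUMNS = (
    "taxon",
    "food_type",
    "basis",
    "protein",
    "carbohydrate",
    "lipid",
    "nondigestible",
    "moisture",
)

_COLUMN_MAP = {
    "protein": "protein",
    "carbohydrate": "carbohydrate",
    "lipid": "lipid",
    "nondigestible": "nondigestible",
}


def load_composition_db(path, energy_factors: Optional[EnergyFactors] = None) -> CompositionDB:
    """Read a composition CSV and return an imputed database.

    The CSV carries one row per taxon with columns
    ``taxon, food_type, basis (fresh|dry), protein, carbohydrate, lipid,
    nondigestible, moisture, source``; empty cells are missing constituents.
    Loading is order-independent: imputation references are collected over
    the whole file before any record is filled.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"composition CSV missing columns: {missing_cols}")

    # Per-type mean moisture, needed up front to put fresh-basis rows that
    # lack a published moisture value onto the dry basis.
    type_moisture: dict[FoodType, float] = {}
    for ft_raw, grp in df.groupby("food_type"):
        vals = grp["moisture"].dropna().astype(float)
        if len(vals):
            type_moisture[FoodType.parse(ft_raw)] = float(vals.mean())

    partials: list[PartialComposition] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        taxon = str(row["taxon"]).strip()
        if taxon in seen:
            raise ValueError(f"duplicate taxon: {taxon}")
        seen.add(taxon)
        food_type = FoodType.parse(row["food_type"])
        basis = str(row["basis"]).strip().lower()
        if basis not in ("fresh", "dry"):
            raise ValueError(f"{taxon}: basis must be 'fresh' or 'dry', got {basis!r}")

        moisture = None if pd.isna(row["moisture"]) else float(row["moisture"])
        if moisture is not None and not (0.0 <= moisture < 1.0):
            raise ValueError(f"{taxon}: moisture {moisture} outside [0, 1)")

        cons: dict[str, Optional[float]] = {}
        for col, name in _COLUMN_MAP.items():
            v = row[col]
            if pd.isna(v):
                cons[name] = None
                continue
            v = float(v)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{taxon}: {name} fraction {v} outside [0, 1]")
            cons[name] = v

        if basis == "fresh":
            # Internal store and imputation ratios are on the dry basis.
            if moisture is None:
                moisture = type_moisture.get(food_type)
                if moisture is None:
                    raise ValueError(
                        f"{taxon}: fresh-basis row lacks moisture and no same-type "
                        "moisture values exist"
                    )
            cons = {
                k: (None if v is None else v / (1.0 - moisture)) for k, v in cons.items()
            }
        partials.append(PartialComposition(taxon, food_type, cons, moisture))

    records = [impute_composition(p, partials) for p in partials]
    return CompositionDB(records)
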