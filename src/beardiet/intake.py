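"""Per-bear-day intake: scat correction, scat equivalents, daily aggregation.

Percent fecal volume misstates percent dietary volume because foods digest
differentially: a bear-day of grass leaves far more residue per gram eaten
than a bear-day of elk. Each item's fecal volume is therefore multiplied by
its food type's scat correction factor (0.3 for above-ground vegetation up
to 2.0 for large vertebrates) and the scat renormalized, so every scat
contributes exactly one sample unit on the corrected scale.

Feeding signs observed at GPS-located sites enter the same scale through
scat equivalents: a light / moderate / heavy sign counts as 0.05 / 0.30 /
0.75 of one scat-unit of the signed food.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .foods import FoodType

#: Default scat-equivalent fractions per feeding-sign intensity class.
DEFAULT_SCAT_EQUIVALENTS: dict[str, float] = {
    "light": 0.05,
    "moderate": 0.30,
    "heavy": 0.75,
}

_PCT_SUM_TOL = 0.5


@dataclass(frozen=True)
class ScatRecord:
    """One scat: items as (taxon, percent fecal volume), summing to 100 ± 0.5."""

    bear_day_id: str
    items: tuple[tuple[str, float], ...]
    scat_id: str = ""

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError(f"scat {self.scat_id or self.bear_day_id}: no items")
        total = 0.0
        for taxon, pct in self.items:
            if not (0.0 < pct <= 100.0):
                raise ValueError(
                    f"scat {self.scat_id or self.bear_day_id}: percent fecal volume "
                    f"{pct} for {taxon} outside (0, 100]"
                )
            total += pct
        if abs(total - 100.0) > _PCT_SUM_TOL:
            raise ValueError(
                f"scat {self.scat_id or self.bear_day_id}: percent fecal volumes "
                f"sum to {total:.2f}, expected 100 ± {_PCT_SUM_TOL}"
            )


@dataclass(frozen=True)
class FeedingSign:
    """One feeding-sign observation with a three-level intensity class."""

    bear_day_id: str
    taxon: str
    intensity: str
    site_id: str = ""

    def __post_init__(self) -> None:
        if self.intensity not in DEFAULT_SCAT_EQUIVALENTS:
            raise ValueError(
                f"unknown feeding-sign intensity {self.intensity!r}; expected one of "
                f"{sorted(DEFAULT_SCAT_EQUIVALENTS)}"
            )


@dataclass(frozen=True)
class DailyIntake:
    """Consumed units per taxon for one bear-day, on the scat-unit scale."""

    bear_day_id: str
    units: Mapping[str, float]
    n_scats: int
    sample_count: float

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.units.values()):
            raise ValueError(f"{self.bear_day_id}: negative intake units")
        if abs(sum(self.units.values()) - self.sample_count) > 1e-9:
            raise ValueError(
                f"{self.bear_day_id}: units sum {sum(self.units.values())} != "
                f"sample_count {self.sample_count}"
            )

    @property
    def is_empty(self) -> bool:
        return self.sample_count == 0


def scat_equivalent(
    intensity: str, equivalents: Optional[Mapping[str, float]] = None
) -> float:
    """Fraction of one scat-unit assigned to a feeding sign of given intensity."""
    table = DEFAULT_SCAT_EQUIVALENTS if equivalents is None else equivalents
    try:
        return table[intensity]
    except KeyError:
        raise ValueError(
            f"unknown feeding-sign intensity {intensity!r}; expected one of "
            f"{sorted(table)}"
        ) from None


def correct_scat(
    scat: ScatRecord,
    factors: Mapping[FoodType, float],
    food_type_of: Callable[[str], FoodType],
) -> dict[str, float]:
    """Convert one scat's fecal volumes into dietary fractions of one scat-unit.

    Each item's percent fecal volume is multiplied by its food type's
    correction factor and the vector renormalized to sum to exactly 1, so the
    output is invariant to rescaling all factors by a common constant.
    Duplicate taxa within a scat are summed. Item order is preserved.
    """
    raw: dict[str, float] = {}
    for taxon, pct in scat.items:
        ft = food_type_of(taxon)
        if ft not in factors:
            raise ValueError(f"no scat correction factor for food type {ft.value!r}")
        if factors[ft] <= 0:
            raise ValueError(f"correction factor for {ft.value!r} must be > 0")
        raw[taxon] = raw.get(taxon, 0.0) + pct * factors[ft]
    total = sum(raw.values())
    return {taxon: v / total for taxon, v in raw.items()}


def aggregate_day(
    scats: Sequence[ScatRecord],
    signs: Sequence[FeedingSign],
    factors: Mapping[FoodType, float],
    food_type_of: Callable[[str], FoodType],
    equivalents: Optional[Mapping[str, float]] = None,
    bear_day_id: Optional[str] = None,
) -> DailyIntake:
    """Sum corrected scats and sign scat-equivalents into one bear-day's intake.

    Aggregation is additive over disjoint observation sets of the same day.
    Empty inputs yield an empty intake with ``sample_count`` 0 (the flagged
    zero-diet case, excluded downstream).
    """
    ids = {s.bear_day_id for s in scats} | {s.bear_day_id for s in signs}
    if len(ids) > 1:
        raise ValueError(f"observations span multiple bear-days: {sorted(ids)}")
    if bear_day_id is None:
        bear_day_id = ids.pop() if ids else ""

    units: dict[str, float] = {}
    for scat in scats:
        for taxon, frac in correct_scat(scat, factors, food_type_of).items():
            units[taxon] = units.get(taxon, 0.0) + frac
    equiv_total = 0.0
    for sign in signs:
        food_type_of(sign.taxon)  # raise early on unresolvable taxon
        eq = scat_equivalent(sign.intensity, equivalents)
        units[sign.taxon] = units.get(sign.taxon, 0.0) + eq
        equiv_total += eq

    return DailyIntake(
        bear_day_id=bear_day_id,
        units=units,
        n_scats=len(scats),
        sample_count=len(scats) + equiv_total,
    )
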