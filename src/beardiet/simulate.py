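"""Synthetic bears, bear-days, and observable scats/feeding signs with ground truth.

The generator emulates the field sampling design: GPS-collared bears of
three populations (grizzly, sympatric black, allopatric black) and both
sexes are followed over spring/summer/fall bear-days; each day has a true
diet drawn from a catalogue of diet types (food-type energy shares), and the
observable record of that day is a handful of scats and feeding signs.

Observations are distorted the way digestion distorts them: true dietary
fractions are *divided* by the food type's scat correction factor and
renormalized to give percent fecal volume, so the pipeline's correction step
is the exact algebraic inverse. Feeding-sign intensities are the class
(light/moderate/heavy) whose scat-equivalent (0.05/0.30/0.75) is nearest the
item's unit share of the day, and signs are allocated across taxa with
weights proportional to share / equivalent so that the expected equivalent
mass per taxon stays proportional to the true share — feeding sign is an
unbiased, if coarse, estimator of the day mix.

All randomness flows from one seed; identical seeds give identical tables.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .composition import CompositionDB, FoodComposition, dry_to_fresh
from .energy import SEASON_WINDOWS
from .foods import EnergyFactors, FoodType, _fixture_path, load_food_type_factors
from .intake import DEFAULT_SCAT_EQUIVALENTS

SPECIES = ("grizzly", "black_sympatric", "black_allopatric")
SEASONS = ("spring", "summer", "fall")
SEXES = ("F", "M")


def load_sampling_structure() -> pd.DataFrame:
    """Packaged sampling-structure fixture: bears, mass ranges, bear-day counts."""
    return pd.read_csv(_fixture_path("sampling_structure.csv"))


def load_diet_type_table() -> pd.DataFrame:
    """Packaged diet-type fixture: per-diet mean energy shares and day counts."""
    return pd.read_csv(_fixture_path("diet_type_catalogue.csv"))


def emit_fixture_tables(outdir) -> list[Path]:
    """Copy the packaged study-constant fixtures (bit-exact) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = [
        "food_type_factors.csv",
        "sampling_structure.csv",
        "diet_type_catalogue.csv",
        "type_means_synthetic.csv",
    ]
    out = []
    for name in names:
        dest = outdir / name
        shutil.copyfile(_fixture_path(name), dest)
        out.append(dest)
    return out


def _catalogue_from_diet_table(vert_large_share: float = 0.8) -> pd.DataFrame:
    """Diet catalogue over the 9 food types, rows normalized to sum to 100.

    Catalogue rows are printed to whole percent and sum to 99-101; they are
    renormalized exactly. The merged vertebrate share is split between large
    and small vertebrates (defaults 80/20, elk dominating the field record).
    """
    t3 = load_diet_type_table().set_index("diet_type")
    cat = pd.DataFrame(index=t3.index, columns=[ft.value for ft in FoodType], dtype=float)
    for merged in ("agveg", "bgveg", "cambium", "fruit", "nut", "insect"):
        cat[merged] = t3[f"{merged}_pct"].astype(float)
    cat["fungi"] = 0.0
    cat["vert_large"] = t3["vertebrate_pct"].astype(float) * vert_large_share
    cat["vert_small"] = t3["vertebrate_pct"].astype(float) * (1.0 - vert_large_share)
    cat = cat.div(cat.sum(axis=1), axis=0) * 100.0
    return cat


@dataclass
class GeneratorConfig:
    """Study conditions for the generator; defaults mirror the field study."""

    bear_counts: Mapping[tuple[str, str], int] = field(default_factory=dict)
    bear_day_counts: Mapping[tuple[str, str, str], int] = field(default_factory=dict)
    mass_ranges: Mapping[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    diet_catalogue: Optional[pd.DataFrame] = None     # diet_type x 9 food types, rows sum 100
    diet_probs: Optional[pd.DataFrame] = None         # (species,sex,season) x diet_type
    scats_per_day_mean: float = 2.6
    signs_per_day_mean: float = 8.2
    concentration: float = 7.0
    taxa_per_type: int = 3
    taxon_concentration: float = 300.0
    scat_equivalents: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SCAT_EQUIVALENTS)
    )
    correction_factors: Optional[Mapping[FoodType, float]] = None
    year: int = 2005

    def __post_init__(self) -> None:
        t2 = load_sampling_structure()
        if not self.bear_counts:
            self.bear_counts = {
                (r["species"], r["sex"]): int(r["n_individuals"]) for _, r in t2.iterrows()
            }
        if not self.bear_day_counts:
            self.bear_day_counts = {
                (r["species"], r["sex"], season): int(r[f"{season}_days"])
                for _, r in t2.iterrows()
                for season in SEASONS
            }
        if not self.mass_ranges:
            self.mass_ranges = {
                (r["species"], r["sex"]): (float(r["mass_min_kg"]), float(r["mass_max_kg"]))
                for _, r in t2.iterrows()
            }
        if self.diet_catalogue is None:
            self.diet_catalogue = _catalogue_from_diet_table()
        sums = self.diet_catalogue.sum(axis=1)
        if not np.allclose(sums, 100.0, atol=1e-6):
            raise ValueError("diet catalogue rows must sum to 100")
        if self.diet_probs is None:
            t3 = load_diet_type_table()
            marginal = t3.set_index("diet_type")["n_bear_days"] / t3["n_bear_days"].sum()
            cells = [
                (sp, sx, se) for sp in SPECIES for sx in SEXES for se in SEASONS
            ]
            self.diet_probs = pd.DataFrame(
                {dt: marginal[dt] for dt in marginal.index}, index=pd.MultiIndex.from_tuples(cells)
            )
        probs = self.diet_probs.sum(axis=1)
        if not np.allclose(probs, 1.0, atol=1e-9):
            raise ValueError("diet-type probabilities must sum to 1 per cell")
        if self.diet_catalogue.empty:
            raise ValueError("empty diet catalogue")
        if self.correction_factors is None:
            from .foods import default_correction_factors

            self.correction_factors = default_correction_factors()


@dataclass
class SimulatedData:
    """Generated observation tables plus the ground truth they were drawn from."""

    days: pd.DataFrame
    scats: pd.DataFrame
    signs: pd.DataFrame
    composition: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.days.to_csv(outdir / "days.csv", index=False)
        self.scats.to_csv(outdir / "scats.csv", index=False)
        self.signs.to_csv(outdir / "signs.csv", index=False)
        self.composition.to_csv(outdir / "composition.csv", index=False)
        self.truth.to_csv(outdir / "ground_truth.csv", index=False)


def _nearest_intensity(share: float, equivalents: Mapping[str, float]) -> str:
    return min(equivalents, key=lambda k: abs(equivalents[k] - share))


def _season_dates(year: int, season: str) -> tuple[pd.Timestamp, int]:
    (m0, d0), (m1, d1) = SEASON_WINDOWS[season]
    start = pd.Timestamp(year=year, month=m0, day=d0)
    end = pd.Timestamp(year=year, month=m1, day=d1)
    return start, (end - start).days + 1


def _make_taxa(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, CompositionDB]:
    """Synthetic taxon layer: a few taxa per food type around the type means."""
    means = pd.read_csv(_fixture_path("type_means_synthetic.csv")).set_index("food_type")
    rows = []
    for ft in FoodType:
        m = means.loc[ft.value]
        base = np.array(
            [m["protein"], m["carbohydrate"], m["lipid"], m["nondigestible"]], dtype=float
        )
        for i in range(config.taxa_per_type):
            vec = rng.dirichlet(base * config.taxon_concentration)
            moist = float(np.clip(rng.normal(m["moisture"], 0.02), 0.0, 0.97))
            rows.append(
                {
                    "taxon": f"{ft.value}_taxon_{i + 1}",
                    "food_type": ft.value,
                    "basis": "dry",
                    "protein": vec[0],
                    "carbohydrate": vec[1],
                    "lipid": vec[2],
                    "nondigestible": vec[3],
                    "moisture": moist,
                    "source": "synthetic",
                }
            )
        # reserved type-level key for items identified only to food type
        rows.append(
            {
                "taxon": f"unidentified_{ft.value}",
                "food_type": ft.value,
                "basis": "dry",
                "protein": float(m["protein"]),
                "carbohydrate": float(m["carbohydrate"]),
                "lipid": float(m["lipid"]),
                "nondigestible": float(m["nondigestible"]),
                "moisture": float(m["moisture"]),
                "source": "synthetic type mean",
            }
        )
    frame = pd.DataFrame(rows)
    records = []
    for _, r in frame.iterrows():
        dry = {
            "protein": r["protein"],
            "carbohydrate": r["carbohydrate"],
            "lipid": r["lipid"],
            "nondigestible": r["nondigestible"],
        }
        fresh = dry_to_fresh(dry, r["moisture"])
        records.append(
            FoodComposition(
                taxon=r["taxon"],
                food_type=FoodType.parse(r["food_type"]),
                fresh_protein=fresh["protein"],
                fresh_carbohydrate=fresh["carbohydrate"],
                fresh_lipid=fresh["lipid"],
                fresh_nondigestible=fresh["nondigestible"],
                moisture=float(r["moisture"]),
                provenance={c: "measured" for c in dry},
            )
        )
    return frame, CompositionDB(records)


def generate(config: GeneratorConfig, seed: int) -> SimulatedData:
    """Generate observation tables and ground truth for one synthetic study."""
    rng = np.random.default_rng(seed)
    factors = EnergyFactors.default()
    comp_frame, db = _make_taxa(config, rng)

    # Per-taxon fresh energy density, used to map energy shares to intake units.
    from .composition import energy_density

    density = {t: energy_density(db[t], factors, "fresh") for t in db.taxa()}
    type_taxa = {
        ft: [f"{ft.value}_taxon_{i + 1}" for i in range(config.taxa_per_type)]
        for ft in FoodType
    }

    # Bears.
    bears = []
    for (species, sex), n in sorted(config.bear_counts.items()):
        lo, hi = config.mass_ranges[(species, sex)]
        for i in range(n):
            fi_lo, fi_hi = (35, 95) if species == "grizzly" else (95, 190)
            bears.append(
                {
                    "bear_id": f"{species}_{sex}_{i + 1:02d}",
                    "species": species,
                    "sex": sex,
                    "body_mass_kg": float(np.round(rng.uniform(lo, hi), 1)),
                    "fix_interval_min": int(rng.integers(fi_lo, fi_hi + 1)),
                }
            )
    bears_by_cell: dict[tuple[str, str], list[dict]] = {}
    for b in bears:
        bears_by_cell.setdefault((b["species"], b["sex"]), []).append(b)

    cat = config.diet_catalogue
    cat_fracs = cat.to_numpy(dtype=float) / 100.0
    diet_names = list(cat.index)
    food_cols = [FoodType.parse(c) for c in cat.columns]

    day_rows, scat_rows, sign_rows, truth_rows = [], [], [], []
    day_counter = 0
    for (species, sex, season), n_days in sorted(config.bear_day_counts.items()):
        cell_bears = bears_by_cell.get((species, sex), [])
        if not cell_bears and n_days > 0:
            raise ValueError(f"no bears in cell {(species, sex)} but days requested")
        probs = config.diet_probs.loc[(species, sex, season)].to_numpy(dtype=float)
        start, span = _season_dates(config.year, season)
        for j in range(n_days):
            bear = cell_bears[j % len(cell_bears)]
            day_counter += 1
            bd_id = f"bd{day_counter:04d}"
            date = start + pd.Timedelta(days=int(rng.integers(0, span)))

            # (1) diet type, (2) jittered true energy shares on the simplex
            di = int(rng.choice(len(diet_names), p=probs))
            mean_frac = cat_fracs[di]
            pos = mean_frac > 0
            shares = np.zeros_like(mean_frac)
            shares[pos] = rng.dirichlet(mean_frac[pos] * config.concentration)

            # (3) energy shares -> taxa -> intake-unit fractions
            taxa: list[str] = []
            taxon_energy: list[float] = []
            for ft, s in zip(food_cols, shares):
                if s <= 0:
                    continue
                split = rng.dirichlet(np.full(config.taxa_per_type, 5.0))
                for t, w in zip(type_taxa[ft], split):
                    if w > 0:
                        taxa.append(t)
                        taxon_energy.append(s * w)
            e_arr = np.array(taxon_energy)
            units = e_arr / np.array([density[t] for t in taxa])
            f = units / units.sum()  # true dietary fractions (unit shares)

            # (4) observations
            n_scats = int(rng.poisson(config.scats_per_day_mean))
            n_signs = int(rng.poisson(config.signs_per_day_mean))
            cf = np.array(
                [config.correction_factors[db.food_type_of(t)] for t in taxa]
            )
            fecal = f / cf
            fecal = 100.0 * fecal / fecal.sum()
            for s_i in range(n_scats):
                for t, pct in zip(taxa, fecal):
                    scat_rows.append(
                        {
                            "bear_day_id": bd_id,
                            "scat_id": f"{bd_id}_s{s_i + 1}",
                            "taxon": t,
                            "percent_fecal_volume": pct,
                        }
                    )
            equivs = np.array(
                [config.scat_equivalents[_nearest_intensity(x, config.scat_equivalents)] for x in f]
            )
            w_sign = (f / equivs)
            w_sign = w_sign / w_sign.sum()
            counts = rng.multinomial(n_signs, w_sign)
            site = 0
            for t, x, c in zip(taxa, f, counts):
                label = _nearest_intensity(x, config.scat_equivalents)
                for _ in range(int(c)):
                    site += 1
                    sign_rows.append(
                        {
                            "bear_day_id": bd_id,
                            "site_id": f"{bd_id}_x{site}",
                            "taxon": t,
                            "intensity": label,
                        }
                    )

            # (5) ground truth
            merged: dict[str, float] = {}
            for ft, s in zip(food_cols, shares):
                merged[ft.merged_name] = merged.get(ft.merged_name, 0.0) + 100.0 * s
            macro = {"protein": 0.0, "carbohydrate": 0.0, "lipid": 0.0}
            for t, u in zip(taxa, f):
                comp = db[t]
                for n in macro:
                    macro[n] += u * comp.fresh_fractions[n] * factors.factor(comp.food_type, n)
            macro_total = sum(macro.values())
            truth_rows.append(
                {
                    "bear_day_id": bd_id,
                    "diet_type": diet_names[di],
                    **{f"true_{k}_pct": v for k, v in merged.items()},
                    "true_protein_pct": 100.0 * macro["protein"] / macro_total,
                    "true_carbohydrate_pct": 100.0 * macro["carbohydrate"] / macro_total,
                    "true_lipid_pct": 100.0 * macro["lipid"] / macro_total,
                    "true_units": ";".join(f"{t}:{u:.12g}" for t, u in zip(taxa, f)),
                    "n_scats": n_scats,
                    "n_signs": n_signs,
                    "observed": bool(n_scats + n_signs > 0),
                }
            )
            day_rows.append(
                {
                    "bear_day_id": bd_id,
                    "bear_id": bear["bear_id"],
                    "date": date.date().isoformat(),
                    "species": species,
                    "sex": sex,
                    "body_mass_kg": bear["body_mass_kg"],
                    "fix_interval_min": bear["fix_interval_min"],
                }
            )

    return SimulatedData(
        days=pd.DataFrame(day_rows),
        scats=pd.DataFrame(
            scat_rows,
            columns=["bear_day_id", "scat_id", "taxon", "percent_fecal_volume"],
        ),
        signs=pd.DataFrame(
            sign_rows, columns=["bear_day_id", "site_id", "taxon", "intensity"]
        ),
        composition=comp_frame,
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# Direct simulator for the protein mixed models (no observation layer).

DEFAULT_MASS_EFFECTS = {
    # intercept and %/kg slope per season; the fall slope corresponds to a
    # rise from 16% at 50 kg to 38% at 200 kg.
    "spring": (22.0, 0.030),
    "summer": (18.0, 0.000),
    "fall": (16.0 - 50.0 * (22.0 / 150.0), 22.0 / 150.0),
}


def simulate_protein_observations(
    n_bears: int = 40,
    days_per_season: int = 3,
    mass_effects: Mapping[str, tuple[float, float]] = None,
    group_effects: Optional[Mapping[tuple[str, str], float]] = None,
    re_sd: float = 4.0,
    resid_sd: float = 8.0,
    mass_range: tuple[float, float] = (44.0, 215.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Protein-share observations drawn directly from a known mixed model.

    Each bear gets a mass, a species-sex group label, a random intercept with
    standard deviation ``re_sd``, and ``days_per_season`` observations per
    season with residual standard deviation ``resid_sd``. The mean structure
    is ``intercept[season] + slope[season] * mass`` plus an optional additive
    group effect.
    """
    if mass_effects is None:
        mass_effects = DEFAULT_MASS_EFFECTS
    rng = np.random.default_rng(seed)
    groups = [(sp, sx) for sp in SPECIES for sx in SEXES]
    rows = []
    for b in range(n_bears):
        mass = float(rng.uniform(*mass_range))
        grp = groups[b % len(groups)]
        u = rng.normal(0.0, re_sd)
        for season in SEASONS:
            a, slope = mass_effects[season]
            for d in range(days_per_season):
                mu = a + slope * mass
                if group_effects is not None:
                    mu += group_effects.get(grp, 0.0)
                y = mu + u + rng.normal(0.0, resid_sd)
                rows.append(
                    {
                        "bear_id": f"bear{b + 1:03d}",
                        "season": season,
                        "group": f"{grp[0]}_{grp[1]}",
                        "body_mass_kg": mass,
                        "protein_pct": float(np.clip(y, 0.0, 100.0)),
                    }
                )
    return pd.DataFrame(rows)
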