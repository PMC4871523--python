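"""End-to-end orchestration: observations -> profiles -> diet types -> models."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .composition import CompositionDB, load_composition_db
from .diet_typing import associate, fit_diet_types, share_of_days
from .energy import (
    OptimalBand,
    classify_protein,
    profile_energy,
    profiles_to_frame,
    summarize_groups,
)
from .foods import EnergyFactors, default_correction_factors
from .intake import FeedingSign, ScatRecord, aggregate_day
from .protein_models import fit_protein_model, predict_group_means
from .readwrite import RunConfig, read_days, read_scats, read_signs

logger = logging.getLogger(__name__)


def build_profiles(
    scats: Sequence[ScatRecord],
    signs: Sequence[FeedingSign],
    days: pd.DataFrame,
    db: CompositionDB,
    factors: Optional[EnergyFactors] = None,
    correction_factors=None,
    scat_equivalents=None,
    band: OptimalBand = OptimalBand(),
) -> pd.DataFrame:
    """Aggregate observations per bear-day and profile digestible energy.

    Returns one row per bear-day listed in ``days`` (days without
    observations come back flagged ``empty``), with merged food-type percent
    columns, macronutrient percents, the protein class, and season.
    """
    if factors is None:
        factors = EnergyFactors.default()
    if correction_factors is None:
        correction_factors = default_correction_factors()
    scats_by_day: dict[str, list[ScatRecord]] = {}
    for s in scats:
        scats_by_day.setdefault(s.bear_day_id, []).append(s)
    signs_by_day: dict[str, list[FeedingSign]] = {}
    for s in signs:
        signs_by_day.setdefault(s.bear_day_id, []).append(s)

    profiles = []
    for bd_id in days["bear_day_id"].astype(str):
        intake = aggregate_day(
            scats_by_day.get(bd_id, []),
            signs_by_day.get(bd_id, []),
            correction_factors,
            db.food_type_of,
            equivalents=scat_equivalents,
            bear_day_id=bd_id,
        )
        profiles.append(profile_energy(intake, db, factors))

    frame = profiles_to_frame(profiles)
    frame["protein_class"] = [
        classify_protein(p, band) if not p.is_empty else "" for p in profiles
    ]
    frame = frame.merge(days[["bear_day_id", "season"]], on="bear_day_id", how="left")
    n_empty = int(frame["empty"].sum())
    if n_empty:
        logger.info("build_profiles: %d bear-day(s) without observations", n_empty)
    return frame


def run_all(config: RunConfig) -> Path:
    """Execute the full chain and write a report directory.

    Stages: read inputs -> composition database -> daily profiles -> diet
    typing -> associations -> group summaries -> protein models. Partial
    outputs are retained if a later stage fails.
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    band = OptimalBand(config.band_center, config.band_half_width)
    thresholds = {
        "dominance": config.dominance,
        "member_min": config.member_min,
        "mean_min": config.mean_min,
    }

    logger.info("run_all: loading inputs")
    days = read_days(config.days)
    scats = read_scats(config.scats)
    signs = read_signs(config.signs)
    db = load_composition_db(config.composition)
    logger.info(
        "run_all: %d bear-days, %d scats, %d signs, %d taxa",
        len(days), len(scats), len(signs), len(db),
    )

    logger.info("run_all: profiling daily energy")
    profiles = build_profiles(
        scats, signs, days, db,
        scat_equivalents=config.scat_equivalents, band=band,
    )
    profiles.to_csv(out / "profiles.csv", index=False)

    logger.info("run_all: diet typing")
    nonempty = profiles[~profiles["empty"]].reset_index(drop=True)
    model = fit_diet_types(
        nonempty, thresholds=thresholds, k_max=config.k_max, n_dims=config.n_dims
    )
    labels = model.labels_frame()
    labels.to_csv(out / "diet_types.csv", index=False)
    model.pca.loadings.to_csv(out / "pc_loadings.csv")

    meta = days.merge(labels, on="bear_day_id", how="right")
    assoc = associate(model.labels, meta, cluster_names=model.cluster_names)
    assoc.to_csv(out / "associations.csv", index=False)

    logger.info("run_all: group summaries")
    summary = summarize_groups(nonempty, days, grouping=("species", "season"))
    summary.to_csv(out / "group_summary.csv", index=False)
    class_by_diet = (
        nonempty.merge(labels, on="bear_day_id")
        .groupby("diet_type")
        .agg(
            n_days=("bear_day_id", "size"),
            mean_protein_pct=("protein_pct", "mean"),
            mean_carbohydrate_pct=("carbohydrate_pct", "mean"),
            mean_lipid_pct=("lipid_pct", "mean"),
        )
        .reset_index()
    )
    class_by_diet["protein_class"] = [
        classify_protein(v, band) for v in class_by_diet["mean_protein_pct"]
    ]
    class_by_diet.to_csv(out / "diet_type_macronutrients.csv", index=False)

    logger.info("run_all: protein models")
    model_data = nonempty.merge(
        days[["bear_day_id", "bear_id", "season", "group", "body_mass_kg"]],
        on="bear_day_id",
    ).rename(columns={"season_x": "season"})
    if "season_y" in model_data.columns:
        model_data = model_data.drop(columns=["season_y"])
    results = {}
    for kind in ("season_group", "season_mass"):
        fit = fit_protein_model(model_data, formula=kind)
        fit.anova.to_csv(out / f"model_{kind}_anova.csv", index=False)
        fit.summary_frame().to_csv(out / f"model_{kind}_effects.csv", index=False)
        if kind == "season_group":
            grid = (
                model_data[["season", "group"]].drop_duplicates().sort_values(
                    ["season", "group"]
                )
            )
        else:
            seasons = sorted(model_data["season"].unique())
            masses = [50.0, 100.0, 150.0, 200.0]
            grid = pd.DataFrame(
                [(s, m) for s in seasons for m in masses],
                columns=["season", "body_mass_kg"],
            )
        pred = predict_group_means(fit, grid)
        pred.to_csv(out / f"model_{kind}_predictions.csv", index=False)
        results[kind] = {
            "n_obs": fit.n_obs,
            "n_bears": fit.n_bears,
            "converged": fit.converged,
            "singular": fit.singular,
        }

    counts = model.counts()
    report = {
        "n_bear_days": int(len(days)),
        "n_empty_days": int(profiles["empty"].sum()),
        "k_selected": int(model.k),
        "k_rule_satisfied": bool(model.selection.satisfied),
        "diet_type_counts": {str(k): int(v) for k, v in counts.items()},
        "protein_class_shares_pct": {
            k: round(100.0 * v / max(len(nonempty), 1), 2)
            for k, v in nonempty["protein_class"].value_counts().items()
        },
        "models": results,
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("run_all: report written to %s", out)
    return out
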