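"""Mixed-effects models of daily protein share.

Two linear mixed models describe how the protein share of daily digestible
energy varies: (1) season crossed with species-sex category, and (2) season
crossed with body mass (species pooled). Repeated bear-days of one
individual are not independent, so both models carry a random intercept per
bear and are fit by restricted maximum likelihood.

Term significance is summarized by Wald F-statistics with containment-style
denominator degrees of freedom: terms built only from bear-level covariates
(species-sex group, body mass) are tested against between-bear degrees of
freedom ``n_bears - p_between - 1``; terms that vary within bears (season
and its interactions) against ``n_obs - n_bears - p_within``. This is an
approximation, chosen for transparency over Satterthwaite-style adjustments,
and is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from patsy import build_design_matrices

logger = logging.getLogger(__name__)

FORMULAS = {
    "season_group": "protein_pct ~ C(season) * C(group)",
    "season_mass": "protein_pct ~ C(season) * body_mass_kg",
}


@dataclass
class ProteinModelFit:
    """A fitted protein-share mixed model and its Wald F summary."""

    formula_kind: str
    params: pd.Series                  # fixed effects
    bse: pd.Series
    cov: pd.DataFrame                  # fixed-effect covariance
    anova: pd.DataFrame                # term, F, df1, df2, p_value
    random_intercept_var: float
    residual_var: float
    n_obs: int
    n_bears: int
    converged: bool
    singular: bool
    design_info: object
    data_columns: tuple[str, ...]

    def summary_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"term": self.params.index, "estimate": self.params.to_numpy(),
             "se": self.bse.to_numpy()}
        )
        return out


def _term_is_between(cols: np.ndarray, groups: np.ndarray) -> bool:
    """True when every design column of a term is constant within each bear."""
    df = pd.DataFrame(cols)
    df["__g"] = groups
    nun = df.groupby("__g").nunique()
    return bool((nun <= 1).to_numpy().all())


def fit_protein_model(
    data: pd.DataFrame,
    formula: str = "season_group",
    reml: bool = True,
) -> ProteinModelFit:
    """Fit one of the two protein-share models with a per-bear random intercept.

    ``data`` needs columns ``protein_pct``, ``season``, ``bear_id`` and either
    ``group`` (species-sex category) or ``body_mass_kg`` depending on the
    formula. Raises on a single bear (the random intercept is then
    unidentifiable); a non-converged or boundary fit is returned flagged, not
    raised.
    """
    if formula not in FORMULAS:
        raise ValueError(f"formula must be one of {sorted(FORMULAS)}, got {formula!r}")
    needed = {"protein_pct", "season", "bear_id"}
    needed |= {"group"} if formula == "season_group" else {"body_mass_kg"}
    missing = needed - set(data.columns)
    if missing:
        raise ValueError(f"data lacks columns: {sorted(missing)}")
    data = data.dropna(subset=list(needed)).copy()
    n_bears = data["bear_id"].nunique()
    if n_bears < 2:
        raise ValueError("need at least 2 bears to identify the random intercept")

    if formula == "season_group":
        cells = pd.crosstab(data["season"], data["group"])
        if (cells == 0).any().any():
            logger.warning(
                "fit_protein_model: empty season x group cells\n%s", cells
            )

    model = smf.mixedlm(FORMULAS[formula], data=data, groups=data["bear_id"])
    import warnings

    with warnings.catch_warnings():
        # boundary (zero) random-effect variance raises chatter we flag below
        warnings.simplefilter("ignore")
        try:
            result = model.fit(reml=reml)
        except np.linalg.LinAlgError:
            result = model.fit(reml=reml, method="powell")
        bse_fe = result.bse_fe  # degenerate designs emit sqrt warnings here
    re_var = float(result.cov_re.iloc[0, 0])
    singular = re_var <= 1e-10 or not result.converged

    fe_names = list(result.fe_params.index)
    cov = pd.DataFrame(
        np.asarray(result.cov_params())[: len(fe_names), : len(fe_names)],
        index=fe_names,
        columns=fe_names,
    )

    # Wald F per term with containment denominator df.
    design_info = model.data.design_info
    groups = data["bear_id"].to_numpy()
    exog = np.asarray(model.exog)
    term_slices = {
        t.name(): design_info.term_name_slices[t.name()] for t in design_info.terms
    }
    between: dict[str, int] = {}
    within: dict[str, int] = {}
    for name, sl in term_slices.items():
        q = sl.stop - sl.start
        if name == "Intercept":
            continue
        if _term_is_between(exog[:, sl], groups):
            between[name] = q
        else:
            within[name] = q
    n_obs = len(data)
    df_between = n_bears - sum(between.values()) - 1
    df_within = n_obs - n_bears - sum(within.values())

    rows = []
    beta = result.fe_params.to_numpy()
    V = cov.to_numpy()
    for name, sl in term_slices.items():
        if name == "Intercept":
            continue
        idx = np.arange(sl.start, sl.stop)
        b = beta[idx]
        Vsub = V[np.ix_(idx, idx)]
        try:
            w = float(b @ np.linalg.solve(Vsub, b))
        except np.linalg.LinAlgError:
            logger.warning("fit_protein_model: singular covariance for term %s", name)
            continue
        q = len(idx)
        df2 = df_between if name in between else df_within
        df2 = max(df2, 1)
        f = w / q
        p = float(stats.f.sf(f, q, df2))
        rows.append({"term": name, "F": f, "df1": q, "df2": df2, "p_value": p})
    anova = pd.DataFrame(rows, columns=["term", "F", "df1", "df2", "p_value"])

    return ProteinModelFit(
        formula_kind=formula,
        params=result.fe_params,
        bse=bse_fe,
        cov=cov,
        anova=anova,
        random_intercept_var=re_var,
        residual_var=float(result.scale),
        n_obs=n_obs,
        n_bears=n_bears,
        converged=bool(result.converged),
        singular=singular,
        design_info=design_info,
        data_columns=tuple(sorted(needed)),
    )


def predict_group_means(
    fit: ProteinModelFit, grid: pd.DataFrame, level: float = 0.95
) -> pd.DataFrame:
    """Model-predicted mean protein share with confidence intervals on a grid.

    The grid carries the model's covariates (``season`` and ``group`` or
    ``body_mass_kg``); categorical levels must have appeared in the training
    design. Intervals come from the fixed-effect covariance (random-effect
    uncertainty describes bears, not the population mean).
    """
    grid = grid.copy()
    try:
        (X,) = build_design_matrices([fit.design_info], grid)
    except Exception as exc:  # patsy raises generic errors on unseen levels
        raise ValueError(f"grid is incompatible with the fitted design: {exc}") from exc
    X = np.asarray(X)
    beta = fit.params.to_numpy()
    V = fit.cov.to_numpy()
    mean = X @ beta
    var = np.einsum("ij,jk,ik->i", X, V, X)
    se = np.sqrt(np.clip(var, 0.0, None))  # guard tiny negative round-off
    z = stats.norm.ppf(0.5 + level / 2.0)
    out = grid.reset_index(drop=True)
    out["predicted_pct"] = mean
    out["se"] = se
    out["lo95"] = mean - z * se
    out["hi95"] = mean + z * se
    return out
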