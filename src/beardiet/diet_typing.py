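"""Diet typing: PCA of food-type energy shares, Ward clustering, cluster selection.

Bear-days are clustered on the daily percentages of digestible energy from
seven food types (fungi omitted for their negligible shares; small and large
vertebrates merged). Variables are standardized, decomposed by PCA, and the
component scores fed to Ward agglomerative clustering — the
hierarchical-clustering-on-principal-components recipe.

The number of clusters is not chosen by eye. A cluster is *homogeneous* in a
food type when that type supplies at least 50% of daily energy on every
member day and at least 75% on average. The selected k is the smallest cut
such that every food type which dominates at least one day (>= 95% of that
day's energy) owns a homogeneous cluster.

Cluster-covariate structure is screened with per-level 2x2 chi-square tests
(categorical supplementary variables) and two-sample t-tests (continuous),
reported in three significance tiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .foods import CLUSTER_VARIABLES

logger = logging.getLogger(__name__)

#: Default thresholds of the cluster-count rule, in percent of daily energy.
DEFAULT_THRESHOLDS = {"dominance": 95.0, "member_min": 50.0, "mean_min": 75.0}


def _variable_columns(profiles: pd.DataFrame) -> list[str]:
    cols = [f"{v}_pct" for v in CLUSTER_VARIABLES]
    missing = [c for c in cols if c not in profiles.columns]
    if missing:
        raise ValueError(f"profiles table lacks clustering variables: {missing}")
    return cols


@dataclass
class PCAResult:
    loadings: pd.DataFrame          # variables x components
    scores: np.ndarray              # days x components
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    scale: np.ndarray


def fit_pca(profiles: pd.DataFrame, standardize: bool = True) -> PCAResult:
    """PCA of the seven standardized food-type energy shares.

    Components carry a deterministic sign convention (the largest-magnitude
    loading of each component is positive) and the full basis is an isometry:
    pairwise distances between score rows equal distances between the
    standardized inputs.
    """
    cols = _variable_columns(profiles)
    X = profiles[cols].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 bear-days to fit principal components")
    # All 7 dimensions are recovered once n_days >= 8; with fewer days the
    # basis is truncated to the data rank, as SVD dictates.
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        dead = [cols[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(
            f"constant clustering variables {dead}; remove them before PCA"
        )
    scale = sd if standardize else np.ones_like(sd)
    Z = (X - mean) / scale

    # SVD gives exact orthonormal loadings; eigenvalues in non-increasing order.
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    # Sign convention: largest-magnitude loading of each component positive.
    for j in range(Vt.shape[0]):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * s
    var = s**2
    evr = var / var.sum()
    loadings = pd.DataFrame(
        Vt.T, index=cols, columns=[f"PC{j + 1}" for j in range(Vt.shape[0])]
    )
    return PCAResult(loadings, scores, evr, mean, scale)


def cluster_tree(scores: np.ndarray, n_dims: Optional[int] = None) -> np.ndarray:
    """Ward linkage on Euclidean distances of the retained component scores."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if n_dims is not None:
        if n_dims < 1 or n_dims > scores.shape[1]:
            raise ValueError(f"n_dims must be in [1, {scores.shape[1]}]")
        scores = scores[:, :n_dims]
    if scores.shape[0] == 1:
        # single-leaf degenerate tree
        return np.empty((0, 4))
    return linkage(scores, method="ward")


def cut_tree(tree: np.ndarray, k: int, n_days: int) -> np.ndarray:
    """Cluster labels (0-based) for the k-cluster cut of a linkage tree."""
    if n_days == 1:
        return np.zeros(1, dtype=int)
    return fcluster(tree, t=k, criterion="maxclust") - 1


def homogeneity_flags(
    labels: np.ndarray,
    profiles: pd.DataFrame,
    member_min: float = 50.0,
    mean_min: float = 75.0,
) -> dict[int, Optional[str]]:
    """Per-cluster homogeneity flag: the food type, if any, supplying
    >= ``member_min`` percent of energy on every member day and
    >= ``mean_min`` percent on average (at most one type can qualify)."""
    flags: dict[int, Optional[str]] = {}
    cols = _variable_columns(profiles)
    X = profiles[cols].to_numpy(dtype=float)
    for c in np.unique(labels):
        sub = X[labels == c]
        flags[int(c)] = None
        for j, var in enumerate(CLUSTER_VARIABLES):
            if sub[:, j].min() >= member_min and sub[:, j].mean() >= mean_min:
                flags[int(c)] = var
                break
    return flags


@dataclass
class KSelection:
    k: int
    satisfied: bool
    required_types: tuple[str, ...]
    flags: dict[int, Optional[str]]


def select_k(
    tree: np.ndarray,
    profiles: pd.DataFrame,
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
    k_max: Optional[int] = None,
) -> KSelection:
    """Smallest cut at which every dominant food type owns a homogeneous cluster.

    A food type is *required* when it supplies >= ``dominance`` percent of
    energy on at least one bear-day. If no cut up to ``k_max`` covers all
    required types, the result carries ``k_max`` with ``satisfied=False``
    rather than raising.
    """
    cols = _variable_columns(profiles)
    X = profiles[cols].to_numpy(dtype=float)
    n_days = X.shape[0]
    if k_max is None:
        k_max = n_days
    if k_max > n_days:
        raise ValueError(f"k_max {k_max} exceeds number of bear-days {n_days}")
    dominance = float(thresholds.get("dominance", 95.0))
    member_min = float(thresholds.get("member_min", 50.0))
    mean_min = float(thresholds.get("mean_min", 75.0))

    required = tuple(
        var for j, var in enumerate(CLUSTER_VARIABLES) if (X[:, j] >= dominance).any()
    )
    for k in range(1, k_max + 1):
        labels = cut_tree(tree, k, n_days)
        flags = homogeneity_flags(labels, profiles, member_min, mean_min)
        covered = {v for v in flags.values() if v is not None}
        if set(required) <= covered:
            return KSelection(k=k, satisfied=True, required_types=required, flags=flags)
    labels = cut_tree(tree, k_max, n_days)
    flags = homogeneity_flags(labels, profiles, member_min, mean_min)
    logger.warning(
        "select_k: no cut up to k=%d yields homogeneous clusters for all of %s",
        k_max,
        required,
    )
    return KSelection(k=k_max, satisfied=False, required_types=required, flags=flags)


def name_clusters(
    labels: np.ndarray,
    profiles: pd.DataFrame,
    flags: Mapping[int, Optional[str]],
    second_min: float = 20.0,
) -> dict[int, str]:
    """Cosmetic cluster names from dominant mean food types.

    A homogeneous cluster is named by its flagged type; otherwise by the top
    mean type, hyphenated with the runner-up when that one averages at least
    ``second_min`` percent.
    """
    cols = _variable_columns(profiles)
    X = profiles[cols].to_numpy(dtype=float)
    names: dict[int, str] = {}
    for c in np.unique(labels):
        c = int(c)
        if flags.get(c):
            names[c] = str(flags[c])
            continue
        means = X[labels == c].mean(axis=0)
        order = np.argsort(means)[::-1]
        name = CLUSTER_VARIABLES[order[0]]
        if means[order[1]] >= second_min:
            name = f"{name}-{CLUSTER_VARIABLES[order[1]]}"
        names[c] = name
    # Disambiguate collisions deterministically.
    seen: dict[str, int] = {}
    for c in sorted(names):
        base = names[c]
        seen[base] = seen.get(base, 0) + 1
        if seen[base] > 1:
            names[c] = f"{base}-{seen[base]}"
    return names


@dataclass
class DietTypeModel:
    """Fitted diet-typing model: PCA basis, tree, selected cut, labels, names."""

    pca: PCAResult
    tree: np.ndarray
    selection: KSelection
    labels: pd.Series           # bear_day_id -> cluster index
    cluster_names: dict[int, str]
    n_dims: int

    @property
    def k(self) -> int:
        return self.selection.k

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bear_day_id": self.labels.index,
                "cluster": self.labels.to_numpy(),
                "diet_type": [self.cluster_names[int(c)] for c in self.labels],
            }
        )

    def counts(self) -> pd.Series:
        """Bear-day counts per diet-type name."""
        return self.labels_frame().groupby("diet_type").size().sort_values(ascending=False)


def fit_diet_types(
    profiles: pd.DataFrame,
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
    k_max: Optional[int] = None,
    n_dims: Optional[int] = None,
    standardize: bool = True,
) -> DietTypeModel:
    """End-to-end diet typing of a profiles table (one row per bear-day)."""
    if "empty" in profiles.columns and profiles["empty"].any():
        profiles = profiles[~profiles["empty"]].reset_index(drop=True)
    pca = fit_pca(profiles, standardize=standardize)
    if n_dims is None:
        n_dims = pca.scores.shape[1]
    tree = cluster_tree(pca.scores, n_dims=n_dims)
    selection = select_k(tree, profiles, thresholds=thresholds, k_max=k_max)
    labels = cut_tree(tree, selection.k, len(profiles))
    names = name_clusters(labels, profiles, selection.flags)
    return DietTypeModel(
        pca=pca,
        tree=tree,
        selection=selection,
        labels=pd.Series(labels, index=profiles["bear_day_id"].to_numpy()),
        cluster_names=names,
        n_dims=n_dims,
    )


TIER_BOUNDS = (0.05, 0.01, 0.001)


def _tier(p: float) -> Optional[int]:
    if p > 0.05:
        return None
    if p < 0.001:
        return 3
    if p < 0.01:
        return 2
    return 1


def associate(
    labels: pd.Series,
    metadata: pd.DataFrame,
    categorical: Sequence[str] = ("season", "sex", "species"),
    continuous: Sequence[str] = ("body_mass_kg", "fix_interval_min"),
    cluster_names: Optional[Mapping[int, str]] = None,
) -> pd.DataFrame:
    """Screen cluster membership against supplementary variables.

    Categorical variables: per (cluster, level) 2x2 chi-square of membership
    vs level (no continuity correction), direction from the sign of
    observed minus expected co-occurrence; tests with any expected cell below
    1 are skipped with a logged note. Continuous variables: Welch two-sample
    t-test of cluster vs rest, direction from the mean difference. Rows with
    p > 0.05 are omitted; tiers are 1 (0.01 <= p <= 0.05), 2 (0.001 <= p <
    0.01) and 3 (p < 0.001).
    """
    meta = metadata.set_index("bear_day_id")
    missing = [i for i in labels.index if i not in meta.index]
    if missing:
        raise ValueError(f"metadata lacks bear-days: {missing[:5]}")
    meta = meta.loc[labels.index]
    rows = []
    for c in np.unique(labels.to_numpy()):
        in_c = labels.to_numpy() == c
        name = cluster_names[int(c)] if cluster_names else str(int(c))
        for var in categorical:
            for level in sorted(meta[var].dropna().unique()):
                is_level = (meta[var] == level).to_numpy()
                table = np.array(
                    [
                        [np.sum(in_c & is_level), np.sum(in_c & ~is_level)],
                        [np.sum(~in_c & is_level), np.sum(~in_c & ~is_level)],
                    ],
                    dtype=float,
                )
                expected = stats.contingency.expected_freq(table)
                if expected.min() < 1.0:
                    logger.info(
                        "associate: skipping %s x %s=%s (expected cell < 1)",
                        name, var, level,
                    )
                    continue
                chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
                tier = _tier(p)
                if tier is None:
                    continue
                rows.append(
                    {
                        "diet_type": name,
                        "variable": var,
                        "level": str(level),
                        "direction": "+" if table[0, 0] > expected[0, 0] else "-",
                        "p_value": p,
                        "tier": tier,
                    }
                )
        for var in continuous:
            if var not in meta.columns:
                continue
            x = meta.loc[in_c, var].dropna().to_numpy(dtype=float)
            y = meta.loc[~in_c, var].dropna().to_numpy(dtype=float)
            if len(x) < 2 or len(y) < 2:
                logger.info("associate: skipping %s x %s (too few values)", name, var)
                continue
            t, p = stats.ttest_ind(x, y, equal_var=False)
            tier = _tier(p)
            if tier is None:
                continue
            rows.append(
                {
                    "diet_type": name,
                    "variable": var,
                    "level": "",
                    "direction": "+" if x.mean() > y.mean() else "-",
                    "p_value": float(p),
                    "tier": tier,
                }
            )
    return pd.DataFrame(
        rows, columns=["diet_type", "variable", "level", "direction", "p_value", "tier"]
    )


def share_of_days(
    subset: Sequence[str], counts: pd.Series, total: Optional[int] = None
) -> tuple[int, float]:
    """Percent of all bear-days falling in a subset of diet types.

    ``counts`` maps diet-type name -> bear-day count. Returns the
    nearest-integer percent (as reported) and the unrounded value.
    """
    unknown = [name for name in subset if name not in counts.index]
    if unknown:
        raise ValueError(f"unknown diet types: {unknown}")
    if total is None:
        total = int(counts.sum())
    pct = 100.0 * counts.loc[list(subset)].sum() / total
    return int(round(pct)), float(pct)
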