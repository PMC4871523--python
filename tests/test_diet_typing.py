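"""PCA, Ward clustering, homogeneity-driven cluster selection, associations."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from beardiet.diet_typing import (
    DEFAULT_THRESHOLDS,
    associate,
    cluster_tree,
    cut_tree,
    fit_diet_types,
    fit_pca,
    homogeneity_flags,
    select_k,
    share_of_days,
)
from beardiet.foods import CLUSTER_VARIABLES
from beardiet.simulate import load_diet_type_table

COLS = [f"{v}_pct" for v in CLUSTER_VARIABLES]


def make_profiles(shares: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(shares, columns=COLS)
    df.insert(0, "bear_day_id", [f"d{i}" for i in range(len(df))])
    return df


def random_profiles(n, rng):
    shares = rng.dirichlet(np.ones(7) * 2, size=n) * 100
    return make_profiles(shares)


def pure_type_profiles(d, per_type, rng, dominant=(96.0, 100.0)):
    """Days each nearly pure in one of d food types (all 7 columns vary)."""
    rows = []
    for j in range(d):
        for _ in range(per_type):
            dom = rng.uniform(*dominant)
            rest = rng.dirichlet(np.ones(6)) * (100 - dom)
            row = np.insert(rest, j, dom)
            rows.append(row)
    return make_profiles(np.array(rows))


class TestPCA:
    def test_full_basis_is_an_isometry(self):
        rng = np.random.default_rng(0)
        profiles = random_profiles(40, rng)
        res = fit_pca(profiles)
        Z = (profiles[COLS].to_numpy() - res.mean) / res.scale
        assert np.allclose(pdist(res.scores), pdist(Z), atol=1e-9)

    def test_explained_variance_sums_to_one_and_is_sorted(self):
        rng = np.random.default_rng(1)
        res = fit_pca(random_profiles(60, rng))
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)

    def test_two_pure_groups_single_separating_component(self):
        rng = np.random.default_rng(2)
        shares = np.zeros((2, 7))
        shares[0, 0] = 100.0
        shares[0, 5] = 0.0
        shares[1, 5] = 100.0
        # perturb remaining columns so nothing is constant
        shares += rng.uniform(0.01, 0.2, shares.shape)
        res = fit_pca(make_profiles(shares))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)
        assert res.scores[0, 0] != pytest.approx(res.scores[1, 0])

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        profiles = random_profiles(30, rng)
        a = fit_pca(profiles)
        b = fit_pca(profiles.iloc[::-1].reset_index(drop=True))
        for col in a.loadings.columns[:5]:
            assert a.loadings[col].abs().idxmax() == b.loadings[col].abs().idxmax()
            assert a.loadings[col].loc[a.loadings[col].abs().idxmax()] > 0

    def test_constant_variable_rejected(self):
        rng = np.random.default_rng(4)
        profiles = random_profiles(20, rng)
        profiles["cambium_pct"] = 0.0
        with pytest.raises(ValueError, match="cambium_pct"):
            fit_pca(profiles)


class TestClusterTree:
    def test_three_separated_blobs_recovered(self):
        rng = np.random.default_rng(5)
        centers = np.array([[0, 0], [10, 0], [0, 10]], dtype=float)
        pts = np.vstack([c + rng.normal(0, 0.5, (10, 2)) for c in centers])
        tree = cluster_tree(pts)
        labels = cut_tree(tree, 3, len(pts))
        truth = np.repeat([0, 1, 2], 10)
        # same partition up to label permutation
        assert len(set(zip(labels, truth))) == 3

    def test_full_basis_equals_clustering_raw_standardized(self):
        rng = np.random.default_rng(6)
        profiles = random_profiles(50, rng)
        res = fit_pca(profiles)
        Z = (profiles[COLS].to_numpy() - res.mean) / res.scale
        t1 = cluster_tree(res.scores, n_dims=res.scores.shape[1])
        t2 = cluster_tree(Z)
        for k in (2, 3, 5, 8):
            l1, l2 = cut_tree(t1, k, 50), cut_tree(t2, k, 50)
            assert len(set(zip(l1, l2))) == k

    def test_single_day_single_leaf(self):
        tree = cluster_tree(np.array([[1.0, 2.0]]))
        assert cut_tree(tree, 1, 1).tolist() == [0]


def brute_force_min_k(tree, profiles, thresholds, k_max):
    """Independent evaluation of every cut: the smallest k covering all
    dominant food types with a homogeneous cluster."""
    X = profiles[COLS].to_numpy()
    required = {
        v for j, v in enumerate(CLUSTER_VARIABLES)
        if (X[:, j] >= thresholds["dominance"]).any()
    }
    for k in range(1, k_max + 1):
        labels = cut_tree(tree, k, len(profiles))
        covered = set()
        for c in np.unique(labels):
            sub = X[labels == c]
            for j, v in enumerate(CLUSTER_VARIABLES):
                if sub[:, j].min() >= thresholds["member_min"] and sub[:, j].mean() >= thresholds["mean_min"]:
                    covered.add(v)
        if required <= covered:
            return k
    return None


class TestSelectK:
    @pytest.mark.parametrize("d", [2, 3, 4, 6])
    def test_pure_types_select_d_clusters(self, d):
        # days that are each 100% one of d food types; tree on the raw shares
        shares = np.zeros((10 * d, 7))
        for j in range(d):
            shares[10 * j : 10 * (j + 1), j] = 100.0
        profiles = make_profiles(shares)
        tree = cluster_tree(shares)
        sel = select_k(tree, profiles, k_max=len(profiles))
        assert sel.satisfied
        assert sel.k == d
        assert sel.k == brute_force_min_k(tree, profiles, DEFAULT_THRESHOLDS, len(profiles))
        flagged = [v for v in sel.flags.values() if v is not None]
        assert sorted(flagged) == sorted(CLUSTER_VARIABLES[:d])

    def test_no_dominant_day_gives_k_one(self):
        rng = np.random.default_rng(9)
        shares = rng.dirichlet(np.ones(7) * 30, size=40) * 100  # nothing near 95%
        profiles = make_profiles(shares)
        assert profiles[COLS].to_numpy().max() < 95
        tree = cluster_tree(fit_pca(profiles).scores)
        sel = select_k(tree, profiles)
        assert sel.k == 1 and sel.satisfied and sel.required_types == ()

    def test_infeasible_rule_flags_not_raises(self):
        rng = np.random.default_rng(10)
        profiles = pure_type_profiles(3, 8, rng)
        tree = cluster_tree(fit_pca(profiles).scores)
        sel = select_k(tree, profiles, k_max=2)  # cannot cover 3 types with 2 clusters
        assert not sel.satisfied and sel.k == 2

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(11)
        profiles = pure_type_profiles(4, 8, rng, dominant=(90.0, 100.0))
        tree = cluster_tree(fit_pca(profiles).scores)
        loose = {"dominance": 95.0, "member_min": 40.0, "mean_min": 60.0}
        strict = {"dominance": 95.0, "member_min": 50.0, "mean_min": 75.0}
        assert select_k(tree, profiles, loose).k <= select_k(tree, profiles, strict).k

    def test_labels_invariant_to_uniform_rescaling(self):
        rng = np.random.default_rng(12)
        profiles = random_profiles(40, rng)
        m1 = fit_diet_types(profiles, k_max=10)
        scaled = profiles.copy()
        scaled[COLS] = scaled[COLS] * 1.0  # percents are already scale-free
        m2 = fit_diet_types(scaled, k_max=10)
        assert (m1.labels.to_numpy() == m2.labels.to_numpy()).all()


class TestAssociate:
    def test_cluster_aligned_with_species_tier3_positive(self):
        n = 40
        labels = pd.Series([0] * 20 + [1] * 20, index=[f"d{i}" for i in range(n)])
        meta = pd.DataFrame(
            {
                "bear_day_id": [f"d{i}" for i in range(n)],
                "species": ["grizzly"] * 20 + ["black_sympatric"] * 20,
            }
        )
        out = associate(labels, meta, categorical=("species",), continuous=())
        row = out[(out["diet_type"] == "0") & (out["level"] == "grizzly")].iloc[0]
        assert row["direction"] == "+" and row["tier"] == 3

    def test_shifted_continuous_variable_tier3(self):
        rng = np.random.default_rng(13)
        n = 60
        labels = pd.Series([0] * 20 + [1] * 40, index=[f"d{i}" for i in range(n)])
        mass = rng.normal(100, 5, n)
        mass[:20] += 15  # +3 sigma inside cluster 0
        meta = pd.DataFrame({"bear_day_id": [f"d{i}" for i in range(n)], "body_mass_kg": mass})
        out = associate(labels, meta, categorical=(), continuous=("body_mass_kg",))
        row = out[out["diet_type"] == "0"].iloc[0]
        assert row["direction"] == "+" and row["tier"] == 3

    def test_tier_boundaries(self):
        from beardiet.diet_typing import _tier

        assert _tier(0.06) is None
        assert _tier(0.05) == 1
        assert _tier(0.01) == 1
        assert _tier(0.009) == 2
        assert _tier(0.001) == 2
        assert _tier(0.0009) == 3


class TestShareOfDays:
    @pytest.fixture()
    def counts(self):
        t3 = load_diet_type_table()
        return t3.set_index("diet_type")["n_bear_days"]

    def test_all_types_is_100(self, counts):
        rounded, raw = share_of_days(list(counts.index), counts)
        assert rounded == 100 and raw == pytest.approx(100.0)

    def test_below_optimal_homogeneous_bgveg(self, counts):
        rounded, raw = share_of_days(["bgveg"], counts, total=274)
        assert rounded == 3
        assert raw == pytest.approx(100 * 7 / 274)

    def test_slightly_above_optimal_group(self, counts):
        rounded, _ = share_of_days(["agveg", "fruit-insect", "bgveg-mixed"], counts, total=274)
        assert rounded == 25

    def test_unknown_diet_type_rejected(self, counts):
        with pytest.raises(ValueError, match="salmon-diet"):
            share_of_days(["salmon-diet"], counts)
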