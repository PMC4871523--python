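# Methods notes

This note records the models, the defaults and their rationale, the
numerical choices, and what the synthetic-data generator does and does not
emulate. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Units and conventions

All tables are UTF-8 CSV with a header row; dates ISO-8601. Percent columns
(0–100) are suffixed `_pct`, fraction columns (0–1) `_frac` where confusion
is possible. Nutrient fractions are stored internally on a **fresh** basis;
the dry basis is a derived view (`dry = fresh / (1 − moisture)`), never a
second store, so the two can never diverge.

## Food composition and imputation

Each taxon carries digestible protein, carbohydrate, lipid, non-digestible
fraction and moisture. Published composition data are patchy, so three
provenance levels are tracked per constituent:

* `measured` — taken from the input row;
* `imputed_from_similar` — the record has some constituents; missing ones
  are scaled from the mean constituent profile of *fully specified records
  of the same food type* so that the aggregate ratio of missing to measured
  constituents matches the reference means. With a single measured
  constituent this reduces to the intuitive rule "carbohydrate:protein in
  the references is 2:1, so fill carbohydrate at twice the measured
  protein."
* `type_mean` — nothing measured; all constituents take the type means.

Two deliberate choices: the reference set is same-food-type only (no
cross-type borrowing — "similar foods" is read as same type), and ratios are
computed on the **dry** basis so that moisture content does not leak into
relative macronutrient structure. If imputation pushes the dry constituent
sum above 1, the imputed values only are shrunk proportionally; measured
values are never altered. Missing moisture takes the same-type mean
moisture.

Energy density is the macronutrient fractions weighted by food-type-specific
Atwater factors (kcal per gram of protein / carbohydrate / lipid). It is
linear in composition and ignores the non-digestible fraction by
construction. The packaged factor table also ships per-type mean total
energies on both bases; the packaged synthetic type-mean compositions are
constructed to reproduce those totals exactly and are labelled synthetic —
they stand in for a literature synthesis that is not redistributable.

## Scat correction and daily aggregation

Within each scat, item percent fecal volumes are multiplied by the food
type's correction factor and the vector renormalized to sum to one, so
**every scat contributes exactly one sample unit**. Renormalization makes
the output invariant to rescaling all factors by a constant; whether the
original field analysis renormalized per scat is not documented, so this
choice is isolated in `correct_scat` and can be toggled by post-processing
its raw output. Feeding signs contribute their intensity's scat equivalent
(0.05 / 0.30 / 0.75 of a unit) to the signed taxon; intensities at the same
site are kept as separate signs and summed, with no per-day cap. A day's
sample count is `n_scats + Σ equivalents`; a day with no observations is an
explicitly flagged empty intake, excluded from profiles downstream rather
than silently dropped.

Items identified only to food type are carried under the reserved key
`unidentified_<type>`, which resolves to the type-mean composition.

## Energy profiles and the protein band

Per food item, energy by macronutrient is
`units × fresh fraction × Atwater factor`; percent shares are the margins
over the day total. Only relative shares are meaningful: units are on the
scat-unit scale, so absolute kcal/day is out of scope by design. Fungi
contribute to the energy *denominator* even though they are excluded from
the clustering variables — the exclusion is about negligible variance in the
PCA inputs, not about the energy accounting.

The optimal protein band is 17 ± 4% of digestible energy, bounds
**inclusive** on both sides (the band is quoted as "17 ± 4%", which reads
naturally as a closed interval). Season windows are fixed calendar windows —
spring 1 May–30 Jun, summer 1 Jul–20 Aug, fall 21 Aug–31 Oct — and dates
outside them are an error, not silently clamped.

## Diet typing

Active variables are the seven food-type shares (fungi excluded, small and
large vertebrates merged). Variables are standardized to unit variance
(population sd) before PCA — the common default for clustering on
components; it can be switched off. The decomposition is an SVD with a
deterministic sign convention (largest-magnitude loading positive), so
results do not depend on row order or library internals. All seven
dimensions feed the Ward tree by default (how many dimensions fed the
original tree is not documented; this is configurable), and no k-means
consolidation pass is applied after cutting, keeping the procedure fully
deterministic.

Cluster-count selection: a cluster is *homogeneous* in a food type when
that type supplies ≥50% of energy on every member day and ≥75% on average
(at most one type can satisfy this, since 50 + 75 > 100). A food type is
*required* when it dominates at least one day at ≥95%. The selected k is
the smallest cut covering all required types with homogeneous clusters;
infeasibility within `k_max` is a flagged result, not an exception. Because
the thresholds act as minima, loosening `member_min`/`mean_min` can only
keep or shrink the selected k (tested as a property).

Associations: per (cluster, categorical level), a 2×2 chi-square of
membership against level, without continuity correction — the correction is
conservative and would push the permutation false-positive rate well below
its nominal level, which the calibration check measures directly. Tests
with any expected cell below 1 are skipped with a logged note. Continuous
variables use Welch two-sample t tests (cluster vs rest). Rows with p > 0.05
are omitted; tiers are 1 (0.01 ≤ p ≤ 0.05), 2 (0.001 ≤ p < 0.01) and
3 (p < 0.001) — the boundary p = 0.001 is assigned the weaker tier, since
the stronger symbol should require strictly stronger evidence.

## Protein mixed models

Both models are linear mixed models with a per-bear random intercept, fit by
REML (statsmodels `MixedLM`). Season and species-sex group enter as
unordered categories; body mass (mass at capture, time-invariant per bear)
enters linearly — the reported gradient is linear and no polynomial terms
are added. Term tests are Wald F statistics with **containment** denominator
degrees of freedom: a term whose design columns are constant within every
bear is tested against `n_bears − p_between − 1`; terms varying within bears
against `n_obs − n_bears − p_within`. With 37 bears and 274 days this
reproduces denominator patterns like F(5, 31) for a bear-level factor and
F(2, 225) for season. This is an approximation chosen for transparency;
Satterthwaite-style adjustments would need the full REML Hessian and change
little at these sizes. Prediction intervals use the fixed-effect covariance
and normal quantiles — random-intercept variance describes bears, not the
uncertainty of the population mean. Empty season × group cells are logged
as a warning at fit time because contrasts touching them are not estimable.

## Synthetic-data generator

The generator emulates the sampling design: bears per species-sex cell,
bear-days per cell and season, and mass ranges default to the packaged
sampling table; each bear-day draws a diet type from a catalogue seeded from
the packaged diet-type table (14 types; printed rows sum to 99–101 and are
renormalized to exactly 100; the merged vertebrate share is split 80/20
large/small, reflecting ungulate dominance in the field record).

* **Within-day jitter** is Dirichlet around the catalogue means with
  concentration 7.0 — chosen so roughly 15% of days are ≥95% dominated by
  one food type, enough to exercise the cluster-count rule's dominance
  condition. The jitter is mean-preserving.
* **Diet-type probabilities** default to the catalogue's marginal day-count
  frequencies in every (species, sex, season) cell. This is deliberately
  neutral: the default generator carries no built-in species or season
  effects, so covariate-association and mixed-model outputs on default
  synthetic data are calibration checks (nothing should be found), while
  effect-recovery checks inject known effects explicitly.
* **Observations**: scats/day ~ Poisson(2.6), signs/day ~ Poisson(8.2),
  matching the field means; days drawing zero of both are kept and flagged.
  Scats carry the day's true dietary fractions pushed through the *forward*
  digestion distortion (divide by correction factor, renormalize), so the
  pipeline's correction step is its exact algebraic inverse — the round trip
  is tested to 1e-6. Sign intensity is the class whose scat equivalent is
  nearest the item's unit share of the day; signs are allocated across taxa
  with weights proportional to share / equivalent, which keeps the expected
  equivalent mass per taxon proportional to the true share (feeding sign is
  a coarse but unbiased estimator of the day mix).
* The **taxon layer** maps each food type to three synthetic taxa whose
  compositions are tightly jittered around the type means (Dirichlet,
  concentration 300 on the dry constituent vector), enough to exercise taxon
  resolution and composition lookups without replicating the real 134-food
  list.
* A separate direct simulator (`simulate_protein_observations`) draws
  protein shares straight from a known mixed model (default fall gradient:
  16% at 50 kg to 38% at 200 kg, i.e. 0.1467 %/kg; random-intercept sd 4,
  residual sd 8 — noise of the order the profile pipeline produces) for
  coefficient-recovery and coverage checks.

What the generator does **not** emulate: spatial/GPS structure, site-revisit
geometry, seasonal within-species change in plant composition, selective
consumption of tissues within a carcass, gut-retention temporal offsets, and
year-to-year mast dynamics. Passing recovery tests therefore show the
estimation chain is internally consistent and unbiased under the stated
observation model — not that field scats behave this ideally.

## Problem sizes in the checks

The acceptance checks use 1,000 random scats for the round trip, 60 days for
the cluster-selection oracle (brute-forced over every cut), ~300 and ~500
synthetic days for share and class recovery, 100 replicates of 40 bears × 9
days for coverage, and 1,000 permutations for calibration — sizes chosen so
Monte-Carlo error is comfortably inside the asserted tolerances while the
whole suite stays fast on a single CPU.

## Known limitations

* Imputation quality depends entirely on the same-type reference pool; a
  type with no fully specified record cannot be imputed (by design, an
  error).
* The renormalize-per-scat decision and the dry-basis ratio rule are
  interpretations of under-specified field procedure; both are isolated
  behind single functions.
* Containment df is approximate for unbalanced designs.
* The chi-square screen is per (cluster, level) with no multiplicity
  correction — it reproduces a descriptive enrichment table, not a
  family-wise inference.
* Absolute energy intake (kcal/day) is out of scope; only relative shares
  are estimated.
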