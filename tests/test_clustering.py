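"""Ratio features, k-means phenotyping, ANOVA contrasts and clinical z-scores."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from mitocoherence import (
    MitoClustering,
    build_index_table,
    clinical_enrichment,
    cluster_anova,
    compute_ratio_features,
    generate_cohort,
    hedges_g,
    kmeans_cluster,
    pca_variance,
)
from mitocoherence.errors import ParameterError
from mitocoherence.simulate import ARCHETYPE_PANEL, archetype_config


def _index_table(values: dict[str, dict[str, float]]) -> pd.DataFrame:
    rows = [
        (s, t, v) for s, tissues in values.items() for t, v in tissues.items()
    ]
    return pd.DataFrame(rows, columns=["subject_id", "tissue", "idx"])


def agreement(truth: pd.Series, labels: pd.Series) -> float:
    cm = pd.crosstab(truth, labels)
    ri, ci = linear_sum_assignment(-cm.values)
    return cm.values[ri, ci].sum() / len(truth)


class TestRatioFeatures:
    def test_four_tissues_give_six_features(self, rng):
        values = {f"p{i}": {t: float(rng.lognormal()) for t in "abcd"}
                  for i in range(10)}
        rf = compute_ratio_features(_index_table(values), "idx", list("abcd"))
        assert rf.features.shape == (10, 6)

    def test_equal_indices_give_zero_raw_ratios(self):
        values = {"p0": {t: 5.0 for t in "abc"}, "p1": {t: 2.0 for t in "abc"}}
        rf = compute_ratio_features(_index_table(values), "idx", list("abc"))
        assert (rf.raw.to_numpy() == 0).all()

    def test_matches_log2_quotient_oracle(self, rng):
        values = {f"p{i}": {t: float(rng.lognormal()) for t in "ab"}
                  for i in range(15)}
        rf = compute_ratio_features(_index_table(values), "idx", ["a", "b"])
        for p, tissues in values.items():
            assert rf.raw.loc[p, "a/b"] == pytest.approx(
                np.log2(tissues["a"] / tissues["b"]))

    def test_incomplete_subjects_dropped(self, rng):
        values = {f"p{i}": {t: float(rng.lognormal()) for t in "ab"}
                  for i in range(8)}
        values["p0"].pop("b")
        rf = compute_ratio_features(_index_table(values), "idx", ["a", "b"])
        assert "p0" in rf.dropped_subjects
        assert len(rf.features) == 7

    def test_antisymmetric_before_zscoring(self, rng):
        values = {f"p{i}": {t: float(rng.lognormal()) for t in "ab"}
                  for i in range(12)}
        fwd = compute_ratio_features(_index_table(values), "idx", ["a", "b"])
        rev = compute_ratio_features(_index_table(values), "idx", ["b", "a"])
        np.testing.assert_allclose(fwd.raw["a/b"], -rev.raw["b/a"])
        # clustering is orientation-invariant after standardization
        lf = kmeans_cluster(fwd, 2, seed=3)
        lr = kmeans_cluster(rev, 2, seed=3)
        assert agreement(lf, lr) == 1.0


class TestKmeans:
    def test_separated_blobs_recovered(self, rng):
        x = np.vstack([rng.normal(0, 0.3, (30, 4)), rng.normal(4, 0.3, (30, 4))])
        feats = pd.DataFrame(x, index=[f"p{i}" for i in range(60)])
        labels = kmeans_cluster(feats, 2, seed=1)
        truth = pd.Series([0] * 30 + [1] * 30, index=feats.index)
        assert agreement(truth, labels) == 1.0

    def test_k_equals_n_gives_singletons(self, rng):
        feats = pd.DataFrame(rng.normal(size=(6, 3)),
                             index=[f"p{i}" for i in range(6)])
        labels = kmeans_cluster(feats, 6, seed=1)
        assert labels.nunique() == 6

    def test_reproducible_for_fixed_seed(self, rng):
        feats = pd.DataFrame(rng.normal(size=(40, 5)),
                             index=[f"p{i}" for i in range(40)])
        a = kmeans_cluster(feats, 3, seed=9, n_restarts=5)
        b = kmeans_cluster(feats, 3, seed=9, n_restarts=5)
        pd.testing.assert_series_equal(a, b)

    def test_invalid_k_rejected(self, rng):
        feats = pd.DataFrame(rng.normal(size=(5, 2)))
        with pytest.raises(ParameterError):
            kmeans_cluster(feats, 1, seed=0)


class TestPcaVariance:
    def test_rank_one_data(self, rng):
        base = rng.normal(size=20)
        feats = pd.DataFrame({"a": base, "b": 2 * base, "c": -base})
        fractions = pca_variance(feats)
        assert fractions[0] == pytest.approx(1.0)

    def test_isotropic_noise_near_uniform(self, rng):
        feats = pd.DataFrame(rng.normal(size=(4000, 5)))
        fractions = pca_variance(feats)
        np.testing.assert_allclose(fractions, 0.2, atol=0.02)

    def test_fractions_sum_to_one_and_descend(self, rng):
        feats = pd.DataFrame(rng.normal(size=(30, 6)) * rng.uniform(0.5, 3, 6))
        fractions = pca_variance(feats)
        assert fractions.sum() == pytest.approx(1.0)
        assert (np.diff(fractions) <= 1e-12).all()


class TestHedgesG:
    def test_frozen_example(self):
        """J = 1 - 3/(4*4 - 1) = 0.8, mean diff -2, pooled SD 1 -> g = -1.6."""
        assert hedges_g([1, 2, 3], [3, 4, 5]) == pytest.approx(-1.6)

    def test_identical_groups_give_zero(self):
        assert hedges_g([1, 2, 3], [1, 2, 3]) == 0.0

    def test_zero_variance_flagged_nan(self):
        assert np.isnan(hedges_g([2, 2], [2, 2]))


class TestClusterAnova:
    @staticmethod
    def _table_and_labels(effect: float, rng, n: int = 50):
        """Cluster 1 shifted by `effect` SD in tissue 'a' only."""
        rows, labels = [], {}
        for c in (0, 1):
            for i in range(n):
                subj = f"c{c}p{i}"
                labels[subj] = c
                rows.append((subj, "a", rng.normal(c * effect, 1)))
                rows.append((subj, "b", rng.normal(0, 1)))
        table = pd.DataFrame(rows, columns=["subject_id", "tissue", "mito_ndna_pct"])
        return table, pd.Series(labels)

    def test_null_case(self, rng):
        table, labels = self._table_and_labels(0.0, rng)
        anova, g = cluster_anova(table, labels, ["a", "b"])
        assert anova.loc["cluster", "PR(>F)"] > 0.01
        assert g["hedges_g"].abs().max() < 0.5

    def test_planted_interaction_detected(self, rng):
        table, labels = self._table_and_labels(1.0, rng)
        anova, g = cluster_anova(table, labels, ["a", "b"])
        assert anova.loc["cluster:tissue", "PR(>F)"] < 0.05
        g_a = g.set_index("tissue").loc["a", "hedges_g"]
        assert abs(abs(g_a) - 1.0) < 0.4


class TestClinicalEnrichment:
    def test_equal_prevalence_gives_zero(self):
        labels = pd.Series([0, 0, 1, 1, 2, 2], index=[f"p{i}" for i in range(6)])
        clinical = pd.DataFrame({"var": [1, 0, 1, 0, 1, 0]},
                                index=labels.index)
        z = clinical_enrichment(labels, clinical)
        np.testing.assert_allclose(z.loc["var"], 0.0)

    def test_graded_prevalence_population_sd(self):
        """Prevalences (0%, 50%, 100%) z-scored with population SD give
        (-1.2247, 0, +1.2247)."""
        labels = pd.Series([0] * 4 + [1] * 4 + [2] * 4,
                           index=[f"p{i}" for i in range(12)])
        clinical = pd.DataFrame(
            {"var": [0, 0, 0, 0, 1, 1, 0, 0, 1, 1, 1, 1]}, index=labels.index)
        z = clinical_enrichment(labels, clinical)
        np.testing.assert_allclose(
            z.loc["var"], [-1.22474487, 0.0, 1.22474487], atol=1e-6)

    def test_missing_cluster_cell_flagged(self):
        labels = pd.Series([0, 0, 1, 1], index=[f"p{i}" for i in range(4)])
        clinical = pd.DataFrame({"var": [1.0, 0.0, np.nan, np.nan]},
                                index=labels.index)
        z = clinical_enrichment(labels, clinical)
        assert np.isnan(z.loc["var", 1])


@pytest.fixture(scope="module")
def fitted():
    cohort = generate_cohort(archetype_config(n_subjects=120, seed=23))
    table = build_index_table(cohort.expression, cohort.samples, cohort.catalog)
    model = MitoClustering(table, "mito_ndna_pct", ARCHETYPE_PANEL, k=3, seed=0)
    return cohort, model.fit()


class TestMitoClusteringModel:

    def test_archetypes_recovered(self, fitted):
        cohort, results = fitted
        truth = cohort.truth.archetypes.loc[results.labels.index]
        assert agreement(truth, results.labels) > 0.9

    def test_cluster_sizes_within_ten_percent(self, fitted):
        cohort, results = fitted
        truth_sizes = cohort.truth.archetypes.value_counts()
        got = results.cluster_sizes.sort_values().to_numpy()
        want = truth_sizes.sort_values().to_numpy()
        assert (np.abs(got - want) <= 0.1 * len(results.labels)).all()

    def test_cluster_factor_significant(self, fitted):
        _, results = fitted
        assert results.anova().loc["cluster", "PR(>F)"] < 0.05

    def test_clinical_sign_pattern_matches_planted(self, fitted):
        cohort, results = fitted
        z = results.clinical_enrichment(cohort.clinical)
        truth = cohort.truth.archetypes.loc[results.labels.index]
        cm = pd.crosstab(truth, results.labels)
        ri, ci = linear_sum_assignment(-cm.values)
        arch_for_cluster = {cm.columns[c]: cm.index[r] for r, c in zip(ri, ci)}
        probs = cohort.truth.config.clusters.clinical
        for var in ("condition_a", "condition_b"):
            hot = int(np.argmax(probs[var]))
            hot_cluster = [c for c, a in arch_for_cluster.items() if a == hot][0]
            assert z.loc[var, hot_cluster] == z.loc[var].max()

    def test_variance_fractions_valid(self, fitted):
        _, results = fitted
        v = results.pca_variance_
        assert v.sum() == pytest.approx(1.0)
        assert (np.diff(v) <= 1e-12).all()
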