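"""PCA/varimax, Mann-Whitney with eta-squared, Bonferroni, group contrasts.

Independent oracles: counting-pairs U with full assignment enumeration for
the exact Mann-Whitney p, and hypergeometric enumeration for Fisher's test.
"""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from phenosom.cohort import CohortMatrix
from phenosom.preprocess import preprocess, zscore
from phenosom.schema import SymptomTable, default_schema
from phenosom.simulate import DEFAULT_EFFECTS, SimulationConfig, generate_cohort
from phenosom.stats import (
    bonferroni_alpha,
    compare_groups,
    eta_squared,
    eta_squared_band,
    mann_whitney,
    pca,
    symptom_contrast,
)


def counting_pairs_u(a, b):
    """U as the count of (a_i > b_j) pairs plus half-credit for ties."""
    return sum(
        1.0 if ai > bj else (0.5 if ai == bj else 0.0)
        for ai in a for bj in b
    )


def enumerated_two_sided_p(pooled, na):
    """Exact two-sided p by enumerating every group assignment."""
    pooled = np.asarray(pooled, dtype=float)
    n = len(pooled)
    mu = na * (n - na) / 2.0
    idx_all = set(range(n))
    u_obs = counting_pairs_u(pooled[:na], pooled[na:])
    dev = abs(u_obs - mu) - 1e-9
    hits = total = 0
    for chosen in combinations(range(n), na):
        rest = sorted(idx_all - set(chosen))
        u = counting_pairs_u(pooled[list(chosen)], pooled[rest])
        total += 1
        hits += abs(u - mu) >= dev
    return hits / total


class TestMannWhitney:
    def test_disjoint_samples_exact_p(self):
        u, z, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples_null_result(self):
        u, z, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert z == 0.0
        assert p == 1.0

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=8),
           st.lists(st.floats(-50, 50), min_size=1, max_size=8))
    def test_rank_sum_identity(self, a, b):
        u_ab, _, _ = mann_whitney(a, b)
        u_ba, _, _ = mann_whitney(b, a)
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))

    def test_exact_path_matches_full_enumeration_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            na = int(rng.integers(2, 5))
            nb = int(rng.integers(2, 5))
            pooled = rng.integers(0, 4, na + nb).astype(float)  # many ties
            u, z, p = mann_whitney(pooled[:na], pooled[na:])
            assert p == pytest.approx(enumerated_two_sided_p(pooled, na))

    def test_normal_approximation_calibrated_against_exact(self):
        """For n_a = n_b = 6 null draws the exact and normal-approximation
        two-sided p agree within the ~0.1 discretization step of the exact
        null distribution (no continuity correction is applied)."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = rng.normal(size=6), rng.normal(size=6)
            _, z, p_exact = mann_whitney(a, b)
            p_norm = 2 * sps.norm.sf(abs(z))
            assert abs(p_exact - min(1.0, p_norm)) <= 0.1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestEffectSizeAndCorrection:
    @pytest.mark.parametrize("z,n,expected",
                             [(3.0, 100, 0.09), (0.0, 50, 0.0), (10.0, 100, 1.0)])
    def test_eta_squared_values(self, z, n, expected):
        assert eta_squared(z, n) == pytest.approx(expected)

    def test_eta_band_thresholds(self):
        assert eta_squared_band(0.05) == "negligible"
        assert eta_squared_band(0.2) == "small"
        assert eta_squared_band(0.4) == "medium"
        assert eta_squared_band(0.6) == "large"

    @pytest.mark.parametrize("alpha,m,expected",
                             [(0.05, 50, 0.001), (0.05, 1, 0.05),
                              (0.05, 53, 0.05 / 53)])
    def test_bonferroni(self, alpha, m, expected):
        assert bonferroni_alpha(alpha, m) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            eta_squared(1.0, 0)
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestPca:
    def test_collinear_data_explained_by_first_component(self):
        t = np.linspace(-1, 1, 20)
        x = np.column_stack([t, t])
        res = pca(x, rotation=None)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self, default_z):
        res = pca(default_z)
        assert res.explained_variance_fraction.sum() == pytest.approx(1.0)
        diffs = np.diff(res.explained_variance_fraction)
        assert np.all(diffs <= 1e-12)

    def test_unrotated_loadings_orthonormal_and_reconstruct(self, default_z):
        res = pca(default_z)
        v = res.unrotated_loadings
        assert np.allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-8)
        xc = default_z.values - default_z.values.mean(axis=0)
        assert np.max(np.abs(xc - (xc @ v) @ v.T)) < 1e-8

    def test_rotation_preserves_communalities(self, default_z):
        res = pca(default_z)
        unrot = res.unrotated_loadings[:, :res.n_retained]
        assert np.allclose((res.loadings ** 2).sum(axis=1),
                           (unrot ** 2).sum(axis=1), atol=1e-8)

    def test_varimax_separates_independent_blocks(self):
        """Two independent correlated 2-variable blocks: after varimax each
        retained component loads on exactly one block."""
        rng = np.random.default_rng(6)
        n = 400
        f1 = rng.normal(size=n)
        f2 = rng.normal(size=n)
        noise = rng.normal(scale=np.sqrt(1 - 0.9 ** 2), size=(n, 4))
        x = np.column_stack([
            0.9 * f1 + noise[:, 0], 0.9 * f1 + noise[:, 1],
            0.9 * f2 + noise[:, 2], 0.9 * f2 + noise[:, 3],
        ])
        res = pca(zscore(_plain_cohort(x)), retain_fraction=0.75)
        assert res.n_retained == 2
        norm = res.loadings / np.abs(res.loadings).max(axis=0)
        for comp in range(2):
            col = np.abs(norm[:, comp])
            on_block = col > 0.5
            assert set(np.where(on_block)[0]) in ({0, 1}, {2, 3})
            assert np.all(col[~on_block] < 0.1 / np.abs(res.loadings).max() + 0.35)


def _plain_cohort(x):
    from phenosom.schema import FeatureSchema

    schema = FeatureSchema((("B", tuple(f"v{i}" for i in range(x.shape[1]))),))
    return CohortMatrix(x, np.zeros_like(x, dtype=bool), schema)


@pytest.fixture(scope="module")
def contrast():
    cohort, _ = generate_cohort(SimulationConfig(seed=101))
    z = preprocess(cohort)
    from phenosom.preprocess import impute_median

    return compare_groups(impute_median(cohort), z, cohort.true_labels,
                          alpha_corrected=0.05 / 53)


class TestCompareGroups:

    def test_effect_variables_flagged_significant(self, contrast):
        flagged = set(contrast.significant_variables)
        # the large caloric effects must be detected at corrected alpha
        assert "caloric_mspv_sum" in flagged
        assert flagged <= set(DEFAULT_EFFECTS)

    def test_sorted_significant_first(self, contrast):
        sig = contrast.table["significant"].to_numpy()
        assert not np.any(sig[1:] > sig[:-1])  # no True after a False

    def test_u_statistics_consistent_with_scipy(self, contrast):
        cohort, _ = generate_cohort(SimulationConfig(seed=101))
        z = preprocess(cohort)
        g1 = cohort.true_labels == 1
        row = contrast.table.set_index("variable").loc["caloric_mspv_sum"]
        j = z.schema.variable_names.index("caloric_mspv_sum")
        ref = sps.mannwhitneyu(z.values[g1, j], z.values[~g1, j])
        assert row["U"] == pytest.approx(ref.statistic)

    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(3)
        schema = default_schema()
        half = rng.normal(size=(20, schema.total_variables))
        x = np.vstack([half, half])
        cohort = CohortMatrix(x, np.zeros_like(x, dtype=bool), schema)
        z = preprocess(cohort)
        labels = np.r_[np.ones(20, int), np.full(20, 2)]
        res = compare_groups(cohort, z, labels, alpha_corrected=0.05 / 53)
        assert res.significant_variables == []
        assert np.allclose(res.table["eta_squared"], 0.0)

    def test_single_group_rejected(self, default_z, default_cohort):
        with pytest.raises(ValueError):
            compare_groups(default_cohort[0], default_z,
                           np.ones(96, int), 0.001)


class TestSymptomContrast:
    def fisher_oracle(self, table):
        """Two-sided Fisher p by hypergeometric enumeration."""
        (a, b), (c, d) = table
        n = a + b + c + d
        row1, col1 = a + b, a + c
        p_obs = (comb(row1, a) * comb(n - row1, col1 - a)) / comb(n, col1)
        p = 0.0
        for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
            px = (comb(row1, x) * comb(n - row1, col1 - x)) / comb(n, col1)
            if px <= p_obs * (1 + 1e-9):
                p += px
        return p

    def test_fisher_path_matches_hypergeometric_enumeration(self):
        labels = np.r_[np.ones(9, int), np.full(9, 2)]
        presence = np.r_[np.ones(9), np.zeros(9)][:, None]
        table = symptom_contrast(
            SymptomTable(symptoms=["s"], presence=presence), labels
        )
        assert table.loc[0, "test"] == "fisher"
        assert table.loc[0, "p"] == pytest.approx(
            self.fisher_oracle([[9, 0], [0, 9]])
        )

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum(axis=1).min() == 0 or t.sum() == 0:
                continue
            _, p_scipy = sps.fisher_exact(t)
            assert p_scipy == pytest.approx(self.fisher_oracle(t.tolist()),
                                            abs=1e-10)

    def test_equal_frequencies_band_similar(self):
        labels = np.r_[np.ones(20, int), np.full(20, 2)]
        presence = np.tile(np.r_[np.ones(10), np.zeros(10)], 2)[:, None]
        table = symptom_contrast(
            SymptomTable(symptoms=["s"], presence=presence), labels
        )
        assert table.loc[0, "band"] == "similar"

    def test_seventeen_point_gap_bands_group_one(self):
        rng = np.random.default_rng(2)
        labels = np.r_[np.ones(100, int), np.full(100, 2)]
        presence = np.r_[
            (np.arange(100) < 76).astype(float),
            (np.arange(100) < 59).astype(float),
        ][:, None]
        table = symptom_contrast(
            SymptomTable(symptoms=["headache"], presence=presence), labels
        )
        assert table.loc[0, "freq_1"] == pytest.approx(0.76)
        assert table.loc[0, "freq_2"] == pytest.approx(0.59)
        assert table.loc[0, "band"] == "more in group 1"

    def test_frequencies_use_nonmissing_denominator(self):
        labels = np.r_[np.ones(4, int), np.full(4, 2)]
        col = np.array([1.0, np.nan, 1.0, 0.0, 0.0, np.nan, np.nan, 1.0])
        table = symptom_contrast(
            SymptomTable(symptoms=["s"], presence=col[:, None]), labels
        )
        assert table.loc[0, "freq_1"] == pytest.approx(2 / 3)
        assert table.loc[0, "freq_2"] == pytest.approx(1 / 2)
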