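"""Pooled-index construction: correlation screening, effect sizes, composite scores."""

import numpy as np
import pandas as pd
import pytest

from mcdt.pooling import (
    ScreeningConfig,
    cohens_d,
    orient_higher_better,
    pooled_score,
    screen_features,
    spearman_matrix,
)


def _labels(n_mci=6, n_oa=6):
    return np.array(["MCI"] * n_mci + ["OA"] * n_oa)


class TestSpearman:
    def test_unit_diagonal_and_symmetry(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        rho = spearman_matrix(df)
        np.testing.assert_allclose(np.diag(rho), 1.0)
        np.testing.assert_allclose(rho.values, rho.values.T)

    def test_rank_invariance_under_monotone_transform(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"x": x, "y": np.exp(x)})
        assert spearman_matrix(df).loc["x", "y"] == pytest.approx(1.0)

    def test_perfect_inversion(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4], "y": [4, 3, 2, 1]})
        assert spearman_matrix(df).loc["x", "y"] == pytest.approx(-1.0)

    def test_near_empty_column_excluded(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        df.loc[2:, "c"] = np.nan
        with pytest.warns(UserWarning):
            rho = spearman_matrix(df)
        assert "c" not in rho.columns


class TestCohensD:
    def test_equal_means_zero(self):
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        assert cohens_d(x, _labels(3, 3)).d == pytest.approx(0.0)

    def test_unit_gap_unit_sd(self, rng):
        a = rng.normal(1.0, 1.0, 20_000)
        b = rng.normal(0.0, 1.0, 20_000)
        x = np.concatenate([a, b])
        d = cohens_d(x, _labels(20_000, 20_000)).d
        assert d == pytest.approx(1.0, abs=0.05)

    def test_hand_computed_example(self):
        """A = (1,2,3), B = (3,4,5): pooled SD 1, d = -2."""
        x = np.array([1.0, 2.0, 3.0, 3.0, 4.0, 5.0])
        assert cohens_d(x, _labels(3, 3)).d == pytest.approx(-2.0)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            cohens_d(np.array([1.0, 2.0, 3.0]), np.array(["MCI", "OA", "OA"]))


def _pool(columns: dict) -> pd.DataFrame:
    return pd.DataFrame(columns)


class TestScreenFeatures:
    def test_uncorrelated_pool_fully_retained(self, rng):
        cols = _pool(
            {
                "tap_CL1": rng.normal(size=40),
                "exc_CL2": rng.normal(size=40),
                "wo_CL3": rng.normal(size=40),
            }
        )
        labels = np.array(["MCI"] * 20 + ["OA"] * 20)
        selected, trace = screen_features(cols, labels)
        assert sorted(selected) == sorted(cols.columns)
        assert trace == []

    def test_hub_column_deleted_first(self, rng):
        """A correlates with both B and C while B-C are unrelated: the
        deletion rule removes A and keeps the rest."""
        b = rng.normal(size=40)
        c = rng.normal(size=40)
        a = b + c  # correlates with both
        cols = _pool({"exc_CL1": a, "tap_CL1": b, "wo_CL1": c})
        labels = np.array(["MCI"] * 20 + ["OA"] * 20)
        selected, trace = screen_features(cols, labels)
        assert "exc_CL1" not in selected
        assert sorted(selected) == ["tap_CL1", "wo_CL1"]
        assert trace[0]["deleted"] == "exc_CL1"
        assert trace[0]["rule"] == "max_high_rho_count"

    def test_tie_broken_by_smaller_effect_size(self, rng):
        """Columns tied at one strong-correlation partner each: the one with
        the smaller |Cohen's d| on the MCI-vs-OA contrast goes first."""
        n = 60
        labels = np.array(["MCI"] * 30 + ["OA"] * 30)
        g = np.where(labels == "MCI", 1.0, 0.0)
        u = rng.normal(0, 1, n)
        v = rng.normal(0, 1, n)
        cols = _pool(
            {
                "tap_CL1": u + 1.2 * g,           # strong effect
                "tap_CL2": u + rng.normal(0, 0.3, n),  # ~no effect, pairs with tap_CL1
                "exc_CL1": v + 0.8 * g,
                "exc_CL2": v + 0.6 * g + rng.normal(0, 0.3, n),
            }
        )
        rho = spearman_matrix(cols).abs()
        # precondition: exactly the two within-pair correlations are strong
        assert rho.loc["tap_CL1", "tap_CL2"] >= 0.4
        assert rho.loc["exc_CL1", "exc_CL2"] >= 0.4
        assert rho.loc["tap_CL1", "exc_CL1"] < 0.4
        assert rho.loc["tap_CL2", "exc_CL2"] < 0.4
        selected, trace = screen_features(cols, labels)
        assert trace[0]["deleted"] == "tap_CL2"  # smallest |d| among the tied
        assert trace[0]["rule"] == "lower_effect_size"
        assert "tap_CL1" in selected

    def test_survivors_never_strongly_correlated(self, rng):
        base = rng.normal(size=(44, 3))
        cols = {}
        for i in range(12):
            cols[f"f{i}_CL{1 + i % 3}"] = base[:, i % 3] + rng.normal(0, 0.4, 44)
        labels = np.array(["MCI"] * 22 + ["OA"] * 22)
        selected, _ = screen_features(pd.DataFrame(cols), labels)
        assert 1 <= len(selected) <= 6
        if len(selected) > 1:
            rho = spearman_matrix(pd.DataFrame({k: cols[k] for k in selected})).abs()
            off = rho.values[~np.eye(len(rho), dtype=bool)]
            assert (off < 0.4).all()

    def test_max_components_capped_by_effect_size(self, rng):
        labels = np.array(["MCI"] * 22 + ["OA"] * 22)
        gap = np.where(labels == "MCI", 1.0, 0.0)
        cols = {}
        for i in range(8):
            cols[f"f{i}_CL1"] = rng.normal(0, 1, 44) * (1 + i) + gap * (8 - i)
        selected, trace = screen_features(pd.DataFrame(cols), labels)
        assert len(selected) <= 6

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            screen_features(pd.DataFrame(), np.array([]))


class TestOrientation:
    def test_mapped_feature_signs(self):
        col = pd.Series([1.0, -2.0])
        cfg = ScreeningConfig(orientation_map={"tap": +1, "exc_sd": -1})
        pd.testing.assert_series_equal(orient_higher_better(col, "tap", cfg), col)
        pd.testing.assert_series_equal(orient_higher_better(col, "exc_sd", cfg), -col)

    def test_unmapped_feature_rejected(self):
        cfg = ScreeningConfig(orientation_map={"tap": +1})
        with pytest.raises(KeyError):
            orient_higher_better(pd.Series([1.0]), "mystery", cfg)


class TestPooledScore:
    def test_single_column_is_its_normalisation(self):
        sel = pd.DataFrame({"a": [0.0, 5.0, 10.0]})
        np.testing.assert_allclose(pooled_score(sel), [0.0, 0.5, 1.0])

    def test_sample_max_everywhere_scores_one(self, rng):
        sel = pd.DataFrame(rng.normal(size=(10, 3)))
        sel.iloc[0] = sel.max() + 1.0
        assert pooled_score(sel).iloc[0] == pytest.approx(1.0)

    def test_mean_of_components(self):
        sel = pd.DataFrame({"a": [0.2, 0.0, 1.0], "b": [0.6, 0.0, 1.0]})
        # both columns already span [0, 1]
        assert pooled_score(sel).iloc[0] == pytest.approx(0.4)

    def test_affine_rescaling_of_component_is_absorbed(self, rng):
        sel = pd.DataFrame(rng.normal(size=(15, 2)), columns=["a", "b"])
        scaled = sel.copy()
        scaled["a"] = 100.0 * scaled["a"] + 7.0
        np.testing.assert_allclose(pooled_score(sel), pooled_score(scaled), atol=1e-12)

    def test_scores_in_unit_interval(self, rng):
        sel = pd.DataFrame(rng.normal(size=(20, 4)))
        s = pooled_score(sel)
        assert (s >= -1e-12).all() and (s <= 1 + 1e-12).all()
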