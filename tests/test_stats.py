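"""Inference layer: response magnitude, responder labels, Wilcoxon vs
enumeration, BH adjustment, Cliff's delta, OLS response models,
split-half reliability and the a-priori power computation."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sct

from brainheart.stats import (
    classify_responders,
    cliffs_delta,
    fdr_adjust,
    fit_response_models,
    power_sample_size,
    response_magnitude,
    spearman_brown,
    split_half_reliability,
    wilcoxon_signed_rank,
)


class TestResponseMagnitude:
    @pytest.mark.parametrize(
        "before,after,baseline,expected",
        [(40, 30, 40, 0.25), (35, 35, 50, 0.0), (30, 36, 40, -0.15)],
    )
    def test_direct_evaluation(self, before, after, baseline, expected):
        assert response_magnitude(before, after, baseline) == pytest.approx(expected)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            response_magnitude(40, 30, 0)


class TestClassify:
    def test_decrease_is_responsive_tie_is_not(self):
        df = pd.DataFrame({
            "participant": ["a", "b", "c"],
            "stai_before": [40, 40, 40],
            "stai_after": [35, 40, 45],
        })
        out = classify_responders(df)
        assert list(out["group"]) == ["responsive", "unresponsive", "unresponsive"]

    def test_missing_scores_excluded_with_log(self, caplog):
        df = pd.DataFrame({
            "participant": ["a", "b"],
            "stai_before": [40, np.nan],
            "stai_after": [35, 38],
        })
        with caplog.at_level("WARNING"):
            out = classify_responders(df)
        assert list(out["participant"]) == ["a"]
        assert "b" in caplog.text


class TestWilcoxon:
    def test_all_positive_differences_n5(self):
        res = wilcoxon_signed_rank([2, 3, 4, 5, 6], [1, 1, 1, 1, 1])
        assert res.w_plus == 15.0
        assert res.p == pytest.approx(0.0625)
        assert res.w_plus + res.w_minus == 15.0

    def test_exact_p_matches_full_enumeration(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        d = x - y
        ranks = sct.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = np.array([
            sum(r for s, r in zip(signs, ranks) if s)
            for signs in product([0, 1], repeat=12)
        ])
        p_enum = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
        res = wilcoxon_signed_rank(x, y)
        assert res.method == "exact"
        assert abs(res.p - min(1.0, p_enum)) < 1e-12

    def test_symmetric_alternating_differences(self):
        n = 6
        y = np.arange(n, dtype=float)
        x = y + np.where(np.arange(n) % 2 == 0, 0.5, -0.5)
        res = wilcoxon_signed_rank(x, y)
        assert res.w_plus == pytest.approx(n * (n + 1) / 4)
        assert res.p == pytest.approx(1.0)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        ours = wilcoxon_signed_rank(x, y)
        ref = sct.wilcoxon(x, y, mode="exact")
        assert abs(ours.p - ref.pvalue) < 1e-12

    def test_normal_approximation_for_large_n(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0.3, 1.0, size=40)
        y = rng.normal(0.0, 1.0, size=40)
        res = wilcoxon_signed_rank(x, y)
        assert res.method == "normal"
        ref = sct.wilcoxon(x, y, mode="approx", correction=False)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0] * 6, [1.0] * 6)


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_bh(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.04, 0.03, 0.005]),
            [0.02, 0.04, 0.04, 0.02],
        )

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_families_adjusted_independently(self):
        p = np.array([0.01, 0.02, 0.03, 0.5])
        joint = fdr_adjust(p)
        split = fdr_adjust(p, {"a": [0, 1], "b": [2, 3]})
        np.testing.assert_allclose(split[:2], fdr_adjust(p[:2]))
        np.testing.assert_allclose(split, [0.02, 0.02, 0.06, 0.5])
        assert not np.allclose(joint, split)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=12))
    def test_monotone_in_raw_p(self, ps):
        adj = fdr_adjust(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_null_uniform_fdr_controlled(self, rng):
        # under the global null, any BH rejection is a false discovery;
        # the family-wise false-discovery rate is at most alpha
        alpha, m, reps = 0.05, 10, 1000
        fdp = []
        for _ in range(reps):
            adj = fdr_adjust(rng.uniform(size=m))
            rejected = (adj <= alpha).sum()
            fdp.append(1.0 if rejected else 0.0)
        assert np.mean(fdp) <= alpha + 0.02


class TestCliffsDelta:
    def test_complete_dominance(self):
        d, ci = cliffs_delta([2, 3, 4], [1, 1, 1])
        assert d == 1.0

    def test_identical_samples_zero(self):
        d, _ = cliffs_delta([1, 2, 3], [1, 2, 3])
        assert d == 0.0

    def test_brute_force_pairs(self):
        d, _ = cliffs_delta([1, 3], [2, 4])
        assert d == pytest.approx(-0.5)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        x=st.lists(st.integers(0, 20), min_size=2, max_size=8),
        y=st.lists(st.integers(0, 20), min_size=2, max_size=8),
    )
    def test_antisymmetry(self, x, y):
        assert cliffs_delta(x, y)[0] == pytest.approx(-cliffs_delta(y, x)[0])

    def test_ci_brackets_delta(self, rng):
        x = rng.normal(0.5, 1.0, 20)
        y = rng.normal(0.0, 1.0, 25)
        d, (lo, hi) = cliffs_delta(x, y)
        assert -1 <= lo <= d <= hi <= 1


class TestResponseModels:
    def test_noiseless_affine_slope_recovered_exactly(self, rng):
        n = 27
        lfhf = rng.uniform(0, 1, n)
        df = pd.DataFrame({
            "delta_stai": 0.279 * lfhf + 0.05,
            "lf": rng.uniform(0, 1, n),
            "hf": rng.uniform(0, 1, n),
            "lf_hf": lfhf,
        })
        m = fit_response_models(df, {"cardiac": ["lf", "hf", "lf_hf"]})["cardiac"]
        assert m.coefficients[2] == pytest.approx(0.279, abs=1e-9)
        assert m.metadata["cohens_d_convention"] == "d = 2t/sqrt(df_resid)"

    def test_null_type_one_error_calibrated(self, rng):
        n, reps, alpha = 27, 1000, 0.05
        hits, total = 0, 0
        for _ in range(reps):
            df = pd.DataFrame({
                "delta_stai": rng.normal(size=n),
                "lf": rng.normal(size=n),
                "hf": rng.normal(size=n),
                "lf_hf": rng.normal(size=n),
            })
            m = fit_response_models(df, {"cardiac": ["lf", "hf", "lf_hf"]})["cardiac"]
            hits += (m.p_values < alpha).sum()
            total += m.p_values.size
        assert 0.03 <= hits / total <= 0.07

    def test_noisy_slope_unbiased(self, rng):
        k, n, reps = 0.3, 27, 200
        slopes = []
        for _ in range(reps):
            x = rng.uniform(0, 2, n)
            df = pd.DataFrame({
                "delta_stai": k * x + rng.normal(scale=0.1, size=n),
                "lf_hf": x,
            })
            m = fit_response_models(df, {"m": ["lf_hf"]})["m"]
            slopes.append(m.coefficients[0])
        mc_se = np.std(slopes) / np.sqrt(reps)
        assert abs(np.mean(slopes) - k) < 2 * mc_se + 1e-3

    def test_too_small_sample_rejected(self):
        df = pd.DataFrame({"delta_stai": [1, 2, 3], "lf": [1, 2, 3]})
        with pytest.raises(ValueError, match="too small"):
            fit_response_models(df, {"m": ["lf"]})

    def test_missing_predictor_named(self):
        df = pd.DataFrame({"delta_stai": np.arange(10.0), "lf": np.arange(10.0)})
        with pytest.raises(ValueError, match="hf"):
            fit_response_models(df, {"m": ["lf", "hf"]})


class TestReliability:
    def test_perfectly_stable_metric(self):
        data = {f"p{i}": np.full(10, float(i)) for i in range(6)}
        res = split_half_reliability(data)
        assert res.spearman_r == pytest.approx(1.0)
        assert res.spearman_brown == pytest.approx(1.0)

    @pytest.mark.parametrize("r,expected", [(0.5, 2 / 3), (0.0, 0.0), (1.0, 1.0)])
    def test_spearman_brown_closed_form(self, r, expected):
        assert spearman_brown(r) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(-0.99, 1.0))
    def test_spearman_brown_identity(self, r):
        sb = spearman_brown(r)
        assert sb == pytest.approx(2 * r / (1 + r))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="8"):
            split_half_reliability({"p": np.arange(4.0)})


class TestPower:
    @pytest.mark.parametrize("d,expected", [(0.6, 24), (1.0, 10), (0.5, 34)])
    def test_known_sample_sizes(self, d, expected):
        assert power_sample_size(d, 0.05, 0.8) == expected

    def test_invalid_effect_size_rejected(self):
        with pytest.raises(ValueError):
            power_sample_size(0.0)
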