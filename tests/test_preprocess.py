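import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micromediate.io import SampleMetadata, StudyData, TaxaTable
from micromediate.preprocess import (
    FilterConfig,
    PropensityMatcher,
    filter_taxa,
    fit_propensity,
    match_samples,
    match_study,
    overall_smd,
    replace_zeros,
    standardized_mean_difference,
)
from micromediate.synthetic import generate_study, preset


def _study(m, r=None, y=None, x=None):
    n = m.shape[0]
    ids = [f"s{i}" for i in range(n)]
    taxa = TaxaTable(ids, [f"t{j}" for j in range(m.shape[1])], m)
    frame = pd.DataFrame(
        {
            "exposure": r if r is not None else [i % 2 for i in range(n)],
            "outcome": y if y is not None else np.zeros(n),
        },
        index=ids,
    )
    cov = []
    if x is not None:
        frame["x1"] = x
        cov = ["x1"]
    return StudyData(taxa, SampleMetadata(frame, covariates=cov))


class TestFilterTaxa:
    def test_zero_thresholds_keep_all(self):
        m = np.full((6, 4), 0.25)
        out = filter_taxa(_study(m), FilterConfig(0.0, 0.0))
        assert out.n_taxa == 4

    def test_absent_taxon_removed(self):
        m = np.column_stack([np.full((6, 3), 1 / 3), np.zeros(6)])
        out = filter_taxa(_study(m), FilterConfig(prevalence_min=0.1, mean_abund_min=0))
        assert out.n_taxa == 3

    def test_prevalence_count(self):
        # one taxon present in only 2 of 6 samples
        m = np.full((6, 4), 0.25)
        m[:4, 3] = 0.0
        m = m / m.sum(axis=1, keepdims=True)
        out = filter_taxa(_study(m), FilterConfig(prevalence_min=0.5, mean_abund_min=0))
        assert out.n_taxa == 3

    def test_too_few_survivors(self):
        m = np.full((4, 3), 1 / 3)
        with pytest.raises(ValueError, match="loosen"):
            filter_taxa(_study(m), FilterConfig(prevalence_min=0, mean_abund_min=0.5))


class TestReplaceZeros:
    def test_zero_free_unchanged(self):
        m = np.full((4, 3), 1 / 3)
        data = _study(m)
        assert replace_zeros(data) is data

    def test_half_min_rule(self):
        m = np.array(
            [[0.0, 0.4, 0.6], [0.2, 0.3, 0.5], [0.1, 0.4, 0.5], [0.3, 0.3, 0.4]]
        )
        out = replace_zeros(_study(m), FilterConfig(zero_method="half_min"))
        expected = np.array([0.2, 0.4, 0.6])
        expected = expected / expected.sum()
        np.testing.assert_allclose(out.m[0], expected)
        np.testing.assert_allclose(out.m[1:], m[1:])

    @given(st.integers(0, 99))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_rows_positive_and_normalized(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((6, 4)) * (rng.random((6, 4)) > 0.4)
        m[m.sum(axis=1) == 0, 0] = 1.0
        m = m / m.sum(axis=1, keepdims=True)
        method = "half_min" if seed % 2 else "multiplicative_pseudo"
        out = replace_zeros(_study(m), FilterConfig(zero_method=method))
        assert (out.m > 0).all()
        np.testing.assert_allclose(out.m.sum(axis=1), 1.0, atol=1e-12)


class TestSMD:
    def test_identical_groups_zero(self):
        v = np.array([1.0, 2, 3, 1, 2, 3])
        g = np.array([1, 1, 1, 0, 0, 0])
        assert standardized_mean_difference(v, g) == pytest.approx(0.0)

    def test_unit_means_unit_sd(self, rng):
        v1 = rng.standard_normal(100000) + 1
        v0 = rng.standard_normal(100000)
        v = np.concatenate([v1, v0])
        g = np.concatenate([np.ones(100000), np.zeros(100000)])
        assert standardized_mean_difference(v, g) == pytest.approx(1.0, abs=0.02)

    def test_binary_hand_value(self):
        # p1 = 0.6, p0 = 0.4 -> 0.2 / sqrt((0.24 + 0.24) / 2) = 0.40825
        v = np.concatenate([np.repeat([1, 0], [6, 4]), np.repeat([1, 0], [4, 6])])
        g = np.concatenate([np.ones(10), np.zeros(10)])
        assert standardized_mean_difference(v, g) == pytest.approx(0.408248, abs=1e-5)

    def test_zero_variance_unequal_means_inf(self):
        v = np.array([1.0, 1, 0, 0])
        g = np.array([1, 1, 0, 0])
        assert np.isinf(standardized_mean_difference(v, g))

    def test_symmetric_and_affine_invariant(self, rng):
        v = rng.standard_normal(50)
        g = (rng.random(50) < 0.5).astype(int)
        if g.sum() in (0, 50):
            g[0] = 1 - g[0]
        s1 = standardized_mean_difference(v, g)
        s2 = standardized_mean_difference(v, 1 - g)
        s3 = standardized_mean_difference(3.5 * v - 2.0, g)
        assert s1 == pytest.approx(s2)
        assert s1 == pytest.approx(s3)


class TestPropensity:
    def test_constant_covariate_gives_group_share(self):
        frame = pd.DataFrame(
            {"exposure": [1, 1, 0, 0, 0], "outcome": np.zeros(5), "x1": np.ones(5)},
            index=list("abcde"),
        )
        meta = SampleMetadata(frame, covariates=["x1"])
        scores = fit_propensity(meta, ["x1"])
        np.testing.assert_allclose(scores, 0.4, atol=1e-4)

    def test_scores_in_open_interval(self, rng):
        x = rng.standard_normal(200)
        r = (rng.random(200) < 1 / (1 + np.exp(-2 * x))).astype(float)
        frame = pd.DataFrame(
            {"exposure": r, "outcome": np.zeros(200), "x1": x},
            index=[f"s{i}" for i in range(200)],
        )
        scores = fit_propensity(SampleMetadata(frame, covariates=["x1"]), ["x1"])
        assert np.all((scores > 0) & (scores < 1))

    def test_coefficient_recovery(self, rng):
        # logistic truth: intercept 0.3, slope -0.8
        n = 2000
        x = rng.standard_normal(n)
        p = 1 / (1 + np.exp(-(0.3 - 0.8 * x)))
        r = (rng.random(n) < p).astype(float)
        frame = pd.DataFrame(
            {"exposure": r, "outcome": np.zeros(n), "x1": x},
            index=[f"s{i}" for i in range(n)],
        )
        from micromediate.preprocess import _propensity_scores

        _, model = _propensity_scores(x[:, None], r)
        slope = model.coef_[0][0]
        # asymptotic SE is ~0.05 at this n; 3 SE band
        assert abs(slope - (-0.8)) < 3 * 0.06


class TestMatching:
    def _meta(self, scores_like, r, extra=None):
        n = len(r)
        frame = pd.DataFrame(
            {"exposure": r, "outcome": np.zeros(n), "x1": scores_like},
            index=[f"s{i}" for i in range(n)],
        )
        if extra is not None:
            frame["sex"] = extra
        cov = ["x1"]
        return SampleMetadata(frame, covariates=cov)

    def test_identical_samples_matched(self):
        meta = self._meta([0.3, 0.3, 0.9, 0.05], [1, 0, 1, 0])
        scores = np.array([0.3, 0.3, 0.9, 0.05])
        res = match_samples(meta, scores)
        assert ("s1", "s0") in res.matched_pairs

    def test_zero_caliper_all_distinct_no_pairs(self):
        meta = self._meta([0.2, 0.4, 0.6, 0.8], [1, 0, 1, 0])
        with pytest.warns(UserWarning, match="no admissible"):
            res = match_samples(meta, np.array([0.2, 0.4, 0.6, 0.8]), caliper=0.0)
        assert res.matched_pairs == []

    def test_no_sample_reused_and_pair_bound(self, rng):
        n = 60
        x = rng.standard_normal(n)
        r = (rng.random(n) < 0.4).astype(int)
        r[:2] = [0, 1]
        meta = self._meta(x, r)
        scores = fit_propensity(meta, ["x1"])
        res = match_samples(meta, scores, caliper=10.0)
        flat = [s for p in res.matched_pairs for s in p]
        assert len(flat) == len(set(flat))
        assert len(res.matched_pairs) <= min((r == 1).sum(), (r == 0).sum())

    def test_exact_stratum_respected(self):
        meta = self._meta([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0], extra=["m", "f", "f", "m"])
        scores = np.array([0.5] * 4)
        res = match_samples(meta, scores, exact_vars=["sex"])
        for comp, ref in res.matched_pairs:
            assert meta.frame.loc[comp, "sex"] == meta.frame.loc[ref, "sex"]

    def test_balance_improves_on_confounded_data(self):
        improved = balanced = 0
        for seed in range(15):
            data, _ = generate_study(preset("confounded", n_per_group=150, n_taxa=4, seed=seed))
            _, res = match_study(data, seed=seed)
            improved += res.overall_smd_after < res.overall_smd_before
            balanced += res.overall_smd_after < 0.1
        assert improved >= 14
        assert balanced >= 13


class TestPropensityMatcherEstimator:
    def test_sklearn_protocol(self, rng):
        from sklearn.base import clone

        x = rng.standard_normal((80, 2))
        r = (rng.random(80) < 1 / (1 + np.exp(-x[:, 0]))).astype(float)
        est = PropensityMatcher(caliper=1.0, random_state=3)
        est2 = clone(est)
        est2.fit(x, r)
        assert est2.propensity_.shape == (80,)
        sub = est2.transform(x)
        assert sub.shape[0] == len(est2.matched_indices_)
        assert est2.get_params()["caliper"] == 1.0


def test_filter_then_replace_composition_contract(rng):
    m = rng.random((20, 6)) * (rng.random((20, 6)) > 0.3)
    m[m.sum(axis=1) == 0, 0] = 1.0
    m = m / m.sum(axis=1, keepdims=True)
    data = _study(m)
    out = replace_zeros(filter_taxa(data, FilterConfig(0.1, 0.0)), FilterConfig())
    assert (out.m > 0).all()
    np.testing.assert_allclose(out.m.sum(axis=1), 1.0, atol=1e-10)


def test_overall_smd_is_mean_of_components(rng):
    x = rng.standard_normal((40, 3))
    g = np.array([1, 0] * 20)
    per = [standardized_mean_difference(x[:, i], g) for i in range(3)]
    assert overall_smd(x, g) == pytest.approx(np.mean(per))


def test_separation_falls_back_to_penalized_fit():
    from micromediate.preprocess import _propensity_scores

    x = np.concatenate([np.ones(20), -np.ones(20)])[:, None]
    r = np.concatenate([np.ones(20), np.zeros(20)])
    with pytest.warns(UserWarning, match="separat"):
        scores, model = _propensity_scores(x, r)
    assert np.all((scores > 0) & (scores < 1))
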