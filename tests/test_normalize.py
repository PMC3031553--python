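import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from seasight.errors import DomainError, FitError, ParameterError, StateError
from seasight.normalize import (
    NormexpParams,
    ValueVector,
    bg_subtract,
    dye_swap,
    interval_map_log,
    loess_ma,
    log_transform,
    ma_transform,
    map_identifiers,
    median_polish,
    normexp_correct,
    normexp_fit,
    quantile_normalize,
    scale_vectors,
    summarize,
)


def vec(values, scale="linear", ids=None):
    ids = ids or [f"f{i}" for i in range(len(values))]
    return ValueVector(pd.Series(list(values), index=ids, dtype=float), scale=scale)


class TestBgSubtract:
    def test_plain_subtraction(self):
        out = bg_subtract(vec([100]), vec([40]))
        assert out.values.iloc[0] == 60.0

    def test_floor_engages(self):
        out = bg_subtract(vec([10]), vec([50]), floor=0.5)
        assert out.values.iloc[0] == 0.5

    def test_zero_background_identity(self):
        out = bg_subtract(vec([5, 7, 9]), vec([0, 0, 0]))
        assert list(out.values) == [5.0, 7.0, 9.0]

    def test_log_input_rejected(self):
        with pytest.raises(StateError):
            bg_subtract(vec([1], scale="log"), vec([0], scale="log"))


class TestNormexpFit:
    def test_parameter_recovery_20_replicates(self):
        # simulation with known ground truth: alpha=100, mu=50, sigma=10
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            x = rng.exponential(100, 10**4) + rng.normal(50, 10, 10**4)
            params = normexp_fit(x)
            assert abs(params.alpha - 100) / 100 < 0.10
            assert abs(params.mu - 50) / 50 < 0.10
            assert abs(params.sigma - 10) / 10 < 0.10

    def test_pure_gaussian_flags_alpha_near_zero(self, caplog):
        rng = np.random.default_rng(1)
        x = rng.normal(50, 10, 5000)
        with caplog.at_level("WARNING"):
            try:
                params = normexp_fit(x)
            except FitError:
                return
        assert params.alpha < 0.5 * params.sigma or "alpha near zero" in caplog.text

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        x = rng.exponential(100, 5000) + rng.normal(50, 10, 5000)
        base = normexp_fit(x, refine=False)
        scaled = normexp_fit(3.0 * x, refine=False)
        assert scaled.alpha == pytest.approx(3 * base.alpha)
        assert scaled.mu == pytest.approx(3 * base.mu)
        assert scaled.sigma == pytest.approx(3 * base.sigma, rel=1e-6)

    def test_degenerate_input_rejected(self):
        with pytest.raises(FitError):
            normexp_fit(np.full(500, 7.0))

    def test_small_sample_warns(self, caplog):
        rng = np.random.default_rng(3)
        with caplog.at_level("WARNING"):
            normexp_fit(rng.exponential(100, 50) + rng.normal(0, 1, 50))
        assert "noisy" in caplog.text


class TestNormexpCorrect:
    PARAMS = NormexpParams(alpha=100.0, mu=50.0, sigma=10.0)

    def test_positivity(self):
        x = vec(np.linspace(0, 300, 50))
        out = normexp_correct(x, self.PARAMS)
        assert (out.values > 0).all()

    def test_monotone(self):
        x = vec(np.linspace(0, 500, 200))
        out = normexp_correct(x, self.PARAMS).values.to_numpy()
        assert (np.diff(out) > 0).all()

    def test_noiseless_limit(self):
        params = NormexpParams(alpha=100.0, mu=0.0, sigma=1e-4)
        x = np.array([200.0, 500.0, 1000.0])
        out = normexp_correct(vec(x), params).values.to_numpy()
        assert np.allclose(out, x, rtol=1e-3)

    def test_quadrature_oracle(self):
        # numeric conditional expectation under the convolution density
        alpha, mu, sigma = 80.0, 40.0, 12.0
        params = NormexpParams(alpha, mu, sigma)
        xs = np.linspace(10.0, 400.0, 20)
        closed = normexp_correct(vec(xs), params).values.to_numpy()
        for x, got in zip(xs, closed):
            def signal_density(s):
                return np.exp(-s / alpha) / alpha * stats.norm.pdf(x - s, mu, sigma)

            # integrand is a narrow bump near s = x - mu; keep it inside a
            # finite interval with an explicit breakpoint
            upper = x + 20 * sigma
            bump = [min(max(x - mu, 0.0), upper)]
            num, _ = integrate.quad(lambda s: s * signal_density(s), 0, upper,
                                    points=bump, limit=200)
            den, _ = integrate.quad(signal_density, 0, upper, points=bump, limit=200)
            assert got == pytest.approx(num / den, rel=1e-6, abs=1e-6)

    def test_invalid_params(self):
        with pytest.raises(DomainError):
            NormexpParams(alpha=-1.0, mu=0.0, sigma=1.0)


class TestQuantile:
    def test_hand_computed_rank_means(self):
        out = quantile_normalize([vec([2, 6]), vec([4, 8])])
        assert list(out[0].values) == [3.0, 7.0]
        assert list(out[1].values) == [3.0, 7.0]

    def test_identical_vectors_fixed_point(self):
        v = vec([5, 1, 9, 3])
        out = quantile_normalize([v, vec([5, 1, 9, 3])])
        assert list(out[0].values) == [5.0, 1.0, 9.0, 3.0]

    def test_sorted_outputs_identical(self):
        rng = np.random.default_rng(4)
        vectors = [vec(rng.lognormal(3, 1, 1000)) for _ in range(6)]
        out = quantile_normalize(vectors)
        reference = np.sort(out[0].values.to_numpy())
        for v in out[1:]:
            assert np.allclose(np.sort(v.values.to_numpy()), reference)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        vectors = [vec(rng.normal(0, 1, 500)) for _ in range(4)]
        once = quantile_normalize(vectors)
        twice = quantile_normalize(once)
        for a, b in zip(once, twice):
            assert np.abs(a.values.to_numpy() - b.values.to_numpy()).max() < 1e-12

    def test_ties_get_mean_of_spanned_ranks(self):
        out = quantile_normalize([vec([1, 1, 10]), vec([2, 4, 6])])
        # tied rank 1.5 -> mean of target ranks 1 and 2
        target = np.sort(np.vstack([[1, 1, 10], [2, 4, 6]]).T, axis=0).mean(axis=1)
        expected = (target[0] + target[1]) / 2
        assert out[0].values.iloc[0] == pytest.approx(expected)
        assert out[0].values.iloc[1] == pytest.approx(expected)

    def test_reference_mode(self):
        ref = vec([10, 20, 30])
        out = quantile_normalize([vec([5, 1, 3])], reference=ref)
        assert list(out[0].values) == [30.0, 10.0, 20.0]

    def test_unequal_feature_sets_rejected(self):
        with pytest.raises(ParameterError):
            quantile_normalize([vec([1, 2]), vec([1, 2], ids=["x", "y"])])


class TestScale:
    def test_hand_computed_average(self):
        out = scale_vectors([vec([10, 10]), vec([30, 30])], mode="average")
        assert out[0].values.mean() == pytest.approx(20.0)
        assert out[1].values.mean() == pytest.approx(20.0)

    def test_single_vector_unchanged(self):
        out = scale_vectors([vec([3, 5, 7])])
        assert list(out[0].values) == [3.0, 5.0, 7.0]

    def test_all_means_equal_grand_mean(self):
        rng = np.random.default_rng(6)
        vectors = [vec(rng.lognormal(2, 1, 300)) for _ in range(5)]
        grand = np.mean([v.values.mean() for v in vectors])
        out = scale_vectors(vectors, mode="average")
        for v in out:
            assert v.values.mean() == pytest.approx(grand)

    def test_percentile_mode(self):
        rng = np.random.default_rng(7)
        vectors = [vec(rng.lognormal(2, 1, 300)) for _ in range(3)]
        out = scale_vectors(vectors, mode="percentile", p=75)
        p75 = [np.percentile(v.values, 75) for v in out]
        assert np.allclose(p75, p75[0])

    def test_zero_statistic_rejected(self):
        with pytest.raises(DomainError):
            scale_vectors([vec([0, 0]), vec([1, 1])])


class TestLoessMA:
    def test_constant_bias_removed(self):
        rng = np.random.default_rng(8)
        green = rng.lognormal(6, 1, 500)
        red = 3.0 * green
        m, a = loess_ma(vec(red), vec(green), span=0.5)
        assert np.abs(m.values.to_numpy()).max() < 1e-6
        assert a.scale == "log"

    def test_banana_bias_removed(self):
        rng = np.random.default_rng(9)
        n = 2000
        a_true = rng.uniform(4, 14, n)
        bias = 0.5 * (a_true - 9) ** 2 / 10  # curved M = f(A) trend
        m_true = bias + rng.normal(0, 0.1, n)
        green = np.power(2.0, a_true - m_true / 2)
        red = np.power(2.0, a_true + m_true / 2)
        m, a = loess_ma(vec(red), vec(green), span=0.3)
        r = np.corrcoef(m.values.to_numpy(), a.values.to_numpy())[0, 1]
        assert abs(r) < 0.05

    def test_printtip_blocks_centered(self):
        rng = np.random.default_rng(10)
        n = 600
        ids = [f"f{i}" for i in range(n)]
        blocks = pd.Series([1] * (n // 2) + [2] * (n // 2), index=ids)
        green = rng.lognormal(6, 0.5, n)
        factor = np.where(np.arange(n) < n // 2, 4.0, 0.25)  # opposite biases
        red = factor * green
        m, _ = loess_ma(vec(red, ids=ids), vec(green, ids=ids), span=0.6, printtip=blocks)
        m_values = m.values.to_numpy()
        assert abs(np.median(m_values[: n // 2])) < 0.05
        assert abs(np.median(m_values[n // 2:])) < 0.05

    def test_small_block_falls_back_global(self, caplog):
        rng = np.random.default_rng(11)
        n = 50
        ids = [f"f{i}" for i in range(n)]
        blocks = pd.Series([1] * 45 + [2] * 5, index=ids)
        green = rng.lognormal(6, 0.5, n)
        with caplog.at_level("WARNING"):
            loess_ma(vec(2 * green, ids=ids), vec(green, ids=ids), printtip=blocks)
        assert "global fit" in caplog.text

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(DomainError):
            ma_transform(vec([0.0, 1.0]), vec([1.0, 1.0]))


class TestMATransforms:
    def test_ma_values(self):
        m, a = ma_transform(vec([8.0]), vec([2.0]))
        assert m.values.iloc[0] == pytest.approx(2.0)  # log2(8/2)
        assert a.values.iloc[0] == pytest.approx(2.0)  # 0.5*log2(16)

    def test_dye_swap_involution(self):
        m = vec([1.5, -0.5, 2.0], scale="log")
        assert list(dye_swap(dye_swap(m)).values) == list(m.values)


class TestSummarize:
    def frame(self, matrix, probes, experiments):
        return pd.DataFrame(matrix, index=probes, columns=experiments)

    def test_median_polish_hand_example(self):
        # hand-traced: overall 2.5, column effects (-0.5, +0.5)
        table = self.frame([[1.0, 2.0], [3.0, 4.0]], ["p1", "p2"], ["e1", "e2"])
        groups = pd.Series({"p1": "g", "p2": "g"})
        out = summarize(table, groups, method="median_polish")
        assert list(out.loc["g"]) == [2.0, 3.0]

    def test_single_probe_group_all_methods(self):
        table = self.frame([[1.5, 2.5]], ["p1"], ["e1", "e2"])
        groups = pd.Series({"p1": "g"})
        for method in ("mean", "median", "median_polish"):
            out = summarize(table, groups, method=method)
            assert list(out.loc["g"]) == [1.5, 2.5]

    def test_residual_medians_vanish(self):
        rng = np.random.default_rng(12)
        matrix = rng.normal(10, 2, (11, 6))
        overall, rows, cols, resid = median_polish(matrix, tol=1e-9, max_iter=50)
        assert np.abs(np.median(resid, axis=0)).max() < 1e-9
        assert np.abs(np.median(resid, axis=1)).max() < 1e-9

    def test_probe_affinity_absorbed_into_row_effect(self):
        # Raising the affinity of the already-strongest probe leaves the
        # median of the row effects untouched, so the summarized values are
        # exactly unchanged.  (Shifting a pivotal row would move that median
        # and with it the overall level — the absorption is robust, not
        # unconditional.)
        rng = np.random.default_rng(13)
        matrix = rng.normal(8, 1, (7, 4))
        table = self.frame(matrix, [f"p{i}" for i in range(7)], list("abcd"))
        groups = pd.Series({f"p{i}": "g" for i in range(7)})
        base = summarize(table, groups, method="median_polish")
        strongest = table.median(axis=1).idxmax()
        shifted = table.copy()
        shifted.loc[strongest] += 5.0  # constant added to one probe row
        out = summarize(shifted, groups, method="median_polish")
        assert np.abs(out.loc["g"] - base.loc["g"]).max() < 1e-9

    def test_mean_and_median(self):
        table = self.frame([[1.0, 4.0], [3.0, 8.0]], ["p1", "p2"], ["e1", "e2"])
        groups = pd.Series({"p1": "g", "p2": "g"})
        assert list(summarize(table, groups, "mean").loc["g"]) == [2.0, 6.0]
        assert list(summarize(table, groups, "median").loc["g"]) == [2.0, 6.0]


class TestValueTransforms:
    def test_log2_with_offset(self):
        out = log_transform(vec([0.0, 1.0, 3.0]), offset=1.0)
        assert list(out.values) == [0.0, 1.0, 2.0]
        assert out.scale == "log"

    def test_interval_map_endpoints(self):
        out = interval_map_log(vec([0.0, 10.0, 100.0]), lo=0.0, hi=16.0)
        assert out.values.iloc[0] == pytest.approx(0.0)
        assert out.values.iloc[-1] == pytest.approx(16.0)

    def test_interval_map_constant_vector(self, caplog):
        with caplog.at_level("WARNING"):
            out = interval_map_log(vec([5.0, 5.0]), lo=2.0, hi=16.0)
        assert list(out.values) == [2.0, 2.0]

    def test_interval_map_shared_range(self):
        shared = (0.0, np.log2(101.0))
        out = interval_map_log(vec([100.0]), lo=0.0, hi=16.0, shared_range=shared)
        assert out.values.iloc[0] == pytest.approx(16.0)

    def test_map_identifiers_mean_aggregation(self):
        v = vec([1.0, 2.0, 3.0], ids=["p1", "p2", "p3"])
        out = map_identifiers(v, {"p1": "g", "p2": "g", "p3": "g"})
        assert out.values["g"] == 2.0

    def test_map_identifiers_identity(self):
        v = vec([1.0, 2.0])
        out = map_identifiers(v, None)
        assert list(out.values) == [1.0, 2.0]


class TestRmaChain:
    def test_gene_ranking_recovered(self):
        # full chain on synthetic probe data with known per-gene signal
        from seasight.synth import StudyDesign, ground_truth, probeset_map, synth_array

        design = StudyDesign(genes=200, probes_per_gene=11, seed=42)
        truth = ground_truth(design)
        tables = [synth_array(design, 0, r, truth=truth)[0] for r in range(2)]
        pmap = probeset_map(design)
        vectors = []
        for table in tables:
            observed = ValueVector(table.fg["ch1"])
            params = normexp_fit(observed)
            vectors.append(normexp_correct(observed, params))
        vectors = quantile_normalize(vectors)
        logged = [log_transform(v, offset=1.0) for v in vectors]
        frame = pd.DataFrame({f"e{i}": v.values for i, v in enumerate(logged)})
        groups = pd.Series(pmap.mapping)
        summarized = summarize(frame, groups, method="median_polish")
        estimate = summarized.mean(axis=1)
        true_signal = truth.expression[0].reindex(estimate.index)
        rho = stats.spearmanr(estimate, true_signal).statistic
        assert rho >= 0.95
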