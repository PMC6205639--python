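"""Systematic Monte Carlo replication and its brute-force cross-checks."""

import numpy as np
import pytest

from quadcount import (
    BoundingBox,
    GridParams,
    PointPattern,
    exact_mean_oracle,
    generate,
    params_from_fraction,
    resample,
    sweep,
    systematic_offsets,
)


class TestSystematicOffsets:
    def test_single_replicate_degenerates_to_one_uniform_offset(self):
        z = systematic_offsets(T=50.0, K=1, rng=0)
        assert z.shape == (1, 2)
        assert ((0 <= z) & (z < 50.0)).all()

    def test_subgrid_size_and_range(self):
        z = systematic_offsets(T=64.0, K=32, rng=1)
        assert z.shape == (1024, 2)
        assert ((0 <= z) & (z < 64.0)).all()
        assert len(np.unique(z.round(9), axis=0)) == 1024

    def test_subgrid_regularity(self):
        """All offsets coincide modulo the subgrid step T/K."""
        T, K = 60.0, 8
        z = systematic_offsets(T=T, K=K, rng=2)
        residues = z % (T / K)
        assert np.allclose(residues, residues[0], atol=1e-9)

    def test_rejects_bad_K(self):
        with pytest.raises(ValueError):
            systematic_offsets(T=10.0, K=0)


class TestResample:
    def test_full_fraction_has_zero_error(self, bbox, uniform_pattern):
        result = resample(uniform_pattern, GridParams(t=40, T=40, theta=30), K=8, rng=0)
        assert np.all(result.estimates == uniform_pattern.N)
        assert result.variance == 0.0
        assert result.ce == 0.0

    def test_rejects_empty_pattern(self, bbox):
        empty = PointPattern(np.empty((0, 2)), bbox)
        with pytest.raises(ValueError):
            resample(empty, GridParams(t=10, T=50), K=4, rng=0)

    def test_reproducible_under_seed(self, bbox, uniform_pattern):
        params = params_from_fraction(0.04, 100, bbox)
        a = resample(uniform_pattern, params, K=8, rng=11)
        b = resample(uniform_pattern, params, K=8, rng=11)
        assert np.array_equal(a.Q_k, b.Q_k) and a.ce2 == b.ce2

    def test_single_point_matches_bernoulli_closed_form(self, bbox):
        """A lone particle is captured with probability f, so CE^2 = (1-f)/f.

        The K = 32 subgrid discretizes the offset integral; averaging over a
        few subgrid shifts removes most of that quantization.
        """
        f = 0.04
        params = params_from_fraction(f, 100, bbox, theta=30.0)
        point = PointPattern(np.array([[321.0, 210.0]]), bbox)
        ce2 = np.mean([resample(point, params, K=32, rng=s).ce2 for s in range(10)])
        assert point.N == 1
        assert ce2 == pytest.approx((1 - f) / f, rel=0.15)

    @pytest.mark.parametrize("kind", ["uniform", "gradient", "clustered", "lattice"])
    def test_mean_sample_size_is_f_N(self, bbox, kind):
        N, f = 500, 0.04
        pattern = generate(kind, N, bbox=bbox, seed=N)
        params = params_from_fraction(f, 100, bbox)
        result = resample(pattern, params, K=32, rng=3)
        se = result.Q_k.std() / result.K  # conservative MC error of the mean
        assert abs(result.mean_Q - f * N) <= max(3 * se, 1e-9)

    def test_independent_offsets_also_unbiased(self, bbox, uniform_pattern):
        params = params_from_fraction(0.04, 100, bbox)
        result = resample(uniform_pattern, params, K=32, rng=4, independent=True)
        se = result.estimates.std() / result.K
        assert abs(result.mean - uniform_pattern.N) <= 3 * se

    def test_subgrid_more_efficient_than_independent_for_mean(self, bbox, uniform_pattern):
        """The stratified subgrid pins E_e closer to N than i.i.d. offsets."""
        params = params_from_fraction(0.04, 100, bbox)
        sys_err = [
            abs(resample(uniform_pattern, params, K=16, rng=s).mean - uniform_pattern.N)
            for s in range(8)
        ]
        ind_err = [
            abs(
                resample(uniform_pattern, params, K=16, rng=s, independent=True).mean
                - uniform_pattern.N
            )
            for s in range(8)
        ]
        assert np.mean(sys_err) < np.mean(ind_err)


class TestExactMeanOracle:
    def test_full_fraction_is_exactly_N(self, bbox, uniform_pattern):
        params = GridParams(t=40, T=40, theta=30)
        assert exact_mean_oracle(uniform_pattern, params, M=50) == pytest.approx(
            uniform_pattern.N
        )

    def test_single_point_integral(self, bbox):
        """Midpoint integration of one indicator: |result - 1| < 0.02 at M = 500."""
        params = params_from_fraction(0.04, 100, bbox, theta=0.0)
        point = PointPattern(np.array([[100.0, 100.0]]), bbox)
        assert abs(exact_mean_oracle(point, params, M=500) - 1.0) < 0.02

    def test_agrees_with_resampling(self, bbox):
        """Two independent implementations of E(N_hat) must coincide."""
        rng = np.random.default_rng(8)
        for kind in ["uniform", "clustered"]:
            pattern = generate(kind, 300, bbox=bbox, seed=17)
            params = params_from_fraction(0.05, 80, bbox, theta=30.0)
            result = resample(pattern, params, K=32, rng=rng)
            oracle = exact_mean_oracle(pattern, params, M=400)
            se = result.estimates.std() / result.K
            assert abs(result.mean - oracle) <= 3 * se + 0.01 * pattern.N


class TestSweep:
    def test_single_cell_consistent_with_resample(self, bbox, uniform_pattern):
        table = sweep({"u1120": uniform_pattern}, [(0.04, 100.0)], K=16, rng=5)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["pattern"] == "u1120" and row["N"] == 1120
        assert row["mean_Q"] == pytest.approx(0.04 * 1120, rel=0.15)
        assert row["E_e"] == pytest.approx(1120, rel=0.1)
        assert row["CE_e"] == pytest.approx(np.sqrt(row["CE2_e"]))
        assert row["error"] == ""

    def test_full_settings_grid_shape(self, bbox):
        patterns = {
            "a": generate("uniform", 200, bbox=bbox, seed=1),
            "b": generate("gradient", 200, bbox=bbox, seed=2),
        }
        settings = [(f, n0) for n0 in (50.0, 100.0) for f in (0.02, 0.04, 0.06)]
        table = sweep(patterns, settings, K=8, rng=6)
        assert len(table) == 12
        assert set(table["pattern"]) == {"a", "b"}
        assert (table["error"] == "").all()

    def test_failing_cell_is_flagged_not_fatal(self, bbox):
        patterns = {
            "ok": generate("uniform", 100, bbox=bbox, seed=1),
            "empty": PointPattern(np.empty((0, 2)), bbox),
        }
        table = sweep(patterns, [(0.04, 100.0)], K=4, rng=7)
        assert len(table) == 2
        errors = dict(zip(table["pattern"], table["error"]))
        assert errors["ok"] == ""
        assert "N = 0" in errors["empty"]

    def test_rejects_empty_inputs(self, bbox, uniform_pattern):
        with pytest.raises(ValueError):
            sweep({}, [(0.04, 100.0)])
        with pytest.raises(ValueError):
            sweep({"u": uniform_pattern}, [])
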