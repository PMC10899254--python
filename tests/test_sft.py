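"""Random-Forest space-for-time diagnostic: components and bootstrap."""

import numpy as np
import pandas as pd
import pytest

from mbcwarm import (
    RandomForestMBC,
    SFTBootstrap,
    WorldSimConfig,
    change_rate,
    coverage_mask_dissimilarity,
    coverage_mask_mahalanobis,
    generate_world,
    predict_global_series,
    spatial_slope,
)
from mbcwarm.sft import dissimilarity_index, fit_mbc_model

from conftest import gaussian_predictor_frame


class TestSpatialSlope:
    def test_exact_linear_relationship(self, small_world):
        _, obs, _ = small_world
        df = obs.copy()
        df["mbc"] = 100 - 8 * df["temperature"]
        assert spatial_slope(df) == pytest.approx(-8.0, abs=1e-10)

    def test_row_order_invariance(self, small_world):
        _, obs, _ = small_world
        shuffled = obs.sample(frac=1.0, random_state=0)
        assert spatial_slope(shuffled) == pytest.approx(spatial_slope(obs), rel=1e-12)

    def test_generator_recovery_over_seeds(self):
        slopes = [
            spatial_slope(
                generate_world(WorldSimConfig(n_cells=1500, n_obs=762, spatial_slope_true=-8.0, seed=s))[0]
            )
            for s in range(5)
        ]
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) + 8.0) < 3 * max(se, 0.1)

    def test_constant_temperature_rejected(self, small_world):
        _, obs, _ = small_world
        df = obs.copy()
        df["temperature"] = 5.0
        with pytest.raises(ValueError):
            spatial_slope(df)


class TestRandomForest:
    def test_constant_target_predicts_constant(self, small_world):
        _, obs, grid = small_world
        df = obs.copy()
        df["mbc"] = 77.0
        model = fit_mbc_model(df, seed=0, n_trees=20)
        pred = model.predict(grid.predictors_for_year(1992))
        assert np.allclose(pred, 77.0)

    def test_beats_mean_prediction_in_bag(self, small_world):
        _, obs, _ = small_world
        model = fit_mbc_model(obs, seed=0, n_trees=50)
        pred = model.predict(obs)
        mbc = obs["mbc"].to_numpy()
        sse = np.sum((mbc - pred) ** 2)
        sst = np.sum((mbc - mbc.mean()) ** 2)
        assert sse < sst

    def test_same_seed_bit_identical(self, small_world):
        _, obs, grid = small_world
        p1 = fit_mbc_model(obs, seed=5, n_trees=25).predict(grid.predictors_for_year(2000))
        p2 = fit_mbc_model(obs, seed=5, n_trees=25).predict(grid.predictors_for_year(2000))
        assert np.array_equal(p1, p2)

    def test_single_landcover_class_still_fits(self, small_world):
        _, obs, _ = small_world
        df = obs.copy()
        df["land_cover"] = "forest"  # fixed global encoding keeps columns aligned
        model = fit_mbc_model(df, seed=0, n_trees=10)
        assert np.isfinite(model.predict(obs)).all()


class TestGlobalSeries:
    def test_time_invariant_grid_gives_flat_series(self, small_world):
        _, obs, grid = small_world
        import copy

        frozen = copy.deepcopy(grid)
        frozen.temperature = np.repeat(frozen.temperature[:, :1], 22, axis=1)
        model = fit_mbc_model(obs, seed=1, n_trees=20)
        totals = predict_global_series(model, frozen)
        assert np.allclose(totals, totals[0])

    def test_mask_locality(self, small_world):
        _, obs, grid = small_world
        model = fit_mbc_model(obs, seed=1, n_trees=20)
        rng = np.random.default_rng(0)
        m1 = rng.random(grid.n_cells) < 0.7
        m2 = rng.random(grid.n_cells) < 0.7
        shared = m1 & m2
        assert np.allclose(
            predict_global_series(model, grid, shared),
            predict_global_series(model, grid, shared),
        )
        # totals over a submask equal the sum restricted to those cells
        t_all = predict_global_series(model, grid, m1)
        t_shared = predict_global_series(model, grid, shared)
        assert (t_shared <= t_all + 1e-9).all()

    def test_empty_mask_rejected(self, small_world):
        _, obs, grid = small_world
        model = fit_mbc_model(obs, seed=1, n_trees=5)
        with pytest.raises(ValueError, match="empty"):
            predict_global_series(model, grid, np.zeros(grid.n_cells, dtype=bool))

    def test_negative_spatial_training_predicts_decline(self, small_world):
        """The space-for-time artifact at component level."""
        _, obs, grid = small_world
        declines = 0
        for s in range(3):
            model = fit_mbc_model(obs, seed=s, n_trees=40)
            totals = predict_global_series(model, grid)
            declines += totals[-1] < totals[0]
        assert declines >= 2


class TestChangeRate:
    def test_constant_series_zero(self):
        rate, se = change_rate(np.full(22, 123.4))
        assert rate == pytest.approx(0.0, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_linear_series(self):
        years = np.arange(1992, 2014)
        totals = 100.0 * (1 - 0.00162 * (years - 1992))
        rate, _ = change_rate(totals, years)
        assert rate == pytest.approx(-0.162, rel=1.8e-2)  # linearization of the denominator
        rate_init, _ = change_rate(totals, years, denominator="initial")
        assert rate_init == pytest.approx(-0.162, rel=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        totals = 50 + rng.normal(0, 2, 22)
        r1, _ = change_rate(totals)
        r2, _ = change_rate(totals * 37.5)
        assert r2 == pytest.approx(r1, rel=1e-12)


class TestMasks:
    def test_centroid_always_valid(self, small_world):
        _, obs, _ = small_world
        centroid = obs.iloc[:1].copy()
        for c in obs.columns:
            if c not in ("land_cover", "cell_id", "mbc"):
                centroid[c] = obs[c].mean()
        assert coverage_mask_mahalanobis(obs, centroid, quantile=0.5)[0]

    def test_mask_monotone_in_quantile(self, small_world):
        _, obs, grid = small_world
        base = grid.predictors_for_year(1992)
        prev = None
        for q in (0.5, 0.8, 0.95, 0.999):
            mask = coverage_mask_mahalanobis(obs, base, quantile=q)
            if prev is not None:
                assert (mask | ~prev).all()  # supersets as q grows
            prev = mask

    def test_same_distribution_valid_fraction_near_quantile(self):
        rng = np.random.default_rng(8)
        train = gaussian_predictor_frame(rng, 800)
        grid = gaussian_predictor_frame(rng, 4000)
        frac = coverage_mask_mahalanobis(train, grid, quantile=0.9).mean()
        assert frac == pytest.approx(0.9, abs=0.03)

    def test_di_zero_for_coincident_point(self, small_world):
        _, obs, _ = small_world
        di, thr = dissimilarity_index(obs, obs.iloc[[3]])
        assert di[0] == pytest.approx(0.0, abs=1e-12)
        assert thr > 0

    def test_di_exclusion_monotone_in_shift(self, small_world):
        _, obs, grid = small_world
        base = grid.predictors_for_year(1992)
        fracs = []
        for shift in (0.0, 10.0, 25.0, 60.0):
            shifted = base.copy()
            shifted["temperature"] = shifted["temperature"] + shift
            fracs.append(coverage_mask_dissimilarity(obs, shifted).mean())
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] < fracs[0]

    def test_di_degenerate_training_rejected(self, small_world):
        _, obs, _ = small_world
        one = obs.iloc[[0]]
        with pytest.raises(ValueError):
            dissimilarity_index(one, obs)


@pytest.fixture(scope="module")
def tiny_boot(small_world):
    _, obs, grid = small_world
    return SFTBootstrap(obs, grid, m=120, reps=8, n_trees=15)


class TestBootstrap:
    def test_determinism_and_m_rows(self, tiny_boot):
        r1 = tiny_boot.fit(seed=3)
        r2 = tiny_boot.fit(seed=3)
        pd.testing.assert_frame_equal(r1.per_rep, r2.per_rep)
        r3 = tiny_boot.fit(seed=4)
        assert not r1.per_rep["change_rate"].equals(r3.per_rep["change_rate"])

    def test_with_replacement_unique_fraction(self, small_world):
        _, obs, grid = small_world
        n, m = len(obs), 120
        boot = SFTBootstrap(obs, grid, m=m, reps=12, n_trees=5)
        res = boot.fit(seed=0)
        expected = n * (1 - (1 - 1 / n) ** m)
        observed = res.per_rep["n_unique"].mean()
        assert observed == pytest.approx(expected, rel=0.08)

    def test_change_rate_unit_invariance(self, small_world):
        """Rescaling MBC units leaves the %/yr rate unchanged up to the
        floating-point sensitivity of near-tied tree splits; the slope
        scales exactly with the units."""
        _, obs, grid = small_world
        scaled = obs.copy()
        scaled["mbc"] = scaled["mbc"] * 1000.0
        a = SFTBootstrap(obs, grid, m=100, reps=6, n_trees=10).fit(seed=1)
        b = SFTBootstrap(scaled, grid, m=100, reps=6, n_trees=10).fit(seed=1)
        assert b.per_rep["spatial_slope"].to_numpy() == pytest.approx(
            1000.0 * a.per_rep["spatial_slope"].to_numpy(), rel=1e-9
        )
        ra, rb = a.mean_change_rate, b.mean_change_rate
        assert np.sign(ra) == np.sign(rb)
        assert rb == pytest.approx(ra, rel=0.3)

    def test_shared_mask_mode(self, small_world):
        _, obs, grid = small_world
        res = SFTBootstrap(obs, grid, m=100, reps=4, n_trees=10, shared_mask=True).fit(seed=2)
        assert res.per_rep["coverage_fraction"].nunique() == 1

    def test_dissimilarity_mask_mode_runs(self, small_world):
        _, obs, grid = small_world
        res = SFTBootstrap(
            obs, grid, m=100, reps=3, n_trees=10, mask_method="dissimilarity"
        ).fit(seed=2)
        assert ((res.per_rep["coverage_fraction"] > 0) & (res.per_rep["coverage_fraction"] <= 1)).all()

    def test_config_validation(self, small_world):
        _, obs, grid = small_world
        with pytest.raises(ValueError):
            SFTBootstrap(obs, grid, reps=1)
        with pytest.raises(ValueError):
            SFTBootstrap(obs, grid, mask_method="nope")
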