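import numpy as np
import pytest
from scipy.stats import chisquare

from conftest import make_grid
from corridorscape.errors import (
    ConfigurationError,
    DegenerateWeightsError,
    MissingLayerError,
)
from corridorscape.synthetic import (
    EnvStackSpec,
    NicheSpec,
    corridor_cell_mask,
    default_bias,
    generate_env_stack,
    sample_occurrences,
    study_specs,
    true_suitability,
)


def spec_no_noise(**kw):
    base = dict(n_rows=12, n_cols=10, cell_size_deg=1.0)
    base.update(kw)
    s = EnvStackSpec(**base)
    for name in s.layer_names:
        s.noise_sd[name] = 0.0
    return s


def flat_niche(optimum, **kw):
    return NicheSpec(optimum_by_month=[optimum] * 12, **kw)


class TestGenerateEnvStack:
    def test_no_noise_no_amplitude_gives_identical_months(self):
        s = spec_no_noise()
        s.seasonal_amplitude = {n: 0.0 for n in s.layer_names}
        first = generate_env_stack(s, 1)["avg_temperature"].values
        for month in range(2, 13):
            np.testing.assert_array_equal(
                generate_env_stack(s, month)["avg_temperature"].values, first
            )

    def test_row_gradient_is_exact(self):
        s = spec_no_noise()
        g = s.spatial_gradient["avg_temperature"]
        t = generate_env_stack(s, 4)["avg_temperature"].values
        np.testing.assert_allclose(np.diff(t, axis=0), g, atol=1e-12)

    def test_seasonal_cycle_peaks_in_july(self):
        s = spec_no_noise()
        means = [generate_env_stack(s, m)["avg_temperature"].values.mean()
                 for m in range(1, 13)]
        assert int(np.argmax(means)) + 1 == 7

    def test_same_seed_is_bit_identical(self):
        s1 = EnvStackSpec(n_rows=8, n_cols=8, seed=42)
        s2 = EnvStackSpec(n_rows=8, n_cols=8, seed=42)
        a = generate_env_stack(s1, 5)
        b = generate_env_stack(s2, 5)
        for name in s1.layer_names:
            np.testing.assert_array_equal(a[name].values, b[name].values)

    def test_static_layers_do_not_change_across_months(self):
        s = EnvStackSpec(n_rows=8, n_cols=8, seed=3)
        jan = generate_env_stack(s, 1)["elevation"].values
        jul = generate_env_stack(s, 7)["elevation"].values
        np.testing.assert_array_equal(jan, jul)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ConfigurationError):
            EnvStackSpec(n_rows=2, n_cols=10)
        with pytest.raises(ConfigurationError):
            EnvStackSpec(cell_size_deg=0.0)


class TestTrueSuitability:
    def test_kernel_maximum_at_optimum(self):
        s = spec_no_noise()
        s.spatial_gradient["avg_temperature"] = 0.0
        s.seasonal_amplitude["avg_temperature"] = 0.0
        base = s.base_level["avg_temperature"]
        stack = generate_env_stack(s, 1)
        suit = true_suitability(stack, flat_niche(base), 1)
        np.testing.assert_allclose(suit.values, 1.0)

    def test_kernel_value_one_tolerance_away(self):
        # exp(-0.5) at T = optimum + tolerance
        s = spec_no_noise()
        s.spatial_gradient["avg_temperature"] = 0.0
        s.seasonal_amplitude["avg_temperature"] = 0.0
        base = s.base_level["avg_temperature"]
        stack = generate_env_stack(s, 1)
        suit = true_suitability(stack, flat_niche(base + 2.0, tolerance=2.0), 1)
        np.testing.assert_allclose(suit.values, np.exp(-0.5))

    def test_zero_boost_is_independent_of_corridor(self):
        s = spec_no_noise()
        stack = generate_env_stack(s, 6)
        niche_a = flat_niche(10.0, corridor_boost=0.0)
        niche_b = flat_niche(
            10.0,
            corridor_boost=0.0,
            corridor_polyline=((4.5, 0.0), (4.5, 12.0)),
        )
        np.testing.assert_array_equal(
            true_suitability(stack, niche_a, 6).values,
            true_suitability(stack, niche_b, 6).values,
        )

    def test_missing_temperature_layer_raises(self):
        s = spec_no_noise()
        stack = generate_env_stack(s, 6)
        del stack["avg_temperature"]
        with pytest.raises(MissingLayerError):
            true_suitability(stack, flat_niche(10.0), 6)

    def test_corridor_cells_exceed_background_at_equal_temperature(self):
        s = spec_no_noise()
        s.spatial_gradient["avg_temperature"] = 0.0
        s.seasonal_amplitude["avg_temperature"] = 0.0
        stack = generate_env_stack(s, 1)
        line = ((-95.5, 38.0), (-95.5, 50.0))
        niche = flat_niche(5.0, corridor_boost=0.3, corridor_polyline=line)
        suit = true_suitability(stack, niche, 1)
        inside = corridor_cell_mask(suit, line, niche.corridor_width_cells)
        assert inside.any() and (~inside).any()
        assert suit.values[inside].mean() > suit.values[~inside].mean()

    def test_suitability_bounded_in_unit_interval(self):
        env, niche = study_specs(n_rows=20, n_cols=20)
        for month in (1, 6, 11):
            suit = true_suitability(generate_env_stack(env, month), niche, month)
            assert np.nanmin(suit.values) >= 0.0
            assert np.nanmax(suit.values) <= niche.max_suitability

    def test_moving_optimum_shifts_argmax_row_linearly(self):
        # optimum moving north by k rows/month moves the suitability peak with it
        s = spec_no_noise(n_rows=30, n_cols=6)
        s.seasonal_amplitude = {n: 0.0 for n in s.layer_names}
        base = s.base_level["avg_temperature"]
        g = s.spatial_gradient["avg_temperature"]
        k = 2
        r0 = 25
        optima = [base + g * (r0 - k * (m - 1)) for m in range(1, 13)]
        niche = NicheSpec(optimum_by_month=optima, tolerance=0.5)
        for m in (1, 4, 8, 12):
            suit = true_suitability(generate_env_stack(s, m), niche, m)
            argmax_row = int(np.argmax(suit.values.max(axis=1)))
            assert argmax_row == r0 - k * (m - 1)


class TestSampleOccurrences:
    def test_degenerate_distribution_puts_all_points_in_one_cell(self):
        vals = np.zeros((5, 5))
        vals[2, 3] = 1.0
        suit = make_grid(vals)
        occ = sample_occurrences(suit, 20, None, seed=0, month=6)
        rows_cols = {suit.cell_of(lon, lat) for lon, lat in zip(occ["lon"], occ["lat"])}
        assert rows_cols == {(2, 3)}

    def test_uniform_suitability_gives_uniform_multinomial_counts(self):
        suit = make_grid(np.ones((10, 10)))
        occ = sample_occurrences(suit, 10_000, None, seed=7, month=6)
        counts = np.zeros(100)
        for lon, lat in zip(occ["lon"], occ["lat"]):
            r, c = suit.cell_of(lon, lat)
            counts[r * 10 + c] += 1
        assert chisquare(counts).pvalue > 0.001

    def test_same_seed_gives_identical_tables(self):
        suit = make_grid(np.random.default_rng(0).random((6, 6)))
        a = sample_occurrences(suit, 30, default_bias(suit), seed=5, month=2)
        b = sample_occurrences(suit, 30, default_bias(suit), seed=5, month=2)
        assert a.equals(b)

    def test_all_zero_weights_raise(self):
        suit = make_grid(np.zeros((4, 4)))
        with pytest.raises(DegenerateWeightsError):
            sample_occurrences(suit, 5, None, seed=0, month=1)

    def test_points_fall_within_their_cells(self):
        suit = make_grid(np.ones((4, 4)), cell_size=0.5, origin_lon=10.0, origin_lat=3.0)
        occ = sample_occurrences(suit, 200, None, seed=1, month=9)
        assert ((occ["lon"] >= 10.0) & (occ["lon"] <= 12.0)).all()
        assert ((occ["lat"] >= 1.0) & (occ["lat"] <= 3.0)).all()
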