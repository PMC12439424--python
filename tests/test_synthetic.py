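"""Synthetic landscape generator: determinism, masks, truth surfaces, sampling."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import spearmanr

import sdmrisk as s
from sdmrisk.synthetic import standardize_layer


class TestGenerateEnvStack:
    def test_same_seed_bit_identical(self, small_spec):
        a = s.generate_env_stack(small_spec)
        b = s.generate_env_stack(small_spec)
        for name in a.names:
            np.testing.assert_array_equal(a.layers[name], b.layers[name])
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_different_seed_differs(self, small_spec, small_stack):
        other = s.generate_env_stack(
            s.LandscapeSpec(n_rows=30, n_cols=40, n_layers=12, seed=8,
                            mask_fraction=0.1))
        assert not np.allclose(other.layers[other.names[0]],
                               small_stack.layers[small_stack.names[0]],
                               equal_nan=True)

    def test_full_registry_layer_count(self):
        stack = s.generate_env_stack(s.LandscapeSpec(n_rows=12, n_cols=12,
                                                     n_layers=45, seed=0))
        assert stack.n_layers == 45
        assert stack.names[0] == "bio1" and "water1500" in stack.names

    def test_zero_mask_fraction_means_no_nodata(self):
        stack = s.generate_env_stack(s.LandscapeSpec(n_rows=12, n_cols=12,
                                                     n_layers=3, seed=1))
        assert stack.mask.all()

    def test_mask_fraction_respected(self, small_spec, small_stack):
        frac = 1 - small_stack.mask.mean()
        assert frac == pytest.approx(small_spec.mask_fraction, abs=0.02)

    def test_correlated_groups_exist(self, small_stack):
        # members 2 and 3 of a latent group are strong mutual proxies
        a = small_stack.layers[small_stack.names[1]]
        b = small_stack.layers[small_stack.names[2]]
        m = small_stack.mask
        r = np.corrcoef(a[m], b[m])[0, 1]
        assert abs(r) > 0.75

    @pytest.mark.parametrize("kwargs", [
        dict(n_rows=0, n_cols=10), dict(n_rows=5, n_cols=5),
        dict(n_rows=20, n_cols=20, smoothing_length=0.0),
        dict(n_rows=20, n_cols=20, mask_fraction=1.0),
        dict(n_rows=20, n_cols=20, n_layers=0),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            s.LandscapeSpec(**kwargs)


class TestTruthSuitability:
    def test_null_model_gives_half(self, small_stack):
        suit = s.truth_suitability(small_stack, s.TruthModel())
        assert np.allclose(suit.values[small_stack.mask], 0.5)
        assert np.isnan(suit.values[~small_stack.mask]).all()

    def test_extreme_negative_intercept_vanishes(self, small_stack):
        suit = s.truth_suitability(small_stack, s.TruthModel(intercept=-50))
        assert np.all(suit.values[small_stack.mask] < 1e-15)

    def test_monotone_single_term_matches_scalar_oracle(self, small_stack):
        name = small_stack.names[0]
        model = s.TruthModel(terms=((name, "increasing", (1.7,)),))
        suit = s.truth_suitability(small_stack, model)
        m = small_stack.mask
        # independent cellwise recomputation through a scalar inverse-logit
        z = standardize_layer(small_stack, name)[m]
        expected = np.array([expit(1.7 * zi) for zi in z])
        np.testing.assert_allclose(suit.values[m], expected, rtol=1e-12)
        rho = spearmanr(small_stack.layers[name][m], suit.values[m]).statistic
        assert rho == pytest.approx(1.0)

    def test_bounded_and_nodata_propagated(self, truth_and_suitability,
                                           small_stack):
        _, suit = truth_and_suitability
        vals = suit.values[small_stack.mask]
        assert np.all((vals >= 0) & (vals <= 1))
        assert np.isnan(suit.values[~small_stack.mask]).all()

    def test_missing_layer_rejected(self, small_stack):
        model = s.TruthModel(terms=(("nope", "increasing", (1.0,)),))
        with pytest.raises(KeyError):
            s.truth_suitability(small_stack, model)

    def test_unimodal_needs_negative_quadratic(self):
        with pytest.raises(ValueError):
            s.TruthModel(terms=(("x", "unimodal", (1.0, 0.5)),))
        with pytest.raises(ValueError):
            s.TruthModel(noise_sd=-1)


class TestSampleOccurrences:
    def test_degenerate_support_forces_cell(self):
        vals = np.zeros((5, 5))
        vals[2, 3] = 0.8
        suit = s.RasterGrid(vals)
        occ = s.sample_occurrences(suit, 1, seed=0)
        np.testing.assert_allclose(occ.points, [[3.5, 2.5]])

    def test_exhaustive_uniform_draw_covers_every_cell(self):
        suit = s.RasterGrid(np.full((4, 4), 0.5))
        occ = s.sample_occurrences(suit, 16, seed=1)
        assert len({tuple(p) for p in occ.points}) == 16

    def test_sampling_weights_match_probabilities(self):
        # 0.9 / 0.1 two-cell grid: high-cell frequency ~0.90 over many seeds
        suit = s.RasterGrid(np.array([[0.9, 0.1]]))
        hits = sum(
            s.sample_occurrences(suit, 1, seed=k).points[0, 0] < 1.0
            for k in range(10_000))
        assert hits / 10_000 == pytest.approx(0.90, abs=0.01)

    def test_insufficient_positive_cells(self):
        suit = s.RasterGrid(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            s.sample_occurrences(suit, 1, seed=0)

    def test_deterministic_per_seed(self, truth_and_suitability):
        _, suit = truth_and_suitability
        a = s.sample_occurrences(suit, 20, seed=3)
        b = s.sample_occurrences(suit, 20, seed=3)
        np.testing.assert_array_equal(a.points, b.points)


class TestMakeFutureStack:
    def test_identity_deltas_identity_output(self, small_stack):
        sc = s.ScenarioSpec(deltas={n: (0.0, 1.0) for n in small_stack.names})
        out = s.make_future_stack(small_stack, sc, seed=0)
        for n in small_stack.names:
            np.testing.assert_allclose(out.layers[n], small_stack.layers[n])

    def test_additive_shift_moves_mean_exactly(self, small_stack):
        name = small_stack.names[0]
        sc = s.ScenarioSpec(deltas={name: (2.0, 1.0)})
        out = s.make_future_stack(small_stack, sc, seed=0)
        assert (np.nanmean(out.layers[name]) - np.nanmean(small_stack.layers[name])
                == pytest.approx(2.0, abs=1e-9))
        # untouched layers pass through
        np.testing.assert_array_equal(out.layers[small_stack.names[1]],
                                      small_stack.layers[small_stack.names[1]])

    def test_unknown_layer_and_bad_factor_rejected(self, small_stack):
        with pytest.raises(KeyError):
            s.make_future_stack(small_stack,
                                s.ScenarioSpec(deltas={"nope": (0, 1)}), 0)
        with pytest.raises(ValueError):
            s.ScenarioSpec(deltas={"bio1": (0.0, -1.0)})

    def test_mask_preserved(self, small_stack):
        sc = s.default_scenarios(small_stack)[0]
        out = s.make_future_stack(small_stack, sc, seed=1, perturbation_sd=0.1)
        np.testing.assert_array_equal(out.mask, small_stack.mask)


def test_gcm_member_average_exact_oracle(small_stack):
    """Averaging n members equals the cellwise mean of the member fields."""
    from sdmrisk.synthetic import _smooth_field
    import numpy as np
    name = small_stack.names[0]
    sc = s.ScenarioSpec(deltas={name: (1.0, 1.1)}, n_gcm_members=3)
    out = s.make_future_stack(small_stack, sc, seed=21, perturbation_sd=0.3)
    # independent recomputation of each member from the spawned seeds
    arr = small_stack.layers[name]
    sd = np.nanstd(arr)
    members = []
    for ss in np.random.SeedSequence(21).spawn(3):
        rng = np.random.default_rng(ss)
        new = arr * 1.1 + 1.0 + 0.3 * sd * _smooth_field(rng, small_stack.shape, 4.0)
        new[~small_stack.mask] = np.nan
        members.append(new)
    np.testing.assert_allclose(out.layers[name], np.mean(members, axis=0))
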