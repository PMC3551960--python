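import numpy as np
import pytest

from rangeshift.envelope import (
    EnvelopeModel,
    fit_envelope,
    predict_envelope,
    trapezoid_suitability,
)
from rangeshift.grids import GridError, GridSpec
from rangeshift.occurrences import PresenceGrid, aggregate_to_grid
from rangeshift.synthetic import VirtualSpecies, sample_occurrences

from conftest import stack_from_arrays


def row_stack(values_by_var, label="1985"):
    """A 1 x n grid whose cells carry the given per-variable values."""
    n = len(next(iter(values_by_var.values())))
    spec = GridSpec(50.0, 50.5, 0.0, 0.5 * n, 0.5)
    return spec, stack_from_arrays(spec, label, **{k: np.array([v], dtype=float) for k, v in values_by_var.items()})


def all_present(spec, species="sp"):
    return PresenceGrid(spec=spec, present=np.ones(spec.shape, bool), species=species,
                        n_records=spec.n_lat * spec.n_lon)


class TestTrapezoid:
    def test_shape(self):
        trap = (8.0, 9.0, 11.0, 12.0)
        assert trapezoid_suitability(10.0, trap) == 1.0
        assert trapezoid_suitability(8.5, trap) == pytest.approx(0.5)  # halfway up left ramp
        assert trapezoid_suitability(11.5, trap) == pytest.approx(0.5)
        assert trapezoid_suitability(7.9, trap) == 0.0
        assert trapezoid_suitability(12.1, trap) == 0.0
        assert np.isnan(trapezoid_suitability(np.nan, trap))

    def test_degenerate_step(self):
        trap = (9.0, 9.0, 9.0, 9.0)
        assert trapezoid_suitability(9.0, trap) == 1.0
        assert trapezoid_suitability(9.0001, trap) == 0.0


class TestFit:
    def test_percentile_oracle_five_values(self):
        """10th/90th percentiles of {8..12} by linear interpolation: 8.4 / 11.6."""
        spec, env = row_stack({"sst": [8.0, 9.0, 10.0, 11.0, 12.0]})
        model = fit_envelope(all_present(spec), env, percentiles=(10, 90), buffer_fraction=0.0)
        assert model.trapezoids["sst"] == pytest.approx((8.0, 8.4, 11.6, 12.0))

    def test_buffer_widens_absolute_limits(self):
        spec, env = row_stack({"sst": [8.0, 9.0, 10.0, 11.0, 12.0]})
        model = fit_envelope(all_present(spec), env, buffer_fraction=0.1)
        width = 11.6 - 8.4
        assert model.trapezoids["sst"][0] == pytest.approx(8.0 - 0.1 * width)
        assert model.trapezoids["sst"][3] == pytest.approx(12.0 + 0.1 * width)

    def test_constant_variable_degenerate_trapezoid(self):
        spec, env = row_stack({"sst": [9.0] * 5})
        model = fit_envelope(all_present(spec), env)
        assert model.trapezoids["sst"] == pytest.approx((9.0, 9.0, 9.0, 9.0))
        suit = predict_envelope(model, env)
        np.testing.assert_allclose(suit.values, 1.0)
        spec2, env2 = row_stack({"sst": [9.5] * 5})
        np.testing.assert_allclose(predict_envelope(model, env2).values, 0.0)

    def test_too_few_presences_rejected(self):
        spec, env = row_stack({"sst": [8.0, 9.0, 10.0]})
        with pytest.raises(GridError, match=">= 5"):
            fit_envelope(all_present(spec), env)

    def test_json_round_trip(self):
        spec, env = row_stack({"sst": [8.0, 9.0, 10.0, 11.0, 12.0]})
        model = fit_envelope(all_present(spec), env)
        back = EnvelopeModel.from_json(model.to_json())
        assert back.trapezoids["sst"] == pytest.approx(model.trapezoids["sst"])
        assert back.combination_rule == model.combination_rule


class TestPredict:
    def test_midpoint_full_suitability_and_product_annihilation(self):
        model = EnvelopeModel(
            species="sp",
            trapezoids={"sst": (8.0, 9.0, 11.0, 12.0), "sbt": (5.0, 6.0, 8.0, 9.0)},
            combination_rule="product",
        )
        spec, env = row_stack({"sst": [10.0, 13.0], "sbt": [7.0, 7.0]})
        suit = predict_envelope(model, env)
        assert suit.values[0, 0] == 1.0  # both at preference midpoint
        assert suit.values[0, 1] == 0.0  # sst beyond max_abs annihilates the product

    def test_half_ramp_with_other_variable_preferred(self):
        model = EnvelopeModel(
            species="sp",
            trapezoids={"sst": (8.0, 9.0, 11.0, 12.0), "sbt": (5.0, 6.0, 8.0, 9.0)},
            combination_rule="product",
        )
        spec, env = row_stack({"sst": [8.5] * 2, "sbt": [7.0] * 2})
        assert predict_envelope(model, env).values[0, 0] == pytest.approx(0.5)

    def test_missing_variable_layer_rejected(self):
        model = EnvelopeModel(species="sp", trapezoids={"sst": (8, 9, 11, 12)})
        spec, env = row_stack({"sbt": [7.0] * 2})
        with pytest.raises(GridError, match="missing|no layer"):
            predict_envelope(model, env)

    def test_geometric_mean_scale(self):
        model = EnvelopeModel(
            species="sp",
            trapezoids={"sst": (8.0, 9.0, 11.0, 12.0), "sbt": (5.0, 6.0, 8.0, 9.0)},
            combination_rule="geometric_mean",
        )
        spec, env = row_stack({"sst": [8.5], "sbt": [7.0]})
        assert predict_envelope(model, env).values[0, 0] == pytest.approx(np.sqrt(0.5))


class TestRecoveryAndEquivariance:
    def test_parameter_recovery_from_noise_free_samples(self):
        """Fitting 500 samples from a known envelope recovers the preferred
        range within 0.5 * sd(variable) / sqrt(n) of the truth.

        The true trapezoid is calibrated so its 10th/90th percentile under
        the (uniform-density) SST gradient sit exactly at pref_min/pref_max.
        """
        spec = GridSpec(40.0, 60.0, 0.0, 2.5, 0.05)  # 400 x 50 fine grid
        lat = spec.lat_centers[:, None] * np.ones((1, spec.n_lon))
        sst = 25.0 - (lat - 40.0)  # 25 -> 5 degC, uniform density over cells
        env = stack_from_arrays(spec, "1985", sst=sst)
        truth = (9.5, 10.0, 12.0, 12.5)  # ramp mass is 10% on each side
        sp = VirtualSpecies(name="calib", true_envelope={"sst": truth})
        n = 500
        occ = sample_occurrences(sp, env, n=n, seed=42)
        presence = aggregate_to_grid(occ, spec)
        model = fit_envelope(presence, env, percentiles=(10, 90), variables=["sst"])
        tol = 0.5 * np.std(sst) / np.sqrt(n)
        assert model.trapezoids["sst"][1] == pytest.approx(truth[1], abs=tol)
        assert model.trapezoids["sst"][2] == pytest.approx(truth[2], abs=tol)

    def test_training_presences_mostly_suitable(self, noise_free_scenario, virtual_species):
        baseline, _ = noise_free_scenario
        occ = sample_occurrences(virtual_species, baseline, n=400, seed=5)
        presence = aggregate_to_grid(occ, baseline.spec)
        model = fit_envelope(presence, baseline, variables=["sst", "sbt"])
        suit = predict_envelope(model, baseline)
        frac_positive = np.mean(suit.values[presence.present] > 0)
        assert frac_positive >= 0.95

    def test_shift_equivariance_under_poleward_translation(self, noise_free_scenario, virtual_species):
        """Translating every layer k cells poleward translates the predicted map."""
        baseline, _ = noise_free_scenario
        k = 3
        spec = baseline.spec
        shifted = stack_from_arrays(
            spec, "future", **{v: np.roll(baseline[v].values, k, axis=0) for v in baseline.layers}
        )
        occ = sample_occurrences(virtual_species, baseline, n=400, seed=6)
        model = fit_envelope(aggregate_to_grid(occ, spec), baseline, variables=["sst", "sbt"])
        pred_base = predict_envelope(model, baseline).values
        pred_shift = predict_envelope(model, shifted).values
        np.testing.assert_allclose(pred_shift[k:], np.roll(pred_base, k, axis=0)[k:], atol=1e-12)
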