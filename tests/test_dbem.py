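import numpy as np
import pytest

from rangeshift.dbem import (
    DBEMParams,
    DBEMState,
    PreferenceProfile,
    build_env_series,
    carrying_capacity,
    derive_profiles,
    run_dbem,
    step_dbem,
)
from rangeshift.grids import GridError, GridSpec, SuitabilityMap
from rangeshift.metrics import latitudinal_centroid

from conftest import stack_from_arrays


def gradient_env(spec=None, lo=5.0, hi=15.0, label="1985"):
    spec = spec or GridSpec(50.0, 60.0, 0.0, 5.0, 0.5)
    lat = spec.lat_centers[:, None] * np.ones((1, spec.n_lon))
    frac = (lat - lat.min()) / (lat.max() - lat.min())
    sst = hi - (hi - lo) * frac
    return spec, stack_from_arrays(spec, label, sst=sst)


class TestProfiles:
    def test_uniform_seed_over_band_gives_indicator_profile(self):
        spec, env = gradient_env()
        sst = env["sst"].values
        seed_vals = ((sst >= 9.0) & (sst <= 11.0)).astype(float)
        smap = SuitabilityMap(spec=spec, values=seed_vals)
        (profile,) = derive_profiles(smap, env, n_bins=5, variables=["sst"])
        centers = 0.5 * (profile.bin_edges[:-1] + profile.bin_edges[1:])
        inside = (centers >= 9.0) & (centers <= 11.0)
        assert np.all(profile.suitability[inside] > 0.9)
        assert np.all(profile.suitability[~inside] < 0.35)

    def test_single_positive_cell(self):
        spec, env = gradient_env()
        vals = np.zeros(spec.shape)
        vals[5, 3] = 1.0
        (profile,) = derive_profiles(SuitabilityMap(spec=spec, values=vals), env, 10, ["sst"])
        assert (profile.suitability == 1.0).sum() == 1
        assert (profile.suitability == 0.0).sum() == 9

    def test_one_bin_is_flat(self):
        spec, env = gradient_env()
        vals = np.random.default_rng(0).random(spec.shape)
        (profile,) = derive_profiles(SuitabilityMap(spec=spec, values=vals), env, 1, ["sst"])
        np.testing.assert_allclose(profile.suitability, [1.0])

    def test_all_zero_seed_rejected(self):
        spec, env = gradient_env()
        with pytest.raises(GridError, match="no positive"):
            derive_profiles(SuitabilityMap(spec=spec, values=np.zeros(spec.shape)), env, 5, ["sst"])


class TestCarryingCapacity:
    def _profile(self, var, suits):
        return PreferenceProfile(var, np.linspace(0, 1, len(suits) + 1), np.asarray(suits))

    def test_max_bins_give_K_scale(self):
        spec = GridSpec(0, 0.5, 0, 0.5, 0.5)
        env = stack_from_arrays(spec, "x", a=[[0.25]], b=[[0.75]])
        profiles = [self._profile("a", [1.0, 0.5]), self._profile("b", [0.5, 1.0])]
        K = carrying_capacity(profiles, env, K_scale=3.0)
        assert K[0, 0] == pytest.approx(3.0)

    def test_zero_bin_annihilates(self):
        spec = GridSpec(0, 0.5, 0, 0.5, 0.5)
        env = stack_from_arrays(spec, "x", a=[[0.25]], b=[[0.75]])
        profiles = [self._profile("a", [1.0, 0.5]), self._profile("b", [1.0, 0.0])]
        assert carrying_capacity(profiles, env)[0, 0] == 0.0

    def test_geometric_mean_of_two(self):
        spec = GridSpec(0, 0.5, 0, 0.5, 0.5)
        env = stack_from_arrays(spec, "x", a=[[0.25]], b=[[0.75]])
        profiles = [self._profile("a", [1.0, 0.5]), self._profile("b", [0.5, 0.25])]
        assert carrying_capacity(profiles, env)[0, 0] == pytest.approx(0.5)  # sqrt(1 * 0.25)

    def test_value_outside_bins_is_zero_not_error(self):
        spec = GridSpec(0, 0.5, 0, 0.5, 0.5)
        env = stack_from_arrays(spec, "x", a=[[5.0]])
        assert carrying_capacity([self._profile("a", [1.0])], env)[0, 0] == 0.0


class TestStep:
    def test_homogeneous_equilibrium_is_fixed_point(self):
        shape = (6, 6)
        sea = np.ones(shape, bool)
        K = np.full(shape, 0.8)
        state = DBEMState(2000, K.copy(), K, sea)
        out = step_dbem(state, K, DBEMParams())
        np.testing.assert_allclose(out.abundance, K, atol=1e-12)
        assert out.year == 2001

    def test_no_dispersal_matches_scalar_logistic_oracle(self):
        shape = (3, 3)
        sea = np.ones(shape, bool)
        K = np.full(shape, 1.0)
        A = np.zeros(shape)
        A[1, 1] = 0.1
        params = DBEMParams(intrinsic_growth=0.4, dispersal_fraction=0.0)
        state = DBEMState(2000, A, K, sea)
        a = 0.1
        prev = a
        for _ in range(30):
            state = step_dbem(state, K, params)
            a = a + 0.4 * a * (1 - a)  # independent scalar recursion
            assert state.abundance[1, 1] == pytest.approx(a, rel=1e-12)
            assert state.abundance[1, 1] >= prev  # monotone approach to K
            prev = state.abundance[1, 1]
        assert state.abundance[1, 1] == pytest.approx(1.0, abs=1e-3)

    def test_pure_dispersal_conserves_mass_with_land(self):
        rng = np.random.default_rng(3)
        shape = (12, 12)
        sea = rng.random(shape) > 0.25  # ragged coastline
        A = np.where(sea, rng.random(shape), 0.0)
        K = np.where(sea, 1.0, 0.0)
        params = DBEMParams(intrinsic_growth=0.0, dispersal_fraction=0.4)
        state = DBEMState(2000, A.copy(), K, sea)
        total0 = A[sea].sum()
        for _ in range(25):
            state = step_dbem(state, K, params)
            assert state.abundance[sea].sum() == pytest.approx(total0, rel=1e-9)
            assert np.all(state.abundance >= 0)

    def test_zero_K_cells_decay(self):
        shape = (2, 2)
        sea = np.ones(shape, bool)
        K = np.zeros(shape)
        A = np.full(shape, 1.0)
        state = step_dbem(DBEMState(2000, A, K, sea), K, DBEMParams(intrinsic_growth=0.5, dispersal_fraction=0.0))
        np.testing.assert_allclose(state.abundance, 0.5)


class TestRun:
    def test_constant_environment_stays_at_capacity_without_dispersal(self):
        spec, env = gradient_env()
        sst = env["sst"].values
        seed_vals = ((sst >= 8.0) & (sst <= 12.0)).astype(float)
        smap = SuitabilityMap(spec=spec, values=seed_vals)
        params = DBEMParams(dispersal_fraction=0.0, start_year=1985, end_year=2005)
        end, traj = run_dbem(smap, lambda year: env, params, variables=["sst"])
        assert abs(traj.centroid_lat[-1] - traj.centroid_lat[0]) < 1e-6
        profiles = derive_profiles(smap, env, params.n_bins, ["sst"])
        K = carrying_capacity(profiles, env)
        np.testing.assert_allclose(end.values, K / K.max(), atol=1e-9)

    def test_constant_environment_total_abundance_converges(self):
        spec, env = gradient_env()
        vals = np.random.default_rng(1).random(spec.shape)
        smap = SuitabilityMap(spec=spec, values=vals)
        params = DBEMParams(start_year=1985, end_year=2035)
        _end, traj = run_dbem(smap, lambda year: env, params, variables=["sst"])
        tail = np.abs(np.diff(traj.total_abundance[-10:]))
        head = np.abs(np.diff(traj.total_abundance[:10]))
        assert tail.max() < 1e-3 or tail.max() < head.max() / 100

    def test_poleward_forcing_shift_bounded_by_forcing(self):
        """A 2-cell poleward isotherm shift moves the centroid poleward by
        between 0 and 2 cells."""
        spec, baseline = gradient_env()
        shift_deg = 1.0  # 2 cells at 0.5 deg
        grad_per_deg = 10.0 / (spec.lat_centers[-1] - spec.lat_centers[0])
        future = stack_from_arrays(
            spec, "2050", sst=baseline["sst"].values + shift_deg * grad_per_deg
        )
        sst = baseline["sst"].values
        seed_vals = ((sst >= 8.0) & (sst <= 12.0)).astype(float)
        smap = SuitabilityMap(spec=spec, values=seed_vals)
        series = build_env_series(baseline, future, 1985, 2050)
        params = DBEMParams(dispersal_fraction=0.3, start_year=1985, end_year=2050)
        _end, traj = run_dbem(smap, series, params, variables=["sst"])
        drift = traj.centroid_lat[-1] - traj.centroid_lat[0]
        assert 0.0 < drift <= shift_deg + 1e-9

    def test_end_equals_start_returns_normalized_K(self):
        spec, env = gradient_env()
        vals = np.random.default_rng(2).random(spec.shape)
        smap = SuitabilityMap(spec=spec, values=vals)
        params = DBEMParams(start_year=1985, end_year=1985)
        end, traj = run_dbem(smap, lambda year: env, params, variables=["sst"])
        profiles = derive_profiles(smap, env, params.n_bins, ["sst"])
        K = carrying_capacity(profiles, env)
        np.testing.assert_allclose(end.values, K / K.max())
        assert traj.years == [1985]


class TestEnvSeries:
    def test_linear_interpolation_and_clamping(self):
        spec, baseline = gradient_env(label="1985")
        future = stack_from_arrays(spec, "2050", sst=baseline["sst"].values + 1.3)
        series = build_env_series(baseline, future, 1985, 2050)
        mid = series(1985 + 65 // 2)
        expected = baseline["sst"].values + 1.3 * (65 // 2) / 65
        np.testing.assert_allclose(mid["sst"].values, expected)
        np.testing.assert_array_equal(series(1971)["sst"].values, baseline["sst"].values)
        np.testing.assert_array_equal(series(2099)["sst"].values, future["sst"].values)
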