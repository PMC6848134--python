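import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from carbfact import synthetic_world as sw
from carbfact.evaluation import anomaly_summary, evaluation_domain
from carbfact.factory_model import (
    FactoryParams,
    combine,
    default_params,
    load_params,
    occurrence,
    predict,
    save_params,
    seasonal_input,
    susceptibility,
    temperature_domains,
)
from carbfact.grid_io import FACTORY_CODES, Grid, build_masks
from carbfact.membership import MembershipSpec

from conftest import make_env


class TestSeasonalInput:
    def test_rules(self):
        env = make_env(28.0, 24.0)
        assert seasonal_input(env, "SST", "mean_of_seasons").values[0, 0] == 26.0
        assert seasonal_input(env, "SST", "warm_season").values[0, 0] == 28.0
        assert seasonal_input(env, "SST", "cool_season").values[0, 0] == 24.0

    def test_class_means_stay_fractional(self):
        env = make_env(28.0, 24.0, sss_class=5.0, sss_class_winter=6.0)
        assert seasonal_input(env, "SSS_class", "mean_of_seasons").values[0, 0] == 5.5

    def test_product_rule_not_a_field(self):
        env = make_env(28.0, 24.0)
        with pytest.raises(ValueError, match="inside susceptibility"):
            seasonal_input(env, "SST", "product_of_two_specs")


class TestParams:
    def test_defaults_valid_and_one_background(self, params_all):
        backgrounds = [f for f, p in params_all.items() if p.background]
        assert backgrounds == ["heterozoan_C"]
        for p in params_all.values():
            assert sum(p.weights) == pytest.approx(1.0, abs=1e-9)
            assert 0.0 < p.final_threshold < 1.0

    def test_weights_off_simplex_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            FactoryParams(
                name="bad", sst=MembershipSpec("independent"),
                sss=MembershipSpec("independent"), prod=MembershipSpec("independent"),
                weight_z=0.5, weight_sst=0.6, weight_sss=0.0, weight_prod=0.0,
                final_threshold=0.5, depth_max=100.0,
            )

    def test_yaml_round_trip(self, params_all, tmp_path):
        path = tmp_path / "params.yaml"
        save_params(params_all, path)
        back = load_params(path)
        from carbfact.factory_model import params_to_dict

        # compare the serialized forms: independent specs carry NaN mid-points,
        # which defeat dataclass equality
        assert params_to_dict(back) == params_to_dict(params_all)


class TestSusceptibility:
    def test_photozoan_reference_cell(self, params_all):
        env = make_env(28.0, 24.0, sss_class=5.0, prod=0.015, depth=20.0)
        masks = build_masks(env, params_all)
        f = susceptibility(env, params_all["photozoan_T"], masks).values.values[0, 0]
        assert f == pytest.approx(0.9983, abs=5e-4)

    def test_biochemical_reference_cell(self, params_all):
        env = make_env(33.0, 20.0, sss_class=8.0, prod=0.02, depth=20.0)
        masks = build_masks(env, params_all)
        f = susceptibility(env, params_all["biochemical"], masks).values.values[0, 0]
        assert f == pytest.approx(0.9954, abs=5e-4)

    def test_high_terrigenous_cell_is_missing(self, params_all):
        env = make_env(28.0, 24.0, terrigenous=2)
        masks = build_masks(env, params_all)
        for f in params_all:
            assert np.isnan(susceptibility(env, params_all[f], masks).values.values[0, 0])

    def test_monotone_in_a_membership(self, params_all):
        # moving productivity toward its optimum can only raise photozoan F
        prods = np.array([[0.08, 0.05, 0.03, 0.015]])
        env = make_env(np.full((1, 4), 28.0), np.full((1, 4), 24.0), prod=prods)
        masks = build_masks(env, params_all)
        f = susceptibility(env, params_all["photozoan_T"], masks).values.values[0]
        assert np.all(np.diff(f) > 0)

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=60)
    def test_bounded_for_random_valid_parameterizations(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.dirichlet(np.ones(4))
        forms = rng.choice(["gaussian", "near_gaussian", "independent"], size=3)

        def spec(form, mp_range, s_range):
            if form == "independent":
                return MembershipSpec("independent")
            return MembershipSpec(form, rng.uniform(*mp_range), rng.uniform(*s_range))

        p = FactoryParams(
            name="random",
            sst=spec(forms[0], (-2, 35), (1e-3, 10)),
            sss=spec(forms[1], (1, 8), (0.01, 5)),
            prod=spec(forms[2], (0.005, 0.1), (100, 5000)),
            weight_z=w[0], weight_sst=w[1], weight_sss=w[2], weight_prod=w[3],
            final_threshold=rng.uniform(0.1, 0.9),
            depth_max=rng.choice([100.0, 200.0]),
        )
        env = make_env(
            rng.uniform(0, 35, (4, 5)), rng.uniform(-2, 20, (4, 5)),
            sss_class=rng.uniform(1, 8, (4, 5)), prod=rng.uniform(0, 0.15, (4, 5)),
            depth=rng.uniform(-50, 300, (4, 5)),
        )
        masks = build_masks(env, {"random": p})
        vals = susceptibility(env, p, masks).values.values
        finite = np.isfinite(vals)
        assert np.all((vals[finite] >= 0.0) & (vals[finite] <= 1.0))
        assert np.array_equal(finite, masks.eligible["random"])


class TestOccurrenceAndCombine:
    def test_strict_threshold(self, params_all):
        env = make_env(28.0, 24.0)
        masks = build_masks(env, params_all)
        s = susceptibility(env, params_all["photozoan_T"], masks)
        assert occurrence(s, 0.7)[0, 0]
        exact = s.values.like(np.full(s.values.shape, 0.7))
        from carbfact.factory_model import SusceptibilityMap

        assert not occurrence(SusceptibilityMap("photozoan_T", exact), 0.7)[0, 0]

    def test_margin_rule_prefers_larger_exceedance(self, params_all):
        # biochemical regime cell: both biochemical and photozoan-T bits set,
        # the larger margin above its own threshold wins
        env = make_env(33.0, 20.0, sss_class=8.0, prod=0.02, depth=20.0)
        fmap, suscs = predict(env, params_all)
        assert suscs["photozoan_T"].values.values[0, 0] > 0.7  # both present...
        assert fmap.category.values[0, 0] == FACTORY_CODES["biochemical"]

    def test_single_presence_wins(self, params_all):
        env = make_env(28.0, 24.0, sss_class=5.0, prod=0.015)
        fmap, _ = predict(env, params_all)
        assert fmap.category.values[0, 0] == FACTORY_CODES["photozoan_T"]

    def test_background_fills_unclaimed_productive_cells(self, params_all):
        env = make_env(10.0, 4.0, sss_class=4.0, prod=0.06, depth=150.0)
        fmap, _ = predict(env, params_all)
        assert fmap.category.values[0, 0] == FACTORY_CODES["heterozoan_C"]

    def test_background_respects_productivity_floor(self, params_all):
        # widen the heterozoan productivity bell so susceptibility clears the
        # threshold at 0.009 m^-1; the explicit 0.01 floor must still veto it
        import dataclasses

        params = dict(params_all)
        params["heterozoan_C"] = dataclasses.replace(
            params_all["heterozoan_C"], prod=MembershipSpec("near_gaussian", 0.06, 100.0)
        )
        env = make_env(10.0, 4.0, sss_class=4.0, prod=0.009, depth=150.0)
        fmap, suscs = predict(env, params)
        assert suscs["heterozoan_C"].values.values[0, 0] > 0.5
        assert fmap.category.values[0, 0] == FACTORY_CODES["none"]

    def test_missing_presence_rejected(self, params_all):
        env = make_env(28.0, 24.0)
        masks = build_masks(env, params_all)
        suscs = {f: susceptibility(env, p, masks) for f, p in params_all.items()}
        with pytest.raises(ValueError, match="presence"):
            combine({"biochemical": np.zeros((1, 1), bool)}, suscs, params_all, env)


class TestPredict:
    def test_all_land_grid_maps_to_none(self, params_all):
        env = make_env(np.full((3, 3), 20.0), np.full((3, 3), 15.0), depth=-100.0)
        fmap, _ = predict(env, params_all)
        assert np.all(fmap.category.values == FACTORY_CODES["none"])

    def test_self_consistency_on_synthetic_world(self, world, params_all):
        env, masks, truth = world
        fmap, _ = predict(env, params_all, masks)
        report = anomaly_summary(truth, fmap, evaluation_domain(env))
        assert report.global_accuracy == 100.0

    def test_deterministic(self, world, params_all):
        env, masks, _ = world
        a, _ = predict(env, params_all, masks)
        b, _ = predict(env, params_all, masks)
        assert np.array_equal(a.category.values, b.category.values)

    def test_orientation_invariant_through_io(self, tmp_path, params_all):
        # a stack stored with descending latitude predicts the same map
        import xarray as xr
        from carbfact.grid_io import read_env_stack, write_env_stack

        env, _ = sw.generate_env(sw.WorldConfig(nlat=24, nlon=48, seed=2))
        fmap, _ = predict(env, params_all)
        path = tmp_path / "env.nc"
        write_env_stack(env, path)
        flipped = xr.open_dataset(path, engine="scipy").isel(lat=slice(None, None, -1))
        path2 = tmp_path / "env_desc.nc"
        flipped.to_netcdf(path2, engine="scipy")
        env2 = read_env_stack(path2)
        fmap2, _ = predict(env2, params_all)
        assert np.array_equal(fmap.category.values, fmap2.category.values)

    def test_warming_shifts_photozoan_poleward(self, world, params_all):
        env, masks, truth = world
        warmed = sw.EnvStack(**{
            name: (g.like(g.values + 5.0) if name.startswith("sst") else g.copy())
            for name, g in env.grids().items()
        })
        warm_map, _ = predict(warmed, params_all, masks)
        LAT = np.meshgrid(env.lat, env.lon, indexing="ij")[0]
        base_extent = np.abs(LAT[truth.presence["photozoan_T"]]).max()
        warm_extent = np.abs(LAT[warm_map.presence["photozoan_T"]]).max()
        assert warm_extent > base_extent


class TestTemperatureDomains:
    def test_three_exclusive_nonempty_domains(self, params_all):
        s_ax = np.linspace(-2.0, 36.0, 300)
        S, W = np.meshgrid(s_ax, s_ax, indexing="ij")
        cat = temperature_domains(params_all, S, W)
        cat = np.where(W <= S, cat, 0)  # physical half-plane: warm season warmer
        regions = {f: cat == FACTORY_CODES[f]
                   for f in ("biochemical", "photozoan_T", "photo_C")}
        names = list(regions)
        for i, a in enumerate(names):
            assert regions[a].any(), f"{a} domain empty"
            for b in names[i + 1:]:
                assert not np.any(regions[a] & regions[b])

    def test_domain_structure_matches_the_described_niches(self, params_all):
        s_ax = np.linspace(-2.0, 36.0, 300)
        S, W = np.meshgrid(s_ax, s_ax, indexing="ij")
        cat = np.where(W <= S, temperature_domains(params_all, S, W), 0)
        mean_summer = {f: S[cat == FACTORY_CODES[f]].mean()
                       for f in ("biochemical", "photozoan_T", "photo_C")}
        assert mean_summer["biochemical"] > mean_summer["photozoan_T"]
        seasonality = {f: (S - W)[cat == FACTORY_CODES[f]].mean()
                       for f in ("photozoan_T", "photo_C")}
        assert seasonality["photo_C"] > seasonality["photozoan_T"]
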