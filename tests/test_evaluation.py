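"""FAC metrics, pair matching, and the improvement fraction."""

import math

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given, strategies as st

from marinp.cnt_model import T_MELT
from marinp.evaluation import (
    evaluate,
    fac_fraction,
    great_circle_km,
    improvement_fraction,
    match_pairs,
)


def toy_inp(lat, lon, temps, value=1.0):
    shape = (len(temps), len(lat), len(lon))
    data = np.full(shape, value)
    coords = {"temperature": list(temps), "lat": list(lat), "lon": list(lon)}
    dims = ("temperature", "lat", "lon")
    return xr.Dataset({v: xr.DataArray(data.copy(), dims=dims, coords=coords)
                       for v in ("inp_dust", "inp_poly", "inp_m18")})


def obs_frame(rows):
    df = pd.DataFrame(rows)
    df["activation_temperature"] = df["activation_temp_C"] + T_MELT
    return df


class TestMatchPairs:
    def test_exact_cell_and_level_match(self):
        inp = toy_inp([-60.0, 0.0, 60.0], [0.0, 90.0, 180.0, 270.0],
                      [258.15, 256.15])
        inp["inp_dust"].loc[{"lat": -60.0, "lon": 90.0,
                             "temperature": 258.15}] = 7.0
        obs = obs_frame([{"campaign": "c", "lat": -60.0, "lon": 90.0,
                          "time_iso": "2010-01-01T00:00:00",
                          "activation_temp_C": -15.0, "inp_per_L": 1.0,
                          "marine_flag": True}])
        pairs, skipped = match_pairs(obs, inp)
        assert len(pairs) == 1
        assert pairs["inp_dust"].iloc[0] == 7.0
        assert pairs["distance_km"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_empty_observations(self):
        inp = toy_inp([0.0], [0.0], [258.15])
        pairs, skipped = match_pairs(obs_frame([
            {"campaign": "c", "lat": 0.0, "lon": 0.0,
             "time_iso": "t", "activation_temp_C": -40.0, "inp_per_L": 1.0,
             "marine_flag": True}]), inp)
        assert len(pairs) == 0
        assert skipped["outside_window"] == 1

    def test_temperature_tolerance_skip(self):
        inp = toy_inp([0.0], [0.0], [258.15])  # only -15 C evaluated
        obs = obs_frame([{"campaign": "c", "lat": 0.0, "lon": 0.0,
                          "time_iso": "t", "activation_temp_C": -18.0,
                          "inp_per_L": 1.0, "marine_flag": True}])
        pairs, skipped = match_pairs(obs, inp)
        assert len(pairs) == 0 and skipped["no_temperature_level"] == 1

    def test_nearest_cell_matches_brute_force(self):
        """Nearest-cell assignment equals exhaustive great-circle minimization
        over all grid cells for a random set of observation points."""
        rng = np.random.default_rng(7)
        lat = np.linspace(-75, 75, 11)
        lon = np.linspace(0, 330, 12)
        inp = toy_inp(lat, lon, [258.15])
        rows = [{"campaign": "c", "lat": rng.uniform(-89, 89),
                 "lon": rng.uniform(0, 360), "time_iso": "t",
                 "activation_temp_C": -15.0, "inp_per_L": 1.0,
                 "marine_flag": True} for _ in range(100)]
        obs = obs_frame(rows)
        pairs, _ = match_pairs(obs, inp)
        assert len(pairs) == 100
        for row, (_, p) in zip(rows, pairs.iterrows()):
            best, b_lat, b_lon = np.inf, None, None
            for la in lat:
                for lo in lon:
                    d = great_circle_km(row["lat"], row["lon"], la, lo)
                    if d < best:
                        best, b_lat, b_lon = d, la, lo
            assert (p["lat"], p["lon"]) == (b_lat, b_lon)


class TestFacFraction:
    def test_perfect_model_scores_one(self):
        frac, n, excl = fac_fraction([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 2.0)
        assert frac == 1.0 and n == 3 and excl == 0

    def test_ratio_beyond_factor_scores_zero(self):
        frac, _, _ = fac_fraction([1.0], [11.0], 10.0)
        assert frac == 0.0

    def test_ratio_exactly_factor_counts_as_within(self):
        frac, _, _ = fac_fraction([1.0], [10.0], 10.0)
        assert frac == 1.0

    def test_zeros_excluded_and_counted(self):
        frac, n, excl = fac_fraction([0.0, 1.0], [1.0, 1.0], 2.0)
        assert frac == 1.0 and n == 1 and excl == 1

    def test_no_valid_pairs_flagged(self):
        with pytest.warns(UserWarning):
            frac, n, excl = fac_fraction([0.0], [1.0], 2.0)
        assert math.isnan(frac)

    @given(st.lists(st.tuples(st.floats(1e-6, 1e6), st.floats(1e-6, 1e6)),
                    min_size=1, max_size=30))
    def test_brute_force_oracle_and_symmetry(self, pairs):
        obs = np.array([p[0] for p in pairs])
        mod = np.array([p[1] for p in pairs])
        for factor in (2.0, 10.0):
            frac, _, _ = fac_fraction(obs, mod, factor)
            brute = sum(
                1 for o, m in pairs if max(m / o, o / m) <= factor
            ) / len(pairs)
            assert frac == pytest.approx(brute, abs=1e-12)
            swapped, _, _ = fac_fraction(mod, obs, factor)
            assert swapped == pytest.approx(frac, abs=1e-12)

    @given(st.lists(st.tuples(st.floats(1e-3, 1e3), st.floats(1e-3, 1e3)),
                    min_size=1, max_size=20))
    def test_monotone_in_factor(self, pairs):
        obs = [p[0] for p in pairs]
        mod = [p[1] for p in pairs]
        f2, _, _ = fac_fraction(obs, mod, 2.0)
        f10, _, _ = fac_fraction(obs, mod, 10.0)
        assert f2 <= f10


class TestImprovementFraction:
    def test_full_reproduction_is_one(self):
        assert improvement_fraction(0.37, 0.60, 0.60) == pytest.approx(1.0)

    def test_no_gain_is_zero(self):
        assert improvement_fraction(0.37, 0.60, 0.37) == pytest.approx(0.0)

    def test_worked_example(self):
        assert improvement_fraction(0.37, 0.60, 0.52) == pytest.approx(
            0.6521739130434783
        )

    def test_undefined_denominator_flagged(self):
        with pytest.warns(UserWarning):
            assert math.isnan(improvement_fraction(0.5, 0.5, 0.7))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            improvement_fraction(1.2, 0.5, 0.5)


class TestEvaluateClosure:
    def test_observations_equal_to_model_close_perfectly(self):
        lat = np.linspace(-60, 60, 5)
        lon = np.linspace(0, 270, 4)
        inp = toy_inp(lat, lon, [258.15, 256.15, 253.15])
        rng = np.random.default_rng(3)
        for v in inp.data_vars:
            inp[v].values[:] = 10 ** rng.uniform(-3, 0, inp[v].shape)
        rows = []
        for k in range(40):
            i = rng.integers(len(lat))
            j = rng.integers(len(lon))
            t = rng.integers(3)
            truth = float((inp["inp_dust"] + inp["inp_poly"]).values[t, i, j])
            rows.append({"campaign": "c", "lat": lat[i], "lon": lon[j],
                         "time_iso": "t",
                         "activation_temp_C": float(
                             inp["temperature"].values[t] - T_MELT),
                         "inp_per_L": truth, "marine_flag": True})
        report = evaluate(obs_frame(rows), inp)
        assert report.n_pairs == 40
        assert report.fac2["N15+HSZ25"] == 1.0
        assert report.fac10["N15+HSZ25"] == 1.0
        assert report.fac2["N15+HSZ25"] <= report.fac10["N15+HSZ25"]
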