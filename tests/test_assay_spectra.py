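"""Assay reduction: frozen fractions, Vali spectra, normalization, treatments."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from marinp.assay_spectra import (
    FreezingAssay,
    SampleChemistry,
    Spectrum,
    cumulative_inm_concentration,
    default_grid,
    frozen_fraction_curve,
    normalize_spectrum,
    pooled_dilution_spectrum,
    read_assay_csv,
    read_chemistry_csv,
    spectrum_frame,
    subtract_background,
    treatment_reduction,
    write_assay_csv,
    write_chemistry_csv,
)
from marinp.synthetic_data import SimConfig, simulate_assay


def make_assay(temps, n_total=30, volume=1e-6, dilution=1.0, sid="s"):
    return FreezingAssay(sid, volume, dilution, np.asarray(temps, dtype=float),
                         n_total)


class TestFrozenFractionCurve:
    def test_no_freezes_gives_zero_curve(self):
        spec = frozen_fraction_curve(make_assay([], 30))
        assert np.all(spec.frozen_fraction == 0.0)

    def test_all_frozen_above_grid_gives_one(self):
        spec = frozen_fraction_curve(make_assay([272.0] * 30, 30),
                                     np.arange(271.15, 241.15, -1.0))
        assert np.all(spec.frozen_fraction == 1.0)

    def test_direct_count_and_inclusive_boundary(self):
        # 5 of 10 droplets frozen at or above 258.15 K; one exactly at the
        # grid temperature counts as frozen there
        temps = [262.0, 261.0, 260.0, 259.0, 258.15]
        spec = frozen_fraction_curve(make_assay(temps, 10),
                                     np.array([258.15]))
        assert spec.frozen_fraction[0] == 0.5

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            frozen_fraction_curve(make_assay([], 10), np.array([]))
        with pytest.raises(ValueError):
            frozen_fraction_curve(make_assay([], 10), np.array([250.0, 260.0]))


class TestCumulativeConcentration:
    def test_zero_fraction_gives_zero_concentration(self):
        spec = frozen_fraction_curve(make_assay([], 30))
        spec = cumulative_inm_concentration(spec, make_assay([], 30))
        assert np.all(spec.n_inm_per_volume == 0.0)

    def test_known_fraction_maps_to_concentration(self):
        # f = 1 - e^-1 in a 1 uL droplet at dilution 1 -> 1e6 INM per litre
        n = 10_000_000
        k = round((1.0 - math.exp(-1.0)) * n)
        assay = make_assay([], n)
        spec = Spectrum("s", np.array([255.15]), np.array([k / n]),
                        np.array([k]), n, 1e-6, 1.0)
        spec = cumulative_inm_concentration(spec, assay)
        assert spec.n_inm_per_volume[0] == pytest.approx(1e6, rel=1e-5)

    def test_fully_frozen_bin_is_censored_lower_bound(self):
        grid = np.array([260.15])
        assay = make_assay([261.0] * 20, 20)
        spec = cumulative_inm_concentration(frozen_fraction_curve(assay, grid),
                                            assay)
        assert spec.censored[0]
        expected = -math.log1p(-(20 - 0.5) / 20) / 1e-6
        assert spec.n_inm_per_volume[0] == pytest.approx(expected)
        assert math.isinf(spec.ci_high[0])

    def test_poisson_monte_carlo_oracle(self):
        """10,000 droplets each holding Poisson(0.5) INMs all active at T:
        the Vali estimate recovers lambda/V within its 95% interval."""
        rng = np.random.default_rng(123)
        lam, v, n = 0.5, 1e-6, 10_000
        frozen = int((rng.poisson(lam, size=n) > 0).sum())
        assay = make_assay([], n, volume=v)
        spec = Spectrum("s", np.array([250.15]),
                        np.array([frozen / n]), np.array([frozen]), n, v, 1.0)
        spec = cumulative_inm_concentration(spec, assay)
        assert spec.ci_low[0] <= lam / v <= spec.ci_high[0]
        assert spec.n_inm_per_volume[0] == pytest.approx(lam / v, rel=0.1)

    @given(st.floats(1e-6, 1.0 - 1e-9), st.floats(1.0, 100.0))
    def test_vali_inversion_consistency(self, f, dilution):
        v = 1e-6
        n = -math.log1p(-f) / v * dilution
        assert 1.0 - math.exp(-n * v / dilution) == pytest.approx(f, abs=1e-12)

    def test_monotone_with_cooling(self, small_config, chemistry):
        assay = simulate_assay(small_config, chemistry, dilution=10.0)
        spec = cumulative_inm_concentration(frozen_fraction_curve(assay), assay)
        assert np.all(np.diff(spec.frozen_fraction) >= 0.0)  # grid descends
        finite = np.isfinite(spec.n_inm_per_volume)
        assert np.all(np.diff(spec.n_inm_per_volume[finite]) >= 0.0)

    def test_dilution_consistency(self, chemistry):
        """Assays of the same sample at dilution 1 and 10 give compatible
        concentration estimates (overlapping confidence intervals)."""
        specs = []
        for i, d in enumerate((1.0, 10.0)):
            cfg = SimConfig(seed=5, n_droplets=1000)
            assay = simulate_assay(cfg, chemistry, dilution=d, stream_key=50 + i)
            specs.append(
                cumulative_inm_concentration(frozen_fraction_curve(assay), assay)
            )
        grid = specs[0].temperature_grid
        t = int(np.argmin(np.abs(grid - (273.15 - 17.0))))
        lo = max(specs[0].ci_low[t], specs[1].ci_low[t])
        hi = min(specs[0].ci_high[t], specs[1].ci_high[t])
        assert lo <= hi  # intervals overlap


class TestNormalization:
    def test_division_by_basis(self):
        spec = Spectrum("s", np.array([255.15]), np.array([0.5]),
                        np.array([5]), 10, 1e-6, 1.0,
                        n_inm_per_volume=np.array([1e6]))
        chem = SampleChemistry("s", c_tccho=1e-3, toc=1e-2)
        out = normalize_spectrum(spec, chem, "per_c_tccho")
        assert out.n_m[0] == pytest.approx(1e9)

    def test_per_volume_is_identity(self):
        spec = Spectrum("s", np.array([255.15]), np.array([0.5]),
                        np.array([5]), 10, 1e-6, 1.0,
                        n_inm_per_volume=np.array([1e6]))
        out = normalize_spectrum(spec, SampleChemistry("s", 1e-3, 1e-2),
                                 "per_volume")
        assert out.n_m is None
        np.testing.assert_array_equal(out.n_inm_per_volume,
                                      spec.n_inm_per_volume)

    def test_zero_basis_raises_with_sample_name(self):
        spec = Spectrum("s", np.array([255.15]), np.array([0.5]),
                        np.array([5]), 10, 1e-6, 1.0,
                        n_inm_per_volume=np.array([1e6]))
        with pytest.raises(ValueError, match="weird-sample"):
            normalize_spectrum(spec, SampleChemistry("weird-sample", 0.0, 0.0),
                               "per_c_tccho")


class TestTreatmentReduction:
    def _spec(self, value, k=50, n=100):
        grid = np.array([255.15])
        s = Spectrum("s", grid, np.array([k / n]), np.array([k]), n, 1e-6, 1.0)
        assay = make_assay([], n)
        s = cumulative_inm_concentration(s, assay)
        s.n_inm_per_volume = np.array([float(value)])
        return s

    def test_arithmetic(self):
        r = treatment_reduction(self._spec(100.0), self._spec(1.0), 255.15)
        assert r.percent == pytest.approx(99.0)

    def test_identity_gives_zero(self):
        r = treatment_reduction(self._spec(5.0), self._spec(5.0), 255.15)
        assert r.percent == pytest.approx(0.0)

    def test_zero_reference_flagged(self):
        r = treatment_reduction(self._spec(0.0), self._spec(1.0), 255.15)
        assert r.flagged and math.isnan(r.percent)

    def test_simulated_filtration_recovers_removal(self, chemistry):
        """Filtration removing 98% of INMs before the assay yields an
        estimated reduction whose confidence interval covers 98%."""
        cfg = SimConfig(seed=21, n_droplets=2000)
        ref = simulate_assay(cfg, chemistry, dilution=10.0, stream_key=60)
        filt = simulate_assay(cfg, chemistry, dilution=10.0, stream_key=61,
                              removal_fraction=0.98,
                              treatment="filtered_0.2um")
        s_ref = cumulative_inm_concentration(frozen_fraction_curve(ref), ref)
        s_fil = cumulative_inm_concentration(frozen_fraction_curve(filt), filt)
        T = 273.15 - 20.0
        r = treatment_reduction(s_ref, s_fil, T)
        assert r.ci_low <= 98.0 <= r.ci_high
        assert r.percent == pytest.approx(98.0, abs=2.0)


class TestPooledSpectrum:
    def test_pooled_matches_single_assay_where_informative(self, chemistry):
        cfg = SimConfig(seed=31, n_droplets=1000)
        assay = simulate_assay(cfg, chemistry, dilution=10.0, stream_key=70)
        single = cumulative_inm_concentration(frozen_fraction_curve(assay), assay)
        pooled = pooled_dilution_spectrum([assay])
        grid = single.temperature_grid
        t = int(np.argmin(np.abs(grid - (273.15 - 18.0))))
        assert pooled.n_inm_per_volume[t] == pytest.approx(
            single.n_inm_per_volume[t], rel=1e-6
        )


class TestBackground:
    def test_subtraction_floors_at_zero(self):
        grid = np.array([255.15])
        mk = lambda v: Spectrum("s", grid, np.array([0.1]), np.array([1]), 10,
                                1e-6, 1.0, n_inm_per_volume=np.array([v]))
        out = subtract_background(mk(5.0), mk(8.0))
        assert out.n_inm_per_volume[0] == 0.0
        out = subtract_background(mk(8.0), mk(5.0))
        assert out.n_inm_per_volume[0] == pytest.approx(3.0)


class TestCsvRoundTrips:
    def test_assay_round_trip(self, tmp_path, chemistry, small_config):
        assays = [
            simulate_assay(small_config, chemistry, dilution=d, stream_key=80 + i)
            for i, d in enumerate((1.0, 10.0))
        ]
        path = tmp_path / "assays.csv"
        write_assay_csv(assays, path)
        back = read_assay_csv(path)
        assert len(back) == 2
        for a, b in zip(assays, back):
            assert b.sample_id == a.sample_id
            assert b.dilution_factor == a.dilution_factor
            assert b.n_droplets_total == a.n_droplets_total
            np.testing.assert_allclose(
                np.sort(b.freezing_temperatures),
                np.sort(a.freezing_temperatures), atol=1e-9,
            )

    def test_chemistry_round_trip(self, tmp_path):
        chem = [SampleChemistry("a", 1e-3, 4e-3, 0.01),
                SampleChemistry("b", 2e-4, 9e-4, None)]
        path = tmp_path / "chem.csv"
        write_chemistry_csv(chem, path)
        back = read_chemistry_csv(path)
        assert back["a"].c_tccho == pytest.approx(1e-3)
        assert back["b"].dry_mass is None

    def test_spectrum_frame_schema(self, chemistry, small_config):
        assay = simulate_assay(small_config, chemistry, dilution=10.0)
        spec = cumulative_inm_concentration(frozen_fraction_curve(assay), assay)
        df = spectrum_frame(normalize_spectrum(spec, chemistry, "per_c_tccho"))
        assert {"sample_id", "temp_C", "frozen_fraction", "n_inm_per_L",
                "ci_low", "ci_high", "n_m", "basis", "censored_flag"} <= set(df)
        assert (df["basis"] == "per_c_tccho").all()
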