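"""Synthetic inputs with known ground truth for every pipeline stage.

Generates (a) stochastic droplet-freezing assays driven by a known CNT
parameter set, (b) per-sample chemistry spanning orders of magnitude,
(c) smooth gridded sea-salt/dust fields with ocean-land contrast and a
hemispherically asymmetric dust burden, and (d) lognormally noised INP
observations — the same CSV/NetCDF dialects the readers consume.

Everything is driven by one integer seed through independent, named
substreams, so the full end-to-end demo is reproducible bit for bit.  The
fields are statistical stand-ins: no meteorology, seasonality or emission
physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter
from scipy.stats import truncnorm

from .assay_spectra import FreezingAssay, SampleChemistry
from .cnt_model import CNTParams, ThermoParams, T_MELT, WATER_ICE_DEFAULT, j_het
from .global_inp import ScenarioConfig, inp_fields
from .inp_parametrizations import MODE_DEFAULTS

__all__ = [
    "SimConfig",
    "substream",
    "simulate_assay",
    "analytic_frozen_fraction",
    "generate_fields",
    "generate_observations",
    "write_synthetic_dataset",
]

#: Default synthetic "T. striatum-like" organism defining the polysaccharide
#: parametrization in the end-to-end demo: freezing onset just below -8 C and
#: n_m per gram carbohydrate carbon of ~1e8 at -15 C, in the range reported
#: for marine microbial ice-nucleating macromolecules.
DEFAULT_TRUE_PARAMS = CNTParams(
    mu_theta=1.70, sigma_theta=0.28, n_max=3.0e10, a_site=1.0e-14,
    delta_t=60.0, basis="c_tccho",
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic end-to-end experiment."""

    seed: int = 0
    true_params: CNTParams = DEFAULT_TRUE_PARAMS
    n_droplets: int = 300
    droplet_volume: float = 1.0e-6          # litre (1 uL)
    dilutions: tuple = (1.0, 10.0, 100.0)
    cooling_rate: float = 1.0 / 60.0        # K s^-1 (1 K per minute)
    cooling_step: float = 1.0               # K per simulation step
    t_start: float = 272.15                 # K, ramp start
    t_stop: float = 237.65                  # K, ramp end
    grid_shape: tuple = (12, 24)            # (n_lat, n_lon)
    n_timesteps: int = 120                  # 6-hourly x 30 days
    obs_noise_sigma: float = math.log(3.0)  # lognormal obs noise (log-space)
    n_observations: int = 200
    obs_t_window: tuple = (T_MELT - 20.0, T_MELT - 15.0)
    c_tccho: float = 5.0e-3                 # g C per litre culture

    def __post_init__(self):
        if self.n_droplets <= 0 or self.n_timesteps <= 0 or self.n_observations < 0:
            raise ValueError("counts must be positive")
        if self.cooling_rate <= 0 or self.cooling_step <= 0:
            raise ValueError("cooling rate and step must be > 0")

    def step_temperatures(self) -> np.ndarray:
        return np.arange(self.t_start, self.t_stop - 1e-9, -self.cooling_step)

    def chemistry(self, sample_id: str = "synthetic-organism") -> SampleChemistry:
        return SampleChemistry(sample_id=sample_id, c_tccho=self.c_tccho,
                               toc=4.0 * self.c_tccho)


def substream(config: SimConfig, key: int) -> np.random.Generator:
    """Independent, named random substream derived from the master seed."""
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, int(key)])


def _draw_angles(rng, params: CNTParams, size: int) -> np.ndarray:
    a = (0.0 - params.mu_theta) / params.sigma_theta
    b = (math.pi - params.mu_theta) / params.sigma_theta
    return truncnorm.rvs(a, b, loc=params.mu_theta, scale=params.sigma_theta,
                         size=size, random_state=rng)


def simulate_assay(
    config: SimConfig,
    chemistry: SampleChemistry,
    dilution: float = 1.0,
    params: Optional[CNTParams] = None,
    thermo: ThermoParams = WATER_ICE_DEFAULT,
    sample_id: Optional[str] = None,
    treatment: str = "none",
    removal_fraction: float = 0.0,
    stream_key: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> FreezingAssay:
    """Monte-Carlo droplet-freezing assay under the CNT forward physics.

    Each droplet holds k ~ Poisson(n_max * c * V / dilution) ice-nucleating
    macromolecules (reduced by ``removal_fraction`` to emulate e.g.
    filtration); each INM draws a contact angle from the truncated normal
    and, while cooling stepwise, nucleates during a step with probability
    1 - exp(-j_het * a_site * dt_step).  The droplet freezes at the first
    step at which any of its INMs nucleates; droplets with no nucleation by
    the end of the ramp stay liquid (censored).  Fully seed-reproducible.
    """
    params = config.true_params if params is None else params
    rng = substream(config, stream_key) if rng is None else rng
    steps = config.step_temperatures()
    dt_step = config.cooling_step / config.cooling_rate
    nu = (params.n_max * chemistry.c_tccho * config.droplet_volume / dilution
          * (1.0 - removal_fraction))
    k = rng.poisson(nu, size=config.n_droplets)
    total = int(k.sum())
    freeze_step = np.full(config.n_droplets, steps.size, dtype=int)
    if total > 0:
        droplet_of = np.repeat(np.arange(config.n_droplets), k)
        thresholds = rng.exponential(size=total)  # unit-exponential hazards
        chunk = max(1, 2_000_000 // steps.size)
        for s in range(0, total, chunk):
            sl = slice(s, min(s + chunk, total))
            theta = _draw_angles(rng, params, sl.stop - sl.start)
            h = j_het(steps[None, :], theta[:, None], thermo) \
                * params.a_site * dt_step
            cum = np.cumsum(h, axis=1)
            idx = np.sum(cum < thresholds[sl, None], axis=1)  # first exceeded
            np.minimum.at(freeze_step, droplet_of[sl], idx)
    frozen = freeze_step < steps.size
    return FreezingAssay(
        sample_id=sample_id or chemistry.sample_id,
        droplet_volume=config.droplet_volume,
        dilution_factor=dilution,
        freezing_temperatures=steps[freeze_step[frozen]],
        n_droplets_total=config.n_droplets,
        treatment=treatment,
    )


def analytic_frozen_fraction(
    config: SimConfig,
    chemistry: SampleChemistry,
    dilution: float = 1.0,
    params: Optional[CNTParams] = None,
    thermo: ThermoParams = WATER_ICE_DEFAULT,
    n_theta: int = 20001,
    q_tail: float = 1.0e-3,
    n_tail: int = 8001,
) -> np.ndarray:
    """Exact expectation of the simulated frozen fraction on the step grid.

    For Poisson-distributed INM counts, f(T) = 1 - exp(-nu * P_frozen(T))
    where P_frozen(T) integrates the cumulative-hazard activation probability
    1 - exp(-sum_{T' >= T} j a dt) over the contact-angle distribution.  The
    bulk of the distribution is integrated on quantile-spaced midpoint nodes;
    the small-contact-angle tail (mass ``q_tail``), which carries the rare
    near-perfect nuclei responsible for sporadic warm freezing events, is
    integrated explicitly in theta.  This is the independent oracle the
    Monte-Carlo assay is checked against.
    """
    params = config.true_params if params is None else params
    steps = config.step_temperatures()
    dt_step = config.cooling_step / config.cooling_rate
    a = (0.0 - params.mu_theta) / params.sigma_theta
    b = (math.pi - params.mu_theta) / params.sigma_theta

    def p_active(theta):
        h = j_het(steps[None, :], theta[:, None], thermo) \
            * params.a_site * dt_step
        return -np.expm1(-np.cumsum(h, axis=1))

    # bulk: quantile midpoint rule on the upper (1 - q_tail) mass
    q = q_tail + (1.0 - q_tail) * (np.arange(n_theta) + 0.5) / n_theta
    theta_bulk = truncnorm.ppf(q, a, b, loc=params.mu_theta,
                               scale=params.sigma_theta)
    bulk = (1.0 - q_tail) * p_active(theta_bulk).mean(axis=0)
    # tail: explicit theta-space trapezoid on [0, theta(q_tail)]
    theta_edge = truncnorm.ppf(q_tail, a, b, loc=params.mu_theta,
                               scale=params.sigma_theta)
    theta_t = np.linspace(0.0, theta_edge, n_tail)
    pdf = truncnorm.pdf(theta_t, a, b, loc=params.mu_theta,
                        scale=params.sigma_theta)
    tail = np.trapezoid(pdf[:, None] * p_active(theta_t), theta_t, axis=0)
    p_frozen = bulk + tail
    nu = params.n_max * chemistry.c_tccho * config.droplet_volume / dilution
    return -np.expm1(-nu * p_frozen)


# ---------------------------------------------------------------------------
# Gridded aerosol fields
# ---------------------------------------------------------------------------

def _smooth_noise(rng, shape, sigma_cells):
    """Zero-mean, unit-variance smooth random field (wrapped in longitude)."""
    white = rng.standard_normal(shape)
    smooth = gaussian_filter(white, sigma=sigma_cells, mode="wrap")
    return (smooth - smooth.mean()) / max(smooth.std(), 1e-12)


def _land_mask(lat, lon):
    """Idealized continents: a large northern landmass and a smaller
    mid-latitude one; the far southern ocean is land-free."""
    la, lo = np.meshgrid(lat, lon, indexing="ij")
    land = ((lo >= 0) & (lo < 120) & (la > -10)) | (
        (lo >= 210) & (lo < 285) & (la > -40)
    )
    return land.astype(float)


def _number_from_mass(mass, d_g, mode):
    """Mode number concentration consistent with mass and a median diameter."""
    ln2 = math.log(mode.sigma_g) ** 2
    per_particle = math.pi / 6.0 * mode.density * d_g**3 * math.exp(4.5 * ln2)
    return mass / per_particle


def generate_fields(config: SimConfig,
                    rng: Optional[np.random.Generator] = None) -> xr.Dataset:
    """Seeded synthetic aerosol fields, dims (time, lat, lon).

    Sea salt peaks over the mid-latitude storm tracks and vanishes over land;
    dust decays from two northern source regions and one weak southern one
    over a small global background, so the Southern Ocean is dust-poor.  Mode
    numbers follow from the masses through the lognormal mode geometry with
    fixed median diameters, so surface areas invert to the same geometry.
    """
    rng = substream(config, 2) if rng is None else rng
    n_lat, n_lon = config.grid_shape
    lat = np.linspace(-90, 90, n_lat + 1)[:-1] + 90.0 / n_lat
    lon = np.linspace(0, 360, n_lon + 1)[:-1]
    time = pd.date_range("2010-01-01", periods=config.n_timesteps, freq="6h")
    land = _land_mask(lat, lon)
    ocean = 1.0 - land
    la = lat[:, None]

    # sea salt: storm-track amplitude, modulated by smooth space-time noise
    amp = 2.0e-9 + 8.0e-9 * np.exp(-(((np.abs(la) - 50.0) / 20.0) ** 2))
    space = np.exp(0.3 * _smooth_noise(rng, (n_lat, n_lon), 1.5))
    tmod = np.exp(0.4 * _smooth_noise(rng, (config.n_timesteps, 1, 1), (2, 0, 0)))
    salt_accu = amp * space * ocean * tmod
    salt_coarse = 3.0 * salt_accu

    # dust: exponential decay from source cells + small well-mixed background
    sources = [  # (lat, lon, amplitude kg m^-3, decay length km)
        (25.0, 15.0, 4.0e-10, 2500.0),
        (40.0, 255.0, 1.5e-10, 2000.0),
        (-25.0, 135.0, 3.0e-11, 1500.0),
    ]
    la2, lo2 = np.meshgrid(lat, lon, indexing="ij")
    plume = np.zeros((n_lat, n_lon))
    from .evaluation import great_circle_km

    for slat, slon, q, length in sources:
        plume += q * np.exp(-great_circle_km(slat, slon, la2, lo2) / length)
    dust_spatial = plume + 2.0e-12
    dmod = np.exp(0.5 * _smooth_noise(rng, (config.n_timesteps, 1, 1), (2, 0, 0)))
    dust_accu = dust_spatial * dmod
    dust_coarse = 2.0 * dust_accu

    # median diameters pinning the mode geometry [m]
    d_salt_accu, d_salt_coarse = 0.2e-6, 2.0e-6
    d_dust_accu, d_dust_coarse = 0.25e-6, 1.2e-6

    def da(arr, units):
        arr = np.broadcast_to(arr, (config.n_timesteps, n_lat, n_lon)).copy()
        return xr.DataArray(arr, dims=("time", "lat", "lon"),
                            coords={"time": time, "lat": lat, "lon": lon},
                            attrs={"units": units})

    ds = xr.Dataset(
        {
            "seasalt_mass_accu": da(salt_accu, "kg m-3"),
            "seasalt_mass_coarse": da(salt_coarse, "kg m-3"),
            "dust_mass_accu": da(dust_accu, "kg m-3"),
            "dust_mass_coarse": da(dust_coarse, "kg m-3"),
            "num_soluble_accu": da(
                _number_from_mass(salt_accu, d_salt_accu,
                                  MODE_DEFAULTS["seasalt_accu"]), "m-3"),
            "num_soluble_coarse": da(
                _number_from_mass(salt_coarse, d_salt_coarse,
                                  MODE_DEFAULTS["seasalt_coarse"]), "m-3"),
            "num_insoluble_accu": da(
                _number_from_mass(dust_accu, d_dust_accu,
                                  MODE_DEFAULTS["dust_accu"]), "m-3"),
            "num_insoluble_coarse": da(
                _number_from_mass(dust_coarse, d_dust_coarse,
                                  MODE_DEFAULTS["dust_coarse"]), "m-3"),
            "land_sea_mask": xr.DataArray(
                land, dims=("lat", "lon"), coords={"lat": lat, "lon": lon},
                attrs={"units": "1", "long_name": "1 = land, 0 = ocean"}),
        }
    )
    ds.attrs["title"] = "synthetic aerosol fields (statistical stand-in)"
    ds.attrs["seed"] = int(config.seed)
    return ds


def generate_observations(
    fields: xr.Dataset,
    scenario: ScenarioConfig,
    config: SimConfig,
    hsz25_params: Optional[CNTParams] = None,
    thermo: ThermoParams = WATER_ICE_DEFAULT,
    truth_variant: str = "n15+hsz25",
    inp: Optional[xr.Dataset] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Lognormally noised observation records drawn from the model truth.

    Samples ocean cells and activation temperatures uniform in the
    configured window; the noise-free truth is the ``truth_variant``
    annual-mean INP at the cell and the *nearest evaluated* temperature
    (consistent with the evaluation matching rule), multiplied by
    exp(N(0, obs_noise_sigma)).
    """
    rng = substream(config, 3) if rng is None else rng
    if inp is None:
        params = DEFAULT_TRUE_PARAMS if hsz25_params is None else hsz25_params
        inp = inp_fields(fields, scenario, params, thermo)
    parts = {
        "n15": ("inp_dust",),
        "n15+m18": ("inp_dust", "inp_m18"),
        "n15+hsz25": ("inp_dust", "inp_poly"),
        "hsz25": ("inp_poly",),
    }[truth_variant]
    truth = sum(inp[p] for p in parts)
    ocean_idx = np.argwhere(fields["land_sea_mask"].values == 0)
    temps = inp["temperature"].values
    lo, hi = min(config.obs_t_window), max(config.obs_t_window)

    cells = ocean_idx[rng.integers(0, len(ocean_idx), size=config.n_observations)]
    t_act = rng.uniform(lo, hi, size=config.n_observations)
    eps = rng.normal(0.0, config.obs_noise_sigma, size=config.n_observations)
    times = pd.to_datetime(fields["time"].values[
        rng.integers(0, fields.sizes["time"], size=config.n_observations)
    ])
    rows = []
    for m in range(config.n_observations):
        i, j = cells[m]
        k = int(np.argmin(np.abs(temps - t_act[m])))
        base = float(truth.values[k, i, j])
        rows.append(
            {
                "campaign": f"synthetic-{'south' if fields['lat'].values[i] < 0 else 'north'}",
                "lat": float(fields["lat"].values[i]),
                "lon": float(fields["lon"].values[j]),
                "time_iso": times[m].isoformat(),
                "activation_temp_C": t_act[m] - T_MELT,
                "inp_per_L": base * math.exp(eps[m]),
                "marine_flag": True,
            }
        )
    df = pd.DataFrame(rows)
    df["activation_temperature"] = df["activation_temp_C"] + T_MELT
    return df


def write_synthetic_dataset(config: SimConfig, outdir, scenario=None,
                            thermo: ThermoParams = WATER_ICE_DEFAULT) -> dict:
    """Emit assays, chemistry, fields, observations and a truth manifest."""
    import pathlib

    import yaml

    from .assay_spectra import write_assay_csv, write_chemistry_csv
    from .evaluation import write_observations_csv
    from .global_inp import write_fields

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = ScenarioConfig() if scenario is None else scenario
    chem = config.chemistry()
    assays = [
        simulate_assay(config, chem, dilution=d, stream_key=10 + i)
        for i, d in enumerate(config.dilutions)
    ]
    fields = generate_fields(config)
    inp = inp_fields(fields, scenario, config.true_params, thermo)
    obs = generate_observations(fields, scenario, config, inp=inp)
    write_assay_csv(assays, outdir / "assays.csv")
    write_chemistry_csv([chem], outdir / "chemistry.csv")
    write_fields(fields, outdir / "fields.nc")
    write_observations_csv(obs, outdir / "observations.csv")
    manifest = {
        "seed": int(config.seed),
        "true_params": config.true_params.to_dict(),
        "scenario": {
            "poly_fraction_accumulation": scenario.poly_fraction_accumulation,
            "poly_fraction_coarse": scenario.poly_fraction_coarse,
            "tag": scenario.tag,
        },
        "thermo_profile": thermo.name,
        "c_tccho_gC_per_L": config.c_tccho,
        "obs_noise_sigma": config.obs_noise_sigma,
    }
    (outdir / "truth.yaml").write_text(yaml.safe_dump(manifest))
    return {"assays": assays, "chemistry": chem, "fields": fields,
            "observations": obs, "inp": inp, "manifest": manifest}
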