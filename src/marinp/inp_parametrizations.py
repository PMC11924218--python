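"""Ice-nucleating-particle parametrizations and aerosol-mode geometry.

Three INP schemes are exposed:

* **HSZ25-style** — polysaccharide mass times the CNT-derived site density per
  carbohydrate carbon, :func:`hsz25_inp`;
* **N15** — mineral-dust surface area times a CNT contact-angle-distribution
  surface-site density (soccer-ball-model family), via :func:`surface_inp`;
* **M18** — sea-spray surface area times an exponential-in-temperature
  surface-site density, via :func:`surface_inp`.

Aerosol surface area is derived from mode mass and number assuming lognormal
modes (:func:`mode_surface_area`).  Scheme coefficients live in named,
configurable profiles rather than inside the operations; the shipped N15/M18
defaults are declared assumptions citing their source publications.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cnt_model import (
    CNTParams,
    ThermoParams,
    T_MELT,
    WATER_ICE_DEFAULT,
    site_activation_probability,
)

__all__ = [
    "ModeSpec",
    "MODE_DEFAULTS",
    "SurfaceParam",
    "N15_DUST",
    "M18_SEASPRAY",
    "mode_surface_area",
    "surface_inp",
    "hsz25_inp",
    "DEFAULT_CARBON_FRACTION",
]

#: default polysaccharide carbon mass fraction (glucan-like CH2O stoichiometry
#: ~0.44, rounded conservatively); the aerosol carries polysaccharide mass,
#: the HSZ25 site density is per carbohydrate *carbon* mass.
DEFAULT_CARBON_FRACTION = 0.40


@dataclass(frozen=True)
class ModeSpec:
    """Lognormal aerosol mode geometry."""

    name: str
    sigma_g: float   # geometric standard deviation, > 1
    density: float   # particle density [kg m^-3]

    def __post_init__(self):
        if self.sigma_g <= 1.0:
            raise ValueError("sigma_g must be > 1")
        if self.density <= 0.0:
            raise ValueError("density must be > 0")


MODE_DEFAULTS = {
    "seasalt_accu": ModeSpec("soluble_accumulation", 1.59, 2200.0),
    "seasalt_coarse": ModeSpec("soluble_coarse", 2.0, 2200.0),
    "dust_accu": ModeSpec("insoluble_accumulation", 1.59, 2650.0),
    "dust_coarse": ModeSpec("insoluble_coarse", 2.0, 2650.0),
}


def mode_surface_area(mass_conc, number_conc, mode: ModeSpec):
    """Surface-area concentration [m^2 per m^3 air] of a lognormal mode.

    From mass M [kg m^-3] and number N [m^-3], the count-median diameter is
    d_g = (6 M / (pi rho N))^(1/3) exp(-1.5 ln^2 sigma_g) and the total
    surface is S = N pi d_g^2 exp(2 ln^2 sigma_g).  Returns 0 where either
    proxy is 0.  Works elementwise on arrays (including xarray objects).
    """
    M = np.asarray(mass_conc, dtype=float) if not hasattr(mass_conc, "dims") else mass_conc
    N = np.asarray(number_conc, dtype=float) if not hasattr(number_conc, "dims") else number_conc
    if np.any(np.asarray(M) < 0) or np.any(np.asarray(N) < 0):
        raise ValueError("mass and number concentrations must be >= 0")
    ln2 = math.log(mode.sigma_g) ** 2
    n_safe = N + (N <= 0)  # avoid 0-division; masked out below
    d_g = (6.0 * M / (math.pi * mode.density * n_safe)) ** (1.0 / 3.0) * math.exp(
        -1.5 * ln2
    )
    s = N * math.pi * d_g**2 * math.exp(2.0 * ln2)
    return s * ((M > 0) & (N > 0))


@dataclass(frozen=True)
class SurfaceParam:
    """Named surface-site-density scheme n_s(T) [m^-2].

    ``scheme="M18"`` uses the exponential form
    n_s(T) = exp(slope_per_K * (T - 273.15) + intercept); ``scheme="N15"``
    carries an embedded CNT contact-angle profile on a per-area site budget.
    """

    scheme: str
    coefficients: dict
    validity: tuple  # (T_min, T_max) [K]
    name: str = ""

    def cnt_params(self) -> CNTParams:
        if self.scheme != "N15":
            raise ValueError("cnt_params only defined for the N15 scheme")
        c = self.coefficients
        return CNTParams(
            mu_theta=c["mu_theta_rad"],
            sigma_theta=c["sigma_theta_rad"],
            n_max=c["ns_max_per_m2"],
            a_site=c["a_site_m2"],
            delta_t=c["delta_t_s"],
            basis="per_m2",
        )

    def n_s(self, T, thermo: ThermoParams = WATER_ICE_DEFAULT, clamp: bool = False):
        """Surface site density [m^-2] at temperature(s) T [K]."""
        T = np.asarray(T, dtype=float)
        lo, hi = self.validity
        if clamp:
            T = np.clip(T, lo, hi)
        elif np.any(T < lo) or np.any(T > hi):
            raise ValueError(
                f"T outside validity range {self.validity} K of scheme "
                f"{self.scheme}; no extrapolation (pass clamp=True to pin at "
                "the validity edge)"
            )
        if self.scheme == "M18":
            c = self.coefficients
            val = np.exp(c["slope_per_K"] * (T - T_MELT) + c["intercept"])
        elif self.scheme == "N15":
            p = self.cnt_params()
            val = p.n_max * np.atleast_1d(
                site_activation_probability(np.atleast_1d(T), p, thermo)
            )
            val = val.reshape(T.shape) if T.shape else val[0]
        else:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        return val if np.ndim(val) else float(val)


#: Mineral-dust surface-site profile in the contact-angle-distribution form of
#: Niedermeier et al. (2015).  The coefficient values are this package's
#: declared defaults (the source coefficients are not reprinted here);
#: magnitudes give n_s(-15 C) ~ 1e7 m^-2 and n_s(-25 C) ~ 1.5e9 m^-2,
#: consistent with desert-dust surface-site observations.
N15_DUST = SurfaceParam(
    scheme="N15",
    coefficients={
        "mu_theta_rad": 2.1,
        "sigma_theta_rad": 0.3,
        "ns_max_per_m2": 1.0e11,
        "a_site_m2": 1.0e-14,
        "delta_t_s": 60.0,
    },
    validity=(236.0, 272.0),
    name="n15-dust-v1",
)

#: Sea-spray surface-site profile, exponential form of McCluskey et al. (2018):
#: n_s(T) = exp(-0.545 (T - 273.15) + 1.0125) m^-2, for immersion freezing of
#: non-heat-labile marine INPs.
M18_SEASPRAY = SurfaceParam(
    scheme="M18",
    coefficients={"slope_per_K": -0.545, "intercept": 1.0125},
    validity=(246.15, 268.15),
    name="m18-seaspray-v1",
)


def surface_inp(T, surface_area_conc, scheme: SurfaceParam,
                thermo: ThermoParams = WATER_ICE_DEFAULT, clamp: bool = False):
    """INP concentration [per litre air] from a surface-area proxy.

    N_INP(T) = S [m^2 m^-3] * n_s(T) [m^-2] / 1000.  Raises outside the
    scheme validity range unless ``clamp=True`` pins n_s at the validity
    edge (never extrapolates).
    """
    if np.any(np.asarray(surface_area_conc) < 0):
        raise ValueError("surface area concentration must be >= 0")
    return surface_area_conc * scheme.n_s(T, thermo, clamp=clamp) / 1000.0


def hsz25_inp(T, polysaccharide_mass_conc, carbon_fraction: float,
              params: CNTParams, thermo: ThermoParams = WATER_ICE_DEFAULT):
    """INP concentration [per litre air] from polysaccharide mass.

    The carbohydrate-carbon mass is m_C = carbon_fraction * polysaccharide
    mass [kg m^-3]; N_INP(T) = m_C [g m^-3] * n_m,C-TCCHO(T) [per g] / 1000.
    ``params`` must be fitted on the carbohydrate-carbon basis; applying the
    carbon fraction to any other basis is a unit error and raises.
    """
    if params.basis not in ("c_tccho", "per_c_tccho"):
        raise ValueError(
            f"basis mismatch: params are per {params.basis!r}, but the carbon "
            "fraction conversion requires a carbohydrate-carbon basis"
        )
    if not (0.0 < carbon_fraction <= 1.0):
        raise ValueError("carbon_fraction must lie in (0, 1]")
    if np.any(np.asarray(polysaccharide_mass_conc) < 0):
        raise ValueError("polysaccharide mass concentration must be >= 0")
    n_m = params.n_max * np.atleast_1d(
        site_activation_probability(np.atleast_1d(np.asarray(T, dtype=float)),
                                    params, thermo)
    )
    n_m = n_m if np.ndim(T) else float(n_m[0])
    m_c_grams = carbon_fraction * polysaccharide_mass_conc * 1000.0
    return m_c_grams * n_m / 1000.0
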