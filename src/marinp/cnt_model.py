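"""Classical nucleation theory (CNT) forward model for immersion freezing.

The model describes heterogeneous ice nucleation by a population of
nucleation-active sites whose efficiency is set by a contact angle ``theta``
drawn from a normal distribution truncated to (0, pi].  A site with contact
angle theta lowers the homogeneous nucleation barrier by the classical
spherical-cap compatibility factor

    f(theta) = (2 + cos theta) (1 - cos theta)^2 / 4,

so the heterogeneous nucleation rate per unit site area is

    j_het(T, theta) = A_kin(T) exp(-[dF_diff(T) + f(theta) dG_hom(T)] / kB T),

with dG_hom the homogeneous Gibbs barrier built from the ice-water
interfacial energy, the molecular volume of ice and the water/ice chemical
potential difference.  Integrating the single-exposure activation
probability over the contact-angle distribution gives the fraction of sites
active at temperature T, and scaling by the site budget ``n_max`` gives the
ice-nucleation site density n_m(T) per gram of the normalization basis
(e.g. carbohydrate carbon).  The site density saturates at n_max at deep
supercooling, which is the feature that distinguishes this model family from
log-linear INP fits and prevents unbounded extrapolation.

Thermodynamic ingredients are bundled in :class:`ThermoParams`; the shipped
default profile combines standard literature forms (see ``WATER_ICE_DEFAULT``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "KB",
    "H_PLANCK",
    "N_AVOGADRO",
    "M_WATER",
    "T_MELT",
    "ThermoParams",
    "WATER_ICE_DEFAULT",
    "CNTParams",
    "compatibility_factor",
    "j_het",
    "j_hom",
    "ActivationTable",
    "site_activation_probability",
    "site_density_curve",
    "predict_frozen_fraction",
]

KB = 1.380649e-23          # Boltzmann constant [J/K]
H_PLANCK = 6.62607015e-34  # Planck constant [J s]
N_AVOGADRO = 6.02214076e23
M_WATER = 18.015e-3        # molar mass of water [kg/mol]
T_MELT = 273.15            # melting point of water [K]


def _ln_psat_liquid(T):
    """ln of saturation vapor pressure over supercooled liquid water [Pa].

    Murphy & Koop (2005) formulation, valid 123-332 K.
    """
    T = np.asarray(T, dtype=float)
    return (
        54.842763
        - 6763.22 / T
        - 4.210 * np.log(T)
        + 0.000367 * T
        + np.tanh(0.0415 * (T - 218.8))
        * (53.878 - 1331.22 / T - 9.44523 * np.log(T) + 0.014025 * T)
    )


def _ln_psat_ice(T):
    """ln of saturation vapor pressure over hexagonal ice [Pa] (Murphy & Koop 2005)."""
    T = np.asarray(T, dtype=float)
    return 9.550426 - 5723.265 / T + 3.53068 * np.log(T) - 0.00728332 * T


@dataclass(frozen=True)
class ThermoParams:
    """Named, versioned thermodynamic coefficient set for the CNT rate.

    Parameters
    ----------
    name:
        Profile identifier recorded with every fit.
    sigma_iw_0, sigma_iw_slope:
        Ice-water interfacial energy sigma_iw(T) = sigma_iw_0 +
        sigma_iw_slope * (T - 273.15) in J m^-2 (Pruppacher & Klett form).
    vft_e, vft_t0:
        Vogel-Fulcher-Tammann coefficients [K] of water self-diffusion; the
        diffusion-activation energy is dF_diff(T) = kB * vft_e * T^2 /
        (T - vft_t0)^2 (Zobrist-type formulation).
    n_contact:
        Number density of water molecules in contact with a unit substrate
        area [m^-2]; the kinetic prefactor is A_kin(T) = (kB T / h) * n_contact.
    t_valid:
        Closed validity interval [K].  Evaluation outside raises ``ValueError``.
    """

    name: str = "water-ice-cnt-v1"
    sigma_iw_0: float = 28.0e-3     # J m^-2 at 0 C
    sigma_iw_slope: float = 0.25e-3  # J m^-2 K^-1
    vft_e: float = 892.0            # K
    vft_t0: float = 118.0           # K
    n_contact: float = 1.0e19       # m^-2
    t_valid: tuple = (235.0, T_MELT)

    def check_range(self, T) -> None:
        T = np.asarray(T, dtype=float)
        lo, hi = self.t_valid
        if np.any(T < lo) or np.any(T > hi):
            raise ValueError(
                f"temperature outside validity range {self.t_valid} K of "
                f"thermo profile {self.name!r}"
            )

    def sigma_iw(self, T):
        """Ice-water interfacial energy [J m^-2]."""
        T = np.asarray(T, dtype=float)
        return self.sigma_iw_0 + self.sigma_iw_slope * (T - T_MELT)

    def delta_mu(self, T):
        """Water-ice chemical potential difference per molecule [J].

        kB T ln(p_sat,liquid / p_sat,ice); <= 0 at and above melting.
        """
        T = np.asarray(T, dtype=float)
        return KB * T * (_ln_psat_liquid(T) - _ln_psat_ice(T))

    def v_ice(self, T):
        """Volume per molecule in ice [m^3] (Pruppacher & Klett ice density)."""
        Tc = np.asarray(T, dtype=float) - T_MELT
        rho = 916.7 - 0.175 * Tc - 5.0e-4 * Tc**2
        return M_WATER / (N_AVOGADRO * rho)

    def delta_f_diff(self, T):
        """Diffusion-activation energy [J] from the VFT water self-diffusivity."""
        T = np.asarray(T, dtype=float)
        return KB * self.vft_e * T**2 / (T - self.vft_t0) ** 2

    def a_kin(self, T):
        """Kinetic prefactor [m^-2 s^-1]."""
        T = np.asarray(T, dtype=float)
        return KB * T / H_PLANCK * self.n_contact

    def delta_g_hom(self, T):
        """Homogeneous nucleation barrier [J]; +inf at/above melting (dmu <= 0)."""
        T = np.asarray(T, dtype=float)
        dmu = self.delta_mu(T)
        with np.errstate(divide="ignore"):
            out = np.where(
                dmu > 0.0,
                (16.0 * math.pi / 3.0)
                * self.sigma_iw(T) ** 3
                * self.v_ice(T) ** 2
                / np.where(dmu > 0.0, dmu, 1.0) ** 2,
                np.inf,
            )
        return out


WATER_ICE_DEFAULT = ThermoParams()


@dataclass(frozen=True)
class CNTParams:
    """Contact-angle distribution and site-budget parameters of one freezing model.

    ``n_max`` is the total density of nucleation-active sites per gram of the
    normalization basis (``basis="c_tccho"`` for the carbohydrate-carbon-mass
    basis of the polysaccharide parametrization; ``"per_m2"`` for surface-area
    bases as used for mineral dust).  ``a_site`` and ``delta_t`` pin the
    kinetic exposure (site area times nucleation time per temperature step)
    and trade off exactly against ``mu_theta``/``n_max``, so they are recorded
    with every fit.
    """

    mu_theta: float            # mean contact angle [rad]
    sigma_theta: float         # contact-angle spread [rad]
    n_max: float               # site budget [sites per gram of basis]
    a_site: float = 1.0e-14    # per-site nucleation-active area [m^2]
    delta_t: float = 60.0      # effective nucleation time per 1-K step [s]
    basis: str = "c_tccho"

    def __post_init__(self):
        if not (0.0 < self.mu_theta < math.pi):
            raise ValueError("mu_theta must lie in (0, pi)")
        if self.sigma_theta <= 0.0:
            raise ValueError("sigma_theta must be > 0")
        if self.n_max < 0.0:
            raise ValueError("n_max must be >= 0")
        if self.a_site <= 0.0 or self.delta_t <= 0.0:
            raise ValueError("a_site and delta_t must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


def compatibility_factor(theta):
    """Spherical-cap geometric factor f(theta) = (2 + cos t)(1 - cos t)^2 / 4.

    Reduces the homogeneous barrier to f(theta) * dG_hom; 0 at perfect
    wetting (theta = 0) and 1 in the homogeneous limit (theta = pi).
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < -1e-12) or np.any(theta > math.pi + 1e-12):
        raise ValueError("contact angle must lie in [0, pi]")
    c = np.cos(theta)
    return (2.0 + c) * (1.0 - c) ** 2 / 4.0


def _d_compatibility(theta):
    """d f / d theta = (3/4) sin^3 theta."""
    return 0.75 * np.sin(theta) ** 3


def j_het(T, theta, thermo: ThermoParams = WATER_ICE_DEFAULT):
    """Heterogeneous nucleation rate per unit site area [m^-2 s^-1].

    Broadcasts over ``T`` and ``theta``.  Defined as 0 where the water-ice
    chemical potential difference is <= 0 (no supercooling).
    """
    thermo.check_range(T)
    T = np.asarray(T, dtype=float)
    f = compatibility_factor(theta)
    dmu = thermo.delta_mu(T)
    kt = KB * T
    with np.errstate(over="ignore", invalid="ignore"):
        barrier = thermo.delta_f_diff(T) + f * thermo.delta_g_hom(T)
        j = thermo.a_kin(T) * np.exp(-barrier / kt)
    j = np.where(dmu > 0.0, j, 0.0)
    return j if j.shape else float(j)


def j_hom(T, thermo: ThermoParams = WATER_ICE_DEFAULT):
    """Homogeneous nucleation rate per unit area [m^-2 s^-1] (theta = pi limit)."""
    thermo.check_range(T)
    T = np.asarray(T, dtype=float)
    dmu = thermo.delta_mu(T)
    kt = KB * T
    barrier = thermo.delta_f_diff(T) + thermo.delta_g_hom(T)
    j = thermo.a_kin(T) * np.exp(-barrier / kt)
    j = np.where(dmu > 0.0, j, 0.0)
    return j if j.shape else float(j)


# ---------------------------------------------------------------------------
# Contact-angle quadrature
#
# The integrand p(theta) * [1 - exp(-j a dt)] contains an "activation front":
# 1 - exp(-h) switches from ~1 to ~0 over a theta interval of width
# w = kB T / (dG_hom * f'(theta*)), typically ~0.01 rad.  A composite
# Gauss-Legendre rule with panels refined around the front integrates this to
# ~1e-10 relative; the front position depends only on (T, thermo, a_site,
# delta_t), not on the distribution parameters, so the exposure factor
# g(theta, T) can be precomputed once and reused for every (mu, sigma)
# evaluation during fitting.
# ---------------------------------------------------------------------------

_GL8 = np.polynomial.legendre.leggauss(8)


def _panel_nodes(edges: np.ndarray):
    """Gauss-Legendre 8-point nodes/weights on each panel defined by edges."""
    x, w = _GL8
    lo = edges[:-1]
    hi = edges[1:]
    half = 0.5 * (hi - lo)
    mid = 0.5 * (hi + lo)
    nodes = (mid[:, None] + half[:, None] * x[None, :]).ravel()
    weights = (half[:, None] * w[None, :]).ravel()
    return nodes, weights


def _front_theta(T: float, thermo: ThermoParams, a_site: float, delta_t: float):
    """Contact angle theta* where j_het * a_site * delta_t = 1, or None.

    Returns (theta*, front_width) when the activation front lies inside
    (0, pi), else (None, None).
    """
    kt = KB * T
    dg = float(thermo.delta_g_hom(T))
    if not np.isfinite(dg):
        return None, None
    log_exposure = math.log(thermo.a_kin(T) * a_site * delta_t)
    c = (kt * log_exposure - float(thermo.delta_f_diff(T))) / dg
    if c <= 0.0 or c >= 1.0:
        return None, None
    theta_star = brentq(lambda t: float(compatibility_factor(t)) - c, 0.0, math.pi)
    slope = max(float(_d_compatibility(theta_star)), 1e-3)
    width = kt / (dg * slope)
    return theta_star, min(max(width, 1e-6), 0.5)


def _quadrature_nodes(T: float, thermo: ThermoParams, a_site: float,
                      delta_t: float, dist_window=None):
    """Composite-GL nodes, weights and exposure factor g on [0, pi] for one T.

    ``dist_window`` optionally refines around the contact-angle distribution
    support (needed when sigma_theta is below the base panel width).
    """
    theta_star, width = _front_theta(T, thermo, a_site, delta_t)
    edges = [np.linspace(0.0, math.pi, 65)]
    if theta_star is not None:
        lo = max(0.0, theta_star - 30.0 * width)
        hi = min(math.pi, theta_star + 30.0 * width)
        if hi > lo:
            edges.append(np.linspace(lo, hi, 41))
    if dist_window is not None:
        lo = max(0.0, dist_window[0])
        hi = min(math.pi, dist_window[1])
        if hi > lo:
            edges.append(np.linspace(lo, hi, 41))
    all_edges = np.unique(np.concatenate(edges))
    nodes, weights = _panel_nodes(all_edges)
    h = j_het(T, nodes, thermo) * a_site * delta_t
    g = -np.expm1(-h)
    return nodes, weights, g


class ActivationTable:
    """Precomputed contact-angle quadrature for a fixed temperature grid.

    Stores, for every grid temperature, the quadrature nodes/weights and the
    single-exposure activation factor g(theta, T) = 1 - exp(-j a_site dt),
    which is independent of the contact-angle distribution.  Evaluating the
    site-activation probability for given (mu_theta, sigma_theta) then costs
    one truncated-normal density evaluation.
    """

    def __init__(self, temperature_grid, thermo: ThermoParams = WATER_ICE_DEFAULT,
                 a_site: float = 1.0e-14, delta_t: float = 60.0,
                 dist_hint=None):
        grid = np.asarray(temperature_grid, dtype=float)
        if grid.ndim != 1 or grid.size == 0:
            raise ValueError("temperature grid must be a non-empty 1-D array")
        thermo.check_range(grid)
        self.temperature_grid = grid
        self.thermo = thermo
        self.a_site = float(a_site)
        self.delta_t = float(delta_t)
        window = None
        if dist_hint is not None:
            mu, sigma = dist_hint
            window = (mu - 8.0 * sigma, mu + 8.0 * sigma)
        per_t = [_quadrature_nodes(float(t), thermo, self.a_site, self.delta_t,
                                   dist_window=window)
                 for t in grid]
        n_nodes = max(n.size for n, _, _ in per_t)
        self._nodes = np.zeros((grid.size, n_nodes))
        self._wg = np.zeros((grid.size, n_nodes))  # weight * g, fused
        for i, (n, w, g) in enumerate(per_t):
            self._nodes[i, : n.size] = n
            self._wg[i, : n.size] = w * g

    def p_site(self, mu_theta: float, sigma_theta: float) -> np.ndarray:
        """Site-activation probability on the stored grid."""
        from scipy.stats import norm

        z_norm = norm.cdf((math.pi - mu_theta) / sigma_theta) - norm.cdf(
            -mu_theta / sigma_theta
        )
        if z_norm <= 0.0:
            raise ValueError("truncated-normal mass on (0, pi] vanished")
        z = (self._nodes - mu_theta) / sigma_theta
        pdf = np.exp(-0.5 * z * z) / (sigma_theta * math.sqrt(2.0 * math.pi) * z_norm)
        p = np.einsum("ij,ij->i", self._wg, pdf)
        if not np.all(np.isfinite(p)) or np.any(p < -1e-9) or np.any(p > 1.0 + 1e-9):
            raise ArithmeticError(
                "contact-angle quadrature produced an invalid probability: "
                f"range [{p.min()}, {p.max()}] for mu={mu_theta}, sigma={sigma_theta}"
            )
        return np.clip(p, 0.0, 1.0)


def site_activation_probability(T, params: CNTParams,
                                thermo: ThermoParams = WATER_ICE_DEFAULT):
    """Probability that a single site is ice-active at temperature T.

    Integrates the single-exposure activation probability
    1 - exp(-j_het(T, theta) a_site delta_t) over the truncated-normal
    contact-angle distribution (renormalized on (0, pi]).  Composite
    Gauss-Legendre quadrature with panels refined around the activation
    front; validated against a dense brute-force integral to ~1e-9 relative.
    """
    T = np.atleast_1d(np.asarray(T, dtype=float))
    table = ActivationTable(T, thermo, params.a_site, params.delta_t,
                            dist_hint=(params.mu_theta, params.sigma_theta))
    p = table.p_site(params.mu_theta, params.sigma_theta)
    return p if p.size > 1 else float(p[0])


def site_density_curve(params: CNTParams, thermo: ThermoParams,
                       temperature_grid) -> np.ndarray:
    """Ice-nucleation site density n_m(T) = n_max * P_site(T) [per gram basis]."""
    grid = np.asarray(temperature_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("temperature grid must be a non-empty 1-D array")
    if grid.size > 1 and not np.all(np.diff(grid) < 0):
        raise ValueError("temperature grid must be strictly descending")
    p = np.atleast_1d(site_activation_probability(grid, params, thermo))
    return params.n_max * p


def predict_frozen_fraction(params: CNTParams, thermo: ThermoParams,
                            c_basis: float, droplet_volume: float,
                            dilution: float, temperature_grid) -> np.ndarray:
    """Forward-modeled frozen fraction of assay droplets on a descending grid.

    lambda(T) = n_m(T) * c_basis * droplet_volume / dilution is the expected
    number of active sites per droplet; f(T) = 1 - exp(-lambda).  This is the
    exact inverse of the Vali cumulative-spectrum transform.
    """
    if c_basis <= 0.0:
        raise ValueError("basis concentration must be > 0")
    if droplet_volume <= 0.0 or dilution < 1.0:
        raise ValueError("need droplet_volume > 0 and dilution >= 1")
    n_m = site_density_curve(params, thermo, temperature_grid)
    lam = n_m * c_basis * droplet_volume / dilution
    return -np.expm1(-lam)
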